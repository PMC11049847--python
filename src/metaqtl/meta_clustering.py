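"""Per-chromosome Gaussian-mixture clustering of projected QTL into meta-QTL.

The defining feature of the meta-QTL model is that each observation (a
projected QTL position x_i, in cM) comes with a *known* Gaussian variance
s_i² derived from its 95% CI (s_i = CI_i / 3.92).  A K-component mixture

    L = Σ_i log Σ_k π_k N(x_i; μ_k, s_i²)

is fitted by EM for each candidate K; only the K means and K−1 weights are
free (p = 2K − 1 parameters).  The number of meta-QTL per chromosome is
chosen by majority vote of five information criteria (AIC, AICc, AIC3, BIC,
AWE), each voting for its minimizing K, with ties broken toward smaller K.
Each QTL is then assigned to its maximum-responsibility component and the
consensus position and CI of a meta-QTL follow from precision weighting:
the consensus variance 1/Σ(1/s_i²) shrinks as member precisions add, which
is why meta-QTL intervals are narrower than any member QTL interval.
"""
from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .projection import ProjectedQTL

__all__ = [
    "MixtureModel",
    "MQTL",
    "ChromosomeResult",
    "MQTLSummary",
    "mixture_loglik",
    "fit_mixture",
    "criterion_values",
    "select_K",
    "consensus_mqtl",
    "cluster_chromosome",
    "meta_analyze",
    "summarize_mqtl",
]

log = logging.getLogger(__name__)

CRITERIA = ("AIC", "AICc", "AIC3", "BIC", "AWE")

DEFAULT_SEED = 20240412
DEFAULT_N_STARTS = 10
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 500

_LOG_2PI = math.log(2.0 * math.pi)


def _component_logpdf(x: np.ndarray, s2: np.ndarray,
                      means: np.ndarray) -> np.ndarray:
    """(n, K) matrix of log N(x_i; mu_k, s_i^2)."""
    d = x[:, None] - means[None, :]
    return -0.5 * (_LOG_2PI + np.log(s2)[:, None] + d * d / s2[:, None])


def mixture_loglik(positions: Sequence[float], variances: Sequence[float],
                   weights: Sequence[float], means: Sequence[float]) -> float:
    """Log-likelihood Σ_i log Σ_k π_k N(x_i; μ_k, s_i²).

    Per-observation variances are known inputs, never estimated.
    """
    x = np.asarray(positions, float)
    s2 = np.asarray(variances, float)
    w = np.asarray(weights, float)
    mu = np.asarray(means, float)
    if np.any(s2 <= 0):
        raise ValueError("variances must be strictly positive")
    if x.shape != s2.shape or w.shape != mu.shape:
        raise ValueError("shape mismatch")
    lp = _component_logpdf(x, s2, mu) + np.log(np.maximum(w, 1e-300))[None, :]
    return float(np.sum(logsumexp(lp, axis=1)))


@dataclass
class MixtureModel:
    """A fitted known-variance Gaussian mixture on one chromosome."""

    K: int
    weights: np.ndarray
    means: np.ndarray            # sorted ascending
    positions: np.ndarray
    variances: np.ndarray
    log_likelihood: float
    responsibilities: np.ndarray  # (n, K)
    n_iter: int = 0
    converged: bool = True

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def n_parameters(self) -> int:
        return 2 * self.K - 1

    def classification_loglik(self) -> float:
        """Complete-data log-likelihood with hard max-responsibility labels."""
        lp = (_component_logpdf(self.positions, self.variances, self.means)
              + np.log(np.maximum(self.weights, 1e-300))[None, :])
        z = np.argmax(self.responsibilities, axis=1)
        return float(lp[np.arange(self.n), z].sum())


def _em(x: np.ndarray, s2: np.ndarray, means0: np.ndarray,
        tol: float, max_iter: int) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    K = len(means0)
    mu = means0.astype(float).copy()
    w = np.full(K, 1.0 / K)
    prev_ll = -np.inf
    converged = False
    it = 0
    inv_s2 = 1.0 / s2
    for it in range(1, max_iter + 1):
        lp = _component_logpdf(x, s2, mu) + np.log(np.maximum(w, 1e-300))[None, :]
        norm = logsumexp(lp, axis=1)
        ll = float(norm.sum())
        # EM guarantee: the observed-data log-likelihood never decreases
        assert ll >= prev_ll - 1e-9, "EM log-likelihood decreased"
        r = np.exp(lp - norm[:, None])
        if ll - prev_ll < tol and it > 1:
            prev_ll = ll
            converged = True
            break
        prev_ll = ll
        # M-step: precision-weighted means, mean responsibilities as weights
        denom = r.T @ inv_s2
        numer = r.T @ (x * inv_s2)
        alive = denom > 1e-300
        mu[alive] = numer[alive] / denom[alive]
        w = r.mean(axis=0)
    return w, mu, prev_ll, it, converged


def _init_means(x: np.ndarray, s2: np.ndarray, K: int,
                rng: np.random.Generator, n_starts: int) -> list[np.ndarray]:
    """Quantile start plus K-means++-style random starts."""
    starts = [np.quantile(x, (np.arange(K) + 0.5) / K)]
    for _ in range(max(0, n_starts - 1)):
        means = [x[rng.integers(len(x))]]
        while len(means) < K:
            d2 = np.min((x[:, None] - np.array(means)[None, :]) ** 2, axis=1)
            total = d2.sum()
            if total <= 0:
                means.append(x[rng.integers(len(x))])
            else:
                means.append(x[rng.choice(len(x), p=d2 / total)])
        starts.append(np.array(sorted(means)))
    return starts


def fit_mixture(positions: Sequence[float], variances: Sequence[float], K: int,
                n_starts: int = DEFAULT_N_STARTS,
                rng: np.random.Generator | int | None = None,
                tol: float = DEFAULT_TOL,
                max_iter: int = DEFAULT_MAX_ITER) -> MixtureModel:
    """Fit the known-variance K-component mixture by multi-start EM.

    K = 1 is closed-form (the precision-weighted mean).  For K > 1, the best
    of ``n_starts`` runs (one quantile start plus K-means++-style random
    starts) is returned, with components sorted by mean.
    """
    x = np.asarray(positions, float)
    s2 = np.asarray(variances, float)
    if np.any(s2 <= 0):
        raise ValueError("variances must be strictly positive")
    n = len(x)
    if K < 1 or n < K:
        raise ValueError(f"infeasible K={K} for n={n}")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(DEFAULT_SEED if rng is None else rng)

    if K == 1:
        mu = float(np.sum(x / s2) / np.sum(1.0 / s2))
        w = np.ones(1)
        ll = mixture_loglik(x, s2, w, [mu])
        return MixtureModel(K=1, weights=w, means=np.array([mu]),
                            positions=x, variances=s2, log_likelihood=ll,
                            responsibilities=np.ones((n, 1)))

    best = None
    for means0 in _init_means(x, s2, K, rng, n_starts):
        w, mu, ll, it, conv = _em(x, s2, means0, tol, max_iter)
        if best is None or ll > best[2]:
            best = (w, mu, ll, it, conv)
    w, mu, ll, it, conv = best
    order = np.argsort(mu, kind="stable")
    mu, w = mu[order], w[order]
    lp = _component_logpdf(x, s2, mu) + np.log(np.maximum(w, 1e-300))[None, :]
    norm = logsumexp(lp, axis=1)
    r = np.exp(lp - norm[:, None])
    ll = float(norm.sum())  # consistent with the returned parameters
    return MixtureModel(K=K, weights=w, means=mu, positions=x, variances=s2,
                        log_likelihood=ll, responsibilities=r,
                        n_iter=it, converged=conv)


def criterion_values(model: MixtureModel, n: int | None = None) -> dict[str, float]:
    """The five information criteria for one fitted model.

    With variances known, the free-parameter count is p = 2K − 1 (K means and
    K − 1 independent weights).  AWE uses the classification (complete-data)
    log-likelihood with the Banfield–Raftery penalty 2p(3/2 + ln n).  AICc is
    undefined (NaN) when n ≤ p + 1.
    """
    n = model.n if n is None else n
    p = model.n_parameters
    m2ll = -2.0 * model.log_likelihood
    aic = m2ll + 2 * p
    aicc = aic + 2 * p * (p + 1) / (n - p - 1) if n > p + 1 else float("nan")
    aic3 = m2ll + 3 * p
    bic = m2ll + p * math.log(n)
    awe = -2.0 * model.classification_loglik() + 2 * p * (1.5 + math.log(n))
    return {"K": model.K, "p": p, "loglik": model.log_likelihood,
            "AIC": aic, "AICc": aicc, "AIC3": aic3, "BIC": bic, "AWE": awe}


def select_K(table: pd.DataFrame) -> tuple[int, dict[str, int]]:
    """Majority vote of the five criteria, each voting for its argmin K.

    Criteria whose values are all NaN abstain.  Ties in a criterion's argmin
    and in the overall vote are broken toward smaller K.  Returns
    ``(K_best, votes)``.
    """
    if len(table) == 0:
        raise ValueError("empty criterion table")
    table = table.sort_values("K")
    votes: dict[str, int] = {}
    for crit in CRITERIA:
        vals = table[crit].to_numpy(float)
        if np.all(np.isnan(vals)):
            continue
        k_idx = int(np.nanargmin(vals))  # first minimum → smallest K on ties
        votes[crit] = int(table["K"].iloc[k_idx])
    if not votes:
        raise ValueError("no criterion produced a finite value")
    counts = Counter(votes.values())
    top = max(counts.values())
    k_best = min(k for k, c in counts.items() if c == top)
    return k_best, votes


@dataclass
class MQTL:
    """A consensus locus: precision-weighted position and 95% CI on the
    reference map, plus its member QTL."""

    mqtl_id: str
    chromosome: int
    consensus_position: float
    ci95_lo: float
    ci95_hi: float
    member_qtl_ids: list[str]
    traits: list[str] = field(default_factory=list)
    variance: float = float("nan")

    @property
    def n_members(self) -> int:
        return len(self.member_qtl_ids)

    @property
    def n_traits(self) -> int:
        return len(set(self.traits))

    @property
    def ci_width(self) -> float:
        return self.ci95_hi - self.ci95_lo


def _assign_members(model: MixtureModel) -> np.ndarray:
    """Maximum-responsibility assignment; ties toward the nearer mean, then
    the lower component index."""
    r = model.responsibilities
    z = np.empty(model.n, dtype=int)
    for i in range(model.n):
        row = r[i]
        best = row.max()
        cand = np.flatnonzero(np.isclose(row, best, rtol=0, atol=1e-12))
        if len(cand) > 1:
            dist = np.abs(model.means[cand] - model.positions[i])
            cand = cand[dist == dist.min()]
        z[i] = cand[0]
    return z


def consensus_mqtl(model: MixtureModel, qtls: Sequence[ProjectedQTL],
                   z95: float = 1.96) -> list[MQTL]:
    """Collapse a fitted model into consensus meta-QTL.

    Members go to their maximum-responsibility component; the consensus
    position is the precision-weighted mean of member positions, the
    consensus variance is 1/Σ(1/s_i²), and the 95% CI is ±1.96 sd.  Empty
    components are dropped (K effectively decremented).  MQTL are numbered
    left to right as ``MQTL{chr}_{index}``.
    """
    if len(qtls) != model.n:
        raise ValueError("qtls and model size mismatch")
    z = _assign_members(model)
    chrom = qtls[0].chromosome
    out: list[MQTL] = []
    for k in range(model.K):
        idx = np.flatnonzero(z == k)
        if len(idx) == 0:
            log.info("chromosome %d: empty component %d dropped", chrom, k)
            continue
        x = model.positions[idx]
        s2 = model.variances[idx]
        prec = 1.0 / s2
        var = 1.0 / prec.sum()
        pos = float((x * prec).sum() * var)
        sd = math.sqrt(var)
        out.append(MQTL(
            mqtl_id="",  # assigned after sorting
            chromosome=chrom,
            consensus_position=pos,
            ci95_lo=pos - z95 * sd,
            ci95_hi=pos + z95 * sd,
            member_qtl_ids=[qtls[i].qtl_id for i in idx],
            traits=[qtls[i].record.trait for i in idx],
            variance=var,
        ))
    out.sort(key=lambda m: m.consensus_position)
    for i, m in enumerate(out, start=1):
        m.mqtl_id = f"MQTL{chrom}_{i}"
    return out


@dataclass
class ChromosomeResult:
    chromosome: int
    mqtls: list[MQTL]
    criterion_table: pd.DataFrame
    votes: dict[str, int]
    K_selected: int
    model: MixtureModel


def cluster_chromosome(qtls: Sequence[ProjectedQTL],
                       k_max: int = 10,
                       n_starts: int = DEFAULT_N_STARTS,
                       seed: int = DEFAULT_SEED,
                       tol: float = DEFAULT_TOL,
                       max_iter: int = DEFAULT_MAX_ITER) -> ChromosomeResult:
    """Fit K = 1..min(n, k_max), select K by criterion vote, build MQTL."""
    qtls = [q for q in qtls if q.ref_position is not None]
    if not qtls:
        raise ValueError("no projected QTL on this chromosome")
    chrom = qtls[0].chromosome
    x = np.array([q.ref_position for q in qtls], float)
    s2 = np.array([q.ref_variance for q in qtls], float)
    rng = np.random.default_rng(seed + chrom)

    rows = []
    models: dict[int, MixtureModel] = {}
    for K in range(1, min(len(qtls), k_max) + 1):
        model = fit_mixture(x, s2, K, n_starts=n_starts, rng=rng,
                            tol=tol, max_iter=max_iter)
        models[K] = model
        rows.append(criterion_values(model))
    table = pd.DataFrame(rows)
    k_best, votes = select_K(table)
    mqtls = consensus_mqtl(models[k_best], qtls)
    return ChromosomeResult(chromosome=chrom, mqtls=mqtls,
                            criterion_table=table, votes=votes,
                            K_selected=k_best, model=models[k_best])


def meta_analyze(projected: Sequence[ProjectedQTL],
                 k_max: int = 10,
                 n_starts: int = DEFAULT_N_STARTS,
                 seed: int = DEFAULT_SEED) -> dict[int, ChromosomeResult]:
    """Cluster every chromosome independently; returns chrom → result."""
    by_chrom: dict[int, list[ProjectedQTL]] = {}
    for q in projected:
        if q.ref_position is None:
            continue
        by_chrom.setdefault(q.chromosome, []).append(q)
    return {
        chrom: cluster_chromosome(qs, k_max=k_max, n_starts=n_starts, seed=seed)
        for chrom, qs in sorted(by_chrom.items())
    }


@dataclass
class MQTLSummary:
    """Genome-wide MQTL report: counts per chromosome and CI statistics."""

    n_mqtl: int
    per_chromosome: dict[int, int]
    mean_ci_cm: float
    mean_member_ci_cm: float
    fold_reduction: float
    n_ci_below: int            # MQTL with CI narrower than `ci_threshold`
    ci_threshold: float = 1.0
    n_singleton: int = 0


def summarize_mqtl(results: dict[int, "ChromosomeResult"],
                   ci_threshold: float = 1.0) -> MQTLSummary:
    """Aggregate clustering results the way meta-QTL studies report them:
    MQTL per chromosome, mean MQTL CI, and the fold reduction of the mean
    member-QTL CI relative to the mean MQTL CI."""
    mqtls = [m for res in results.values() for m in res.mqtls]
    widths = np.array([m.ci_width for m in mqtls], float)
    member_widths = []
    for res in results.values():
        member_widths.extend(
            3.92 * math.sqrt(v) for v in res.model.variances)
    member_widths = np.array(member_widths, float)
    mean_ci = float(widths.mean()) if len(widths) else float("nan")
    mean_member = float(member_widths.mean()) if len(member_widths) else float("nan")
    return MQTLSummary(
        n_mqtl=len(mqtls),
        per_chromosome={c: len(res.mqtls) for c, res in sorted(results.items())},
        mean_ci_cm=mean_ci,
        mean_member_ci_cm=mean_member,
        fold_reduction=mean_member / mean_ci if mean_ci > 0 else float("nan"),
        n_ci_below=int(np.sum(widths < ci_threshold)),
        ci_threshold=ci_threshold,
        n_singleton=sum(1 for m in mqtls if m.n_members == 1),
    )


def mqtl_table(results: dict[int, ChromosomeResult]) -> pd.DataFrame:
    """Flat MQTL output table (one row per meta-QTL)."""
    rows = []
    for res in results.values():
        for m in res.mqtls:
            rows.append({
                "mqtl_id": m.mqtl_id, "chr": m.chromosome,
                "pos_cM": m.consensus_position,
                "ci_lo_cM": m.ci95_lo, "ci_hi_cM": m.ci95_hi,
                "n_qtl": m.n_members, "n_traits": m.n_traits,
                "members": ",".join(m.member_qtl_ids),
            })
    return pd.DataFrame(rows)
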