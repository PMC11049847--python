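"""Known-variance Gaussian mixture, information criteria, and consensus MQTL."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from metaqtl.compendium import QTLRecord
from metaqtl.meta_clustering import (CRITERIA, MQTL, cluster_chromosome,
                                     consensus_mqtl, criterion_values,
                                     fit_mixture, meta_analyze, mixture_loglik,
                                     select_K, summarize_mqtl)
from metaqtl.projection import ProjectedQTL


def brute_force_loglik(x, s2, w, mu):
    """Direct double-sum evaluation, no vectorization or log-space tricks."""
    total = 0.0
    for xi, vi in zip(x, s2):
        mix = 0.0
        for wk, mk in zip(w, mu):
            mix += wk * math.exp(-(xi - mk) ** 2 / (2 * vi)) / math.sqrt(
                2 * math.pi * vi)
        total += math.log(mix)
    return total


def make_projected(positions, variances, chrom=1, traits=None):
    out = []
    for i, (x, v) in enumerate(zip(positions, variances)):
        w = 3.92 * math.sqrt(v)
        rec = QTLRecord(qtl_id=f"q{i}", study_id="S", trait=(traits[i] if traits
                                                             else "GY"),
                        chromosome=chrom, position=x, ci_start=x - w / 2,
                        ci_end=x + w / 2, lod=3.0, pve=10.0, pop_type="RIL",
                        pop_size=200, map_id="M", trait_category="GY")
        out.append(ProjectedQTL(record=rec, ref_position=x, ref_ci_lo=x - w / 2,
                                ref_ci_hi=x + w / 2, ref_variance=v,
                                projection_status="projected"))
    return out


class TestLoglik:
    def test_single_point_at_mean_closed_form(self):
        ll = mixture_loglik([5.0], [1.0], [1.0], [5.0])
        assert ll == pytest.approx(math.log(1 / math.sqrt(2 * math.pi)))

    def test_k1_maximized_at_precision_weighted_mean(self, rng):
        x = rng.uniform(0, 50, 12)
        s2 = rng.uniform(0.5, 9.0, 12)
        mu_star = np.sum(x / s2) / np.sum(1 / s2)
        best = mixture_loglik(x, s2, [1.0], [mu_star])
        for d in (-1.0, -0.1, 0.1, 1.0):
            assert mixture_loglik(x, s2, [1.0], [mu_star + d]) < best

    def test_matches_brute_force_oracle(self, rng):
        x = rng.uniform(0, 100, 10)
        s2 = rng.uniform(0.5, 20.0, 10)
        w = np.array([0.3, 0.7])
        mu = np.array([20.0, 70.0])
        assert mixture_loglik(x, s2, w, mu) == pytest.approx(
            brute_force_loglik(x, s2, w, mu), rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            mixture_loglik([1.0], [0.0], [1.0], [1.0])


class TestFitMixture:
    def test_k1_closed_form(self, rng):
        x = rng.uniform(0, 50, 8)
        s2 = rng.uniform(0.5, 5.0, 8)
        m = fit_mixture(x, s2, K=1)
        assert m.means[0] == pytest.approx(np.sum(x / s2) / np.sum(1 / s2))
        assert m.weights[0] == 1.0

    def test_two_tight_groups_recovered(self, rng):
        xa = rng.normal(10.0, 1.0, 10)
        xb = rng.normal(60.0, 1.0, 10)
        x = np.concatenate([xa, xb])
        s2 = np.ones(20)
        m = fit_mixture(x, s2, K=2, rng=rng)
        # group precision-weighted means computed directly
        assert m.means[0] == pytest.approx(xa.mean(), abs=0.1)
        assert m.means[1] == pytest.approx(xb.mean(), abs=0.1)

    def test_k_equals_n_attains_supremum_configuration(self):
        x = np.array([5.0, 30.0, 80.0])
        s2 = np.ones(3)
        m = fit_mixture(x, s2, K=3, n_starts=6, rng=1)
        assert np.allclose(np.sort(m.means), x, atol=1e-6)

    def test_infeasible_k_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            fit_mixture([1.0, 2.0], [1.0, 1.0], K=3)

    def test_order_invariance(self, rng):
        x = rng.uniform(0, 100, 15)
        s2 = rng.uniform(0.5, 9.0, 15)
        perm = rng.permutation(15)
        a = fit_mixture(x, s2, K=2, rng=0)
        b = fit_mixture(x[perm], s2[perm], K=2, rng=0)
        assert np.allclose(a.means, b.means, atol=1e-6)
        assert a.log_likelihood == pytest.approx(b.log_likelihood, abs=1e-8)

    def test_agrees_with_direct_numerical_optimization(self, rng):
        """Independent route: maximize the same likelihood with scipy."""
        x = np.concatenate([rng.normal(20, 2, 8), rng.normal(55, 2, 8)])
        s2 = np.full(16, 4.0)
        em = fit_mixture(x, s2, K=2, n_starts=8, rng=3)

        def neg_ll(theta):
            mu = theta[:2]
            w1 = 1 / (1 + np.exp(-theta[2]))
            return -mixture_loglik(x, s2, [w1, 1 - w1], mu)

        best = None
        for start in ([15.0, 50.0, 0.0], [25.0, 60.0, 0.5], [20.0, 55.0, -0.5]):
            r = minimize(neg_ll, start, method="Nelder-Mead",
                         options={"xatol": 1e-10, "fatol": 1e-12,
                                  "maxiter": 5000})
            if best is None or r.fun < best.fun:
                best = r
        assert em.log_likelihood == pytest.approx(-best.fun, abs=1e-6)
        assert np.allclose(np.sort(best.x[:2]), em.means, atol=1e-3)


class TestCriteria:
    def _model(self, ll=-20.0, K=1, n=10):
        x = np.linspace(0, 10, n)
        m = fit_mixture(x, np.ones(n), K=K)
        m.log_likelihood = ll
        return m

    def test_formula_arithmetic(self):
        # K=1, n=10, lnL=-20: p=1, AIC=42, BIC=40+ln10
        m = self._model()
        vals = criterion_values(m, n=10)
        assert vals["AIC"] == pytest.approx(42.0)
        assert vals["BIC"] == pytest.approx(40.0 + math.log(10))
        assert vals["AIC3"] == pytest.approx(43.0)

    @pytest.mark.parametrize("K", [1, 2, 3])
    def test_aic3_minus_aic_is_p(self, K, rng):
        x = rng.uniform(0, 100, 12)
        m = fit_mixture(x, np.ones(12), K=K, rng=0)
        vals = criterion_values(m)
        assert vals["AIC3"] - vals["AIC"] == pytest.approx(vals["p"])

    def test_aicc_missing_when_n_too_small(self):
        x = np.array([0.0, 5.0, 10.0, 20.0])
        m = fit_mixture(x, np.ones(4), K=2, rng=0)  # p=3, n=4 <= p+1
        assert math.isnan(criterion_values(m)["AICc"])

    def test_all_criteria_minimized_at_true_k(self, rng):
        # two well-separated clusters: every criterion should choose K=2
        x = np.concatenate([rng.normal(20, 1, 12), rng.normal(80, 1, 12)])
        s2 = np.ones(24)
        rows = [criterion_values(fit_mixture(x, s2, K=k, rng=0))
                for k in range(1, 6)]
        table = pd.DataFrame(rows)
        for crit in CRITERIA:
            assert int(table.loc[table[crit].idxmin(), "K"]) == 2


class TestSelectK:
    def _table(self, votes_by_crit):
        # build a criterion table whose per-criterion argmins equal the votes
        ks = range(1, 5)
        rows = []
        for k in ks:
            row = {"K": k}
            for crit, kbest in votes_by_crit.items():
                row[crit] = 0.0 if k == kbest else 10.0 + k
            rows.append(row)
        return pd.DataFrame(rows)

    def test_majority(self):
        t = self._table({"AIC": 2, "AICc": 2, "AIC3": 2, "BIC": 3, "AWE": 2})
        k, votes = select_K(t)
        assert k == 2 and votes["BIC"] == 3

    def test_tie_broken_toward_smaller_k(self):
        t = self._table({"AIC": 1, "AICc": 2, "AIC3": 1, "BIC": 2, "AWE": 3})
        k, _ = select_K(t)
        assert k == 1

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            select_K(pd.DataFrame())

    def test_single_qtl_chromosome_gives_singleton_mqtl(self):
        qtls = make_projected([42.0], [4.0])
        res = cluster_chromosome(qtls, k_max=10)
        assert res.K_selected == 1
        (m,) = res.mqtls
        assert m.n_members == 1
        # singleton MQTL inherits the member's CI
        assert m.ci95_lo == pytest.approx(42.0 - 1.96 * 2.0)
        assert m.ci95_hi == pytest.approx(42.0 + 1.96 * 2.0)


class TestConsensus:
    def test_two_member_closed_form(self):
        qtls = make_projected([10.0, 14.0], [4.0, 4.0])
        m = fit_mixture([10.0, 14.0], [4.0, 4.0], K=1)
        (mq,) = consensus_mqtl(m, qtls)
        assert mq.consensus_position == pytest.approx(12.0)
        assert mq.variance == pytest.approx(2.0)
        assert mq.ci95_lo == pytest.approx(12.0 - 1.96 * math.sqrt(2.0))
        assert mq.ci95_hi == pytest.approx(12.0 + 1.96 * math.sqrt(2.0))
        assert mq.mqtl_id == "MQTL1_1"

    def test_ci_narrower_than_narrowest_member(self, rng):
        x = rng.uniform(20, 30, 8)
        s2 = rng.uniform(1.0, 16.0, 8)
        qtls = make_projected(x, s2)
        model = fit_mixture(x, s2, K=1)
        (mq,) = consensus_mqtl(model, qtls)
        min_member_ci = 3.92 * math.sqrt(s2.min())
        assert mq.ci_width <= min_member_ci
        # with m equal-variance members the width shrinks by sqrt(m)
        eq = make_projected([25.0] * 9, [4.0] * 9)
        model = fit_mixture([25.0] * 9, [4.0] * 9, K=1)
        (mq9,) = consensus_mqtl(model, eq)
        assert mq9.ci_width == pytest.approx(3.92 * 2.0 / 3.0)

    def test_n_traits_counts_distinct_codes(self):
        qtls = make_projected([10.0, 11.0, 12.0], [4.0] * 3,
                              traits=["GY", "GY", "ASI"])
        model = fit_mixture([10.0, 11.0, 12.0], [4.0] * 3, K=1)
        (mq,) = consensus_mqtl(model, qtls)
        assert mq.n_members == 3 and mq.n_traits == 2

    def test_mqtl_numbered_left_to_right(self, rng):
        x = np.concatenate([rng.normal(80, 1, 6), rng.normal(15, 1, 6)])
        s2 = np.ones(12)
        qtls = make_projected(x, s2, chrom=5)
        model = fit_mixture(x, s2, K=2, rng=0)
        mqtls = consensus_mqtl(model, qtls)
        assert [m.mqtl_id for m in mqtls] == ["MQTL5_1", "MQTL5_2"]
        assert mqtls[0].consensus_position < mqtls[1].consensus_position


class TestRecovery:
    def test_em_loglik_nondecreasing_is_asserted(self, rng):
        # the EM loop asserts monotonicity internally; run a stress instance
        x = rng.uniform(0, 200, 60)
        s2 = rng.uniform(0.25, 100.0, 60)
        for K in (1, 2, 4, 6):
            m = fit_mixture(x, s2, K=K, rng=0)
            assert np.isfinite(m.log_likelihood)

    def test_select_k_recovers_true_k_on_separated_clusters(self):
        # >=90% recovery over seeded replicates, K in {1,2,3}, separation
        # >= 5x member sd, >= 6 QTL per cluster
        hits = 0
        n_rep = 60
        for rep in range(n_rep):
            rg = np.random.default_rng(1000 + rep)
            true_k = 1 + rep % 3
            centers = 20.0 + 30.0 * np.arange(true_k)  # separation 30 = 15*sd
            sd = 2.0
            x = np.concatenate([rg.normal(c, sd, 7) for c in centers])
            s2 = np.full(len(x), sd ** 2)
            rows = [criterion_values(fit_mixture(x, s2, K=k, rng=rg))
                    for k in range(1, min(len(x), 6) + 1)]
            k_best, _ = select_K(pd.DataFrame(rows))
            hits += k_best == true_k
        assert hits / n_rep >= 0.9

    def test_consensus_positions_near_truth_in_zero_noise_limit(self, rng):
        centers = [30.0, 70.0]
        x = np.concatenate([rng.normal(c, 0.01, 8) for c in centers])
        s2 = np.full(16, 0.01 ** 2)
        qtls = make_projected(x, s2)
        res = cluster_chromosome(qtls, k_max=5)
        assert res.K_selected == 2
        for m, c in zip(res.mqtls, centers):
            assert m.consensus_position == pytest.approx(c, abs=0.1)


class TestSummarize:
    def test_fold_reduction_and_counts(self, rng):
        x = np.concatenate([rng.normal(20, 1, 8), rng.normal(120, 1, 8)])
        s2 = np.full(16, 4.0)
        qtls = make_projected(x, s2)
        results = meta_analyze(qtls, k_max=5)
        s = summarize_mqtl(results)
        assert s.n_mqtl == 2
        assert s.per_chromosome == {1: 2}
        assert s.mean_member_ci_cm == pytest.approx(3.92 * 2.0)
        # 8 equal-variance members per cluster: sqrt(8) shrinkage
        assert s.fold_reduction == pytest.approx(math.sqrt(8), rel=0.05)
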