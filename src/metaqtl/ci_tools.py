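"""Confidence-interval imputation and CI ↔ variance conversion.

When a study does not report a QTL's 95% confidence interval, it is imputed
from the mapping-population size N and the QTL's PVE (R²) with the
Darvasi–Soller approximations

    CI95 = 530 / (N · R²)   (backcross and F2 populations)
    CI95 = 163 / (N · R²)   (RIL-type populations)

with CI in centimorgans and R² the *proportion* of variance explained
(PVE percent / 100).  The same 95% interval is converted to the Gaussian
variance used by the meta-clustering likelihood via the normal quantile
factor z95 = 2·1.96 = 3.92: sd = CI/3.92.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import math

from .compendium import QTLRecord

__all__ = [
    "VarianceModel",
    "DEFAULT_VARIANCE_MODEL",
    "CI_CONSTANT_F2_BC",
    "CI_CONSTANT_RIL",
    "impute_ci",
    "ci_to_variance",
    "variance_to_ci",
    "apply_imputation",
]

#: Darvasi–Soller constants (cM · individuals).
CI_CONSTANT_F2_BC = 530.0
CI_CONSTANT_RIL = 163.0

#: Population types that use the RIL constant.  DH and immortalized-F2
#: populations behave like RILs (homozygous lines), so they share Eq. 2;
#: unknown types conservatively use the wider F2/BC constant.
RIL_LIKE = frozenset({"RIL", "DH", "IF2"})


@dataclass(frozen=True)
class VarianceModel:
    """Conversion between a 95% CI width and a Gaussian standard deviation."""

    z95: float = 3.92  # 2 × 1.96

    def __post_init__(self) -> None:
        if self.z95 <= 0:
            raise ValueError("z95 must be positive")


DEFAULT_VARIANCE_MODEL = VarianceModel()


def impute_ci(pop_type: str, pop_size: int, pve: float) -> float:
    """Impute a 95% CI width (cM) from population type/size and PVE (percent).

    ``pve`` is on the percent scale (e.g. 8.15 for 8.15%); it is divided by
    100 inside the formula so that typical inputs yield CIs of the observed
    tens-of-cM magnitude.
    """
    if pop_size is None or pop_size < 1 or pve is None or pve <= 0:
        raise ValueError("CI undefined: requires pop_size >= 1 and PVE > 0")
    r2 = pve / 100.0
    constant = CI_CONSTANT_RIL if pop_type in RIL_LIKE else CI_CONSTANT_F2_BC
    return constant / (pop_size * r2)


def ci_to_variance(ci_width: float,
                   model: VarianceModel = DEFAULT_VARIANCE_MODEL) -> float:
    """Gaussian position variance (cM²) implied by a 95% CI width."""
    if ci_width <= 0:
        raise ValueError("CI width must be positive")
    return (ci_width / model.z95) ** 2


def variance_to_ci(variance: float,
                   model: VarianceModel = DEFAULT_VARIANCE_MODEL) -> float:
    """Inverse of :func:`ci_to_variance` (round-trip identity)."""
    if variance <= 0:
        raise ValueError("variance must be positive")
    return model.z95 * math.sqrt(variance)


def apply_imputation(records: Iterable[QTLRecord],
                     ril_like: frozenset[str] = RIL_LIKE) -> list[QTLRecord]:
    """Fill in missing CIs, centered on each QTL's position.

    Records that already carry a CI are returned unchanged (imputation only
    applies where the source study reported none).  Records lacking both a CI
    and a PVE cannot be imputed and are returned unchanged with the CI still
    missing.  Imputed records are flagged ``ci_imputed``.
    """
    out: list[QTLRecord] = []
    for r in records:
        if r.ci_start is not None or r.pve is None:
            out.append(r)
            continue
        constant = CI_CONSTANT_RIL if r.pop_type in ril_like else CI_CONSTANT_F2_BC
        width = constant / (r.pop_size * (r.pve / 100.0))
        half = width / 2.0
        out.append(replace(
            r,
            ci_start=r.position - half,
            ci_end=r.position + half,
            ci_imputed=True,
        ))
    return out
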