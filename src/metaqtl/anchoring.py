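"""Physical anchoring of meta-QTL genetic intervals.

The genetic 95% CI of a meta-QTL is converted to a physical interval by
looking up the nearest reference-map markers flanking the CI that have a
known physical position (bp, 1-based, RefGen_v4 convention) — the
nearest-*outside* marker on each side, which gives a conservative interval.
The physical peak of the meta-QTL is placed by scaling half the genetic CI
into base pairs with the interval's local bp-per-cM rate:

    peak(bp) = start(bp) + (end(bp) − start(bp)) / (end(cM) − start(cM)) × CI(cM)/2

Coordinates are 1-based closed intervals (GFF3 convention); BED export is
0-based half-open.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .compendium import GeneticMap, _read_delimited
from .meta_clustering import MQTL

__all__ = [
    "PhysicalMQTL",
    "read_marker_physical",
    "anchor_interval",
    "anchor_all",
    "peak_position",
    "peak_window",
    "physical_mqtl_table",
    "physical_mqtl_bed",
]

log = logging.getLogger(__name__)


@dataclass
class PhysicalMQTL:
    """A meta-QTL with a physical interval and peak position."""

    mqtl: MQTL
    start_bp: Optional[int] = None
    end_bp: Optional[int] = None
    peak_bp: Optional[int] = None
    flank_markers: Optional[tuple[str, str]] = None
    anchor_quality: str = "failed"  # both_flanks | interpolated | failed
    inverted: bool = False

    @property
    def mqtl_id(self) -> str:
        return self.mqtl.mqtl_id

    @property
    def chromosome(self) -> int:
        return self.mqtl.chromosome

    @property
    def physical_width(self) -> Optional[int]:
        if self.start_bp is None:
            return None
        return self.end_bp - self.start_bp


def read_marker_physical(path: str | Path) -> pd.DataFrame:
    """Read a ``marker chr pos_bp`` table of marker physical positions."""
    df = _read_delimited(path)
    need = ["marker", "chr", "pos_bp"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if (df["pos_bp"] < 1).any():
        raise ValueError(f"{path}: physical positions must be >= 1")
    return df[need].copy()


def _mapped_markers(ref_map: GeneticMap, marker_bp: pd.DataFrame,
                    chromosome: int) -> pd.DataFrame:
    """Reference-map markers on one chromosome that have a physical position."""
    genetic = ref_map.markers(chromosome)
    phys = marker_bp[marker_bp["chr"] == chromosome]
    merged = pd.merge(genetic, phys[["marker", "pos_bp"]], on="marker")
    return merged.sort_values("pos_cM", kind="stable").reset_index(drop=True)


def anchor_interval(mqtl: MQTL, ref_map: GeneticMap,
                    marker_bp: pd.DataFrame,
                    nearest_inside: bool = False) -> PhysicalMQTL:
    """Anchor one meta-QTL's genetic CI to a physical interval.

    Left flank: the nearest physically-placed marker with cM ≤ CI lower
    bound; right flank analogous with cM ≥ CI upper bound (nearest-outside
    rule; set ``nearest_inside`` for the opposite convention).  When no
    marker exists outside a bound, the nearest marker inside is used and the
    anchor is downgraded to ``interpolated``.  Physically inverted flanks
    are swapped and flagged.
    """
    mm = _mapped_markers(ref_map, marker_bp, mqtl.chromosome)
    if len(mm) == 0:
        return PhysicalMQTL(mqtl=mqtl, anchor_quality="failed")
    cm = mm["pos_cM"].to_numpy(float)
    lo_bound, hi_bound = mqtl.ci95_lo, mqtl.ci95_hi
    if nearest_inside:
        left_candidates = np.flatnonzero(cm >= lo_bound)
        right_candidates = np.flatnonzero(cm <= hi_bound)
        left_i = left_candidates[0] if len(left_candidates) else None
        right_i = right_candidates[-1] if len(right_candidates) else None
        if left_i is not None and right_i is not None and left_i > right_i:
            left_i = right_i = None  # no marker inside the CI
    else:
        left_candidates = np.flatnonzero(cm <= lo_bound)
        right_candidates = np.flatnonzero(cm >= hi_bound)
        left_i = left_candidates[-1] if len(left_candidates) else None
        right_i = right_candidates[0] if len(right_candidates) else None

    quality = "both_flanks"
    if left_i is None and right_i is None:
        return PhysicalMQTL(mqtl=mqtl, anchor_quality="failed")
    if left_i is None:
        left_i, quality = 0, "interpolated"
    if right_i is None:
        right_i, quality = len(mm) - 1, "interpolated"

    left = mm.iloc[int(left_i)]
    right = mm.iloc[int(right_i)]
    start_bp, end_bp = int(left["pos_bp"]), int(right["pos_bp"])
    inverted = start_bp > end_bp
    if inverted:
        start_bp, end_bp = end_bp, start_bp
        log.warning("%s: physically inverted flanks swapped", mqtl.mqtl_id)

    phys = PhysicalMQTL(
        mqtl=mqtl, start_bp=start_bp, end_bp=end_bp,
        flank_markers=(str(left["marker"]), str(right["marker"])),
        anchor_quality=quality, inverted=inverted,
    )
    start_cm, end_cm = float(left["pos_cM"]), float(right["pos_cM"])
    if end_cm > start_cm and end_bp > start_bp:
        phys.peak_bp = peak_position(start_bp, end_bp, start_cm, end_cm,
                                     mqtl.ci_width)
    else:
        phys.peak_bp = (start_bp + end_bp) // 2
    return phys


def anchor_all(mqtls: Sequence[MQTL], ref_map: GeneticMap,
               marker_bp: pd.DataFrame,
               nearest_inside: bool = False) -> list[PhysicalMQTL]:
    return [anchor_interval(m, ref_map, marker_bp, nearest_inside)
            for m in mqtls]


def peak_position(start_bp: int, end_bp: int, start_cm: float, end_cm: float,
                  ci_cm: float) -> int:
    """Physical peak: half the genetic CI measured from the left physical
    bound at the interval's bp-per-cM rate, rounded to the nearest bp.

    Clamped to ``end_bp`` (with a warning) when the CI exceeds twice the
    anchored genetic span.
    """
    if end_cm <= start_cm:
        raise ValueError("degenerate genetic span")
    if end_bp <= start_bp:
        raise ValueError("degenerate physical span")
    if ci_cm <= 0:
        raise ValueError("CI must be positive")
    peak = start_bp + (end_bp - start_bp) / (end_cm - start_cm) * (ci_cm / 2.0)
    if peak > end_bp:
        warnings.warn("peak beyond anchored interval; clamped to end_bp",
                      stacklevel=2)
        peak = float(end_bp)
    return int(round(peak))


def peak_window(peak_bp: int, half_width: int = 500_000,
                chrom_length: Optional[int] = None) -> tuple[int, int]:
    """The 1 Mb candidate-gene window: ±500 kb around the peak, clamped to
    the chromosome."""
    lo = max(1, peak_bp - half_width)
    hi = peak_bp + half_width
    if chrom_length is not None:
        hi = min(chrom_length, hi)
    return lo, hi


def physical_mqtl_table(physicals: Sequence[PhysicalMQTL]) -> pd.DataFrame:
    rows = []
    for p in physicals:
        rows.append({
            "mqtl_id": p.mqtl_id, "chr": p.chromosome,
            "pos_cM": p.mqtl.consensus_position,
            "ci_lo_cM": p.mqtl.ci95_lo, "ci_hi_cM": p.mqtl.ci95_hi,
            "n_qtl": p.mqtl.n_members, "n_traits": p.mqtl.n_traits,
            "start_bp": p.start_bp, "end_bp": p.end_bp, "peak_bp": p.peak_bp,
            "flank_left": p.flank_markers[0] if p.flank_markers else None,
            "flank_right": p.flank_markers[1] if p.flank_markers else None,
            "anchor_quality": p.anchor_quality,
        })
    return pd.DataFrame(rows)


def physical_mqtl_bed(physicals: Sequence[PhysicalMQTL]) -> pd.DataFrame:
    """BED representation (0-based, half-open) of anchored meta-QTL."""
    rows = []
    for p in physicals:
        if p.start_bp is None:
            continue
        rows.append({
            "chrom": f"chr{p.chromosome}",
            "chromStart": p.start_bp - 1,
            "chromEnd": p.end_bp,
            "name": p.mqtl_id,
        })
    return pd.DataFrame(rows, columns=["chrom", "chromStart", "chromEnd", "name"])
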