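"""Projection of QTL from study linkage maps onto a reference map.

Each study reports QTL positions on its own genetic map; meta-analysis
requires all QTL on a single reference map (the IBM2 2008 Neighbors map for
maize).  Projection uses the markers shared between a study map and the
reference map as anchors and transfers positions by local affine
(homothetic) scaling between the tightest flanking shared markers — the
standard BioMercator-style rule.  CI endpoints are mapped piecewise-linearly
(each endpoint uses the scale of the shared-marker interval it falls in),
then clamped to the chromosome ends, and the Gaussian position variance is
recomputed from the projected CI width.
"""
from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ci_tools import VarianceModel, DEFAULT_VARIANCE_MODEL
from .compendium import GeneticMap, QTLRecord

__all__ = [
    "ProjectedQTL",
    "ChromProjector",
    "find_common_flank",
    "project_qtl",
    "project_all",
]

log = logging.getLogger(__name__)


@dataclass
class ProjectedQTL:
    """A QTL with coordinates transferred to the reference map."""

    record: QTLRecord
    ref_position: Optional[float] = None
    ref_ci_lo: Optional[float] = None
    ref_ci_hi: Optional[float] = None
    ref_variance: Optional[float] = None
    anchor_markers: Optional[tuple[str, str]] = None
    projection_status: str = "unanchored"  # projected | unanchored_extrapolated | unanchored

    @property
    def qtl_id(self) -> str:
        return self.record.qtl_id

    @property
    def chromosome(self) -> int:
        return self.record.chromosome


def _longest_increasing_subsequence(values: np.ndarray) -> np.ndarray:
    """Indices of a longest strictly-increasing subsequence (O(n log n))."""
    tails: list[float] = []
    tails_idx: list[int] = []
    prev = np.full(len(values), -1)
    for i, v in enumerate(values):
        j = bisect_left(tails, v)
        if j == len(tails):
            tails.append(v)
            tails_idx.append(i)
        else:
            tails[j] = v
            tails_idx[j] = i
        if j > 0:
            prev[i] = tails_idx[j - 1]
    out = []
    i = tails_idx[-1] if tails_idx else -1
    while i >= 0:
        out.append(i)
        i = prev[i]
    return np.array(out[::-1], dtype=int)


class ChromProjector:
    """Shared-marker anchor set between a study map and the reference map.

    Markers whose order conflicts between the two maps (local inversions)
    are discarded from the anchor set — a longest order-consistent subset is
    retained — and the number of discarded anchors is recorded.
    """

    def __init__(self, study_map: GeneticMap, ref_map: GeneticMap,
                 chromosome: int) -> None:
        s = study_map.markers(chromosome)
        r = ref_map.markers(chromosome)
        shared = pd.merge(s, r, on="marker", suffixes=("_study", "_ref"))
        shared = shared.sort_values("pos_cM_study", kind="stable")
        # collapse markers co-located on the study map (zero-length intervals)
        shared = shared.drop_duplicates(subset="pos_cM_study", keep="first")
        spos = shared["pos_cM_study"].to_numpy(float)
        rpos = shared["pos_cM_ref"].to_numpy(float)
        names = shared["marker"].to_numpy(object)
        keep = _longest_increasing_subsequence(rpos) if len(rpos) else np.array([], int)
        self.n_conflicts = len(spos) - len(keep)
        if self.n_conflicts:
            log.warning("chromosome %d: discarded %d order-conflicting anchors",
                        chromosome, self.n_conflicts)
        self.study_pos = spos[keep]
        self.ref_pos = rpos[keep]
        self.marker_names = names[keep]
        self.chromosome = chromosome
        self.ref_length = ref_map.length(chromosome)

    @property
    def n_anchors(self) -> int:
        return len(self.study_pos)

    def bracket(self, position: float) -> Optional[tuple[int, int]]:
        """Indices of the tightest anchor pair bracketing ``position``."""
        if self.n_anchors < 2:
            return None
        s = self.study_pos
        hi = bisect_right(s, position)
        lo = hi - 1
        if lo < 0 or hi > len(s):
            return None
        if hi == len(s):  # position at or beyond the last anchor
            if s[lo] == position and lo >= 1:
                return lo - 1, lo
            return None
        return lo, hi

    def transform(self, position: float) -> tuple[float, bool]:
        """Map a study-map cM position to the reference map.

        Returns ``(ref_position, extrapolated)``.  Inside the anchored span
        this is piecewise-linear interpolation; outside, linear extrapolation
        with the nearest shared interval's scale.
        """
        s, r = self.study_pos, self.ref_pos
        if self.n_anchors < 2:
            raise ValueError("fewer than two consistent shared anchors")
        if position < s[0]:
            scale = (r[1] - r[0]) / (s[1] - s[0])
            return r[0] + (position - s[0]) * scale, True
        if position > s[-1]:
            scale = (r[-1] - r[-2]) / (s[-1] - s[-2])
            return r[-1] + (position - s[-1]) * scale, True
        return float(np.interp(position, s, r)), False


def find_common_flank(study_map: GeneticMap, ref_map: GeneticMap,
                      chromosome: int, position: float
                      ) -> Optional[tuple[str, str]]:
    """The nearest order-consistent shared markers bracketing ``position``.

    Returns ``None`` when fewer than two shared markers exist or no shared
    pair brackets the position (the QTL is then extrapolated or dropped,
    per configuration).  Raises ``KeyError`` if the chromosome is absent
    from either map.
    """
    if chromosome not in study_map or chromosome not in ref_map:
        raise KeyError(f"chromosome {chromosome} absent from one of the maps")
    proj = ChromProjector(study_map, ref_map, chromosome)
    pair = proj.bracket(position)
    if pair is None:
        return None
    lo, hi = pair
    return str(proj.marker_names[lo]), str(proj.marker_names[hi])


def project_qtl(record: QTLRecord, study_map: GeneticMap, ref_map: GeneticMap,
                projector: ChromProjector | None = None,
                model: VarianceModel = DEFAULT_VARIANCE_MODEL,
                drop_extrapolated: bool = False) -> ProjectedQTL:
    """Project one QTL (position and CI) onto the reference map.

    Requires a present CI (impute first if needed).  QTL already expressed
    on the reference map (``map_id`` equal to the reference's) pass through
    unchanged.
    """
    if record.ci_start is None:
        raise ValueError(f"QTL {record.qtl_id}: CI missing; impute before projection")
    chrom = record.chromosome

    if record.map_id == ref_map.map_id:
        width = record.ci_end - record.ci_start
        return ProjectedQTL(
            record=record,
            ref_position=record.position,
            ref_ci_lo=record.ci_start,
            ref_ci_hi=record.ci_end,
            ref_variance=(width / model.z95) ** 2,
            projection_status="projected",
        )

    proj = projector or ChromProjector(study_map, ref_map, chrom)
    if proj.n_anchors < 2:
        return ProjectedQTL(record=record, projection_status="unanchored")

    pos, pos_extrap = proj.transform(record.position)
    lo, _ = proj.transform(record.ci_start)
    hi, _ = proj.transform(record.ci_end)
    if hi < lo:  # cannot happen for order-consistent anchors; guard anyway
        lo, hi = hi, lo
    if pos_extrap and drop_extrapolated:
        return ProjectedQTL(record=record, projection_status="unanchored")

    # clamp to chromosome extent on the reference map
    lo = max(0.0, lo)
    hi = min(proj.ref_length, hi)
    pos = min(max(pos, lo), hi)
    width = hi - lo
    if width <= 0:
        return ProjectedQTL(record=record, projection_status="unanchored")

    pair = proj.bracket(record.position)
    anchors = None
    if pair is not None:
        anchors = (str(proj.marker_names[pair[0]]), str(proj.marker_names[pair[1]]))
    return ProjectedQTL(
        record=record,
        ref_position=pos,
        ref_ci_lo=lo,
        ref_ci_hi=hi,
        ref_variance=(width / model.z95) ** 2,
        anchor_markers=anchors,
        projection_status="unanchored_extrapolated" if pos_extrap else "projected",
    )


def project_all(records: Sequence[QTLRecord],
                study_maps: dict[str, GeneticMap],
                ref_map: GeneticMap,
                model: VarianceModel = DEFAULT_VARIANCE_MODEL,
                drop_extrapolated: bool = False
                ) -> tuple[list[ProjectedQTL], pd.DataFrame]:
    """Project a whole compendium; returns projected QTL plus a status report.

    Projector objects are cached per (study map, chromosome).  The report
    lists the anchors and projection status for every QTL.
    """
    cache: dict[tuple[str, int], ChromProjector] = {}
    out: list[ProjectedQTL] = []
    rows = []
    for r in records:
        if r.map_id == ref_map.map_id:
            p = project_qtl(r, ref_map, ref_map, model=model)
        else:
            study_map = study_maps[r.map_id]
            key = (r.map_id, r.chromosome)
            if key not in cache:
                cache[key] = ChromProjector(study_map, ref_map, r.chromosome)
            p = project_qtl(r, study_map, ref_map, projector=cache[key],
                            model=model, drop_extrapolated=drop_extrapolated)
        out.append(p)
        rows.append({
            "qtl_id": r.qtl_id, "chr": r.chromosome, "map_id": r.map_id,
            "status": p.projection_status,
            "ref_pos_cM": p.ref_position,
            "ref_ci_lo_cM": p.ref_ci_lo, "ref_ci_hi_cM": p.ref_ci_hi,
            "anchor_left": p.anchor_markers[0] if p.anchor_markers else None,
            "anchor_right": p.anchor_markers[1] if p.anchor_markers else None,
        })
    return out, pd.DataFrame(rows)
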