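"""Data model and I/O for multi-study QTL compendia.

A *compendium* is the curated table of initial QTL collected from published
mapping studies: one row per QTL with its trait, genetic position and 95%
confidence interval on the source study's linkage map, LOD support, the
proportion of phenotypic variance explained (PVE), and the mapping-population
metadata (type and size) needed to impute missing confidence intervals.

The module also holds the drought-tolerance trait ontology (24 trait codes in
four categories: grain-yield components GY, flowering-related FR, plant
morphology PM, and drought-tolerance index DTI), the published quality filter
(CI > 200 cM, PVE < 1%, or LOD < 1.5 removed), genetic maps, and GWAS
marker-trait associations (MTAs).
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "DEFAULT_TRAIT_CATEGORIES",
    "TRAIT_LABELS",
    "TraitOntology",
    "QTLRecord",
    "GeneticMap",
    "MTA",
    "FilterResult",
    "CompendiumSummary",
    "read_qtl_table",
    "write_qtl_table",
    "read_genetic_maps",
    "read_mta_table",
    "quality_filter",
    "summarize_compendium",
    "records_to_frame",
]

#: The four trait categories used throughout maize drought meta-QTL work.
CATEGORIES = ("GY", "FR", "PM", "DTI")

#: Default 24-code trait ontology.  Sixteen grain-yield component traits, five
#: flowering-time traits, two plant-morphology traits, and the drought
#: tolerance index.
DEFAULT_TRAIT_CATEGORIES: dict[str, str] = {
    **{c: "GY" for c in (
        "GY", "KWT", "KWE", "NRE", "NKR", "EN", "KN", "EL",
        "EW", "ED", "KL", "KW", "KT", "CW", "CD", "ES")},
    **{c: "FR" for c in ("ASI", "MF", "FD", "FF", "TBN")},
    "PH": "PM",
    "EH": "PM",
    "DTI": "DTI",
}

TRAIT_LABELS: dict[str, str] = {
    "GY": "grain yield",
    "KWT": "1000 kernel weight",
    "KWE": "kernel weight per ear",
    "NRE": "number of rows per ear",
    "NKR": "number of kernels per row",
    "EN": "ear number",
    "KN": "kernel number",
    "EL": "ear length",
    "EW": "ear weight",
    "ED": "ear diameter",
    "KL": "kernel length",
    "KW": "kernel width",
    "KT": "kernel thickness",
    "CW": "cob weight",
    "CD": "cob diameter",
    "ES": "ear setting percentage",
    "ASI": "anthesis to silking interval",
    "MF": "male flowering",
    "FD": "flowering days",
    "FF": "female flowering",
    "TBN": "tassel branch number",
    "PH": "plant height",
    "EH": "ear height",
    "DTI": "drought tolerance index",
}

#: Recognized mapping-population types; anything else is normalized to "other".
POP_TYPES = ("F2", "BC", "RIL", "DH", "IF2", "other")

_QTL_COLUMNS = [
    "qtl_id", "study_id", "trait", "chr", "pos_cM", "ci_lo_cM", "ci_hi_cM",
    "lod", "pve", "pop_type", "pop_size", "map_id",
]


@dataclass(frozen=True)
class TraitOntology:
    """Trait-code → category mapping with human-readable labels.

    The default ontology carries exactly 24 codes; user-supplied ontologies
    (e.g. to move TBN from FR to PM) may differ in size but every code must
    map into the four canonical categories.
    """

    mapping: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_CATEGORIES))
    labels: dict[str, str] = field(default_factory=lambda: dict(TRAIT_LABELS))

    def __post_init__(self) -> None:
        bad = {c for c, cat in self.mapping.items() if cat not in CATEGORIES}
        if bad:
            raise ValueError(
                f"trait codes mapped outside {CATEGORIES}: {sorted(bad)}")

    def category(self, trait: str) -> str:
        try:
            return self.mapping[trait]
        except KeyError:
            raise KeyError(f"unknown trait code {trait!r}") from None

    @classmethod
    def from_table(cls, path: str | Path) -> "TraitOntology":
        """Load a two-column (code, category) delimited config file."""
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
        code_col, cat_col = df.columns[:2]
        mapping = dict(zip(df[code_col].astype(str), df[cat_col].astype(str)))
        labels = {c: TRAIT_LABELS.get(c, c) for c in mapping}
        return cls(mapping=mapping, labels=labels)


@dataclass
class QTLRecord:
    """One initial QTL as curated from a mapping study.

    Positions are centimorgans on the *source* study map; ``ci_start`` /
    ``ci_end``, ``lod`` and ``pve`` may be ``None`` when the study did not
    report them (CI can be imputed later from ``pop_type``/``pop_size``/
    ``pve``).
    """

    qtl_id: str
    study_id: str
    trait: str
    chromosome: int
    position: float
    ci_start: Optional[float] = None
    ci_end: Optional[float] = None
    lod: Optional[float] = None
    pve: Optional[float] = None
    pop_type: str = "other"
    pop_size: int = 1
    map_id: str = ""
    trait_category: str = ""
    ci_imputed: bool = False

    def __post_init__(self) -> None:
        if not 1 <= int(self.chromosome) <= 10:
            raise ValueError(
                f"QTL {self.qtl_id}: chromosome {self.chromosome} outside 1-10")
        self.chromosome = int(self.chromosome)
        if (self.ci_start is None) != (self.ci_end is None):
            raise ValueError(f"QTL {self.qtl_id}: half-specified CI")
        if self.ci_start is not None:
            if not self.ci_start <= self.position <= self.ci_end:
                raise ValueError(
                    f"QTL {self.qtl_id}: position {self.position} outside CI "
                    f"[{self.ci_start}, {self.ci_end}]")
        if self.pve is not None and not 0 < self.pve <= 100:
            raise ValueError(f"QTL {self.qtl_id}: PVE {self.pve} outside (0, 100]")
        if self.lod is not None and self.lod < 0:
            raise ValueError(f"QTL {self.qtl_id}: negative LOD")
        if self.pop_size < 1:
            raise ValueError(f"QTL {self.qtl_id}: pop_size < 1")

    @property
    def ci_width(self) -> Optional[float]:
        if self.ci_start is None:
            return None
        return self.ci_end - self.ci_start


@dataclass(frozen=True)
class MTA:
    """A GWAS marker-trait association at a single physical position (bp, 1-based)."""

    marker: str
    chromosome: int
    position_bp: int
    trait: str
    source_study: str = ""

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValueError(f"MTA {self.marker}: position_bp < 1")


class GeneticMap:
    """An ordered genetic map: per-chromosome markers with cM positions.

    Within a chromosome positions must be nondecreasing and marker names
    unique within the map.
    """

    def __init__(self, map_id: str,
                 chromosomes: dict[int, pd.DataFrame]) -> None:
        self.map_id = map_id
        self.chromosomes: dict[int, pd.DataFrame] = {}
        seen: set[str] = set()
        for chrom, df in sorted(chromosomes.items()):
            df = df[["marker", "pos_cM"]].reset_index(drop=True)
            pos = df["pos_cM"].to_numpy(float)
            if np.any(np.diff(pos) < 0):
                order = np.argsort(pos, kind="stable")
                df = df.iloc[order].reset_index(drop=True)
            dup = seen.intersection(df["marker"])
            if dup:
                raise ValueError(
                    f"map {map_id}: duplicate marker names {sorted(dup)[:5]}")
            seen.update(df["marker"])
            self.chromosomes[int(chrom)] = df

    def markers(self, chromosome: int) -> pd.DataFrame:
        if chromosome not in self.chromosomes:
            raise KeyError(
                f"chromosome {chromosome} absent from map {self.map_id}")
        return self.chromosomes[chromosome]

    def length(self, chromosome: int) -> float:
        return float(self.markers(chromosome)["pos_cM"].iloc[-1])

    def total_length(self) -> float:
        return float(sum(self.length(c) for c in self.chromosomes))

    def __contains__(self, chromosome: int) -> bool:
        return chromosome in self.chromosomes

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for chrom, df in self.chromosomes.items():
            part = df.copy()
            part.insert(0, "chr", chrom)
            part.insert(0, "map_id", self.map_id)
            parts.append(part)
        return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# I/O

def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a tab- or comma-delimited table, auto-detected from the header."""
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep)


def read_qtl_table(path: str | Path,
                   ontology: TraitOntology | None = None) -> list[QTLRecord]:
    """Read an initial-QTL table into :class:`QTLRecord` objects.

    Required columns: ``qtl_id study_id trait chr pos_cM ci_lo_cM ci_hi_cM
    lod pve pop_type pop_size map_id``.  Empty LOD/PVE/CI cells become
    ``None`` (missing, never zero); row order is preserved.
    """
    ontology = ontology or TraitOntology()
    df = _read_delimited(path)
    missing = [c for c in _QTL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    records: list[QTLRecord] = []
    for i, row in df.iterrows():
        trait = str(row["trait"])
        try:
            category = ontology.category(trait)
        except KeyError:
            raise ValueError(
                f"{path} row {i + 1}: unknown trait code {trait!r}") from None
        chrom = int(row["chr"])
        if not 1 <= chrom <= 10:
            raise ValueError(f"{path} row {i + 1}: chromosome {chrom} outside 1-10")

        def _opt(col: str) -> Optional[float]:
            v = row[col]
            return None if pd.isna(v) else float(v)

        records.append(QTLRecord(
            qtl_id=str(row["qtl_id"]),
            study_id=str(row["study_id"]),
            trait=trait,
            chromosome=chrom,
            position=float(row["pos_cM"]),
            ci_start=_opt("ci_lo_cM"),
            ci_end=_opt("ci_hi_cM"),
            lod=_opt("lod"),
            pve=_opt("pve"),
            pop_type=str(row["pop_type"]),
            pop_size=int(row["pop_size"]),
            map_id=str(row["map_id"]),
            trait_category=category,
        ))
    return records


def records_to_frame(records: Sequence[QTLRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "qtl_id": r.qtl_id, "study_id": r.study_id, "trait": r.trait,
            "chr": r.chromosome, "pos_cM": r.position,
            "ci_lo_cM": np.nan if r.ci_start is None else r.ci_start,
            "ci_hi_cM": np.nan if r.ci_end is None else r.ci_end,
            "lod": np.nan if r.lod is None else r.lod,
            "pve": np.nan if r.pve is None else r.pve,
            "pop_type": r.pop_type, "pop_size": r.pop_size,
            "map_id": r.map_id,
        })
    return pd.DataFrame(rows, columns=_QTL_COLUMNS)


def write_qtl_table(records: Sequence[QTLRecord], path: str | Path) -> None:
    """Write records as a TSV that round-trips through :func:`read_qtl_table`."""
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_genetic_maps(path: str | Path) -> dict[str, GeneticMap]:
    """Read one or more genetic maps from a ``map_id chr marker pos_cM`` table."""
    df = _read_delimited(path)
    need = ["map_id", "chr", "marker", "pos_cM"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    maps: dict[str, GeneticMap] = {}
    for map_id, sub in df.groupby("map_id", sort=False):
        chroms = {
            int(chrom): part[["marker", "pos_cM"]]
            for chrom, part in sub.groupby("chr", sort=True)
        }
        maps[str(map_id)] = GeneticMap(str(map_id), chroms)
    return maps


def read_mta_table(path: str | Path) -> list[MTA]:
    """Read a GWAS MTA table with columns ``marker chr pos_bp trait study``."""
    df = _read_delimited(path)
    need = ["marker", "chr", "pos_bp", "trait", "study"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return [
        MTA(marker=str(r["marker"]), chromosome=int(r["chr"]),
            position_bp=int(r["pos_bp"]), trait=str(r["trait"]),
            source_study=str(r["study"]))
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Quality filter and summaries

@dataclass
class FilterResult:
    kept: list[QTLRecord]
    dropped: list[tuple[QTLRecord, str]]

    @property
    def drop_reasons(self) -> Counter:
        return Counter(reason for _, reason in self.dropped)


def quality_filter(records: Iterable[QTLRecord],
                   max_ci_cm: float = 200.0,
                   min_pve: float = 1.0,
                   min_lod: float = 1.5,
                   strict_filters: bool = False) -> FilterResult:
    """Apply the published QTL quality filter.

    A record is removed iff its CI width exceeds ``max_ci_cm`` (200 cM), its
    PVE is below ``min_pve`` (1%), or its LOD is below ``min_lod`` (1.5) —
    strict inequalities on the removal side, so values exactly at a threshold
    are kept.  Missing LOD/PVE/CI pass the corresponding sub-filter unless
    ``strict_filters`` is set, in which case missing values are removed too.
    Each dropped record carries its first failing reason (CI, then PVE, then
    LOD).
    """
    kept: list[QTLRecord] = []
    dropped: list[tuple[QTLRecord, str]] = []
    for r in records:
        reason = None
        if r.ci_width is not None:
            if r.ci_width > max_ci_cm:
                reason = f"CI > {max_ci_cm:g} cM"
        elif strict_filters:
            reason = "missing CI"
        if reason is None:
            if r.pve is not None:
                if r.pve < min_pve:
                    reason = f"PVE < {min_pve:g}%"
            elif strict_filters:
                reason = "missing PVE"
        if reason is None:
            if r.lod is not None:
                if r.lod < min_lod:
                    reason = f"LOD < {min_lod:g}"
            elif strict_filters:
                reason = "missing LOD"
        if reason is None:
            kept.append(r)
        else:
            dropped.append((r, reason))
    return FilterResult(kept=kept, dropped=dropped)


#: Bin edges used in compendium summaries (right-open except the last bin).
LOD_BIN_EDGES = (2.0, 4.0, 6.0)
PVE_BIN_EDGES = (5.0, 10.0, 15.0)


def _bin_counts(values: np.ndarray, edges: Sequence[float]) -> tuple[int, ...]:
    idx = np.searchsorted(edges, values, side="right")
    return tuple(int(np.sum(idx == k)) for k in range(len(edges) + 1))


@dataclass
class CompendiumSummary:
    """Counts by LOD bin, PVE bin and trait category for a QTL compendium."""

    n: int
    lod_bins: tuple[int, int, int, int]   # <2, [2,4), [4,6), >=6
    pve_bins: tuple[int, int, int, int]   # <5, [5,10), [10,15), >=15 (%)
    category_counts: dict[str, int]
    category_shares: dict[str, float]     # percent, one-decimal rounding

    def to_frame(self) -> pd.DataFrame:
        rows = [("n_qtl", self.n)]
        for label, v in zip(("lod_lt2", "lod_2_4", "lod_4_6", "lod_ge6"),
                            self.lod_bins):
            rows.append((label, v))
        for label, v in zip(("pve_lt5", "pve_5_10", "pve_10_15", "pve_ge15"),
                            self.pve_bins):
            rows.append((label, v))
        for cat in CATEGORIES:
            rows.append((f"n_{cat}", self.category_counts.get(cat, 0)))
            rows.append((f"share_{cat}_pct", self.category_shares.get(cat, 0.0)))
        return pd.DataFrame(rows, columns=["quantity", "value"])


def summarize_compendium(records: Sequence[QTLRecord]) -> CompendiumSummary:
    """Summarize a (quality-filtered) compendium by LOD, PVE and category.

    Only records with a present LOD (resp. PVE) enter the LOD (resp. PVE)
    bins; category shares are percentages of all records, rounded to one
    decimal.
    """
    n = len(records)
    lod = np.array([r.lod for r in records if r.lod is not None], float)
    pve = np.array([r.pve for r in records if r.pve is not None], float)
    lod_bins = _bin_counts(lod, LOD_BIN_EDGES)
    pve_bins = _bin_counts(pve, PVE_BIN_EDGES)
    cat_counts = Counter(r.trait_category for r in records)
    shares = {
        cat: round(100.0 * cat_counts.get(cat, 0) / n, 1) if n else 0.0
        for cat in CATEGORIES
    }
    return CompendiumSummary(
        n=n,
        lod_bins=lod_bins,
        pve_bins=pve_bins,
        category_counts={cat: cat_counts.get(cat, 0) for cat in CATEGORIES},
        category_shares=shares,
    )
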