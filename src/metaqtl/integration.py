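"""GWAS co-localization, meta-QTL classification, and candidate-gene mining.

Three independent lines of evidence are combined around anchored meta-QTL:

* **MTA co-localization** — GWAS marker-trait associations falling within
  500 kb up/downstream of a meta-QTL's physical interval count as
  verification of the locus.
* **Classification** — *breeders' MQTL* have a physical CI < 1 Mb, a genetic
  CI < 4 cM and more than 2 member QTL (directly usable in marker-assisted
  selection); *MTA-MQTL* are verified by more than ``mta_min`` (default 3)
  MTAs; the *core* set is their union.
* **Candidate genes** — the union of (i) cross-species protein-homology hits
  filtered at E-value < 1e-10 and identity > 40%, (ii) genes inside
  breeders' MQTL intervals, and (iii) genes in the ±500 kb window around
  MTA-MQTL peaks; plus a tissue-expression filter keeping genes with
  TPM > 2 in at least one tissue (log2(TPM+1) transform for heat-map
  matrices).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .anchoring import PhysicalMQTL, peak_window
from .compendium import MTA

__all__ = [
    "OverlapReport",
    "GeneModel",
    "BLAST6_COLUMNS",
    "mta_overlap",
    "classify_mqtl",
    "read_blast_tabular",
    "filter_homology",
    "read_gff3_genes",
    "genes_in_interval",
    "candidate_gene_union",
    "expression_filter",
    "transform_log2",
]

log = logging.getLogger(__name__)

#: BLAST tabular (outfmt 6) default column order.
BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene locus extracted from GFF3 (1-based, closed coordinates)."""

    gene_id: str
    chromosome: int
    start_bp: int
    end_bp: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"gene {self.gene_id}: start > end")


# ---------------------------------------------------------------------------
# MTA co-localization and classification

@dataclass
class OverlapReport:
    """Per-MQTL overlapping MTAs plus classification flags."""

    overlaps: dict[str, list[MTA]]     # mqtl_id -> MTAs within the window
    window: int

    def n_mta(self, mqtl_id: str) -> int:
        return len(self.overlaps.get(mqtl_id, []))

    @property
    def n_mqtl_with_mta(self) -> int:
        return sum(1 for v in self.overlaps.values() if v)

    @property
    def n_mta_total(self) -> int:
        return sum(len(v) for v in self.overlaps.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"mqtl_id": mid, "n_mta": len(mtas),
                 "mta_markers": ",".join(m.marker for m in mtas)}
                for mid, mtas in self.overlaps.items()]
        return pd.DataFrame(rows, columns=["mqtl_id", "n_mta", "mta_markers"])


def mta_overlap(mqtls: Sequence[PhysicalMQTL], mtas: Sequence[MTA],
                window: int = 500_000) -> OverlapReport:
    """Count MTAs within ``window`` bp up/downstream of each meta-QTL.

    An MTA at position p overlaps an MQTL [start, end] iff it is on the same
    chromosome and start − window ≤ p ≤ end + window (inclusive bounds).
    Unanchored MQTL get empty overlap lists.
    """
    overlaps: dict[str, list[MTA]] = {}
    for p in mqtls:
        hits: list[MTA] = []
        if p.start_bp is not None:
            lo = p.start_bp - window
            hi = p.end_bp + window
            hits = [m for m in mtas
                    if m.chromosome == p.chromosome and lo <= m.position_bp <= hi]
        overlaps[p.mqtl_id] = hits
    return OverlapReport(overlaps=overlaps, window=window)


@dataclass
class MQTLFlags:
    breeders: set[str]
    mta_mqtl: set[str]

    @property
    def core(self) -> set[str]:
        return self.breeders | self.mta_mqtl


def classify_mqtl(mqtls: Sequence[PhysicalMQTL],
                  report: Optional[OverlapReport] = None,
                  max_physical_bp: int = 1_000_000,
                  max_genetic_cm: float = 4.0,
                  min_members: int = 2,
                  mta_min: int = 3) -> MQTLFlags:
    """Flag breeders' MQTL, MTA-verified MQTL, and their core union.

    ``breeders``: physical width < 1 Mb AND genetic CI < 4 cM AND member
    count strictly greater than ``min_members`` (2).  ``mta_mqtl``: strictly
    more than ``mta_min`` (3) overlapping MTAs.  All comparisons are strict
    as published.  MQTL without a physical anchor cannot be classified as
    breeders' and are logged.
    """
    breeders: set[str] = set()
    for p in mqtls:
        if p.start_bp is None:
            log.info("%s: no physical anchor; breeders' flag undefined",
                     p.mqtl_id)
            continue
        if (p.physical_width < max_physical_bp
                and p.mqtl.ci_width < max_genetic_cm
                and p.mqtl.n_members > min_members):
            breeders.add(p.mqtl_id)
    mta_ids: set[str] = set()
    if report is not None:
        mta_ids = {mid for mid, hits in report.overlaps.items()
                   if len(hits) > mta_min}
    return MQTLFlags(breeders=breeders, mta_mqtl=mta_ids)


# ---------------------------------------------------------------------------
# Homology filtering

def read_blast_tabular(path: str | Path,
                       columns: Sequence[str] = BLAST6_COLUMNS) -> pd.DataFrame:
    """Parse a BLAST outfmt-6 tabular file; malformed rows are skipped with a
    warning and counted in ``df.attrs['n_malformed']``."""
    rows = []
    n_bad = 0
    ncol = len(columns)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < ncol:
                n_bad += 1
                log.warning("%s line %d: %d fields, expected %d — skipped",
                            path, lineno, len(parts), ncol)
                continue
            try:
                row = dict(zip(columns, parts[:ncol]))
                row["pident"] = float(row["pident"])
                row["evalue"] = float(row["evalue"])
                row["bitscore"] = float(row["bitscore"])
                rows.append(row)
            except ValueError:
                n_bad += 1
                log.warning("%s line %d: unparseable numerics — skipped",
                            path, lineno)
    df = pd.DataFrame(rows, columns=list(columns))
    df.attrs["n_malformed"] = n_bad
    return df


def filter_homology(hits: pd.DataFrame,
                    max_evalue: float = 1e-10,
                    min_identity: float = 40.0) -> pd.DataFrame:
    """Keep hits with E-value strictly below 1e-10 AND identity strictly
    above 40%, then the single best hit per (query, subject) pair (lowest
    E-value, ties by highest identity)."""
    kept = hits[(hits["evalue"] < max_evalue)
                & (hits["pident"] > min_identity)].copy()
    kept = kept.sort_values(["evalue", "pident"],
                            ascending=[True, False], kind="stable")
    kept = kept.drop_duplicates(subset=["qseqid", "sseqid"], keep="first")
    return kept.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Gene intervals

def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Extract ``gene`` features from a GFF3 file.

    Chromosome names may be plain integers or ``chrN``.  Uses gffutils with
    an in-memory database.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        seqid = feat.seqid.removeprefix("chr")
        try:
            chrom = int(seqid)
        except ValueError:
            continue  # scaffolds etc. are outside the 1-10 chromosome model
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(GeneModel(gene_id=gene_id, chromosome=chrom,
                               start_bp=feat.start, end_bp=feat.end,
                               strand=feat.strand or "+"))
    return genes


def genes_in_interval(genes: Iterable[GeneModel], lo_bp: int, hi_bp: int,
                      chromosome: int) -> list[GeneModel]:
    """Genes whose span intersects [lo_bp, hi_bp] on ``chromosome``
    (any-overlap rule, both strands)."""
    return [g for g in genes
            if g.chromosome == chromosome
            and g.start_bp <= hi_bp and g.end_bp >= lo_bp]


def candidate_gene_union(
        orthologs: Iterable[str],
        breeders_genes: Iterable[str],
        mta_peak_genes: Iterable[str]) -> dict[str, set[str]]:
    """De-duplicated union of the three candidate sources, each gene tagged
    with every source that produced it."""
    tagged: dict[str, set[str]] = {}
    for tag, source in (("ortholog", orthologs),
                        ("breeders_interval", breeders_genes),
                        ("mta_peak", mta_peak_genes)):
        for gene in source:
            tagged.setdefault(gene, set()).add(tag)
    return tagged


# ---------------------------------------------------------------------------
# Expression

def expression_filter(matrix: pd.DataFrame, tpm_min: float = 2.0) -> list[str]:
    """Genes whose maximum TPM over tissues strictly exceeds ``tpm_min``
    (i.e. expressed above the threshold in at least one tissue)."""
    if (matrix.to_numpy(float) < 0).any():
        raise ValueError("negative TPM values")
    keep = matrix.max(axis=1) > tpm_min
    return list(matrix.index[keep])


def transform_log2(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2(TPM + 1), the standard heat-map transform."""
    if (matrix.to_numpy(float) < 0).any():
        raise ValueError("negative TPM values")
    return np.log2(matrix + 1.0)
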