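"""Configuration-driven end-to-end meta-QTL pipeline.

Stages run in the published order: read → quality filter → CI imputation →
projection → per-chromosome meta-clustering → physical anchoring → GWAS MTA
overlap → classification → candidate genes → expression screen.  Every
stage writes a TSV report into the run directory and logs its input/output
counts; stages whose inputs were not supplied (e.g. no GWAS table) are
skipped with a warning while independent stages still run.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import anchoring, ci_tools, compendium, integration, meta_clustering
from . import projection as projection_mod

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline inputs and thresholds; defaults are the published study
    configuration."""

    # input paths
    qtl_table: Optional[str] = None
    genetic_maps: Optional[str] = None
    reference_map_id: str = "REF"
    marker_physical: Optional[str] = None
    mta_table: Optional[str] = None
    gff3: Optional[str] = None
    blast_tabular: Optional[str] = None
    tpm_matrix: Optional[str] = None
    trait_ontology: Optional[str] = None

    # thresholds (published defaults)
    max_ci_cm: float = 200.0
    min_pve: float = 1.0
    min_lod: float = 1.5
    strict_filters: bool = False
    z95: float = 3.92
    k_max: int = 10
    em_tol: float = 1e-8
    em_max_iter: int = 500
    n_starts: int = 10
    seed: int = 20240412
    window_bp: int = 500_000
    breeders_max_bp: int = 1_000_000
    breeders_max_cm: float = 4.0
    breeders_min_members: int = 2
    mta_min: int = 3
    max_evalue: float = 1e-10
    min_identity: float = 40.0
    tpm_min: float = 2.0
    tpm_min_secondary: float = 10.0

    outdir: str = "metaqtl_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class PipelineResult:
    config: RunConfig
    summary: compendium.CompendiumSummary
    filter_result: compendium.FilterResult
    projected: list
    cluster_results: dict
    mqtl_summary: meta_clustering.MQTLSummary
    physicals: list = field(default_factory=list)
    overlap: Optional[integration.OverlapReport] = None
    flags: Optional[integration.MQTLFlags] = None
    candidates: dict[str, set[str]] = field(default_factory=dict)
    expressed: list[str] = field(default_factory=list)
    stage_counts: dict[str, dict] = field(default_factory=dict)


def _write(df: pd.DataFrame, outdir: Path, name: str) -> None:
    df.to_csv(outdir / name, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full pipeline per ``config`` and write reports."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, dict] = {}

    ontology = (compendium.TraitOntology.from_table(config.trait_ontology)
                if config.trait_ontology else compendium.TraitOntology())

    if config.qtl_table is None:
        raise ValueError("qtl_table input is required")
    records = compendium.read_qtl_table(config.qtl_table, ontology)
    counts["read"] = {"input": len(records)}
    log.info("read: %d QTL records", len(records))

    fres = compendium.quality_filter(
        records, max_ci_cm=config.max_ci_cm, min_pve=config.min_pve,
        min_lod=config.min_lod, strict_filters=config.strict_filters)
    counts["filter"] = {"input": len(records), "kept": len(fres.kept),
                        "dropped": len(fres.dropped)}
    log.info("filter: kept %d, dropped %d", len(fres.kept), len(fres.dropped))
    _write(pd.DataFrame(
        [{"qtl_id": r.qtl_id, "reason": reason} for r, reason in fres.dropped],
        columns=["qtl_id", "reason"]), outdir, "dropped_qtl.tsv")

    summary = compendium.summarize_compendium(fres.kept)
    _write(summary.to_frame(), outdir, "compendium_summary.tsv")

    imputed = ci_tools.apply_imputation(fres.kept)
    n_imputed = sum(r.ci_imputed for r in imputed)
    counts["impute"] = {"input": len(fres.kept), "imputed": n_imputed}
    log.info("impute: %d CIs imputed", n_imputed)
    compendium.write_qtl_table(imputed, outdir / "qtl_imputed.tsv")

    if config.genetic_maps is None:
        raise ValueError("genetic_maps input is required")
    maps = compendium.read_genetic_maps(config.genetic_maps)
    if config.reference_map_id not in maps:
        raise ValueError(
            f"reference map {config.reference_map_id!r} not in map file")
    ref_map = maps.pop(config.reference_map_id)

    model = ci_tools.VarianceModel(z95=config.z95)
    projectable = [r for r in imputed if r.ci_start is not None]
    projected, proj_report = projection_mod.project_all(
        projectable, maps, ref_map, model=model)
    ok = [p for p in projected if p.ref_position is not None]
    counts["project"] = {"input": len(projectable), "projected": len(ok),
                         "unanchored": len(projected) - len(ok)}
    log.info("project: %d/%d QTL placed on %s", len(ok), len(projectable),
             ref_map.map_id)
    _write(proj_report, outdir, "projection_report.tsv")

    cluster_results = meta_clustering.meta_analyze(
        ok, k_max=config.k_max, n_starts=config.n_starts, seed=config.seed)
    mqtls = [m for res in cluster_results.values() for m in res.mqtls]
    msum = meta_clustering.summarize_mqtl(cluster_results)
    counts["cluster"] = {"input": len(ok), "n_mqtl": msum.n_mqtl}
    log.info("cluster: %d MQTL (mean CI %.2f cM, %.1f-fold reduction)",
             msum.n_mqtl, msum.mean_ci_cm, msum.fold_reduction)
    _write(meta_clustering.mqtl_table(cluster_results), outdir, "mqtl.tsv")
    crit = pd.concat(
        [res.criterion_table.assign(chr=chrom)
         for chrom, res in cluster_results.items()], ignore_index=True)
    _write(crit, outdir, "criterion_table.tsv")
    with open(outdir / "criterion_votes.json", "w") as fh:
        json.dump({str(c): res.votes for c, res in cluster_results.items()},
                  fh, indent=1)

    result = PipelineResult(config=config, summary=summary,
                            filter_result=fres, projected=projected,
                            cluster_results=cluster_results,
                            mqtl_summary=msum, stage_counts=counts)

    if config.marker_physical is None:
        log.warning("no marker physical table: anchoring and downstream "
                    "physical stages skipped")
        _finish(result, outdir)
        return result
    marker_bp = anchoring.read_marker_physical(config.marker_physical)
    physicals = anchoring.anchor_all(mqtls, ref_map, marker_bp)
    anchored = [p for p in physicals if p.start_bp is not None]
    counts["anchor"] = {"input": len(mqtls), "anchored": len(anchored)}
    log.info("anchor: %d/%d MQTL physically anchored", len(anchored), len(mqtls))
    _write(anchoring.physical_mqtl_table(physicals), outdir, "mqtl_physical.tsv")
    _write(anchoring.physical_mqtl_bed(physicals), outdir, "mqtl.bed")
    result.physicals = physicals

    overlap = None
    if config.mta_table is not None:
        mtas = compendium.read_mta_table(config.mta_table)
        overlap = integration.mta_overlap(physicals, mtas,
                                          window=config.window_bp)
        counts["overlap"] = {"n_mta": len(mtas),
                             "mqtl_with_mta": overlap.n_mqtl_with_mta,
                             "overlapping_mta": overlap.n_mta_total}
        log.info("overlap: %d MQTL overlap %d MTAs",
                 overlap.n_mqtl_with_mta, overlap.n_mta_total)
        _write(overlap.to_frame(), outdir, "mta_overlap.tsv")
        result.overlap = overlap
    else:
        log.warning("no MTA table: overlap stage skipped")

    flags = integration.classify_mqtl(
        physicals, overlap, max_physical_bp=config.breeders_max_bp,
        max_genetic_cm=config.breeders_max_cm,
        min_members=config.breeders_min_members, mta_min=config.mta_min)
    counts["classify"] = {"breeders": len(flags.breeders),
                          "mta_mqtl": len(flags.mta_mqtl),
                          "core": len(flags.core)}
    log.info("classify: %d breeders', %d MTA-MQTL, %d core",
             len(flags.breeders), len(flags.mta_mqtl), len(flags.core))
    _write(pd.DataFrame(
        [{"mqtl_id": p.mqtl_id,
          "breeders": p.mqtl_id in flags.breeders,
          "mta_mqtl": p.mqtl_id in flags.mta_mqtl,
          "core": p.mqtl_id in flags.core} for p in physicals]),
        outdir, "mqtl_classification.tsv")
    result.flags = flags

    # candidate genes
    orthologs: list[str] = []
    if config.blast_tabular is not None:
        hits = integration.read_blast_tabular(config.blast_tabular)
        kept = integration.filter_homology(
            hits, max_evalue=config.max_evalue, min_identity=config.min_identity)
        orthologs = sorted(set(kept["sseqid"]))
        counts["homology"] = {"input": len(hits), "kept": len(kept)}

    breeders_genes: list[str] = []
    mta_peak_genes: list[str] = []
    if config.gff3 is not None:
        genes = integration.read_gff3_genes(config.gff3)
        chrom_len = marker_bp.groupby("chr")["pos_bp"].max().to_dict()
        by_id = {p.mqtl_id: p for p in physicals}
        for mid in sorted(flags.breeders):
            p = by_id[mid]
            breeders_genes += [g.gene_id for g in integration.genes_in_interval(
                genes, p.start_bp, p.end_bp, p.chromosome)]
        for mid in sorted(flags.mta_mqtl - flags.breeders):
            p = by_id[mid]
            if p.peak_bp is None:
                continue
            lo, hi = anchoring.peak_window(
                p.peak_bp, half_width=config.window_bp,
                chrom_length=int(chrom_len.get(p.chromosome, 10**12)))
            mta_peak_genes += [g.gene_id for g in integration.genes_in_interval(
                genes, lo, hi, p.chromosome)]

    candidates = integration.candidate_gene_union(
        orthologs, breeders_genes, mta_peak_genes)
    counts["candidates"] = {"orthologs": len(set(orthologs)),
                            "breeders_genes": len(set(breeders_genes)),
                            "mta_peak_genes": len(set(mta_peak_genes)),
                            "union": len(candidates)}
    log.info("candidates: %d genes (union of three sources)", len(candidates))
    _write(pd.DataFrame(
        [{"gene_id": g, "sources": ",".join(sorted(tags))}
         for g, tags in sorted(candidates.items())],
        columns=["gene_id", "sources"]), outdir, "candidate_genes.tsv")
    result.candidates = candidates

    if config.tpm_matrix is not None and candidates:
        tpm = pd.read_csv(config.tpm_matrix, sep="\t", index_col=0)
        present = [g for g in candidates if g in tpm.index]
        sub = tpm.loc[present]
        expressed = integration.expression_filter(sub, tpm_min=config.tpm_min)
        high = integration.expression_filter(sub, tpm_min=config.tpm_min_secondary)
        counts["expression"] = {"candidates_with_tpm": len(present),
                                "expressed": len(expressed),
                                "high": len(high)}
        log.info("expression: %d/%d candidates above TPM %g (%d above %g)",
                 len(expressed), len(present), config.tpm_min,
                 len(high), config.tpm_min_secondary)
        integration.transform_log2(sub.loc[expressed]).to_csv(
            outdir / "expression_log2.tsv", sep="\t")
        result.expressed = expressed
    elif config.tpm_matrix is None:
        log.warning("no TPM matrix: expression stage skipped")

    _finish(result, outdir)
    return result


def _finish(result: PipelineResult, outdir: Path) -> None:
    with open(outdir / "stage_counts.json", "w") as fh:
        json.dump(result.stage_counts, fh, indent=1)
    result.config.to_yaml(outdir / "config_used.yaml")
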