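"""Mine candidate genes by homology, interval, and expression evidence.

Three sources are combined: cross-species protein homologs (BLAST hits at
E-value < 1e-10 and identity > 40%), genes inside breeders' MQTL
intervals, and genes within ±500 kb of MTA-MQTL peaks.  Candidates are
then screened for expression: TPM > 2 in at least one tissue.
"""
from metaqtl import (candidate_gene_union, expression_filter, filter_homology,
                     genes_in_interval, transform_log2)
from metaqtl.synthetic import (ScenarioConfig, generate_annotations,
                               generate_compendium)

comp = generate_compendium(ScenarioConfig.small(), seed=7)
ann = generate_annotations(comp, seed=8)

kept = filter_homology(ann.blast)
orthologs = sorted(set(kept["sseqid"]))
print(f"homology: {len(ann.blast)} alignments -> {len(kept)} pass the "
      f"E-value/identity filter ({len(orthologs)} genes)")

# genes around the first planted locus's peak
locus = comp.truth.true_mqtl.iloc[0]
center = int(locus["pos_bp"])
peak_genes = [g.gene_id for g in genes_in_interval(
    ann.genes, center - 500_000, center + 500_000, int(locus["chr"]))]
print(f"peak window chr{int(locus['chr'])}:{center-500_000}-{center+500_000}: "
      f"{len(peak_genes)} genes")

candidates = candidate_gene_union(orthologs, [], peak_genes)
multi = [g for g, tags in candidates.items() if len(tags) > 1]
print(f"candidate union: {len(candidates)} genes "
      f"({len(multi)} supported by two sources)")

tpm = ann.tpm.loc[[g for g in candidates if g in ann.tpm.index]]
expressed = expression_filter(tpm, tpm_min=2.0)
high = expression_filter(tpm, tpm_min=10.0)
print(f"expression screen: {len(expressed)}/{len(tpm)} candidates with "
      f"TPM > 2 in some tissue ({len(high)} above 10)")
print("\nlog2(TPM+1) for the first expressed candidate:")
print(transform_log2(tpm.loc[[expressed[0]]]).round(2).to_string())
# Genes passing several independent filters at once are the strongest
# candidates for follow-up work.
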