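"""MTA co-localization, MQTL classification, and candidate-gene filters."""
import numpy as np
import pandas as pd
import pytest

from metaqtl.anchoring import PhysicalMQTL
from metaqtl.compendium import MTA
from metaqtl.integration import (BLAST6_COLUMNS, GeneModel,
                                 candidate_gene_union, classify_mqtl,
                                 expression_filter, filter_homology,
                                 genes_in_interval, mta_overlap,
                                 read_blast_tabular, read_gff3_genes,
                                 transform_log2)
from tests.test_anchoring import make_mqtl


def make_physical(mqtl_id="MQTL1_1", chrom=1, start=5_000_000, end=6_000_000,
                  ci_lo=10.0, ci_hi=12.0, n_members=3):
    m = make_mqtl(ci_lo, ci_hi, chrom=chrom, n_members=n_members)
    m.mqtl_id = mqtl_id
    return PhysicalMQTL(mqtl=m, start_bp=start, end_bp=end,
                        peak_bp=(start + end) // 2,
                        anchor_quality="both_flanks")


def mta_at(pos, chrom=1, marker="s1"):
    return MTA(marker=marker, chromosome=chrom, position_bp=pos, trait="GY")


class TestMtaOverlap:
    def test_within_window(self):
        rep = mta_overlap([make_physical()], [mta_at(6_400_000)])
        assert rep.n_mta("MQTL1_1") == 1

    def test_strictly_outside_window(self):
        rep = mta_overlap([make_physical()], [mta_at(6_500_001)])
        assert rep.n_mta("MQTL1_1") == 0
        # inclusive boundary: exactly at end + window overlaps
        rep = mta_overlap([make_physical()], [mta_at(6_500_000)])
        assert rep.n_mta("MQTL1_1") == 1

    def test_other_chromosome_never_overlaps(self):
        rep = mta_overlap([make_physical()], [mta_at(5_500_000, chrom=2)])
        assert rep.n_mta("MQTL1_1") == 0

    def test_window_zero_is_plain_intersection_and_monotone(self, rng):
        mqtl = make_physical()
        mtas = [mta_at(int(p), marker=f"s{i}")
                for i, p in enumerate(rng.integers(4e6, 8e6, 50))]
        inside = [m for m in mtas
                  if mqtl.start_bp <= m.position_bp <= mqtl.end_bp]
        rep0 = mta_overlap([mqtl], mtas, window=0)
        assert rep0.n_mta("MQTL1_1") == len(inside)
        prev = 0
        for w in (0, 100_000, 500_000, 2_000_000):
            n = mta_overlap([mqtl], mtas, window=w).n_mta("MQTL1_1")
            assert n >= prev
            prev = n


class TestClassify:
    def test_breeders_criteria_strict(self):
        good = make_physical("A", start=5_000_000, end=5_500_000,
                             ci_lo=10.0, ci_hi=13.0, n_members=3)
        two_members = make_physical("B", start=5_000_000, end=5_500_000,
                                    ci_lo=10.0, ci_hi=13.0, n_members=2)
        wide_phys = make_physical("C", start=5_000_000, end=6_000_000,
                                  ci_lo=10.0, ci_hi=13.0, n_members=3)
        wide_gen = make_physical("D", start=5_000_000, end=5_500_000,
                                 ci_lo=10.0, ci_hi=14.0, n_members=3)
        flags = classify_mqtl([good, two_members, wide_phys, wide_gen])
        assert flags.breeders == {"A"}

    def test_exactly_1mb_not_breeders(self):
        # physical width must be strictly below 1 Mb
        at_limit = make_physical("E", start=5_000_000, end=6_000_000,
                                 ci_lo=10.0, ci_hi=12.0)
        assert classify_mqtl([at_limit]).breeders == set()

    def test_mta_mqtl_strictly_more_than_three(self):
        p = make_physical()
        three = mta_overlap([p], [mta_at(5_100_000 + i, marker=f"s{i}")
                                  for i in range(3)])
        four = mta_overlap([p], [mta_at(5_100_000 + i, marker=f"s{i}")
                                 for i in range(4)])
        assert classify_mqtl([p], three).mta_mqtl == set()
        assert classify_mqtl([p], four).mta_mqtl == {"MQTL1_1"}

    def test_core_is_union(self):
        a = make_physical("A", start=5_000_000, end=5_400_000,
                          ci_lo=10.0, ci_hi=12.0)
        b = make_physical("B", chrom=2, start=8_000_000, end=12_000_000,
                          ci_lo=50.0, ci_hi=60.0)
        rep = mta_overlap([a, b], [mta_at(9_000_000 + i, chrom=2,
                                          marker=f"s{i}") for i in range(5)])
        flags = classify_mqtl([a, b], rep)
        assert flags.core == {"A", "B"}

    def test_unanchored_mqtl_not_breeders(self):
        p = PhysicalMQTL(mqtl=make_mqtl(10.0, 11.0), anchor_quality="failed")
        assert classify_mqtl([p]).breeders == set()

    def test_pure_function(self):
        p = make_physical()
        rep = mta_overlap([p], [mta_at(5_100_000 + i, marker=f"s{i}")
                                for i in range(6)])
        f1 = classify_mqtl([p], rep)
        f2 = classify_mqtl([p], rep)
        assert f1.breeders == f2.breeders and f1.mta_mqtl == f2.mta_mqtl


class TestHomology:
    def _hits(self, rows):
        return pd.DataFrame(rows, columns=["qseqid", "sseqid", "pident",
                                           "evalue"]).assign(bitscore=100.0)

    def test_boundary_semantics(self):
        hits = self._hits([
            ("r1", "z1", 55.0, 1e-12),   # kept
            ("r2", "z2", 55.0, 1e-10),   # dropped: e-value not < 1e-10
            ("r3", "z3", 40.0, 1e-30),   # dropped: identity not > 40
        ])
        kept = filter_homology(hits)
        assert list(kept["qseqid"]) == ["r1"]

    def test_best_hit_per_pair(self):
        hits = self._hits([
            ("r1", "z1", 50.0, 1e-20),
            ("r1", "z1", 90.0, 1e-15),   # worse e-value: dropped
            ("r1", "z2", 60.0, 1e-15),
        ])
        kept = filter_homology(hits)
        assert len(kept) == 2
        z1 = kept[kept["sseqid"] == "z1"].iloc[0]
        assert z1["evalue"] == 1e-20

    def test_malformed_rows_skipped_and_counted(self, tmp_path):
        p = tmp_path / "hits.tsv"
        good = "\t".join(["r1", "z1", "55.0", "100", "45", "0", "1", "100",
                          "1", "100", "1e-20", "200.5"])
        p.write_text(good + "\nshort\tline\n" + good.replace("r1", "r2") + "\n")
        df = read_blast_tabular(p)
        assert len(df) == 2
        assert df.attrs["n_malformed"] == 1


class TestGenes:
    GENES = [GeneModel("g1", 1, 100, 200),
             GeneModel("g2", 1, 250, 300, strand="-"),
             GeneModel("g3", 2, 100, 200)]

    def test_any_overlap_rule(self):
        assert [g.gene_id for g in
                genes_in_interval(self.GENES, 150, 300, 1)] == ["g1", "g2"]

    def test_adjacent_but_disjoint_excluded(self):
        assert genes_in_interval([GeneModel("g", 1, 100, 200)], 201, 300, 1) == []

    def test_containment_included(self):
        spanning = GeneModel("big", 1, 50, 500)
        assert genes_in_interval([spanning], 150, 160, 1) == [spanning]

    def test_gff3_round_trip(self, tmp_path):
        from metaqtl.synthetic import write_gff3
        p = tmp_path / "genes.gff3"
        write_gff3(self.GENES, p)
        back = read_gff3_genes(p)
        assert [(g.gene_id, g.chromosome, g.start_bp, g.end_bp, g.strand)
                for g in back] == \
            [(g.gene_id, g.chromosome, g.start_bp, g.end_bp, g.strand)
             for g in self.GENES]


class TestCandidateUnion:
    def test_multi_source_gene_tagged_once(self):
        union = candidate_gene_union(["g1", "g2"], ["g2"], [])
        assert union["g2"] == {"ortholog", "breeders_interval"}
        assert len(union) == 2

    def test_empty_sources(self):
        assert candidate_gene_union([], [], []) == {}

    def test_union_bounded_by_sum(self, rng):
        a = [f"g{i}" for i in rng.integers(0, 30, 20)]
        b = [f"g{i}" for i in rng.integers(0, 30, 20)]
        c = [f"g{i}" for i in rng.integers(0, 30, 20)]
        union = candidate_gene_union(a, b, c)
        assert len(union) <= len(a) + len(b) + len(c)
        assert set(union) == set(a) | set(b) | set(c)


class TestExpression:
    def _matrix(self, rows):
        return pd.DataFrame(rows).T.rename(columns=lambda i: f"t{i}")

    def test_kept_if_above_threshold_in_any_tissue(self):
        m = self._matrix({"g1": [0.0, 0.0, 2.5], "g2": [1.0, 1.5, 1.9]})
        assert expression_filter(m) == ["g1"]

    def test_exactly_two_dropped(self):
        m = self._matrix({"g1": [2.0, 2.0, 2.0]})
        assert expression_filter(m) == []

    def test_threshold_10_subset_of_2(self, rng):
        m = pd.DataFrame(rng.uniform(0, 20, size=(30, 5)),
                         index=[f"g{i}" for i in range(30)])
        assert set(expression_filter(m, 10.0)) <= set(expression_filter(m, 2.0))

    def test_negative_tpm_rejected(self):
        m = self._matrix({"g1": [-0.1, 1.0]})
        with pytest.raises(ValueError):
            expression_filter(m)

    def test_log2_transform(self):
        m = self._matrix({"g1": [3.0, 0.0]})
        out = transform_log2(m)
        assert out.loc["g1"].tolist() == pytest.approx([2.0, 0.0])
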