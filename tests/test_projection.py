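"""QTL projection between genetic maps via shared flanking markers."""
import numpy as np
import pytest

from metaqtl.projection import (ChromProjector, find_common_flank, project_all,
                                project_qtl)
from tests.conftest import make_map


class TestFindCommonFlank:
    def test_basic_bracket(self, simple_maps):
        study, ref = simple_maps
        assert find_common_flank(study, ref, 1, 18.0) == ("a", "b")

    def test_no_bracket_below_first_anchor(self, simple_maps):
        study, ref = simple_maps
        assert find_common_flank(study, ref, 1, 5.0) is None

    def test_tightest_bracket_chosen(self):
        study = make_map("S", {1: [("a", 10.0), ("b", 20.0), ("c", 30.0)]})
        ref = make_map("R", {1: [("a", 10.0), ("b", 20.0), ("c", 30.0)]})
        assert find_common_flank(study, ref, 1, 22.0) == ("b", "c")

    def test_absent_chromosome_raises(self, simple_maps):
        study, ref = simple_maps
        with pytest.raises(KeyError):
            find_common_flank(study, ref, 2, 18.0)

    def test_fewer_than_two_shared_markers_is_none(self):
        study = make_map("S", {1: [("a", 10.0), ("x", 20.0)]})
        ref = make_map("R", {1: [("a", 10.0), ("y", 20.0)]})
        assert find_common_flank(study, ref, 1, 15.0) is None


class TestProjectQtl:
    def test_affine_scale_two(self, record):
        study = make_map("STUDY", {1: [("a", 10.0), ("b", 30.0)]})
        ref = make_map("REF", {1: [("a", 100.0), ("b", 140.0), ("z", 200.0)]})
        p = project_qtl(record(), study, ref)
        assert p.projection_status == "projected"
        assert p.ref_position == pytest.approx(120.0)
        assert (p.ref_ci_lo, p.ref_ci_hi) == (pytest.approx(110.0),
                                              pytest.approx(130.0))
        assert p.ref_variance == pytest.approx((20.0 / 3.92) ** 2)
        assert p.anchor_markers == ("a", "b")

    def test_identity_on_identical_maps(self, record):
        m = make_map("A", {1: [("a", 0.0), ("b", 25.0), ("c", 60.0)]})
        ref = make_map("B", {1: [("a", 0.0), ("b", 25.0), ("c", 60.0)]})
        p = project_qtl(record(map_id="A"), m, ref)
        assert p.ref_position == pytest.approx(20.0)
        assert p.ref_ci_lo == pytest.approx(15.0)
        assert p.ref_ci_hi == pytest.approx(25.0)

    def test_compression_by_half(self, record):
        # anchors study (0,10) -> ref (0,5): every coordinate halves
        study = make_map("S", {1: [("a", 0.0), ("b", 10.0)]})
        ref = make_map("R", {1: [("a", 0.0), ("b", 5.0)]})
        rec = record(position=4.0, ci_start=2.0, ci_end=6.0)
        p = project_qtl(rec, study, ref)
        # independent linear interpolation: x_ref = x_study * (5-0)/(10-0)
        assert p.ref_position == pytest.approx(4.0 * 0.5)
        assert p.ref_ci_lo == pytest.approx(1.0)
        assert p.ref_ci_hi == pytest.approx(3.0)

    def test_reference_map_passthrough(self, record):
        ref = make_map("REF", {1: [("a", 0.0), ("b", 100.0)]})
        p = project_qtl(record(map_id="REF"), ref, ref)
        assert p.ref_position == 20.0 and p.projection_status == "projected"

    def test_extrapolation_is_flagged(self, record):
        study = make_map("S", {1: [("a", 30.0), ("b", 50.0)]})
        ref = make_map("R", {1: [("a", 30.0), ("b", 50.0), ("z", 100.0)]})
        p = project_qtl(record(position=20.0, ci_start=15.0, ci_end=25.0),
                        study, ref)
        assert p.projection_status == "unanchored_extrapolated"

    def test_missing_ci_rejected(self, record):
        study = make_map("S", {1: [("a", 0.0), ("b", 100.0)]})
        with pytest.raises(ValueError, match="CI missing"):
            project_qtl(record(ci_start=None, ci_end=None), study, study)


class TestProjectionProperties:
    @pytest.fixture()
    def distorted_maps(self, rng):
        # monotone piecewise-linear distortion between the two maps
        n = 20
        study_pos = np.sort(rng.uniform(0, 100, n))
        ref_pos = np.cumsum(rng.uniform(0.5, 3.0, n))
        markers = [f"m{i}" for i in range(n)]
        study = make_map("S", {1: list(zip(markers, study_pos))})
        ref = make_map("R", {1: list(zip(markers, ref_pos))})
        return study, ref

    def test_order_preserved(self, distorted_maps, record, rng):
        study, ref = distorted_maps
        positions = np.sort(rng.uniform(5, 95, 15))
        projected = [
            project_qtl(record(qtl_id=f"q{i}", position=p, ci_start=p - 1,
                               ci_end=p + 1), study, ref).ref_position
            for i, p in enumerate(positions)
        ]
        assert np.all(np.diff(projected) >= 0)

    def test_round_trip_identity(self, distorted_maps, record, rng):
        study, ref = distorted_maps
        fwd = ChromProjector(study, ref, 1)
        back = ChromProjector(ref, study, 1)
        for p in rng.uniform(5, 95, 20):
            there, _ = fwd.transform(p)
            home, _ = back.transform(there)
            assert home == pytest.approx(p, abs=1e-9)

    def test_monotone_maps_never_invert_ci(self, distorted_maps, record, rng):
        study, ref = distorted_maps
        for p in rng.uniform(5, 90, 10):
            q = project_qtl(record(position=p, ci_start=p - 3.0, ci_end=p + 4.0),
                            study, ref)
            assert q.ref_ci_lo <= q.ref_position <= q.ref_ci_hi

    def test_conflicting_marker_discarded(self, record):
        # marker x is inverted on the reference map; it must not anchor
        study = make_map("S", {1: [("a", 0.0), ("x", 10.0), ("b", 20.0)]})
        ref = make_map("R", {1: [("a", 0.0), ("b", 40.0), ("x", 60.0)]})
        proj = ChromProjector(study, ref, 1)
        assert proj.n_conflicts == 1
        assert "x" not in set(proj.marker_names)
        p = project_qtl(record(position=10.0, ci_start=8.0, ci_end=12.0),
                        study, ref)
        assert p.ref_position == pytest.approx(20.0)  # scale 2 from (a, b)


class TestProjectAll:
    def test_synthetic_projection_recovers_reference_positions(
            self, small_compendium):
        comp = small_compendium
        from metaqtl.ci_tools import apply_imputation

        recs = [r for r in apply_imputation(comp.records)
                if r.ci_start is not None]
        projected, report = project_all(recs, comp.study_maps, comp.ref_map)
        assert (report["status"] == "projected").all()
        # study maps are rescaled reference subsets: projection must undo the
        # rescaling exactly (QTL sit between retained markers)
        scales = {m.map_id: m.markers(1)["pos_cM"].iloc[-1]
                  / comp.ref_map.markers(1)["pos_cM"].iloc[-1]
                  for m in comp.study_maps.values()}
        for p in projected[:30]:
            expected = p.record.position / scales[p.record.map_id]
            assert p.ref_position == pytest.approx(expected, abs=1e-6)
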