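import numpy as np
import pytest

from metaqtl.compendium import GeneticMap, QTLRecord
from metaqtl.synthetic import ScenarioConfig, generate_compendium


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_map(map_id, chrom_markers):
    """Build a GeneticMap from {chrom: [(name, cM), ...]}."""
    import pandas as pd

    return GeneticMap(map_id, {
        c: pd.DataFrame(rows, columns=["marker", "pos_cM"])
        for c, rows in chrom_markers.items()
    })


@pytest.fixture()
def simple_maps():
    """A study map and reference map sharing markers with a 2x scale."""
    study = make_map("STUDY", {1: [("a", 10.0), ("b", 30.0), ("c", 50.0)]})
    ref = make_map("REF", {1: [("a", 100.0), ("b", 140.0), ("c", 180.0)]})
    return study, ref


@pytest.fixture()
def record():
    def _make(**kw):
        base = dict(qtl_id="q1", study_id="S1", trait="GY", chromosome=1,
                    position=20.0, ci_start=15.0, ci_end=25.0, lod=3.0,
                    pve=10.0, pop_type="RIL", pop_size=200, map_id="STUDY",
                    trait_category="GY")
        base.update(kw)
        return QTLRecord(**base)
    return _make


@pytest.fixture(scope="session")
def small_compendium():
    """A deterministic 2-chromosome compendium shared across tests."""
    return generate_compendium(ScenarioConfig.small(), seed=7)
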