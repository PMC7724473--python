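"""Shared fixtures: synthetic studies are generated once per session."""

import numpy as np
import pytest

from pcs import simulate as sim
from pcs.pipeline import clustering_features


@pytest.fixture(scope="session")
def study():
    """The default 6-class, 14-condition synthetic study."""
    return sim.simulate_study(seed=1)


@pytest.fixture(scope="session")
def study_features(study):
    """Clustering feature matrix (peaks x (bins * conditions)) for it."""
    return clustering_features(study)


@pytest.fixture(scope="session")
def planted_labels(study):
    return [p.class_label for p in study.universe.planted]


@pytest.fixture(scope="session")
def minimal_study():
    """A small two-class, two-condition study for fast I/O tests."""
    classes = [
        sim.PeakClassSpec("narrow1", 30, (1000, 2000), (15.0, 30.0),
                          "sharp-gaussian", gcg_density=8.0, cpg_like=True),
        sim.PeakClassSpec("broad5", 15, (4000, 8000), (8.0, 16.0),
                          "flat-plateau", gcg_density=1.0),
    ]
    conditions = [
        sim.ConditionSpec(("EZH2", "WT", "none"), {"narrow1": 1.0, "broad5": 1.0}),
        sim.ConditionSpec(("EZH2", "Mtf2GT", "none"), {"narrow1": 0.10, "broad5": 0.50},
                          global_efficiency=0.5),
    ]
    return sim.simulate_study(7, class_specs=classes,
                              genome={"chrS1": 1_200_000}, conditions=conditions)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
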