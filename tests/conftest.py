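"""Shared fixtures: one full discovery study reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from latentmix import synthio, workflow
from latentmix.containers import ExpressionMatrix


@pytest.fixture(scope="session")
def profiles():
    return synthio.make_reference_profiles(1500, seed=1)


@pytest.fixture(scope="session")
def study():
    """Full discovery study at the default cohort scale (n=120, 1500 genes)."""
    return workflow.run_discovery_study(seed=1)


@pytest.fixture(scope="session")
def validation_cohort(study):
    """Independently simulated cohort from the same tissue profiles."""
    config = synthio.SimulationConfig(seed=1001)
    counts, meta, truth = synthio.simulate_bulk(study.profiles, config)
    return counts, meta, truth


@pytest.fixture(scope="session")
def single_cell(study):
    """Labeled single cells for a fresh cohort from the same profiles."""
    return synthio.simulate_single_cell(
        study.profiles, synthio.SimulationConfig(seed=2001))


@pytest.fixture(scope="session")
def spatial(study):
    """Layer-structured spatial spots from the same profiles."""
    return synthio.simulate_spatial(study.profiles, n_spots_per_layer=30,
                                    seed=3001)


@pytest.fixture
def tiny_counts():
    """3 genes x 2 samples counts matrix."""
    return ExpressionMatrix(pd.DataFrame(
        [[1.0, 2.0], [3.0, 6.0], [5.0, 10.0]],
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
        columns=["s1", "s2"]), "counts")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
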