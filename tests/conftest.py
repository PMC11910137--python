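"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pandas as pd
import pytest

import ramantax as rt
from ramantax import benchmark as bm


def make_tiny_config(**overrides):
    """4 strains / 3 genera / 2 phyla, 10 spectra per strain per stage."""
    base = dict(
        n_strains=4,
        genus_partition=(2, 1, 1),
        phylum_partition=(2, 1),
        spectra_per_strain_per_stage=10,
        grid=(600.0, 1800.0, 80),
        seed=0,
    )
    base.update(overrides)
    return rt.SyntheticConfig(**base)


@pytest.fixture(scope="session")
def tiny_ds():
    """160 spectra x 80 channels: 4 strains x 4 stages x 10."""
    cfg = make_tiny_config()
    return rt.generate_dataset(rt.make_taxonomy(cfg), cfg)


@pytest.fixture(scope="session")
def small_ds():
    """6 strains x 4 stages x 15 = 360 spectra x 120 channels."""
    cfg = rt.small_config(
        n_strains=6, genus_partition=(2, 2, 1, 1), phylum_partition=(3, 1),
        spectra_per_strain_per_stage=15, grid=(600.0, 1800.0, 120), seed=1,
    )
    return rt.generate_dataset(rt.make_taxonomy(cfg), cfg)


@pytest.fixture
def toy_ds():
    """Hand-built 3-cell x 5-channel dataset."""
    grid = rt.WavenumberGrid(np.array([600.0, 700.0, 800.0, 900.0, 1000.0]))
    X = np.array([
        [1.0, 2.0, 3.0, 4.0, 5.0],
        [5.0, 6.0, 7.0, 8.0, 9.0],
        [0.5, 0.5, 0.5, 0.5, 0.5],
    ])
    labels = pd.DataFrame({
        "cell_id": ["c1", "c2", "c3"],
        "strain": ["a", "a", "b"],
        "genus": ["ga", "ga", "gb"],
        "phylum": ["p", "p", "p"],
        "stage": ["Exp", "S1", rt.STAGE_UNKNOWN],
    })
    return rt.SpectraDataset(grid=grid, intensities=X, labels=labels)


def fast_plan(**overrides):
    base = dict(n_folds=2, inner_folds=3, seed=0)
    base.update(overrides)
    return bm.CVPlan(**base)
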