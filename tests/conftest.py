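"""Shared fixtures: one small synthetic cohort and its trained classifier.

Everything here is generated at test time from fixed seeds; session scope
keeps the expensive pieces (cohort simulation, classifier training) to a
single build shared by all tests.
"""

import numpy as np
import pytest

import langmap as lm
from langmap import connectivity


@pytest.fixture(scope="session")
def grid():
    return lm.GridSpec()


@pytest.fixture(scope="session")
def mask(grid):
    return grid.brain_mask()


@pytest.fixture(scope="session")
def atlas(grid):
    return lm.make_network_atlas(grid, 7, seed=1)


@pytest.fixture(scope="session")
def roi_set(atlas, grid):
    return lm.make_roi_set(atlas[0], grid)


@pytest.fixture(scope="session")
def cohort(grid):
    """Five subjects under the default study conditions, master seed 3."""
    return lm.make_cohort(5, master_seed=3, grid=grid)


@pytest.fixture(scope="session")
def trained_model(cohort, mask):
    ts = connectivity.build_training_set(
        cohort, cohort[0].truth_atlas, mask=mask, seed=11
    )
    return connectivity.train_mlp(ts, seed=5)


@pytest.fixture(scope="session")
def subject_likelihoods(cohort, trained_model, mask):
    return connectivity.classify_voxelwise(cohort[0].rest_runs, trained_model, mask)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
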