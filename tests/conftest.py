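"""Shared fixtures: one default synthetic dataset per session plus its
fitted curves and training sets, so the expensive generation happens once."""

import numpy as np
import pandas as pd
import pytest

from mirdyn.fda import fit_curves, make_basis, rms_scale
from mirdyn.synthetic import SynthConfig, generate_timecourse
from mirdyn.targets import build_training_sets

MICROARRAY_GRID = (2., 4., 6., 8., 10., 12., 14., 16., 18., 20., 22., 26.,
                   32., 40., 56., 80., 112.)


@pytest.fixture(scope="session")
def default_config():
    return SynthConfig(rng_seed=1)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    return generate_timecourse(default_config)


@pytest.fixture(scope="session")
def default_basis(default_config):
    return make_basis(default_config.time_grid)


@pytest.fixture(scope="session")
def default_curves(default_dataset, default_basis):
    return fit_curves(default_dataset.fc, default_basis)


@pytest.fixture(scope="session")
def default_sets(default_dataset):
    return build_training_sets(default_dataset.predictions,
                               default_dataset.annotations,
                               default_dataset.fc, threshold=1.5,
                               rng_seed=0)


@pytest.fixture(scope="session")
def scaled_early(default_curves):
    return rms_scale(default_curves, window=(2.0, 20.0))


@pytest.fixture(scope="session")
def training_labels(default_sets):
    ids = sorted(default_sets.direct) + sorted(default_sets.indirect)
    labels = np.array([1] * len(default_sets.direct)
                      + [0] * len(default_sets.indirect))
    return ids, labels


def toy_fc(values, times=MICROARRAY_GRID, genes=None):
    """Small fold-change frame helper for unit tests."""
    values = np.atleast_2d(values)
    if genes is None:
        genes = [f"g{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=genes,
                        columns=[f"t{t:g}" for t in times])
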