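"""Shared fixtures: all test data is generated programmatically.

Session-scoped fixtures hold the expensive artifacts (a labeled synthetic
reconstruction and a rendered two-channel movie) so the suite builds each
only once.
"""
import numpy as np
import pytest

from spindlemorph import classify as cls
from spindlemorph import synthetic as syn


@pytest.fixture(scope="session")
def labeled_model():
    """A small metaphase reconstruction with designed KMT labels."""
    recipe = syn.GeometryRecipe(seed=7, n_mts=80, x_end_on=8, x_lateral=8,
                                autosome_end_on=20, autosome_lateral=20)
    model, truth = syn.simulate_geometry(recipe)
    return model, truth, recipe


@pytest.fixture(scope="session")
def annotations(labeled_model):
    model, truth, _ = labeled_model
    return cls.classify_all(model)


@pytest.fixture(scope="session")
def movie():
    """A meiosis-I movie rendered from measured kinetics (with noise)."""
    params = syn.KineticsParams(seed=11, duration_min=6.0)
    rng = np.random.default_rng(11)
    traj = syn.simulate_kinetics(params, rng)
    series, truth = syn.render_movie(traj, params, rng)
    return series, traj, truth, params


@pytest.fixture(scope="session")
def quiet_movie():
    """A short noise-free movie for sub-voxel accuracy checks."""
    params = syn.KineticsParams(seed=5, duration_min=3.0, baseline_min=1.0)
    traj = syn.simulate_kinetics(params, np.random.default_rng(5))
    series, truth = syn.render_movie(traj, params, noise=False)
    return series, traj, truth, params
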