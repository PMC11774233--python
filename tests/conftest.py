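import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from namdclust.datasets import load_ensemble
from namdclust.synthetic import SynthConfig, simulate_ensemble


@pytest.fixture(scope="session")
def small_ensemble_dir(tmp_path_factory):
    """A small on-disk synthetic ensemble with the default (oscillating) modes."""
    out = tmp_path_factory.mktemp("ens_small")
    simulate_ensemble(SynthConfig(n_trajs=5, n_steps=50, dt=0.1, seed=42), out)
    return out


@pytest.fixture(scope="session")
def small_ensemble(small_ensemble_dir):
    return load_ensemble(small_ensemble_dir)


@pytest.fixture(scope="session")
def separated_ensemble_dir(tmp_path_factory):
    """Three planted conformer classes separated far beyond the class spread."""
    out = tmp_path_factory.mktemp("ens_sep")
    simulate_ensemble(SynthConfig.well_separated(seed=11), out)
    return out


@pytest.fixture(scope="session")
def separated_ensemble(separated_ensemble_dir):
    return load_ensemble(separated_ensemble_dir)


def random_rigid_motion(rng):
    """A uniformly random proper rotation plus a translation."""
    rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    shift = rng.uniform(-10, 10, size=3)
    return rot, shift


def apply_rigid(geom, rot, shift):
    from namdclust.datasets import Geometry

    return Geometry(geom.labels, geom.coords @ rot.T + shift)
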