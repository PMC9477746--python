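"""Shared fixtures: synthetic assemblies and their decompositions.

Everything is generated programmatically at test time; session scope keeps
the suite fast since the generated series are immutable inputs.
"""

import numpy as np
import pytest

import ruvmotor as rm
from ruvmotor.decomposition import decompose_state

DNA_CHAINS = ("X", "Y")
RUVA_CHAINS = ("U", "V")


def make_decomps(models):
    return [decompose_state(m, dna_chains=DNA_CHAINS, ruva_chains=RUVA_CHAINS)
            for m in models]


def random_rigid_transform(rng) -> rm.RigidTransform:
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-30, 30, size=3)
    return rm.RigidTransform(R, t)


@pytest.fixture(scope="session")
def canonical_series():
    """Five noise-free states with no programmed motion (static control)."""
    models, gt = rm.build_motor_series(rm.SyntheticAssemblySpec(), 5)
    return models, make_decomps(models), gt


@pytest.fixture(scope="session")
def lever_series():
    """Five noise-free states with a programmed 1.75 A lift per transition."""
    spec = rm.SyntheticAssemblySpec(lift_per_transition=1.75)
    models, gt = rm.build_motor_series(spec, 5)
    return models, make_decomps(models), gt


@pytest.fixture(scope="session")
def trajectory_series():
    """Five noise-free states where subunit E steps 1.75 A per transition."""
    spec = rm.SyntheticAssemblySpec(trajectory_step_E=1.75)
    models, gt = rm.build_motor_series(spec, 5)
    return models, make_decomps(models), gt


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A default five-state fixture set written to disk, with its manifest."""
    out = tmp_path_factory.mktemp("fixtures")
    manifest = rm.write_fixture_set(rm.SyntheticAssemblySpec(), out, n_states=5)
    return manifest
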