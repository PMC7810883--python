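import warnings

import numpy as np
import pytest

from pdzdyn import SyntheticSpec, generate_trajectory

# biotite warns about nonstandard residues in toy PDBs; irrelevant here
warnings.filterwarnings("ignore", module="biotite")


@pytest.fixture(scope="session")
def small_traj():
    """A small OU trajectory over the toy PDZ topology (full backbone)."""
    return generate_trajectory(SyntheticSpec(seed=11, n_frames=40, dt_ns=0.5, sigma_nm=0.02))


@pytest.fixture(scope="session")
def toy_topology(small_traj):
    return small_traj.topology


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """The canonical emitted fixture set, shared across pipeline tests."""
    from pdzdyn import emit_fixture_set

    outdir = tmp_path_factory.mktemp("fixtures")
    manifest = emit_fixture_set(outdir, seed=7)
    return outdir, manifest


def rigid_transform(rng):
    """A random proper rotation + translation, for invariance tests."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    trans = rng.normal(size=3)
    return rot, trans
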