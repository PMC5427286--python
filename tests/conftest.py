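import numpy as np
import pytest

from oligoxl import synthetic


@pytest.fixture(scope="session")
def dodecamer_fixture():
    """A toy dodecamer with known screw parameters (30 deg, 35 A)."""
    return synthetic.make_assembly_fixture(theta=30.0, d=35.0, seed=11)


@pytest.fixture(scope="session")
def toy_dimer():
    return synthetic.make_toy_dimer(n_residues=30, seed=5)


@pytest.fixture(scope="session")
def hsp21_sequence():
    return synthetic.hsp21_synthetic_sequence()


@pytest.fixture(scope="session")
def sphere_cloud():
    """Uniform point cloud in a sphere of radius 20 A (2 nm)."""
    rng = np.random.default_rng(0)
    n, radius = 3000, 20.0
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    pts *= radius * rng.uniform(0.0, 1.0, n)[:, None] ** (1.0 / 3.0)
    return pts, radius
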