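import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pamscope.io_selection import AtomMeta, Structure, Trajectory

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_structure(spec, coords):
    """Build a Structure from (name, resid, resname, chain, mass) tuples."""
    atoms = [
        AtomMeta(i, name, resid, resname, chain, mass)
        for i, (name, resid, resname, chain, mass) in enumerate(spec)
    ]
    return Structure(atoms=atoms, coords=np.asarray(coords, dtype=float))


def make_trajectory(structure, frames, dt=1.0):
    frames = np.asarray(frames, dtype=float)
    return Trajectory(
        structure=structure, frames=frames, times=dt * np.arange(frames.shape[0])
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def water_dimer():
    """Two pseudo-residues with unit masses for COM arithmetic tests."""
    spec = [
        ("A1", 1, "RES", "A", 1.0),
        ("A2", 1, "RES", "A", 1.0),
        ("B1", 2, "RES", "A", 1.0),
        ("B2", 2, "RES", "A", 1.0),
    ]
    coords = [[0, 0, 0], [0, 0, 0], [0.3, 0.4, 0], [0.3, 0.4, 0]]
    return make_structure(spec, coords)
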