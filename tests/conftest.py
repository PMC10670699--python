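import numpy as np
import pytest

from gelion.model import SystemState


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_state(positions, charges=None, bonds=None, box_length=10.0,
               species=None, velocities=None):
    """Convenience constructor for ad-hoc test systems."""
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    return SystemState(
        positions=pos,
        velocities=(np.zeros_like(pos) if velocities is None
                    else np.asarray(velocities, dtype=float)),
        charge=(np.zeros(n, dtype=np.int64) if charges is None
                else np.asarray(charges, dtype=np.int64)),
        species=(np.full(n, 3, dtype=np.int64) if species is None
                 else np.asarray(species, dtype=np.int64)),
        bonds=(np.empty((0, 2), dtype=np.int64) if bonds is None
               else np.asarray(bonds, dtype=np.int64).reshape(-1, 2)),
        box_length=float(box_length),
    )


@pytest.fixture
def wca_fluid():
    """100-particle WCA fluid on a jittered lattice (no overlaps)."""
    rng = np.random.default_rng(7)
    L = 6.0
    grid = (np.arange(5) + 0.5) * L / 5
    pts = np.array(np.meshgrid(grid, grid, grid)).reshape(3, -1).T[:100]
    pts = pts + rng.normal(0, 0.03, pts.shape)
    return make_state(pts, box_length=L)
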