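import numpy as np
import pytest

from conformerkit.structure import CoarseStructure


@pytest.fixture(scope="session")
def free_site_structure():
    """A single far-away bead: effectively free space around the origin anchor."""
    return CoarseStructure(
        coords=[[500.0, 0.0, 0.0], [0.0, 0.0, 0.0]],
        radii=1.0,
        weights=1.0,
        residue_ids=[1, 2],
    )


@pytest.fixture(scope="session")
def toy_system():
    from conformerkit.synthetic import make_toy_system

    return make_toy_system(seed=3)


@pytest.fixture(scope="session")
def bead_sphere():
    """Filled-sphere bead model, radius 20 A, ~8000 beads."""
    R = 20.0
    g = np.arange(-R + 0.8, R, 1.6)
    pts = np.array(
        [(x, y, z) for x in g for y in g for z in g if x * x + y * y + z * z <= R * R]
    )
    return CoarseStructure(coords=pts, radii=1.0, weights=1.0), R
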