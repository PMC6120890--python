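import numpy as np
import pytest

import retgeom as rg


@pytest.fixture
def rng():
    return np.random.default_rng(20180903)


@pytest.fixture
def polyene_model():
    """All-trans 14-atom chromophore-like chain."""
    return rg.generate_polyene()


@pytest.fixture
def twisted_polyene_spec():
    return rg.PolyeneSpec(torsions=(165.0, -170.0, 179.0, 150.0, 180.0, 170.0,
                                    -160.0, 175.0, 180.0, 160.0, 155.0))


def random_rigid_motion(rng):
    """A uniform random proper rotation plus translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    trans = rng.normal(scale=10.0, size=3)
    return rot, trans


@pytest.fixture
def water_box_model(rng):
    """500 randomly placed waters in a 25 A box — a polar-atom soup for
    neighbor-search cross-checks."""
    atoms = []
    coords = rng.uniform(0.0, 25.0, size=(500, 3))
    for i, pos in enumerate(coords):
        atoms.append(rg.AtomRecord(serial=i + 1, name="O", altloc="", res_name="HOH",
                                   chain_id="W", res_seq=i + 1, icode="", pos=pos,
                                   occupancy=1.0, b_iso=20.0, element="O"))
    return rg.StructureModel(atoms=atoms, label="water-box")
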