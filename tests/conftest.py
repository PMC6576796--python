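import numpy as np
import pytest

from fragnet import (ConformerEnsemble, ideal_helix, load_alphabet)
from fragnet.ensemble import Atom


@pytest.fixture(scope="session")
def alphabet():
    return load_alphabet("SA25")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_ca_ensemble(coords, chain_ids=None, first_resid=1):
    """CA-only ensemble from (F, A, 3) coordinates."""
    coords = np.asarray(coords, float)
    A = coords.shape[1]
    chain_ids = chain_ids or ["A"] * A
    atoms = []
    resid = first_resid
    prev_chain = chain_ids[0]
    for i in range(A):
        if chain_ids[i] != prev_chain:
            resid = first_resid
            prev_chain = chain_ids[i]
        atoms.append(Atom(atom_index=i, atom_name="CA", element="C",
                          residue_index=resid, residue_name="ALA",
                          chain_id=chain_ids[i]))
        resid += 1
    return ConformerEnsemble(atoms=atoms, coords=coords)


@pytest.fixture
def helix_ensemble():
    """10-frame copy of a 12-residue ideal helix (identical frames)."""
    single = ideal_helix(12)
    coords = np.repeat(single.coords, 10, axis=0)
    return single.with_coords(coords)


def random_rotation(rng):
    """Uniform random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
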