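import numpy as np
import pandas as pd
import pytest

from screenmd import curate, load_reference_actives
from screenmd.trajectory import Trajectory


@pytest.fixture(scope="session")
def reference_actives():
    """The packaged 25-compound active table, curated."""
    return curate(load_reference_actives())


def make_atoms(n, segment="protein", name="CA", element="C", mass=12.011):
    return pd.DataFrame(
        {
            "name": [name] * n,
            "element": [element] * n,
            "mass": [mass] * n,
            "resid": np.arange(1, n + 1),
            "resname": ["ALA"] * n,
            "chain": ["A"] * n,
            "segment": [segment] * n,
        }
    )


def make_trajectory(coords, atoms=None, **kwargs):
    coords = np.asarray(coords, dtype=float)
    if atoms is None:
        atoms = make_atoms(coords.shape[1])
    return Trajectory(coords=coords, atoms=atoms, **kwargs)


@pytest.fixture
def five_atom_frame():
    """Small non-degenerate point set used as a superposition reference."""
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [1.5, 0.0, 0.0],
            [0.0, 2.0, 0.0],
            [0.0, 0.0, 2.5],
            [1.0, 1.0, 1.0],
        ]
    )


def random_rotation(rng):
    """A proper random rotation matrix via QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
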