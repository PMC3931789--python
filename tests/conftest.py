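"""Shared fixtures: one session-scoped toy complex, contact potentials, and
small hand-built structures used across modules."""

import numpy as np
import pytest

from pairdock.fixtures import (
    FixtureSpec,
    fixture_atom_types,
    make_redock_potentials,
    make_toy_complex,
)
from pairdock.structure import TypedStructure


@pytest.fixture(scope="session")
def toy_spec():
    return FixtureSpec(seed=1)


@pytest.fixture(scope="session")
def toy_complex(toy_spec):
    return make_toy_complex(toy_spec)


@pytest.fixture(scope="session")
def contact_potentials(toy_complex):
    """Repulsion-augmented potentials over the toy complex's type alphabet."""
    types = fixture_atom_types(*toy_complex)
    return make_redock_potentials(types, seed=99, n_per_pair=2000)


def simple_structure(coords, names=None, resnames=None, elements=None,
                     chain="A", atom_types=None, resnums=None):
    """Quickly assemble a TypedStructure from coordinates."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    names = names or ["CA"] * n
    resnames = resnames or ["GLY"] * n
    elements = elements or ["C"] * n
    resnums = resnums if resnums is not None else list(range(1, n + 1))
    return TypedStructure(
        serial=list(range(1, n + 1)), name=names, residue_name=resnames,
        chain=[chain] * n, residue_number=resnums,
        insertion_code=[""] * n, element=elements, coords=coords,
        atom_type=atom_types,
    )
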