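"""Shared fixtures: RDKit molecules, random tree molecules, toy regression
instances.  All randomness is seeded; no fixture touches the network or
disk-resident data."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

SMILES = {
    "ethane": "CC",
    "propane": "CCC",
    "benzene": "c1ccccc1",
    "toluene": "Cc1ccccc1",
    "thiophene": "c1ccsc1",
    "chlorobenzene": "Clc1ccccc1",
    "tetrachloromethane": "ClC(Cl)(Cl)Cl",
    "chlorothiophene": "Clc1cccs1",
    "anisole": "COc1ccccc1",
}


@pytest.fixture(scope="session")
def mols():
    return {name: Chem.MolFromSmiles(smi) for name, smi in SMILES.items()}


def random_tree_molecule(rng: np.random.Generator, n_min: int = 4, n_max: int = 12):
    """A random chemically valid tree-shaped molecule (C/N/O/S skeleton,
    single/double bonds), built by attaching atoms to a random parent and
    retrying until sanitization passes."""
    elements = ["C", "C", "C", "N", "O", "S"]
    for _ in range(50):
        n = int(rng.integers(n_min, n_max + 1))
        rw = Chem.RWMol()
        rw.AddAtom(Chem.Atom("C"))
        for i in range(1, n):
            rw.AddAtom(Chem.Atom(elements[rng.integers(len(elements))]))
            parent = int(rng.integers(0, i))
            order = Chem.BondType.DOUBLE if rng.random() < 0.15 else Chem.BondType.SINGLE
            rw.AddBond(i, parent, order)
        mol = rw.GetMol()
        try:
            Chem.SanitizeMol(mol)
            return mol
        except Exception:
            continue
    raise RuntimeError("could not build a valid random molecule")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_regression(rng):
    """(X, y, coefficients): a well-conditioned linear instance with noise."""
    X = rng.normal(size=(20, 3))
    beta = np.array([1.5, -0.7, 0.3])
    y = 2.0 + X @ beta + rng.normal(0, 0.1, 20)
    return X, y, beta
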