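"""2D descriptor families: electrotopological state (E-state), alignment-
independent atom-pair counts, element counts, and matrix assembly.

The E-state follows the Kier–Hall definitions.  For heavy atom i with
heavy-atom degree δ, valence-electron count Zv, attached hydrogens H and
principal quantum number N:

    intrinsic state   I_i = ((2/N)^2 · δv + 1) / δ,   δv = Zv − H
    perturbation      ΔI_i = Σ_j (I_i − I_j) / (d_ij + 1)^2
    E-state value     S_i = I_i + ΔI_i

with d_ij the topological (bond-count) distance between heavy atoms.  The
perturbation is antisymmetric, so Σ_i ΔI_i = 0 for every molecule — a useful
conservation check.  Type sums over these values (e.g. over aliphatic CH3
carbons, or aromatic-disubstituted sulfur) are the descriptors the selected
models use.

Alignment-independent (AI) descriptors count atom pairs carrying attribute
pairs at a fixed topological distance; the attribute registry is
{2 (double-bonded atom), 3 (triple-bonded atom), C, N, O, S, H, F, Cl, Br, I}
over distances 0–7, named ``T_<a>_<b>_<d>`` (e.g. T_C_Cl_1 = carbon–chlorine
pairs one bond apart).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Lipinski

from .compound_data import Compound

logger = logging.getLogger(__name__)

__all__ = [
    "EStateResult",
    "DescriptorMatrix",
    "estate_values",
    "estate_sum_by_type",
    "count_atoms_of_type",
    "ai_pair_count",
    "assemble_matrix",
    "remove_invariant_columns",
    "expected_column_count",
    "AI_ATTRIBUTES",
    "ATOM_TYPE_REGISTRY",
]

# principal quantum number by period
_PERIOD_BOUNDS = (2, 10, 18, 36, 54, 86)


def _principal_quantum_number(z: int) -> int:
    for n, bound in enumerate(_PERIOD_BOUNDS, start=1):
        if z <= bound:
            return n
    return 7


def _as_mol(mol):
    if isinstance(mol, Compound):
        mol = mol.mol
    if mol is None:
        raise ValueError("no molecular graph available")
    return mol


# ---------------------------------------------------------------------------
# E-state
# ---------------------------------------------------------------------------

@dataclass
class EStateResult:
    intrinsic: np.ndarray     # I per heavy atom
    perturbation: np.ndarray  # ΔI per heavy atom
    values: np.ndarray        # S = I + ΔI

    def __post_init__(self):
        resid = abs(float(self.perturbation.sum()))
        if resid > 1e-9:
            raise AssertionError(f"E-state perturbation sum {resid:g} != 0")


def estate_values(mol) -> EStateResult:
    """Per-atom intrinsic state, perturbation and E-state value.

    Operates on the heavy-atom graph with implicit or explicit hydrogens
    counted via the atom's total H count.  Raises for an isolated heavy atom
    (degree 0), where the intrinsic state is undefined.
    """
    mol = _as_mol(mol)
    heavy = Chem.RemoveHs(mol)
    n = heavy.GetNumAtoms()
    if n == 0:
        raise ValueError("molecule has no heavy atoms")
    pt = Chem.GetPeriodicTable()
    intrinsic = np.empty(n)
    for atom in heavy.GetAtoms():
        delta = atom.GetDegree()
        if delta == 0:
            if n == 1:  # single-heavy-atom molecule: convention I = δv + 1
                zv = pt.GetNOuterElecs(atom.GetAtomicNum())
                intrinsic[0] = (zv - atom.GetTotalNumHs()) + 1.0
                continue
            raise ValueError(
                f"isolated heavy atom idx {atom.GetIdx()} "
                f"({atom.GetSymbol()}): intrinsic state undefined"
            )
        zv = pt.GetNOuterElecs(atom.GetAtomicNum())
        dv = zv - atom.GetTotalNumHs()
        nq = _principal_quantum_number(atom.GetAtomicNum())
        intrinsic[atom.GetIdx()] = ((2.0 / nq) ** 2 * dv + 1.0) / delta
    dmat = Chem.GetDistanceMatrix(heavy)
    # RDKit marks unreachable pairs with a 1e8 sentinel
    if np.any(~np.isfinite(dmat)) or dmat.max() > 1e6:
        raise ValueError("heavy-atom graph is disconnected")
    attn = 1.0 / (dmat + 1.0) ** 2
    np.fill_diagonal(attn, 0.0)
    # ΔI_i = Σ_j (I_i − I_j) · attn_ij
    perturbation = intrinsic * attn.sum(axis=1) - attn @ intrinsic
    return EStateResult(
        intrinsic=intrinsic,
        perturbation=perturbation,
        values=intrinsic + perturbation,
    )


def _is_sch3(atom) -> bool:
    """Aliphatic CH3 carbon: exactly 3 hydrogens, one single bond to a heavy atom."""
    if atom.GetSymbol() != "C" or atom.GetTotalNumHs() != 3:
        return False
    bonds = atom.GetBonds()
    return len(bonds) == 1 and bonds[0].GetBondType() == Chem.BondType.SINGLE


def _is_aas(atom) -> bool:
    """Sulfur with exactly two aromatic bonds (thiophene-like)."""
    if atom.GetSymbol() != "S":
        return False
    arom = [b for b in atom.GetBonds() if b.GetIsAromatic()]
    return len(arom) == 2


ATOM_TYPE_REGISTRY: dict[str, Callable] = {
    "sCH3": _is_sch3,
    "aaS": _is_aas,
}


def _matching_atoms(mol, atom_type: str):
    if atom_type not in ATOM_TYPE_REGISTRY:
        raise KeyError(
            f"unknown atom type {atom_type!r}; registry: "
            f"{sorted(ATOM_TYPE_REGISTRY)}"
        )
    heavy = Chem.RemoveHs(_as_mol(mol))
    pred = ATOM_TYPE_REGISTRY[atom_type]
    return heavy, [a.GetIdx() for a in heavy.GetAtoms() if pred(a)]


def estate_sum_by_type(mol, atom_type: str) -> float:
    """Sum of E-state values over atoms matching a registered type.

    Returns 0.0 when no atom matches (e.g. the sCH3 sum of benzene).
    """
    heavy, idx = _matching_atoms(mol, atom_type)
    if not idx:
        return 0.0
    res = estate_values(heavy)
    return float(res.values[idx].sum())


def count_atoms_of_type(mol, atom_type: str) -> int:
    """Literal number of atoms matching a registered type (integer count,
    distinct from the E-state sum exposed under ``S<type>_sum``)."""
    _, idx = _matching_atoms(mol, atom_type)
    return len(idx)


# ---------------------------------------------------------------------------
# alignment-independent pair counts
# ---------------------------------------------------------------------------

AI_ATTRIBUTES = ("2", "3", "C", "N", "O", "S", "H", "F", "Cl", "Br", "I")
AI_MAX_DIST = 7


def _atom_attributes(mol_h) -> list[set]:
    """Per-atom attribute sets on the explicit-hydrogen graph."""
    attrs = []
    for atom in mol_h.GetAtoms():
        s = set()
        sym = atom.GetSymbol()
        if sym in AI_ATTRIBUTES:
            s.add(sym)
        for bond in atom.GetBonds():
            if bond.GetBondType() == Chem.BondType.DOUBLE:
                s.add("2")
            elif bond.GetBondType() == Chem.BondType.TRIPLE:
                s.add("3")
        attrs.append(s)
    return attrs


def _ai_counts(mol) -> dict[tuple[str, str, int], int]:
    """All AI pair counts for one molecule in a single pass over atom pairs.

    An unordered atom pair {i, j} at distance d contributes once to
    ``(a, b, d)`` when one end matches a and the other matches b; at d = 0
    single atoms matching both attributes are counted.
    """
    mol_h = Chem.AddHs(_as_mol(mol))
    attrs = _atom_attributes(mol_h)
    dmat = Chem.GetDistanceMatrix(mol_h)
    order = {a: k for k, a in enumerate(AI_ATTRIBUTES)}
    counts: dict[tuple[str, str, int], int] = {}
    n = mol_h.GetNumAtoms()
    for i in range(n):
        for a in attrs[i]:
            for b in attrs[i]:
                if order[a] <= order[b]:
                    key = (a, b, 0)
                    counts[key] = counts.get(key, 0) + 1
        for j in range(i + 1, n):
            d = int(dmat[i, j])
            if d > AI_MAX_DIST:
                continue
            seen = set()
            for a in attrs[i]:
                for b in attrs[j]:
                    key = (a, b) if order[a] <= order[b] else (b, a)
                    seen.add(key)
            for a, b in seen:
                key = (a, b, d)
                counts[key] = counts.get(key, 0) + 1
    return counts


def ai_pair_count(mol, attr_a: str, attr_b: str, dist: int) -> int:
    """Count of unordered atom pairs matching (attr_a, attr_b) at topological
    distance ``dist`` (0–7); symmetric in the attributes."""
    for a in (attr_a, attr_b):
        if a not in AI_ATTRIBUTES:
            raise KeyError(f"unknown AI attribute {a!r}; registry: {AI_ATTRIBUTES}")
    if not 0 <= dist <= AI_MAX_DIST:
        raise ValueError(f"distance {dist} outside 0..{AI_MAX_DIST}")
    order = {a: k for k, a in enumerate(AI_ATTRIBUTES)}
    key = (attr_a, attr_b) if order[attr_a] <= order[attr_b] else (attr_b, attr_a)
    return _ai_counts(mol).get((*key, dist), 0)


def _ai_column_names() -> list[str]:
    names = []
    for i, a in enumerate(AI_ATTRIBUTES):
        for b in AI_ATTRIBUTES[i:]:
            for d in range(AI_MAX_DIST + 1):
                names.append(f"T_{a}_{b}_{d}")
    return names


_ELEMENTS = ("C", "N", "O", "S", "H", "F", "Cl", "Br", "I")
_ESTATE_COLUMNS = ("SsCH3_sum", "SaaS_sum", "SsCH3_count")


def expected_column_count(n_external: int = 0) -> int:
    """Deterministic column count of an assembled matrix before pruning:
    element counts + H-donor/acceptor + the full AI block (unordered attribute
    pairs × 8 distances) + E-state type columns + externals."""
    n_attr_pairs = len(AI_ATTRIBUTES) * (len(AI_ATTRIBUTES) + 1) // 2
    return (
        len(_ELEMENTS)
        + 2
        + n_attr_pairs * (AI_MAX_DIST + 1)
        + len(_ESTATE_COLUMNS)
        + n_external
    )


# ---------------------------------------------------------------------------
# matrix assembly
# ---------------------------------------------------------------------------

@dataclass
class DescriptorMatrix:
    """Compounds × named descriptors with per-column provenance
    (``computed`` or ``external``)."""

    df: pd.DataFrame
    provenance: dict[str, str]

    def __post_init__(self):
        if self.df.columns.duplicated().any():
            dupes = self.df.columns[self.df.columns.duplicated()].tolist()
            raise ValueError(f"duplicate descriptor names: {dupes}")
        if self.df.isna().any().any():
            bad = self.df.columns[self.df.isna().any()].tolist()
            raise ValueError(f"missing values in columns: {bad}")
        missing = set(self.df.columns) - set(self.provenance)
        if missing:
            raise ValueError(f"columns without provenance: {sorted(missing)}")

    @property
    def compound_ids(self) -> list:
        return list(self.df.index)

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        """CSV with a second header row carrying provenance."""
        prov = pd.DataFrame(
            [[self.provenance[c] for c in self.df.columns]],
            index=["#provenance"],
            columns=self.df.columns,
        )
        pd.concat([prov, self.df]).to_csv(path, index_label="id")

    @classmethod
    def from_csv(cls, path) -> "DescriptorMatrix":
        raw = pd.read_csv(path, index_col=0)
        prov_row = raw.loc["#provenance"]
        df = raw.drop(index="#provenance").astype(float)
        return cls(df=df, provenance=dict(prov_row))


def assemble_matrix(
    mols: Sequence[Compound],
    external: pd.DataFrame | dict | None = None,
) -> DescriptorMatrix:
    """Build the full 2D descriptor matrix for a compound series.

    Columns: element counts, H-donor/acceptor counts, the complete AI pair
    block, E-state type sums (plus the literal sCH3 count), and any external
    columns (e.g. a LUMO energy column from quantum chemistry outside this
    package), flagged ``external``.  External columns must cover every
    compound.
    """
    ids = [c.id for c in mols]
    ai_names = _ai_column_names()
    rows = []
    for comp in mols:
        mol = _as_mol(comp)
        mol_h = Chem.AddHs(mol)
        row: dict[str, float] = {}
        symbols = [a.GetSymbol() for a in mol_h.GetAtoms()]
        for el in _ELEMENTS:
            row[f"{el}_count"] = float(symbols.count(el))
        row["HDonor_count"] = float(Lipinski.NumHDonors(mol))
        row["HAcceptor_count"] = float(Lipinski.NumHAcceptors(mol))
        counts = _ai_counts(comp)
        for name in ai_names:
            _, a, b, d = name.split("_")
            row[name] = float(counts.get((a, b, int(d)), 0))
        row["SsCH3_sum"] = estate_sum_by_type(comp, "sCH3")
        row["SaaS_sum"] = estate_sum_by_type(comp, "aaS")
        row["SsCH3_count"] = float(count_atoms_of_type(comp, "sCH3"))
        rows.append(row)
    df = pd.DataFrame(rows, index=ids)
    provenance = {c: "computed" for c in df.columns}

    if external is not None:
        ext = pd.DataFrame(external)
        if not ext.index.equals(df.index):
            try:
                ext = ext.loc[df.index]
            except KeyError:
                missing = sorted(set(df.index) - set(ext.index))
                raise ValueError(
                    f"external columns missing compounds: {missing}"
                ) from None
        if ext.isna().any().any():
            bad = ext.columns[ext.isna().any()].tolist()
            raise ValueError(f"external columns with missing values: {bad}")
        for c in ext.columns:
            df[c] = ext[c].astype(float)
            provenance[c] = "external"
    return DescriptorMatrix(df=df, provenance=provenance)


def remove_invariant_columns(
    X: DescriptorMatrix, tol: float = 1e-12
) -> DescriptorMatrix:
    """Drop constant columns (sample variance below ``tol``); idempotent."""
    if len(X.df) < 2:
        raise ValueError("need at least 2 rows to assess column variance")
    variances = X.df.var(axis=0, ddof=1)
    keep = variances[variances >= tol].index.tolist()
    dropped = [c for c in X.df.columns if c not in keep]
    if not keep:
        raise ValueError("all descriptor columns are constant")
    if dropped:
        logger.info("dropping %d invariant columns: %s", len(dropped), dropped[:10])
    return DescriptorMatrix(
        df=X.df[keep].copy(),
        provenance={c: X.provenance[c] for c in keep},
    )
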