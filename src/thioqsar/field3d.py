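"""Template alignment, lattice fields, and kNN molecular field analysis.

Compounds sharing a rigid substructure are superposed onto a reference
(least-squares rigid-body fit on the mapped template atoms), a regular
lattice (default spacing 2.0 Å, margin 4.0 Å around the aligned set) is laid
over them, and three interaction fields are evaluated at every lattice point
with a united-atom methyl probe of charge +1:

  * electrostatic — Coulomb, 332.0·q_i·q_probe/(ε(r)·r) kcal/mol with a
    distance-dependent dielectric ε(r) = r by default, truncated to ±10;
  * steric — Lennard-Jones 6-12 against the probe with Lorentz–Berthelot
    combination, truncated to ±30;
  * hydrophobic — atomic increments attenuated as h_i/(1 + r), truncated
    to ±30.

Field columns are labeled ``S_<i>``, ``E_<i>``, ``H_<i>`` with lattice
points numbered 1-based in x-fastest raster order from the grid origin.
The kNN-MFA model predicts activity as the inverse-distance-weighted mean of
the k nearest training compounds in the subspace of selected field columns;
columns are selected by the same stepwise/GA/SA engines as the 2D models
with the kNN leave-one-out q² as fitness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import validation
from .compound_data import Compound
from .selection import SelectionConfig, SearchResult, run_search

logger = logging.getLogger(__name__)

__all__ = [
    "Grid",
    "FieldTable",
    "KNNFieldModel",
    "ProbeParameters",
    "align_to_template",
    "kabsch",
    "build_grid",
    "electrostatic_field",
    "steric_field",
    "hydrophobic_field",
    "compute_field_table",
    "knn_loo_q2",
    "knn_mfa_fit",
    "knn_predict",
    "LJ_TABLE",
    "HYDROPHOBIC_INCREMENTS",
]

COULOMB_CONSTANT = 332.0       # kcal·Å/(mol·e²)
MIN_DISTANCE = 0.1             # Å clamp against on-atom singularities
ELECTROSTATIC_CUTOFF = 10.0    # kcal/mol
STERIC_CUTOFF = 30.0           # kcal/mol

# united-atom Lennard-Jones parameters, sigma in Å and epsilon in kcal/mol
LJ_TABLE: dict[str, tuple[float, float]] = {
    "H": (2.47, 0.030),
    "C": (3.40, 0.086),
    "N": (3.25, 0.170),
    "O": (2.96, 0.210),
    "S": (3.56, 0.250),
    "F": (3.12, 0.061),
    "Cl": (3.47, 0.265),
    "Br": (3.60, 0.320),
    "I": (3.80, 0.400),
}

# crude atomic logP-style hydrophobicity increments
HYDROPHOBIC_INCREMENTS: dict[str, float] = {
    "H": 0.12, "C": 0.14, "N": -0.60, "O": -0.25, "S": 0.40,
    "F": 0.20, "Cl": 0.60, "Br": 0.85, "I": 1.00,
}


@dataclass(frozen=True)
class ProbeParameters:
    """United-atom CH3 probe: one interaction site, charge +1."""

    charge: float = 1.0
    sigma: float = 3.775        # Å, united-atom methyl
    epsilon: float = 0.207      # kcal/mol


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t minimizing ||R·P + t − Q||
    (proper rotation; reflections excluded via the determinant correction)."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def align_to_template(
    mol, template_mapping, reference
) -> tuple[np.ndarray, float]:
    """Rigidly superpose a molecule onto a reference via mapped template atoms.

    ``template_mapping`` is a sequence of (mol_atom_index, ref_atom_index)
    pairs (or a single index sequence applying to both).  Returns the
    transformed full-molecule coordinates and the RMSD over mapped atoms.
    Requires at least 3 non-collinear mapped atoms.
    """
    coords = mol.coordinates() if isinstance(mol, Compound) else np.asarray(mol, float)
    ref = (
        reference.coordinates()
        if isinstance(reference, Compound)
        else np.asarray(reference, float)
    )
    pairs = [(int(p), int(p)) if np.isscalar(p) else (int(p[0]), int(p[1]))
             for p in template_mapping]
    if len(pairs) < 3:
        raise ValueError("template mapping must cover at least 3 atoms")
    P = coords[[i for i, _ in pairs]]
    Q = ref[[j for _, j in pairs]]
    if np.linalg.matrix_rank(Q - Q.mean(axis=0), tol=1e-8) < 2:
        raise ValueError("mapped template atoms are collinear")
    R, t = kabsch(P, Q)
    aligned = coords @ R.T + t
    mapped = P @ R.T + t
    rmsd = float(np.sqrt(((mapped - Q) ** 2).sum() / len(pairs)))
    return aligned, rmsd


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Grid:
    """Regular axis-aligned lattice: point i·spacing from the origin along
    each axis, numbered in x-fastest raster order."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(d < 2 for d in self.dims):
            raise ValueError("each grid dimension must be >= 2")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """(n_points, 3) lattice coordinates, x varying fastest."""
        nx, ny, nz = self.dims
        ix = np.arange(nx)
        iy = np.arange(ny)
        iz = np.arange(nz)
        gz, gy, gx = np.meshgrid(iz, iy, ix, indexing="ij")
        idx = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        return np.asarray(self.origin) + idx * self.spacing

    def to_dict(self) -> dict:
        return {
            "origin": list(self.origin),
            "spacing": self.spacing,
            "dims": list(self.dims),
            "n_points": self.n_points,
        }


def build_grid(aligned_coords, spacing: float = 2.0, margin: float = 4.0) -> Grid:
    """Lattice over the bounding box of the aligned set, expanded by
    ``margin`` Å on every side; deterministic."""
    stacks = [np.asarray(c, float).reshape(-1, 3) for c in aligned_coords]
    if not stacks:
        raise ValueError("no coordinates supplied")
    allc = np.vstack(stacks)
    lo = allc.min(axis=0) - margin
    hi = allc.max(axis=0) + margin
    dims = tuple(int(np.floor((h - l) / spacing)) + 1 for l, h in zip(lo, hi))
    dims = tuple(max(d, 2) for d in dims)
    return Grid(origin=tuple(float(v) for v in lo), spacing=float(spacing), dims=dims)


# ---------------------------------------------------------------------------
# fields
# ---------------------------------------------------------------------------

def _distances(coords: np.ndarray, points: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, float).reshape(-1, 3)
    points = np.asarray(points, float).reshape(-1, 3)
    d = np.linalg.norm(points[:, None, :] - coords[None, :, :], axis=-1)
    return np.maximum(d, MIN_DISTANCE)


def _points_of(grid) -> np.ndarray:
    return grid.points() if isinstance(grid, Grid) else np.asarray(grid, float)


def electrostatic_field(
    charges,
    coords,
    grid,
    probe_charge: float = 1.0,
    cutoff: float = ELECTROSTATIC_CUTOFF,
    dielectric: str = "distance",
    epsilon: float = 1.0,
) -> np.ndarray:
    """Coulomb field of the partial charges at each lattice point, truncated
    to ±cutoff.  ``dielectric='distance'`` uses ε(r) = r (so E ~ q/r²);
    ``'constant'`` uses the fixed ``epsilon``."""
    charges = np.asarray(charges, float)
    if charges.size == 0 or not np.all(np.isfinite(charges)):
        raise ValueError("partial charges missing or non-finite")
    r = _distances(coords, _points_of(grid))
    if dielectric == "distance":
        eps_r = r
    elif dielectric == "constant":
        eps_r = np.full_like(r, float(epsilon))
    else:
        raise ValueError(f"unknown dielectric model {dielectric!r}")
    raw = (COULOMB_CONSTANT * probe_charge * charges[None, :] / (eps_r * r)).sum(axis=1)
    return np.clip(raw, -cutoff, cutoff)


def _lj_params(elements, probe: ProbeParameters):
    A = np.empty(len(elements))
    B = np.empty(len(elements))
    for i, el in enumerate(elements):
        if el not in LJ_TABLE:
            raise KeyError(f"no Lennard-Jones parameters for element {el!r}")
        sig_i, eps_i = LJ_TABLE[el]
        sig = 0.5 * (sig_i + probe.sigma)           # Lorentz
        eps = np.sqrt(eps_i * probe.epsilon)        # Berthelot
        A[i] = 4.0 * eps * sig ** 12
        B[i] = 4.0 * eps * sig ** 6
    return A, B


def steric_field(
    elements,
    coords,
    grid,
    probe: ProbeParameters = ProbeParameters(),
    cutoff: float = STERIC_CUTOFF,
) -> np.ndarray:
    """6-12 Lennard-Jones field of the molecule against the methyl probe,
    truncated to ±cutoff."""
    A, B = _lj_params(list(elements), probe)
    r = _distances(coords, _points_of(grid))
    raw = (A[None, :] / r ** 12 - B[None, :] / r ** 6).sum(axis=1)
    return np.clip(raw, -cutoff, cutoff)


def hydrophobic_field(
    increments_or_elements,
    coords,
    grid,
    cutoff: float = STERIC_CUTOFF,
) -> np.ndarray:
    """Hydrophobicity field: Σ h_i/(1 + r_i), truncated to ±cutoff.  Accepts
    per-atom increments or element symbols (looked up in the built-in table)."""
    items = list(increments_or_elements)
    if items and isinstance(items[0], str):
        missing = [el for el in items if el not in HYDROPHOBIC_INCREMENTS]
        if missing:
            raise KeyError(f"no hydrophobicity increment for {sorted(set(missing))}")
        h = np.array([HYDROPHOBIC_INCREMENTS[el] for el in items])
    else:
        h = np.asarray(items, float)
    r = _distances(coords, _points_of(grid))
    raw = (h[None, :] / (1.0 + r)).sum(axis=1)
    return np.clip(raw, -cutoff, cutoff)


@dataclass
class FieldTable:
    """Grid geometry plus the compounds × field-columns matrix
    (columns S_1..S_N, E_1..E_N, H_1..H_N)."""

    grid: Grid
    df: pd.DataFrame
    electrostatic_cutoff: float = ELECTROSTATIC_CUTOFF
    steric_cutoff: float = STERIC_CUTOFF

    def __post_init__(self):
        for prefix, cut in (("E_", self.electrostatic_cutoff),
                            ("S_", self.steric_cutoff),
                            ("H_", self.steric_cutoff)):
            cols = [c for c in self.df.columns if c.startswith(prefix)]
            if cols and np.abs(self.df[cols].to_numpy()).max() > cut + 1e-9:
                raise ValueError(f"{prefix} values exceed cutoff {cut}")

    @property
    def n_columns(self) -> int:
        return self.df.shape[1]

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index_label="id")


def compute_field_table(
    compounds,
    grid: Grid,
    probe: ProbeParameters = ProbeParameters(),
    electrostatic_cutoff: float = ELECTROSTATIC_CUTOFF,
    steric_cutoff: float = STERIC_CUTOFF,
    dielectric: str = "distance",
    aligned_coords=None,
) -> FieldTable:
    """Evaluate all three fields for every compound on one shared grid.

    ``compounds`` supply elements and partial charges; ``aligned_coords``
    (if given) override each compound's own coordinates with its aligned
    pose.  Charges for RDKit molecules without explicit charges are computed
    Gasteiger-style.
    """
    points = grid.points()
    n = grid.n_points
    names = (
        [f"S_{i}" for i in range(1, n + 1)]
        + [f"E_{i}" for i in range(1, n + 1)]
        + [f"H_{i}" for i in range(1, n + 1)]
    )
    rows, ids = [], []
    for idx, comp in enumerate(compounds):
        coords = (
            np.asarray(aligned_coords[idx], float)
            if aligned_coords is not None
            else comp.coordinates()
        )
        elements, charges = _atoms_of(comp)
        s = steric_field(elements, coords, points, probe, steric_cutoff)
        e = electrostatic_field(
            charges, coords, points, probe.charge, electrostatic_cutoff, dielectric
        )
        h = hydrophobic_field(elements, coords, points, steric_cutoff)
        rows.append(np.concatenate([s, e, h]))
        ids.append(comp.id if isinstance(comp, Compound) else f"mol{idx+1}")
    df = pd.DataFrame(rows, index=ids, columns=names)
    return FieldTable(
        grid=grid,
        df=df,
        electrostatic_cutoff=electrostatic_cutoff,
        steric_cutoff=steric_cutoff,
    )


def _atoms_of(comp):
    if isinstance(comp, Compound) and comp.elements is not None:
        if comp.charges is None:
            raise ValueError(f"compound {comp.id} lacks partial charges")
        return list(comp.elements), np.asarray(comp.charges, float)
    mol = comp.mol if isinstance(comp, Compound) else comp
    from rdkit.Chem import AllChem

    if not mol.GetNumAtoms():
        raise ValueError("empty molecule")
    if not all(a.HasProp("_GasteigerCharge") for a in mol.GetAtoms()):
        AllChem.ComputeGasteigerCharges(mol)
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    charges = np.array([float(a.GetProp("_GasteigerCharge")) for a in mol.GetAtoms()])
    if not np.all(np.isfinite(charges)):
        raise ValueError("non-finite Gasteiger charges")
    return elements, charges


# ---------------------------------------------------------------------------
# kNN-MFA
# ---------------------------------------------------------------------------

@dataclass
class KNNFieldModel:
    """kNN molecular-field model over selected lattice-field columns."""

    selected_points: list[str]
    k: int
    train_fields: pd.DataFrame = field(repr=False)
    train_activities: np.ndarray = field(repr=False)
    q2: float = float("nan")
    q2_se: float = float("nan")
    search: SearchResult | None = None

    def __post_init__(self):
        if not self.selected_points:
            raise ValueError("selected_points must be nonempty")
        if not 1 <= self.k <= len(self.train_activities) - 1:
            raise ValueError("k must lie in [1, n_train - 1]")

    def report(self) -> dict:
        return {
            "selected_points": list(self.selected_points),
            "k": self.k,
            "q2": self.q2,
            "q2_se": self.q2_se,
            "n_train": int(len(self.train_activities)),
        }


def _knn_value(dist: np.ndarray, acts: np.ndarray, k: int) -> float:
    """Inverse-distance-weighted mean over the k nearest; an exact match
    (distance 0) returns that activity."""
    order = np.argsort(dist, kind="stable")[:k]
    d = dist[order]
    if d[0] < 1e-12:
        return float(acts[order[0]])
    w = 1.0 / d
    return float((w * acts[order]).sum() / w.sum())


def knn_predict(model: KNNFieldModel, query_fields) -> float | np.ndarray:
    """Predict activity for one query vector or a table of queries."""
    train = model.train_fields[model.selected_points].to_numpy(float)
    acts = model.train_activities
    if isinstance(query_fields, pd.DataFrame):
        Q = query_fields[model.selected_points].to_numpy(float)
    else:
        Q = np.asarray(query_fields, float)
        if Q.ndim == 1:
            d = np.linalg.norm(train - Q, axis=1)
            return _knn_value(d, acts, model.k)
    out = np.array(
        [_knn_value(np.linalg.norm(train - q, axis=1), acts, model.k) for q in Q]
    )
    return out


def knn_loo_predictions(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """LOO predictions of the kNN estimator on the given column subspace."""
    n = len(y)
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
    preds = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        preds[i] = _knn_value(d[i][mask], y[mask], k)
    return preds


def knn_loo_q2(subset_matrix: np.ndarray, y, k: int) -> float:
    y = np.asarray(y, float).ravel()
    preds = knn_loo_predictions(np.asarray(subset_matrix, float), y, k)
    return validation.q2_stat(y, preds, float(y.mean()))


def knn_mfa_fit(
    fields: FieldTable | pd.DataFrame,
    y,
    selector_cfg: SelectionConfig,
    k: int = 2,
    variance_tol: float = 1e-12,
) -> KNNFieldModel:
    """Select field columns with the configured engine (fitness = kNN LOO q²)
    and return the fitted kNN-MFA model."""
    df = fields.df if isinstance(fields, FieldTable) else pd.DataFrame(fields)
    y = np.asarray(y, float).ravel()
    if len(y) < 6:
        raise ValueError("need at least 6 training compounds")
    keep = df.columns[df.var(axis=0, ddof=1) >= variance_tol]
    if len(keep) == 0:
        raise ValueError("all field columns are constant")
    sub = df[keep]
    Xarr = sub.to_numpy(float)

    def fitness(subset):
        return knn_loo_q2(Xarr[:, list(subset)], y, k)

    result = run_search(Xarr.shape[1], fitness, selector_cfg)
    selected = [keep[i] for i in result.subset]
    preds = knn_loo_predictions(Xarr[:, list(result.subset)], y, k)
    model = KNNFieldModel(
        selected_points=selected,
        k=k,
        train_fields=sub,
        train_activities=y,
        q2=validation.q2_stat(y, preds, float(y.mean())),
        q2_se=validation.rmse_se(y, preds, len(y)),
        search=result,
    )
    return model
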