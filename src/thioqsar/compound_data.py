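"""Compound containers, activity scales, and rational train/test splitting.

Activities arrive as IC50 values in nanomolar and are modeled on the pIC50
scale (negative log10 of the *molar* IC50, so pIC50 = 9 - log10(IC50 nM)).
Published unicolumn tables for this series are on the mirror scale
log10(IC50 nM) = 9 - pIC50; both are supported.  Training/test splits are
built with the sphere-exclusion method in standardized descriptor space and
checked against the containment conditions (test max <= train max and test
min >= train min on the activity column).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Compound",
    "UnicolumnStats",
    "SplitResult",
    "ValidityReport",
    "pic50_from_ic50",
    "log_activity",
    "truncate_decimal",
    "unicolumn_stats",
    "check_split_validity",
    "sphere_exclusion_split",
    "load_activity_csv",
    "load_smiles_file",
    "load_sdf_file",
    "write_split_csv",
    "write_unicolumn_csv",
]


# ---------------------------------------------------------------------------
# activity scales
# ---------------------------------------------------------------------------

def pic50_from_ic50(ic50_nM):
    """pIC50 from an IC50 in nanomolar: 9 - log10(IC50 nM).

    Accepts a scalar or array; strictly monotone decreasing in the input.
    Raises ``ValueError`` for non-positive or non-finite input.
    """
    arr = np.asarray(ic50_nM, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("IC50 values must be positive and finite")
    out = 9.0 - np.log10(arr)
    return float(out) if np.isscalar(ic50_nM) or arr.ndim == 0 else out


def log_activity(ic50_nM):
    """log10(IC50 nM) — the scale of the published unicolumn tables.

    Satisfies ``log_activity(x) + pic50_from_ic50(x) == 9`` for any x > 0.
    """
    arr = np.asarray(ic50_nM, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("IC50 values must be positive and finite")
    out = np.log10(arr)
    return float(out) if np.isscalar(ic50_nM) or arr.ndim == 0 else out


def truncate_decimal(x, decimals: int = 4):
    """Truncate toward zero at ``decimals`` places.

    The published activity/unicolumn tables for this series truncate rather
    than round (e.g. 9 - log10(86.5) = 7.06298... is printed as 7.0629), so
    table output uses this instead of half-up rounding.
    """
    f = 10.0 ** decimals
    return np.trunc(np.asarray(x, dtype=float) * f) / f


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Compound:
    """One small molecule with its measured activity.

    ``mol`` is an RDKit molecule (may be ``None`` for toy point-atom
    compounds); ``coords``, ``elements`` and ``charges`` carry an explicit 3D
    representation used by the field module when no RDKit conformer exists.
    """

    id: str
    mol: object | None = None
    ic50_nM: float | None = None
    coords: np.ndarray | None = None
    elements: list[str] | None = None
    charges: np.ndarray | None = None

    def __post_init__(self):
        if self.ic50_nM is not None:
            if not math.isfinite(self.ic50_nM) or self.ic50_nM <= 0:
                raise ValueError(f"compound {self.id}: IC50 must be positive")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=float)

    @property
    def pic50(self) -> float:
        if self.ic50_nM is None:
            raise ValueError(f"compound {self.id} has no activity")
        return pic50_from_ic50(self.ic50_nM)

    def coordinates(self) -> np.ndarray:
        """3D coordinates in Å, from the explicit array or the RDKit conformer."""
        if self.coords is not None:
            return self.coords
        if self.mol is not None and self.mol.GetNumConformers() > 0:
            return np.asarray(self.mol.GetConformer().GetPositions(), dtype=float)
        raise ValueError(f"compound {self.id} has no 3D coordinates")


@dataclass(frozen=True)
class UnicolumnStats:
    """Summary statistics of one activity column (sample std, n-1)."""

    average: float
    max: float
    min: float
    std_dev: float
    sum: float
    n: int

    def as_row(self) -> dict:
        return {
            "Average": self.average,
            "Max": self.max,
            "Min": self.min,
            "Std. dev.": self.std_dev,
            "Sum": self.sum,
        }


def unicolumn_stats(values: Sequence[float]) -> UnicolumnStats:
    """Average / max / min / sample std-dev / sum of an activity column."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("unicolumn statistics require a nonempty list")
    std = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return UnicolumnStats(
        average=float(arr.mean()),
        max=float(arr.max()),
        min=float(arr.min()),
        std_dev=std,
        sum=float(arr.sum()),
        n=int(arr.size),
    )


@dataclass
class SplitResult:
    train_ids: list
    test_ids: list
    stats_train: UnicolumnStats
    stats_test: UnicolumnStats

    def __post_init__(self):
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)}")
        if not self.train_ids or not self.test_ids:
            raise ValueError("both train and test sets must be nonempty")


@dataclass
class ValidityReport:
    ok: bool
    messages: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok


def check_split_validity(split: SplitResult) -> ValidityReport:
    """Containment check: the test set activity range must sit inside the
    training range (test max <= train max AND test min >= train min).

    The conjunction is invariant under the pIC50 <-> log10(nM) mirror, so it
    can be applied on either scale.
    """
    msgs = []
    if split.stats_test.max > split.stats_train.max:
        msgs.append(
            f"test max {split.stats_test.max:.4f} exceeds "
            f"train max {split.stats_train.max:.4f}"
        )
    if split.stats_test.min < split.stats_train.min:
        msgs.append(
            f"test min {split.stats_test.min:.4f} below "
            f"train min {split.stats_train.min:.4f}"
        )
    return ValidityReport(ok=not msgs, messages=msgs)


# ---------------------------------------------------------------------------
# sphere exclusion
# ---------------------------------------------------------------------------

def _sphere_select(order: np.ndarray, dist: np.ndarray, radius: float):
    """One pass of sphere exclusion: walk ``order``; each still-unassigned
    point becomes a training center and every unassigned point within
    ``radius`` of it is excluded into the test pool."""
    n = len(order)
    assigned = np.zeros(n, dtype=bool)
    train, test = [], []
    for i in order:
        if assigned[i]:
            continue
        assigned[i] = True
        train.append(int(i))
        inside = np.nonzero((dist[i] <= radius) & ~assigned)[0]
        for j in inside:
            assigned[j] = True
            test.append(int(j))
    return train, test


def sphere_exclusion_split(
    X,
    y: Sequence[float],
    test_fraction: float,
    radius: float | None = None,
    seed: int = 0,
    ids: Sequence | None = None,
    max_retries: int = 200,
) -> SplitResult:
    """Sphere-exclusion train/test split in standardized descriptor space.

    Descriptors are z-scored and the Euclidean metric used.  Training
    compounds are sphere centers (mutually farther apart than ``radius``);
    excluded compounds form the test pool.  When ``radius`` is None it is
    found by bisection so that the test set has ``round(test_fraction * n)``
    members; a deterministic post-adjustment enforces the exact size.  The
    whole procedure retries with fresh random orderings until the activity
    containment conditions hold, up to ``max_retries``.

    Deterministic (bit-for-bit) for a fixed seed.
    """
    Xarr = np.asarray(X.values if hasattr(X, "values") else X, dtype=float)
    yarr = np.asarray(list(y), dtype=float)
    n = Xarr.shape[0]
    if n < 4:
        raise ValueError("sphere exclusion needs at least 4 compounds")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if radius is not None and radius <= 0:
        raise ValueError("radius must be positive")
    if ids is None:
        ids = list(X.index) if hasattr(X, "index") else list(range(n))
    ids = list(ids)

    mu = Xarr.mean(axis=0)
    sd = Xarr.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (Xarr - mu) / sd
    diff = Z[:, None, :] - Z[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))

    n_test = int(round(test_fraction * n))
    n_test = min(max(n_test, 1), n - 1)
    rng = np.random.default_rng(seed)
    best = None  # (n_violations, train, test)

    for attempt in range(max_retries):
        order = rng.permutation(n)
        if radius is not None:
            train, test = _sphere_select(order, dist, radius)
        else:
            lo, hi = 0.0, float(dist.max()) + 1e-9
            train = test = None
            for _ in range(60):  # bisection on radius for the target size
                mid = 0.5 * (lo + hi)
                tr, te = _sphere_select(order, dist, mid)
                if len(te) >= n_test:
                    hi = mid
                    train, test = tr, te
                else:
                    lo = mid
            if train is None:
                train, test = _sphere_select(order, dist, hi)
        train, test = _adjust_sizes(train, test, dist, n_test)
        st_tr = unicolumn_stats(yarr[train])
        st_te = unicolumn_stats(yarr[test])
        split = SplitResult(
            train_ids=[ids[i] for i in train],
            test_ids=[ids[i] for i in test],
            stats_train=st_tr,
            stats_test=st_te,
        )
        report = check_split_validity(split)
        if report.ok:
            logger.info("sphere exclusion: valid split on attempt %d", attempt + 1)
            return split
        if best is None or len(report.messages) < best[0]:
            best = (len(report.messages), split, report)

    _, split, report = best
    raise RuntimeError(
        "sphere exclusion could not satisfy the containment conditions after "
        f"{max_retries} orderings; best attempt violated: {report.messages}"
    )


def _adjust_sizes(train: list[int], test: list[int], dist, n_test: int):
    """Deterministically trade members between sets to hit the exact test size.

    Oversized test pool: promote the test points farthest from any training
    center (most diverse) back into training.  Undersized: demote the
    training centers closest to another center (least diverse).
    """
    train, test = list(train), list(test)
    while len(test) > n_test:
        far = max(test, key=lambda j: (min(dist[j][t] for t in train), j))
        test.remove(far)
        train.append(far)
    while len(test) < n_test and len(train) > 1:
        close = min(
            train,
            key=lambda j: (min(dist[j][t] for t in train if t != j), j),
        )
        train.remove(close)
        test.append(close)
    return sorted(train), sorted(test)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def load_activity_csv(path) -> pd.DataFrame:
    """Read an activity table CSV with columns ``id`` and ``ic50_nM``;
    a ``pic50`` column is appended."""
    df = pd.read_csv(path)
    missing = {"id", "ic50_nM"} - set(df.columns)
    if missing:
        raise ValueError(f"activity table missing columns: {sorted(missing)}")
    df = df.copy()
    df["pic50"] = pic50_from_ic50(df["ic50_nM"].to_numpy())
    return df


def load_smiles_file(path, activities: pd.DataFrame | None = None) -> list[Compound]:
    """Read a SMILES file (``SMILES<whitespace>id`` per line)."""
    from rdkit import Chem

    compounds = []
    act = None
    if activities is not None:
        act = dict(zip(activities["id"].astype(str), activities["ic50_nM"]))
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        smiles, cid = parts[0], (parts[1] if len(parts) > 1 else f"mol{len(compounds)+1}")
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES for {cid!r}: {smiles}")
        compounds.append(
            Compound(id=cid, mol=mol, ic50_nM=act.get(cid) if act else None)
        )
    return compounds


def load_sdf_file(path, activities: pd.DataFrame | None = None) -> list[Compound]:
    """Read an SDF (V2000/V3000); 3D coordinates are taken as provided."""
    from rdkit import Chem

    act = None
    if activities is not None:
        act = dict(zip(activities["id"].astype(str), activities["ic50_nM"]))
    compounds = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"unparseable SDF record #{i + 1} in {path}")
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i+1}"
        compounds.append(
            Compound(id=cid, mol=mol, ic50_nM=act.get(cid) if act else None)
        )
    return compounds


def write_split_csv(split: SplitResult, path) -> None:
    rows = [{"id": i, "set": "train"} for i in split.train_ids]
    rows += [{"id": i, "set": "test"} for i in split.test_ids]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_unicolumn_csv(split: SplitResult, path, decimals: int = 4) -> None:
    """Unicolumn report mirroring the published table layout
    (rows Training/Test; columns Average, Max, Min, Std. dev., Sum)."""
    rows = []
    for name, st in (("Training", split.stats_train), ("Test", split.stats_test)):
        row = {"Data set": name}
        row.update(
            {k: float(truncate_decimal(v, decimals)) for k, v in st.as_row().items()}
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
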