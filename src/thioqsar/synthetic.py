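"""Synthetic inputs with planted structure for every pipeline stage.

Two generators:

* ``gen_descriptor_study`` — a descriptor matrix shaped like the real
  series (default 33 compounds × 216 non-constant columns, nM-range
  activities) in which a small named subset drives activity through a
  linear model with additive Gaussian noise on the pIC50 scale.  The
  default planted coefficients are the magnitudes of the published 4-term
  model (0.6451, 0.4287, −0.2574, 0.2789) on column types mimicking an
  E-state sum, a halogen indicator, an orbital-energy column and a second
  E-state sum; default noise (sd 0.25 pIC50 units) puts the recoverable fit
  in the r² ≈ 0.85 regime of the published model.

* ``gen_toy_3d_set`` — point-atom "molecules" sharing an identical rigid
  5-atom core (for template alignment) plus a few substituent atoms, each
  emitted in a random rigid pose.  One substituent site is shared across
  molecules and its partial charge varies compound-to-compound; activity is
  a declared linear function of that charge, so after alignment the
  electrostatic lattice columns near the site carry the planted signal.

Both are bit-for-bit reproducible for a fixed seed, and both return a truth
record (support, coefficients, noise level) for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compound_data import Compound
from .descriptors2d import DescriptorMatrix

# re-exported here so the generator module is the one-stop shop for test inputs
from .reference_data import (  # noqa: F401
    activity_table,
    loo_predictions_table,
    model1_summary,
    unicolumn_reference,
)

__all__ = [
    "SyntheticSpec",
    "Toy3DSpec",
    "gen_descriptor_study",
    "gen_toy_3d_set",
    "activity_table",
    "unicolumn_reference",
    "loo_predictions_table",
    "model1_summary",
]

_DEFAULT_SUPPORT = ("SsCH3_sum", "halo_indicator", "orbital_energy", "SaaS_sum")
_DEFAULT_COEFFICIENTS = (0.6451, 0.4287, -0.2574, 0.2789)


@dataclass
class SyntheticSpec:
    """World description for the planted 2D descriptor study."""

    n_compounds: int = 33
    n_descriptors: int = 216
    planted_support: tuple[str, ...] = _DEFAULT_SUPPORT
    planted_coefficients: tuple[float, ...] = _DEFAULT_COEFFICIENTS
    intercept: float = 7.0
    noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if len(self.planted_support) != len(self.planted_coefficients):
            raise ValueError("support and coefficients must have equal length")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_descriptors < len(self.planted_support):
            raise ValueError("n_descriptors smaller than the planted support")


def _nonconstant(rng, draw, n):
    """Redraw a column until it is non-constant (bounded retries)."""
    for _ in range(100):
        col = draw(rng, n)
        if np.ptp(col) > 0:
            return col
    raise RuntimeError("could not draw a non-constant column")


def gen_descriptor_study(spec: SyntheticSpec):
    """Generate (DescriptorMatrix, activities, truth record).

    Planted columns mimic the scales of the published model's descriptors:
    a continuous E-state-like sum ~ N(13, 0.9), a 0/1 halogen indicator
    (p = 0.7), an orbital-energy-like column ~ N(−1.2, 0.4) and a second
    E-state-like sum ~ N(1.8, 0.5).  Decoy columns are a mix of integer
    counts (Poisson), continuous sums (normal) and sparse binary
    indicators.  Activity (pIC50 scale) is
    intercept + Σ c_j x_j + N(0, noise_sd); the companion activity table
    carries IC50(nM) = 10^(9 − pIC50).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_compounds
    ids = [f"syn{i+1:02d}" for i in range(n)]

    planted_draws = {
        "SsCH3_sum": lambda r, m: r.normal(13.0, 0.9, m),
        "halo_indicator": lambda r, m: (r.random(m) < 0.7).astype(float),
        "orbital_energy": lambda r, m: r.normal(-1.2, 0.4, m),
        "SaaS_sum": lambda r, m: r.normal(1.8, 0.5, m),
    }
    decoy_draws = (
        lambda r, m: r.poisson(2.0, m).astype(float),
        lambda r, m: r.normal(0.0, 1.0, m),
        lambda r, m: (r.random(m) < 0.3).astype(float),
    )

    cols: dict[str, np.ndarray] = {}
    for j, name in enumerate(spec.planted_support):
        draw = planted_draws.get(name)
        if draw is None:  # user-specified support name: generic continuous column
            draw = lambda r, m: r.normal(0.0, 1.0, m)
        cols[name] = _nonconstant(rng, draw, n)
    k = 1
    while len(cols) < spec.n_descriptors:
        name = f"D{k:03d}"
        k += 1
        if name in cols:
            continue
        draw = decoy_draws[rng.integers(len(decoy_draws))]
        cols[name] = _nonconstant(rng, draw, n)

    df = pd.DataFrame(cols, index=ids)
    missing = [s for s in spec.planted_support if s not in df.columns]
    if missing:
        raise ValueError(f"planted support absent from matrix: {missing}")

    coef = np.asarray(spec.planted_coefficients, float)
    y_clean = spec.intercept + df[list(spec.planted_support)].to_numpy() @ coef
    y = y_clean + rng.normal(0.0, spec.noise_sd, n)
    activities = pd.DataFrame(
        {"id": ids, "ic50_nM": 10.0 ** (9.0 - y), "pic50": y}
    ).set_index("id")

    matrix = DescriptorMatrix(df=df, provenance={c: "computed" for c in df.columns})
    truth = {
        "support": list(spec.planted_support),
        "coefficients": coef.tolist(),
        "intercept": spec.intercept,
        "noise_sd": spec.noise_sd,
        "y_clean": y_clean,
        "seed": spec.seed,
    }
    return matrix, activities, truth


# ---------------------------------------------------------------------------
# toy 3D molecules
# ---------------------------------------------------------------------------

# rigid 5-atom core: a thiophene-like pentagon in the xy-plane, 1.4 Å bonds
_CORE_ELEMENTS = ("S", "C", "C", "C", "C")
_CORE_RADIUS = 1.19  # pentagon circumradius for ~1.4 Å edges


def _core_coords() -> np.ndarray:
    ang = 2.0 * np.pi * np.arange(5) / 5.0 + np.pi / 2.0
    return np.column_stack(
        [_CORE_RADIUS * np.cos(ang), _CORE_RADIUS * np.sin(ang), np.zeros(5)]
    )


@dataclass
class Toy3DSpec:
    """World description for the planted 3D field study."""

    n_molecules: int = 20
    n_substituents: int = 3
    signal_site: tuple[float, float, float] = (2.6, 0.0, 0.5)
    charge_range: tuple[float, float] = (-0.5, 0.5)
    activity_intercept: float = 7.5
    activity_slope: float = 1.5   # pIC50 per unit signal charge
    noise_sd: float = 0.0
    position_jitter: float = 0.3  # Å sd on non-signal substituent positions
    element_palette: tuple[str, ...] = ("C", "N", "O")
    seed: int = 0

    def __post_init__(self):
        if self.n_molecules < 6:
            raise ValueError("need at least 6 molecules")
        if self.n_substituents < 1:
            raise ValueError("need at least one substituent atom")
        if self.noise_sd < 0 or self.position_jitter < 0:
            raise ValueError("noise/jitter must be nonnegative")


def _random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def gen_toy_3d_set(spec: Toy3DSpec):
    """Generate (compounds, activities, truth record) for the field stage.

    Every molecule shares the identical rigid core (atoms 0–4); substituent
    atom 5 sits at the shared signal site with a charge drawn uniformly from
    ``charge_range``, and further substituents take jittered positions and
    small background charges.  Each molecule is emitted in its own random
    rigid pose, so template alignment is required before field evaluation.
    Activity = intercept + slope · signal_charge + N(0, noise_sd).
    """
    rng = np.random.default_rng(spec.seed)
    core = _core_coords()
    base_sites = [np.asarray(spec.signal_site, float)]
    for j in range(1, spec.n_substituents):
        ang = 2.0 * np.pi * j / max(spec.n_substituents, 2)
        base_sites.append(np.array([-2.2 * np.cos(ang), -2.2 * np.sin(ang), -0.6]))

    compounds, acts = [], []
    charges_signal = rng.uniform(*spec.charge_range, size=spec.n_molecules)
    for m in range(spec.n_molecules):
        elements = list(_CORE_ELEMENTS)
        coords = [core.copy()]
        charges = list(rng.uniform(-0.05, 0.05, size=5))
        for j, site in enumerate(base_sites):
            if j == 0:
                pos = site.copy()  # signal site: fixed in the core frame
                q = charges_signal[m]
                el = "O"
            else:
                pos = site + rng.normal(0.0, spec.position_jitter, 3)
                q = rng.uniform(-0.1, 0.1)
                el = spec.element_palette[rng.integers(len(spec.element_palette))]
            elements.append(el)
            coords.append(pos[None, :])
            charges.append(float(q))
        local = np.vstack(coords)
        R = _random_rotation(rng)
        t = rng.uniform(-5.0, 5.0, 3)
        pose = local @ R.T + t
        y = (
            spec.activity_intercept
            + spec.activity_slope * charges_signal[m]
            + rng.normal(0.0, spec.noise_sd)
        )
        compounds.append(
            Compound(
                id=f"toy{m+1:02d}",
                ic50_nM=float(10.0 ** (9.0 - y)),
                coords=pose,
                elements=elements,
                charges=np.asarray(charges),
            )
        )
        acts.append(y)

    truth = {
        "core_indices": list(range(5)),
        "signal_atom_index": 5,
        "signal_site": list(spec.signal_site),
        "signal_charges": charges_signal.tolist(),
        "intercept": spec.activity_intercept,
        "slope": spec.activity_slope,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    return compounds, np.asarray(acts), truth
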