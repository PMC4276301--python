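"""Configuration-driven orchestration of the full study.

``run_2d`` executes ingest → descriptors → split → SW/GA/SA selection →
validation and writes the report bundle (model JSON ranked by q², LOO
residual tables, unicolumn report, descriptor correlation matrix, manifest).
``run_3d`` executes alignment → grid → fields → three kNN-MFA selector
variants and writes field-model reports.  Every run writes a manifest
(config hash, seed, versions, stage timings, record counts) sufficient to
reproduce the outputs exactly.

Inputs come either from files (SMILES/SDF + activity CSV, or a descriptor
CSV) or from the synthetic generators; all numeric defaults of the study
(grid spacing 2.0 Å, probe charge +1, electrostatic cutoff 10, steric and
hydrophobic cutoff 30 kcal/mol) are named configuration fields.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compound_data import (
    load_activity_csv,
    load_sdf_file,
    load_smiles_file,
    pic50_from_ic50,
    sphere_exclusion_split,
    write_split_csv,
    write_unicolumn_csv,
)
from .descriptors2d import DescriptorMatrix, assemble_matrix, remove_invariant_columns
from .field3d import (
    ProbeParameters,
    align_to_template,
    build_grid,
    compute_field_table,
    knn_mfa_fit,
    knn_predict,
)
from .model2d import correlation_matrix, select_descriptors, y_randomization
from .selection import SelectionConfig
from .synthetic import SyntheticSpec, Toy3DSpec, gen_descriptor_study, gen_toy_3d_set
from .validation import golbraikh_tropsha, pred_r2_stat, residual_table, rmse_se

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_2d", "run_3d"]


@dataclass
class RunConfig:
    """Full study configuration with defaulting; loadable from YAML."""

    outdir: str = "results/run"
    seed: int = 0
    log_level: str = "INFO"
    # inputs (one of: synthetic, descriptor CSV, structures + activities)
    synthetic: bool = True
    structures: str | None = None          # .smi or .sdf
    activities: str | None = None          # CSV id,ic50_nM
    descriptors_csv: str | None = None
    external_columns_csv: str | None = None
    # split
    test_fraction: float = 7.0 / 33.0
    split_radius: float | None = None
    # selection
    max_terms: int = 4
    fitness: str = "loo_q2"
    population: int = 30
    generations: int = 100
    n_permutations: int = 99
    # 3D
    grid_spacing: float = 2.0              # Å
    grid_margin: float = 4.0               # Å
    probe_charge: float = 1.0
    electrostatic_cutoff: float = 10.0     # kcal/mol
    steric_cutoff: float = 30.0            # kcal/mol
    knn_k: int = 2
    grid_dims: tuple[int, int, int] | None = None
    # synthetic world overrides
    synthetic_2d: dict = field(default_factory=dict)
    synthetic_3d: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("structures", "activities", "descriptors_csv",
                     "external_columns_csv"):
            p = getattr(cfg, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        if cfg.grid_dims is not None:
            cfg.grid_dims = tuple(int(d) for d in cfg.grid_dims)
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class _Manifest:
    def __init__(self, config: RunConfig, stage: str):
        self.data = {
            "stage": stage,
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "versions": {"thioqsar": __version__, "numpy": np.__version__,
                         "pandas": pd.__version__},
            "timings_s": {},
            "counts": {},
        }
        self._t0 = time.perf_counter()

    def stage_done(self, name: str, **counts):
        t = time.perf_counter()
        self.data["timings_s"][name] = round(t - self._t0, 4)
        self._t0 = t
        self.data["counts"].update(counts)
        logger.info("stage %s done (%s)", name, counts)

    def write(self, outdir: Path):
        (outdir / "manifest.json").write_text(json.dumps(self.data, indent=2))


def _load_2d_inputs(config: RunConfig):
    """Resolve the configured input mode into (DescriptorMatrix, activities)."""
    if config.descriptors_csv:
        X = DescriptorMatrix.from_csv(config.descriptors_csv)
        if not config.activities:
            raise ValueError("descriptor CSV input requires an activity CSV")
        act = load_activity_csv(config.activities).set_index("id")
        act.index = act.index.astype(str)
        X.df.index = X.df.index.astype(str)
        act = act.loc[X.df.index]
        return X, act
    if config.structures:
        act = load_activity_csv(config.activities) if config.activities else None
        if str(config.structures).endswith((".sdf", ".mol")):
            mols = load_sdf_file(config.structures, act)
        else:
            mols = load_smiles_file(config.structures, act)
        external = None
        if config.external_columns_csv:
            external = pd.read_csv(config.external_columns_csv, index_col=0)
        X = assemble_matrix(mols, external=external)
        if act is None:
            raise ValueError("structure input requires an activity CSV")
        act = act.set_index("id")
        act.index = act.index.astype(str)
        X.df.index = X.df.index.astype(str)
        act = act.loc[X.df.index]
        return X, act
    spec = SyntheticSpec(seed=config.seed, **config.synthetic_2d)
    X, act, truth = gen_descriptor_study(spec)
    return X, act.assign(_truth=json.dumps({k: v for k, v in truth.items()
                                            if k != "y_clean"}))


def run_2d(config: RunConfig) -> dict:
    """Execute the 2D study; returns the report dict and writes the bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config, "2d")

    X, act = _load_2d_inputs(config)
    X = remove_invariant_columns(X)
    y = act["pic50"].to_numpy(float)
    manifest.stage_done("descriptors", n_compounds=len(y), n_descriptors=len(X.columns))

    split = sphere_exclusion_split(
        X.df, y, config.test_fraction, radius=config.split_radius, seed=config.seed
    )
    write_split_csv(split, outdir / "split.csv")
    write_unicolumn_csv(split, outdir / "unicolumn.csv")
    train_pos = [X.compound_ids.index(i) for i in split.train_ids]
    test_pos = [X.compound_ids.index(i) for i in split.test_ids]
    Xtr, ytr = X.df.iloc[train_pos], y[train_pos]
    Xte, yte = X.df.iloc[test_pos], y[test_pos]
    manifest.stage_done("split", n_train=len(train_pos), n_test=len(test_pos))

    models = {}
    for method in ("SW", "GA", "SA"):
        cfg = SelectionConfig(
            method=method,
            max_terms=config.max_terms,
            fitness=config.fitness,
            seed=config.seed,
            population=config.population,
            generations=config.generations,
        )
        model = select_descriptors(Xtr, ytr, cfg)
        yhat_te = model.predict(Xte)
        model.stats.n_test = len(yte)
        model.stats.pred_r2 = pred_r2_stat(yte, yhat_te, float(ytr.mean()))
        model.stats.pred_r2_se = rmse_se(yte, yhat_te, len(yte))
        model.stats.gt_report = golbraikh_tropsha(yte, yhat_te, model.stats.q2)
        models[method] = model
        from .model2d import loo_predictions

        loo = loo_predictions(Xtr[model.selected].to_numpy(float), ytr)
        residual_table(ytr, loo, ids=split.train_ids).to_csv(
            outdir / f"residuals_{method.lower()}.csv", index=False
        )
        pd.DataFrame(
            model.search.trace, columns=["iteration", "subset", "fitness"]
        ).to_csv(outdir / f"trace_{method.lower()}.csv", index=False)
        manifest.stage_done(f"fit_{method}", **{f"q2_{method}": round(model.stats.q2, 4)})

    ranking = sorted(models, key=lambda m: models[m].stats.q2, reverse=True)
    best = models[ranking[0]]
    yrand = y_randomization(
        best.selected, Xtr, ytr, n_perm=config.n_permutations, seed=config.seed
    )
    correlation_matrix(Xtr, ytr, selected=best.selected).to_csv(
        outdir / "correlation_matrix.csv"
    )
    manifest.stage_done("validate", yrand_confidence=yrand.confidence_pct)

    report = {
        "ranking": ranking,
        "best_method": ranking[0],
        "models": {m: models[m].report() for m in models},
        "y_randomization": {
            "n_perm": yrand.n_perm,
            "true_r2": yrand.true_r2,
            "confidence_pct": yrand.confidence_pct,
        },
        "split": {"train": list(split.train_ids), "test": list(split.test_ids)},
    }
    (outdir / "models_2d.json").write_text(json.dumps(report, indent=2, default=str))
    manifest.data["report"] = "models_2d.json"
    manifest.write(outdir)
    return report


def run_3d(config: RunConfig) -> dict:
    """Execute the 3D field study; returns the report dict, writes the bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config, "3d")

    if config.structures:
        act = load_activity_csv(config.activities) if config.activities else None
        compounds = load_sdf_file(config.structures, act)
        y = np.array([c.pic50 for c in compounds])
        template = list(range(min(5, len(compounds[0].coordinates()))))
        truth = None
    else:
        spec = Toy3DSpec(seed=config.seed, **config.synthetic_3d)
        compounds, y, truth = gen_toy_3d_set(spec)
        template = truth["core_indices"]

    # alignment onto the most active compound
    ref_idx = int(np.argmax(y))
    reference = compounds[ref_idx]
    aligned, rmsds = [], []
    for comp in compounds:
        coords, rmsd = align_to_template(comp, template, reference)
        aligned.append(coords)
        rmsds.append(rmsd)
    manifest.stage_done(
        "align", n_compounds=len(compounds),
        reference=str(reference.id), max_template_rmsd=round(max(rmsds), 6),
    )

    if config.grid_dims is not None:
        allc = np.vstack(aligned)
        origin = tuple(float(v) for v in (allc.min(axis=0) - config.grid_margin))
        from .field3d import Grid

        grid = Grid(origin=origin, spacing=config.grid_spacing,
                    dims=tuple(config.grid_dims))
    else:
        grid = build_grid(aligned, config.grid_spacing, config.grid_margin)
    probe = ProbeParameters(charge=config.probe_charge)
    fields = compute_field_table(
        compounds, grid, probe,
        electrostatic_cutoff=config.electrostatic_cutoff,
        steric_cutoff=config.steric_cutoff,
        aligned_coords=aligned,
    )
    fields.to_csv(outdir / "fields.csv")
    manifest.stage_done("fields", n_grid_points=grid.n_points,
                        n_field_columns=fields.n_columns)

    split = sphere_exclusion_split(
        fields.df, y, config.test_fraction, radius=config.split_radius,
        seed=config.seed,
    )
    train_pos = [list(fields.df.index).index(i) for i in split.train_ids]
    test_pos = [list(fields.df.index).index(i) for i in split.test_ids]
    Ftr, ytr = fields.df.iloc[train_pos], y[train_pos]
    Fte, yte = fields.df.iloc[test_pos], y[test_pos]

    models = {}
    for method in ("SW", "GA", "SA"):
        cfg = SelectionConfig(
            method=method, max_terms=config.max_terms, seed=config.seed,
            population=config.population, generations=config.generations,
        )
        model = knn_mfa_fit(Ftr, ytr, cfg, k=config.knn_k)
        yhat_te = knn_predict(model, Fte)
        rep = model.report()
        rep["pred_r2"] = pred_r2_stat(yte, yhat_te, float(ytr.mean()))
        rep["pred_r2_se"] = rmse_se(yte, yhat_te, len(yte))
        models[method] = rep
        manifest.stage_done(f"fit3d_{method}", **{f"q2_3d_{method}": round(rep["q2"], 4)})

    ranking = sorted(models, key=lambda m: models[m]["q2"], reverse=True)
    report = {
        "ranking": ranking,
        "best_method": ranking[0],
        "grid": grid.to_dict(),
        "models": {m: models[m] for m in models},
        "split": {"train": list(split.train_ids), "test": list(split.test_ids)},
    }
    if truth is not None:
        report["truth"] = {k: v for k, v in truth.items() if k != "signal_charges"}
    (outdir / "models_3d.json").write_text(json.dumps(report, indent=2, default=str))
    manifest.data["report"] = "models_3d.json"
    manifest.write(outdir)
    return report
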