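"""End-to-end pipeline: structures -> QSAR parameters -> simulated exposure.

Orchestrates the scenario families of the framework: a 1-compartment model
driven by predicted CL and Vdss, and the whole-body PBPK model under each
distribution method with either in vivo CL or microsomal CLint as the
clearance input (11 scenarios in total). Every stage is a pure function of
its inputs, the configuration and one root seed; a run manifest records
the configuration snapshot and SHA-256 hashes of every file produced.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chem import CompoundRecord, feature_matrix
from .distribution import KP_METHODS, ParameterSet, compute_kp
from .nca import fold_metrics, summarize
from .physio import PhysiologyTable, TissueComposition
from .qsar import (
    ALGORITHMS,
    REPRESENTATIONS,
    TARGETS,
    QsarModel,
    SplitSpec,
    make_split,
    select_best,
    train_model,
)
from .simulate import (
    DEFAULT_TIMES,
    ConcentrationProfile,
    SimulationConfig,
    build_pbpk,
    simulate_1cmt,
    simulate_pbpk,
)
from .synthio import (
    SynthConfig,
    generate_library,
    generate_observed_profiles,
    profiles_from_frame,
    profiles_to_frame,
)

#: prediction grid: the sparse sampling design refined between samples
PREDICTION_TIMES = tuple(sorted(set(DEFAULT_TIMES) | set(np.round(np.geomspace(0.083, 24.0, 24), 4))))


@dataclass
class PipelineConfig:
    """One structured configuration for the whole pipeline."""

    seed: int = 0
    synth: SynthConfig | None = None
    candidates: list = field(
        default_factory=lambda: [(a, r) for a in ALGORITHMS for r in REPRESENTATIONS]
    )
    grids: dict | None = None  # per-algorithm hyperparameter grid override
    folds: int = 10
    targets: tuple = TARGETS
    distribution_methods: tuple = KP_METHODS
    clearance_modes: tuple = ("invivo_cl", "microsomal_clint")
    dose: float = 1.0
    bp: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = raw.pop("synth", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if synth is not None:
            cfg.synth = SynthConfig(**synth)
        cfg.candidates = [tuple(c) for c in cfg.candidates]
        return cfg


def train_all_targets(
    records: list[CompoundRecord],
    split: SplitSpec,
    config: PipelineConfig,
) -> dict[str, QsarModel]:
    """Train candidate models per target and select the best by CV MAPE."""
    by_id = {r.compound_id: r for r in records}
    reps_needed = {rep for _, rep in config.candidates}
    features = {
        rep: feature_matrix(records, "fingerprint" if rep == "fingerprint" else "descriptors")
        for rep in reps_needed
    }
    models: dict[str, QsarModel] = {}
    for ti, target in enumerate(config.targets):
        train_ids = split.train_ids_per_target[target]
        y = pd.Series({cid: by_id[cid].measured[target] for cid in train_ids})
        candidates = []
        for ci, (algorithm, rep) in enumerate(config.candidates):
            x = features[rep].loc[train_ids]
            grid = (config.grids or {}).get(algorithm)
            candidates.append(
                train_model(
                    target, x, y, algorithm, rep,
                    grid=grid, folds=config.folds,
                    seed=config.seed + 1000 * ti + ci,
                )
            )
        models[target] = select_best(candidates)
    return models


def predict_parameters(
    records: list[CompoundRecord],
    models: dict[str, QsarModel],
) -> pd.DataFrame:
    """ML-predicted parameters plus RDKit-computed logP/MW/halogens.

    One row per compound with every mechanistic-model input; the structure-
    derived quantities are computed, not learned.
    """
    from .chem import compute_logp, compute_mw, count_halogens

    reps = {m.representation for m in models.values()}
    features = {
        rep: feature_matrix(records, "fingerprint" if rep == "fingerprint" else "descriptors")
        for rep in reps
    }
    out = pd.DataFrame(index=[r.compound_id for r in records])
    for target, model in models.items():
        out[target] = model.predict(features[model.representation])
    out["logp"] = [compute_logp(r.smiles_std) for r in records]
    out["mw"] = [compute_mw(r.smiles_std) for r in records]
    out["n_halogens"] = [count_halogens(r.smiles_std) for r in records]
    return out


def parameter_set_from_row(row: pd.Series) -> ParameterSet:
    return ParameterSet(
        fu=float(row["fu"]),
        logp=float(row["logp"]),
        mw=float(row["mw"]),
        n_halogens=int(row["n_halogens"]),
        cl_invivo=float(row["cl_invivo"]) if "cl_invivo" in row and pd.notna(row["cl_invivo"]) else None,
        clint_microsomal=float(row["clint"]) if "clint" in row and pd.notna(row["clint"]) else None,
        pka_acid=float(row["pka_acid"]) if "pka_acid" in row and pd.notna(row["pka_acid"]) else None,
        pka_base=float(row["pka_base"]) if "pka_base" in row and pd.notna(row["pka_base"]) else None,
    )


def simulate_scenarios(
    params_table: pd.DataFrame,
    config: PipelineConfig,
    phys: PhysiologyTable | None = None,
    comp: TissueComposition | None = None,
    times=PREDICTION_TIMES,
) -> dict[str, list[ConcentrationProfile]]:
    """Predicted profiles for every scenario (1-compartment + PBPK grid)."""
    phys = phys or PhysiologyTable.default_rat()
    comp = comp or TissueComposition.default_rat()
    scenarios: dict[str, list[ConcentrationProfile]] = {}
    times = np.asarray(times, dtype=float)

    profiles = []
    for cid, row in params_table.iterrows():
        prof = simulate_1cmt(float(row["cl_invivo"]), float(row["vdss"]), config.dose, times)
        prof.compound_id = str(cid)
        profiles.append(prof)
    scenarios["one_compartment"] = profiles

    for mode in config.clearance_modes:
        for method in config.distribution_methods:
            profiles = []
            for cid, row in params_table.iterrows():
                params = parameter_set_from_row(row)
                kp = compute_kp(method, params, comp)
                sim_cfg = SimulationConfig(
                    model="pbpk",
                    distribution_method=method,
                    clearance_mode=mode,
                    dose=config.dose,
                    bp=config.bp,
                    times=tuple(times),
                )
                system = build_pbpk(params, kp, phys, sim_cfg, compound_id=str(cid))
                profiles.append(simulate_pbpk(system, times))
            scenarios[f"pbpk:{mode}:{method}"] = profiles
    return scenarios


def evaluate_scenarios(
    scenarios: dict[str, list[ConcentrationProfile]],
    observed: list[ConcentrationProfile],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fold metrics of every scenario against the observed profiles.

    Returns (per-compound fold metrics, per-scenario summary).
    """
    obs_by_id = {p.compound_id: p for p in observed}
    all_metrics = []
    for scenario, profiles in scenarios.items():
        for pred in profiles:
            obs = obs_by_id.get(pred.compound_id)
            if obs is None:
                continue
            fm = fold_metrics(obs, pred, method=scenario)
            all_metrics.append(
                {
                    "compound_id": fm.compound_id,
                    "method": fm.method,
                    "auc_ratio": fm.auc_ratio,
                    "cmax_ratio": fm.cmax_ratio,
                }
            )
    metrics = pd.DataFrame(all_metrics)
    summary = summarize(metrics, group_by="method")
    parts = summary["method"].str.split(":", expand=True)
    summary.insert(0, "model", parts[0].where(parts[0] != "pbpk", "pbpk"))
    summary.insert(1, "clearance_mode", parts[1] if parts.shape[1] > 1 else None)
    summary.insert(2, "distribution_method", parts[2] if parts.shape[1] > 2 else None)
    summary.loc[summary["model"] == "one_compartment", "clearance_mode"] = "invivo_cl"
    return metrics, summary


def leaderboard(models: dict[str, QsarModel], split: SplitSpec) -> pd.DataFrame:
    """Per-target model-selection record (parameter, sizes, winner, CV metrics)."""
    rows = []
    for target, model in models.items():
        rows.append(
            {
                "parameter": target,
                "train_size": len(split.train_ids_per_target[target]),
                "test_size": len(split.test_ids),
                "algorithm": model.algorithm,
                "representation": model.representation,
                "cv_mape": model.cv_metrics["mape"],
                "cv_rmse": model.cv_metrics["rmse"],
                "unit": model.unit,
            }
        )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Full synthetic-data pipeline run; writes CSV outputs plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()

    synth_cfg = config.synth or SynthConfig(seed=config.seed)
    library = generate_library(synth_cfg)
    observed = generate_observed_profiles(library)

    from .chem import compounds_to_frame

    compounds_to_frame(library.records).to_csv(outdir / "compounds.csv", index=False)
    profiles_to_frame(observed).to_csv(outdir / "observed_profiles.csv", index=False)

    split = make_split(library.records, library.profile_ids)
    models = train_all_targets(library.records, split, config)
    board = leaderboard(models, split)
    board.to_csv(outdir / "leaderboard.csv", index=False)

    by_id = {r.compound_id: r for r in library.records}
    test_records = [by_id[cid] for cid in split.test_ids]
    params_table = predict_parameters(test_records, models)
    params_table.to_csv(outdir / "predicted_parameters.csv", index_label="compound_id")

    scenarios = simulate_scenarios(params_table, config)
    long_rows = []
    for scenario, profiles in scenarios.items():
        for p in profiles:
            df = p.to_frame()
            df.insert(1, "scenario", scenario)
            long_rows.append(df)
    pd.concat(long_rows, ignore_index=True).to_csv(outdir / "predicted_profiles.csv", index=False)

    metrics, summary = evaluate_scenarios(scenarios, observed)
    metrics.to_csv(outdir / "fold_metrics.csv", index=False)
    summary.to_csv(outdir / "summary.csv", index=False)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_snapshot(config),
        "started_unix": t_start,
        "elapsed_s": time.time() - t_start,
        "files": {
            p.name: _sha256(p) for p in sorted(outdir.glob("*.csv"))
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {
        "library": library,
        "observed": observed,
        "split": split,
        "models": models,
        "leaderboard": board,
        "params": params_table,
        "scenarios": scenarios,
        "metrics": metrics,
        "summary": summary,
        "manifest": manifest,
    }


def _config_snapshot(config: PipelineConfig) -> dict:
    snap = asdict(config)
    if snap.get("synth") is not None:
        snap["synth"]["times"] = list(snap["synth"]["times"])
    snap["candidates"] = [list(c) for c in snap["candidates"]]
    for key in ("targets", "distribution_methods", "clearance_modes"):
        snap[key] = list(snap[key])
    return snap
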