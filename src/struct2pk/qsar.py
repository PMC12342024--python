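"""Per-parameter QSAR regression: train, cross-validate, select, apply.

Each PK/PC parameter (CL, Vdss, CLint, acidic/basic pKa, Fu) gets its own
regressor mapping a molecular representation (Morgan fingerprints or the
RDKit descriptor panel) to the measured value. Candidate models span
random forest, gradient boosting (XGBoost) and support-vector regression
over configurable hyperparameter grids; selection is by ten-fold
cross-validated MAPE with RMSE as tie-break. Targets spanning orders of
magnitude are fitted on log scale, Fu on logit scale, pKa untransformed;
metrics are always computed in natural units after back-transform.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .chem import CompoundRecord

TARGETS = ("cl_invivo", "vdss", "clint", "pka_acid", "pka_base", "fu")
TARGET_UNITS = {
    "cl_invivo": "mL/min/kg",
    "vdss": "mL/kg",
    "clint": "uL/min/mg",
    "pka_acid": "",
    "pka_base": "",
    "fu": "",
}
TARGET_TRANSFORMS = {
    "cl_invivo": "log",
    "vdss": "log",
    "clint": "log",
    "pka_acid": "identity",
    "pka_base": "identity",
    "fu": "logit",
}
ALGORITHMS = ("random_forest", "gradient_boosting", "svr")
REPRESENTATIONS = ("fingerprint", "descriptors")

#: default hyperparameter grids; only the families named for each algorithm
#: are searched. Overridable per call.
DEFAULT_GRIDS = {
    "random_forest": {
        "n_estimators": [100, 300, 500],
        "max_depth": [4, 8, 16, None],
    },
    "gradient_boosting": {
        "n_estimators": [100, 300, 500],
        "subsample": [0.6, 0.8, 1.0],
        "colsample_bytree": [0.6, 0.8, 1.0],
        "learning_rate": [0.01, 0.05, 0.1],
    },
    "svr": {
        "kernel": ["rbf", "linear"],
        "C": [0.1, 1.0, 10.0],
        "gamma": ["scale", 0.01, 0.1],
        "epsilon": [0.01, 0.1],
    },
}

_LOGIT_EPS = 1e-6


def _transform(y: np.ndarray, how: str) -> np.ndarray:
    if how == "log":
        return np.log(y)
    if how == "logit":
        p = np.clip(y, _LOGIT_EPS, 1.0 - _LOGIT_EPS)
        return np.log(p / (1.0 - p))
    return np.asarray(y, dtype=float)


def _back_transform(z: np.ndarray, how: str) -> np.ndarray:
    if how == "log":
        return np.exp(z)
    if how == "logit":
        return 1.0 / (1.0 + np.exp(-z))
    return np.asarray(z, dtype=float)


def score(pred, obs) -> dict[str, float]:
    """MAPE (as a fraction) and RMSE in natural units.

    Observations equal to zero are excluded from MAPE with a warning; RMSE
    uses all points.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("pred and obs must have equal length")
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    nonzero = obs != 0
    n_excluded = int(np.sum(~nonzero))
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} zero observation(s) from MAPE")
    if not np.any(nonzero):
        raise ValueError("MAPE undefined: all observations are zero")
    mape = float(np.mean(np.abs(obs[nonzero] - pred[nonzero]) / np.abs(obs[nonzero])))
    return {"mape": mape, "rmse": rmse}


@dataclass
class SplitSpec:
    """Test/train membership: one shared test set, per-target train sets."""

    test_ids: list[str]
    train_ids_per_target: dict[str, list[str]]

    def __post_init__(self) -> None:
        test = set(self.test_ids)
        for target, ids in self.train_ids_per_target.items():
            overlap = test & set(ids)
            if overlap:
                raise ValueError(f"train/test leakage for {target}: {sorted(overlap)[:5]}")


def make_split(compounds: list[CompoundRecord], profile_ids: set[str]) -> SplitSpec:
    """Complete-data test split.

    The test set is every compound possessing all measured parameters AND
    an observed PK profile; each target's training set is every remaining
    compound with that measurement. Deterministic: ids are sorted.
    """
    test_ids = sorted(
        rec.compound_id
        for rec in compounds
        if rec.compound_id in profile_ids and all(rec.has(t) for t in TARGETS)
    )
    if not test_ids:
        raise ValueError(
            "empty test set: no compound has every measurement plus a profile; "
            "regenerate the library with higher completeness"
        )
    test = set(test_ids)
    train: dict[str, list[str]] = {}
    for target in TARGETS:
        ids = sorted(
            rec.compound_id
            for rec in compounds
            if rec.compound_id not in test and rec.has(target)
        )
        if not ids:
            raise ValueError(f"empty training set for {target}; every compound is complete")
        train[target] = ids
    return SplitSpec(test_ids=test_ids, train_ids_per_target=train)


@dataclass
class QsarModel:
    """A fitted per-parameter regressor with its CV record."""

    target: str
    unit: str
    algorithm: str
    representation: str
    transform: str
    hyperparams: dict
    cv_metrics: dict  # {"per_fold": [...], "mape": float, "rmse": float}
    train_ids: list[str]
    feature_names: list[str]
    impute_medians: pd.Series | None
    estimator: object
    leaderboard: pd.DataFrame | None = field(default=None, repr=False)

    def predict(self, features: pd.DataFrame) -> pd.Series:
        return predict(self, features)

    def save(self, directory) -> Path:
        """Persist estimator (joblib) plus a JSON sidecar of the metadata."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        stem = directory / self.target
        joblib.dump(self.estimator, stem.with_suffix(".joblib"))
        meta = {
            "target": self.target,
            "unit": self.unit,
            "algorithm": self.algorithm,
            "representation": self.representation,
            "transform": self.transform,
            "hyperparams": self.hyperparams,
            "cv_metrics": {
                "mape": self.cv_metrics["mape"],
                "rmse": self.cv_metrics["rmse"],
                "per_fold": self.cv_metrics["per_fold"],
            },
            "train_ids": self.train_ids,
            "feature_names": self.feature_names,
            "impute_medians": None
            if self.impute_medians is None
            else self.impute_medians.to_dict(),
        }
        stem.with_suffix(".json").write_text(json.dumps(meta, indent=1))
        return stem.with_suffix(".joblib")

    @classmethod
    def load(cls, directory, target: str) -> "QsarModel":
        stem = Path(directory) / target
        meta = json.loads(stem.with_suffix(".json").read_text())
        estimator = joblib.load(stem.with_suffix(".joblib"))
        medians = meta["impute_medians"]
        return cls(
            target=meta["target"],
            unit=meta["unit"],
            algorithm=meta["algorithm"],
            representation=meta["representation"],
            transform=meta["transform"],
            hyperparams=meta["hyperparams"],
            cv_metrics={
                "mape": meta["cv_metrics"]["mape"],
                "rmse": meta["cv_metrics"]["rmse"],
                "per_fold": meta["cv_metrics"]["per_fold"],
            },
            train_ids=meta["train_ids"],
            feature_names=meta["feature_names"],
            impute_medians=None if medians is None else pd.Series(medians),
            estimator=estimator,
        )


def _make_estimator(algorithm: str, hyperparams: dict, seed: int):
    if algorithm == "random_forest":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **hyperparams)
    if algorithm == "gradient_boosting":
        return XGBRegressor(
            random_state=seed, n_jobs=1, verbosity=0, objective="reg:squarederror", **hyperparams
        )
    if algorithm == "svr":
        return Pipeline([("scale", StandardScaler()), ("svr", SVR(**hyperparams))])
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _clean_features(features: pd.DataFrame, medians: pd.Series | None = None):
    """Replace non-finite descriptor values by training medians."""
    x = features.replace([np.inf, -np.inf], np.nan)
    if medians is None:
        medians = x.median(axis=0).fillna(0.0)
    x = x.fillna(medians)
    return x, medians


def train_model(
    target: str,
    features: pd.DataFrame,
    y: pd.Series,
    algorithm: str,
    representation: str,
    grid: dict | None = None,
    folds: int = 10,
    seed: int = 0,
) -> QsarModel:
    """Grid-search one algorithm/representation pair with k-fold CV.

    ``features`` rows and ``y`` are aligned by compound id index. Fold
    metrics (MAPE/RMSE) are computed on natural-unit back-transformed
    predictions; the winning hyperparameters are refitted on the full
    training set. Fully reproducible for a given seed.
    """
    if target not in TARGETS:
        raise ValueError(f"unknown target {target!r}")
    y = y.loc[features.index]
    bad = y.index[~np.isfinite(y.to_numpy(dtype=float))].tolist()
    if bad:
        raise ValueError(f"non-finite target values for: {bad[:10]}")
    if len(y) < folds:
        warnings.warn(f"only {len(y)} points; reducing folds from {folds}")
        folds = max(2, len(y))
    transform = TARGET_TRANSFORMS[target]
    if transform == "log" and (y <= 0).any():
        raise ValueError(f"{target} must be strictly positive for log-scale fitting")

    x, medians = _clean_features(features, None)
    z = _transform(y.to_numpy(dtype=float), transform)
    grid = grid if grid is not None else DEFAULT_GRIDS[algorithm]
    names = sorted(grid)
    combos = [dict(zip(names, vals)) for vals in itertools.product(*(grid[n] for n in names))]

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    x_np = x.to_numpy(dtype=float)
    results = []
    for hp in combos:
        fold_scores = []
        for train_idx, val_idx in kf.split(x_np):
            est = _make_estimator(algorithm, hp, seed)
            est.fit(x_np[train_idx], z[train_idx])
            pred = _back_transform(est.predict(x_np[val_idx]), transform)
            fold_scores.append(score(pred, y.to_numpy(dtype=float)[val_idx]))
        mean_mape = float(np.mean([s["mape"] for s in fold_scores]))
        mean_rmse = float(np.mean([s["rmse"] for s in fold_scores]))
        results.append((mean_mape, mean_rmse, hp, fold_scores))
    results.sort(key=lambda r: (r[0], r[1]))
    best_mape, best_rmse, best_hp, best_folds = results[0]

    final = _make_estimator(algorithm, best_hp, seed)
    final.fit(x_np, z)
    return QsarModel(
        target=target,
        unit=TARGET_UNITS[target],
        algorithm=algorithm,
        representation=representation,
        transform=transform,
        hyperparams=best_hp,
        cv_metrics={"mape": best_mape, "rmse": best_rmse, "per_fold": best_folds},
        train_ids=list(x.index),
        feature_names=list(x.columns),
        impute_medians=medians if representation == "descriptors" else None,
        estimator=final,
    )


def select_best(candidates: list[QsarModel]) -> QsarModel:
    """Rank candidates by mean CV MAPE, ties by RMSE, then algorithm order.

    The winner carries the full leaderboard as a DataFrame attribute.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    targets = {c.target for c in candidates}
    if len(targets) > 1:
        raise ValueError(f"candidates span multiple targets: {sorted(targets)}")
    order = {a: i for i, a in enumerate(ALGORITHMS)}
    ranked = sorted(
        candidates,
        key=lambda c: (c.cv_metrics["mape"], c.cv_metrics["rmse"], order[c.algorithm]),
    )
    board = pd.DataFrame(
        {
            "algorithm": [c.algorithm for c in ranked],
            "representation": [c.representation for c in ranked],
            "cv_mape": [c.cv_metrics["mape"] for c in ranked],
            "cv_rmse": [c.cv_metrics["rmse"] for c in ranked],
        }
    )
    winner = ranked[0]
    winner.leaderboard = board
    return winner


def predict(model: QsarModel, features: pd.DataFrame) -> pd.Series:
    """Apply a fitted model; back-transform to natural units.

    Fu predictions are clipped into (0, 1] (with a warning when clipping
    fires); log-scale targets come back strictly positive by construction.
    """
    if list(features.columns) != model.feature_names:
        if set(features.columns) >= set(model.feature_names):
            features = features[model.feature_names]
        else:
            raise ValueError(
                f"feature mismatch: model expects {len(model.feature_names)} named columns"
            )
    x, _ = _clean_features(features, model.impute_medians)
    z = model.estimator.predict(x.to_numpy(dtype=float))
    values = _back_transform(z, model.transform)
    if model.target == "fu":
        if np.any(values > 1.0) or np.any(values <= 0.0):
            warnings.warn("clipping fu predictions into (0, 1]")
        values = np.clip(values, _LOGIT_EPS, 1.0)
    return pd.Series(values, index=features.index, name=model.target)
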