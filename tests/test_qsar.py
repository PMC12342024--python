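"""QSAR training, selection, prediction and scoring."""

import numpy as np
import pandas as pd
import pytest

from struct2pk.chem import CompoundRecord
from struct2pk.qsar import (
    QsarModel,
    SplitSpec,
    make_split,
    predict,
    score,
    select_best,
    train_model,
)

SMILES = "CCO"  # structure content is irrelevant for these fixtures


def _record(cid, measured):
    return CompoundRecord(cid, SMILES, smiles_std=SMILES, measured=measured)


def _full_measurements():
    return {
        "cl_invivo": 10.0,
        "vdss": 1000.0,
        "clint": 20.0,
        "pka_acid": 4.0,
        "pka_base": 9.0,
        "fu": 0.2,
    }


class TestSplit:
    def test_complete_data_rule(self):
        complete = [_record(f"c{i}", _full_measurements()) for i in range(2)]
        common = {"vdss": 800.0, "clint": 9.0, "pka_acid": 4.2, "pka_base": 8.1}
        partial = [
            _record("p0", {"fu": 0.3, **common}),
            _record("p1", {"cl_invivo": 5.0, "fu": 0.1, **common}),
            _record("p2", {"cl_invivo": 7.0, **common}),
        ]
        split = make_split(complete + partial, profile_ids={"c0", "c1"})
        assert split.test_ids == ["c0", "c1"]
        assert split.train_ids_per_target["fu"] == ["p0", "p1"]
        assert split.train_ids_per_target["cl_invivo"] == ["p1", "p2"]

    def test_all_complete_degenerate(self):
        records = [_record(f"c{i}", _full_measurements()) for i in range(4)]
        with pytest.raises(ValueError, match="empty training set"):
            make_split(records, profile_ids={r.compound_id for r in records})

    def test_empty_test_set_instructs_regeneration(self):
        records = [_record("p0", {"fu": 0.3})]
        with pytest.raises(ValueError, match="regenerate"):
            make_split(records, profile_ids=set())

    def test_synthio_counts_match_bruteforce(self, tiny_library):
        lib = tiny_library
        split = make_split(lib.records, lib.profile_ids)
        targets = ("cl_invivo", "vdss", "clint", "pka_acid", "pka_base", "fu")
        expected_test = sorted(
            r.compound_id
            for r in lib.records
            if r.compound_id in lib.profile_ids and all(r.has(t) for t in targets)
        )
        assert split.test_ids == expected_test
        for t in targets:
            expected_train = sorted(
                r.compound_id
                for r in lib.records
                if r.compound_id not in expected_test and r.has(t)
            )
            assert split.train_ids_per_target[t] == expected_train

    def test_leakage_guard(self):
        with pytest.raises(ValueError, match="leakage"):
            SplitSpec(test_ids=["a", "b"], train_ids_per_target={"fu": ["b", "c"]})


class TestScore:
    def test_identity(self):
        assert score([1.0, 2.0], [1.0, 2.0]) == {"mape": 0.0, "rmse": 0.0}

    def test_hand_arithmetic(self):
        out = score([2.0, 2.0], [1.0, 4.0])
        assert out["mape"] == pytest.approx(0.75)
        assert out["rmse"] == pytest.approx(np.sqrt((1 + 4) / 2))

    def test_zero_observations_excluded(self):
        with pytest.warns(UserWarning, match="excluded 1"):
            out = score([3.0, 4.0], [0.0, 2.0])
        assert out["mape"] == pytest.approx(1.0)  # only the nonzero point
        assert out["rmse"] == pytest.approx(np.sqrt((9 + 4) / 2))

    def test_all_zero_observations_error(self):
        with pytest.raises(ValueError, match="MAPE undefined"), pytest.warns(UserWarning):
            score([3.0, 4.0], [0.0, 0.0])


def _toy_training_data(n=60, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    x = pd.DataFrame(
        {"d1": rng.uniform(0, 4, n), "d2": rng.normal(0, 1, n)},
        index=[f"c{i}" for i in range(n)],
    )
    y = pd.Series(np.exp(1.0 + 0.5 * x["d1"] + noise * rng.normal(0, 1, n)), index=x.index)
    return x, y


class TestTrainModel:
    def test_representable_function_near_interpolation(self):
        x, y = _toy_training_data()
        model = train_model(
            "cl_invivo", x, y, "gradient_boosting", "descriptors",
            grid={"n_estimators": [300], "learning_rate": [0.1], "subsample": [1.0], "colsample_bytree": [1.0]},
            folds=5, seed=1,
        )
        train_pred = predict(model, x)
        mape = float(np.mean(np.abs(y - train_pred) / y))
        assert mape < 0.05

    def test_constant_target_predicted_exactly(self):
        x, _ = _toy_training_data(30)
        y = pd.Series(7.0, index=x.index)
        model = train_model(
            "pka_base", x, y, "random_forest", "descriptors",
            grid={"n_estimators": [50], "max_depth": [4]}, folds=5, seed=0,
        )
        pred = predict(model, x)
        assert np.allclose(pred, 7.0)
        assert model.cv_metrics["mape"] == pytest.approx(0.0, abs=1e-12)

    def test_nonfinite_target_lists_offenders(self):
        x, y = _toy_training_data(20)
        y.iloc[3] = np.nan
        with pytest.raises(ValueError, match="c3"):
            train_model("cl_invivo", x, y, "svr", "descriptors",
                        grid={"kernel": ["linear"], "C": [1.0], "gamma": ["scale"], "epsilon": [0.1]})

    def test_fold_reduction_warns(self):
        x, y = _toy_training_data(6)
        with pytest.warns(UserWarning, match="reducing folds"):
            train_model("cl_invivo", x, y, "svr", "descriptors",
                        grid={"kernel": ["linear"], "C": [1.0], "gamma": ["scale"], "epsilon": [0.1]},
                        folds=10)

    def test_seeded_rerun_identical(self):
        x, y = _toy_training_data(50, noise=0.2)
        kwargs = dict(
            grid={"n_estimators": [100], "max_depth": [4, 8]}, folds=5, seed=42
        )
        m1 = train_model("cl_invivo", x, y, "random_forest", "descriptors", **kwargs)
        m2 = train_model("cl_invivo", x, y, "random_forest", "descriptors", **kwargs)
        assert m1.hyperparams == m2.hyperparams
        assert np.array_equal(predict(m1, x).to_numpy(), predict(m2, x).to_numpy())

    def test_monotone_data_benefit(self):
        """More training data never hurts median held-out error (5 seeds)."""
        grid = {"n_estimators": [150], "learning_rate": [0.1], "subsample": [1.0], "colsample_bytree": [1.0]}
        deltas = {150: [], 300: []}
        for seed in range(5):
            rng = np.random.default_rng(1000 + seed)
            x_test = pd.DataFrame(
                {"d1": rng.uniform(0, 4, 80), "d2": rng.normal(0, 1, 80)},
                index=[f"t{i}" for i in range(80)],
            )
            y_test = pd.Series(np.exp(1.0 + 0.5 * x_test["d1"]), index=x_test.index)
            for n in (150, 300):
                x, y = _toy_training_data(n, seed=2000 + seed, noise=0.2)
                model = train_model("cl_invivo", x, y, "gradient_boosting", "descriptors",
                                    grid=grid, folds=5, seed=seed)
                mape = score(predict(model, x_test).to_numpy(), y_test.to_numpy())["mape"]
                deltas[n].append(mape)
        assert np.median(deltas[300]) <= np.median(deltas[150])


class TestSelectBest:
    def _model(self, algorithm, mape, rmse):
        return QsarModel(
            target="cl_invivo", unit="mL/min/kg", algorithm=algorithm,
            representation="descriptors", transform="log", hyperparams={},
            cv_metrics={"mape": mape, "rmse": rmse, "per_fold": []},
            train_ids=[], feature_names=[], impute_medians=None, estimator=None,
        )

    def test_single_candidate(self):
        m = self._model("svr", 0.5, 1.0)
        assert select_best([m]) is m

    def test_lower_mape_wins(self):
        best = select_best([self._model("svr", 0.8, 1.0), self._model("random_forest", 0.3, 5.0)])
        assert best.algorithm == "random_forest"

    def test_rmse_tiebreak(self):
        best = select_best([self._model("svr", 0.5, 12.0), self._model("gradient_boosting", 0.5, 10.0)])
        assert best.algorithm == "gradient_boosting"

    def test_algorithm_order_final_tiebreak(self):
        best = select_best([self._model("svr", 0.5, 1.0), self._model("random_forest", 0.5, 1.0)])
        assert best.algorithm == "random_forest"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best([])

    def test_leaderboard_attached(self):
        best = select_best([self._model("svr", 0.8, 1.0), self._model("random_forest", 0.3, 5.0)])
        assert list(best.leaderboard["algorithm"]) == ["random_forest", "svr"]


class TestPredict:
    def test_log_scale_back_transform_is_positive(self):
        x, y = _toy_training_data(40)
        model = train_model("vdss", x, y, "svr", "descriptors",
                            grid={"kernel": ["linear"], "C": [1.0], "gamma": ["scale"], "epsilon": [0.1]},
                            folds=5)
        assert (predict(model, x) > 0).all()

    def test_fu_clipped_with_warning(self):
        x, _ = _toy_training_data(30)
        y = pd.Series(0.999, index=x.index)  # near-boundary constant
        model = train_model("fu", x, y, "random_forest", "descriptors",
                            grid={"n_estimators": [50], "max_depth": [None]}, folds=3)
        x_far = x.copy() + 100.0
        pred = predict(model, x_far)
        assert ((pred > 0) & (pred <= 1.0)).all()

    def test_feature_mismatch_rejected(self):
        x, y = _toy_training_data(30)
        model = train_model("cl_invivo", x, y, "svr", "descriptors",
                            grid={"kernel": ["linear"], "C": [1.0], "gamma": ["scale"], "epsilon": [0.1]},
                            folds=3)
        with pytest.raises(ValueError, match="feature mismatch"):
            predict(model, x.rename(columns={"d1": "other"}))

    def test_roundtrip_persistence(self, tmp_path):
        x, y = _toy_training_data(30)
        model = train_model("clint", x, y, "gradient_boosting", "descriptors",
                            grid={"n_estimators": [50], "learning_rate": [0.1], "subsample": [1.0], "colsample_bytree": [1.0]},
                            folds=3, seed=3)
        model.save(tmp_path)
        loaded = QsarModel.load(tmp_path, "clint")
        assert loaded.algorithm == "gradient_boosting"
        assert np.allclose(predict(loaded, x), predict(model, x))
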