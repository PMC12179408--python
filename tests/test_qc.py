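"""Qualification classifier: separability, standardization, persistence,
metric identities."""

import json

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import train_test_split

from cardiomorph.descriptors import FEATURE_COLUMNS
from cardiomorph.qc import QCClassifier, classify, evaluate, train_qc


def separable_table(n=200, seed=0) -> pd.DataFrame:
    """Rod-like vs rounded-like feature rows with a wide margin."""
    rng = np.random.default_rng(seed)
    half = n // 2
    rows = []
    for label in (1, 0):
        for _ in range(half):
            if label:  # intact rod
                ar = rng.normal(5.0, 0.5)
                sol = rng.normal(0.98, 0.005)
                area = rng.normal(3200, 400)
                circ = rng.normal(0.45, 0.05)
            else:      # rounded cell
                ar = rng.normal(1.1, 0.1)
                sol = rng.normal(0.99, 0.005)
                area = rng.normal(2500, 400)
                circ = rng.normal(0.95, 0.03)
            per = np.sqrt(4 * np.pi * area / max(circ, 0.05))
            rows.append({
                "area_um2": area, "perimeter_um": per, "circularity": circ,
                "aspect_ratio": ar, "roundness": 1.0 / max(ar, 1.0),
                "solidity": sol, "ar_x_solidity": ar * sol,
                "scaled_perimeter_area": per / np.sqrt(area),
                "label": label})
    return pd.DataFrame(rows)


class TestTraining:
    def test_separable_classes_give_perfect_heldout_accuracy(self):
        model, metrics = train_qc(separable_table(), seed=1)
        assert metrics["accuracy"] == 1.0
        assert metrics["f1"] == 1.0

    def test_scaler_statistics_come_from_training_split_only(self):
        df = separable_table()
        model, _ = train_qc(df, test_fraction=0.2, seed=3)
        train_df, _ = train_test_split(
            df, test_size=0.2, random_state=3,
            stratify=df["label"].to_numpy())
        X = train_df[FEATURE_COLUMNS].to_numpy(float)
        z = (X - model.scaler_mean_) / model.scaler_sd_
        assert np.abs(z.mean(axis=0)).max() < 1e-9
        assert np.abs(z.std(axis=0) - 1.0).max() < 1e-9

    def test_training_is_reproducible(self):
        m1, _ = train_qc(separable_table(), seed=5)
        m2, _ = train_qc(separable_table(), seed=5)
        assert np.array_equal(m1.coef_, m2.coef_)
        assert np.array_equal(m1.scaler_mean_, m2.scaler_mean_)

    def test_single_class_rejected(self):
        df = separable_table()
        df["label"] = 1
        with pytest.raises(ValueError, match="single class"):
            train_qc(df, seed=0)

    def test_zero_variance_feature_named_in_error(self):
        df = separable_table()
        df["solidity"] = 0.98
        df["ar_x_solidity"] = df["aspect_ratio"] * 0.98
        with pytest.raises(ValueError, match="solidity"):
            train_qc(df, seed=0)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="50"):
            train_qc(separable_table(n=20), seed=0)


class TestClassify:
    def test_empty_table_passes_through(self, trained_qc):
        model, _ = trained_qc
        out = classify(model, pd.DataFrame(columns=FEATURE_COLUMNS))
        assert len(out) == 0
        assert "qualified" in out.columns

    def test_qualified_class_centroid_is_qualified(self):
        df = separable_table()
        model, _ = train_qc(df, seed=1)
        centroid = df[df["label"] == 1][FEATURE_COLUMNS].mean().to_frame().T
        assert classify(model, centroid)["qualified"].iloc[0] == 1

    def test_missing_feature_column_named_in_error(self, trained_qc):
        model, _ = trained_qc
        df = separable_table().drop(columns=["roundness"])
        with pytest.raises(ValueError, match="roundness"):
            classify(model, df)

    def test_persistence_round_trip_preserves_predictions(self, trained_qc, tmp_path):
        model, _ = trained_qc
        df = separable_table(seed=9)
        path = tmp_path / "model.json"
        model.save(path)
        reloaded = QCClassifier.load(path)
        assert np.array_equal(model.predict(df), reloaded.predict(df))
        # JSON payload is complete and plain
        payload = json.loads(path.read_text())
        assert payload["feature_order"] == FEATURE_COLUMNS
        assert len(payload["weights"]) == 8

    def test_affine_feature_rescaling_leaves_predictions_unchanged(self):
        df = separable_table()
        scaled = df.copy()
        scaled["area_um2"] = scaled["area_um2"] * 7.0 + 100.0
        m1, _ = train_qc(df, seed=2)
        m2, _ = train_qc(scaled, seed=2)
        test = separable_table(seed=11)
        test_scaled = test.copy()
        test_scaled["area_um2"] = test_scaled["area_um2"] * 7.0 + 100.0
        assert np.array_equal(m1.predict(test), m2.predict(test_scaled))


class TestEvaluate:
    def _always_positive_model(self):
        m = QCClassifier()
        m.feature_order_ = list(FEATURE_COLUMNS)
        m.scaler_mean_ = np.zeros(8)
        m.scaler_sd_ = np.ones(8)
        m.coef_ = np.zeros((1, 8))
        m.intercept_ = np.array([50.0])
        m.classes_ = np.array([0, 1])
        m.feature_range_ = (np.full(8, -1e6), np.full(8, 1e6))
        m.training_meta_ = {}
        return m

    def test_all_positive_on_balanced_set_gives_closed_form_metrics(self):
        df = separable_table(n=100)
        metrics = evaluate(self._always_positive_model(), df)
        assert metrics["precision"] == pytest.approx(0.5)
        assert metrics["recall"] == pytest.approx(1.0)
        assert metrics["f1"] == pytest.approx(2.0 / 3.0)

    def test_perfect_predictions_give_unit_metrics(self):
        df = separable_table()
        model, _ = train_qc(df, seed=1)
        metrics = evaluate(model, df)
        assert metrics["accuracy"] == 1.0
        assert metrics["f1"] == 1.0

    def test_metrics_match_brute_force_confusion_counts(self, trained_qc,
                                                        benchmark_table):
        model, _ = trained_qc
        pred = model.predict(benchmark_table)
        y = benchmark_table["label"].to_numpy(int)
        tp = sum(1 for p, t in zip(pred, y) if p == 1 and t == 1)
        fp = sum(1 for p, t in zip(pred, y) if p == 1 and t == 0)
        tn = sum(1 for p, t in zip(pred, y) if p == 0 and t == 0)
        fn = sum(1 for p, t in zip(pred, y) if p == 0 and t == 1)
        metrics = evaluate(model, benchmark_table)
        assert (metrics["tp"], metrics["fp"], metrics["tn"], metrics["fn"]) \
            == (tp, fp, tn, fn)
        assert metrics["accuracy"] == pytest.approx((tp + tn) / len(y))


class TestPrevalence:
    def test_qualified_fraction_tracks_rod_composition(self, trained_qc):
        """On a 97% intact-rod population the classified-qualified fraction
        stays within 0.97 +/- 0.03."""
        from cardiomorph.benchmark import labeled_benchmark_table

        model, _ = trained_qc
        df = labeled_benchmark_table(
            n_cells=300, proportions={"intact_rod": 0.97, "rounded": 0.03},
            seed=13)
        frac = classify(model, df)["qualified"].mean()
        assert abs(frac - 0.97) <= 0.03
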