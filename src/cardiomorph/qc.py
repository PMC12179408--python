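"""Supervised qualification of segmented cells.

A standard-scaled, L2-regularised logistic regression decides, per measured
particle, whether it is a single intact rod-shaped cell (``qualified = 1``)
or a touching/overlaying or abnormally shaped object (``qualified = 0``).
Only qualified rows enter downstream group statistics.

The model operates on a fixed eight-feature order (area, perimeter,
circularity, aspect ratio, roundness, solidity, AR x solidity, scaled
perimeter/area); features are z-scored with statistics learned on the
training split only.  The fitted model serialises to plain JSON (feature
order, scaler statistics, weights, metadata) so it can be inspected or
re-loaded from any language.
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .descriptors import FEATURE_COLUMNS

log = logging.getLogger(__name__)


def _feature_matrix(data: pd.DataFrame, feature_order: list[str]) -> np.ndarray:
    missing = [c for c in feature_order if c not in data.columns]
    if missing:
        raise ValueError(f"missing feature column(s): {', '.join(missing)}")
    X = data[feature_order].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature table contains missing values")
    return X


class QCClassifier(ClassifierMixin, BaseEstimator):
    """Standard-scaled logistic regression over the fixed 8-feature order.

    Parameters
    ----------
    C : float
        Inverse L2 regularisation strength (unit strength by default).
    threshold : float
        Posterior-probability cut for ``qualified = 1``.
    tol : float
        Convergence tolerance of the deterministic lbfgs solver.

    Attributes (after :meth:`fit`)
    ------------------------------
    feature_order_ : list of str
    scaler_mean_, scaler_sd_ : ndarray, per-feature z-scoring statistics
    coef_, intercept_ : logistic weights in scaled-feature space
    feature_range_ : (min, max) per feature on the training data, used to
        flag extrapolating inputs at prediction time
    training_meta_ : dict with split sizes, seed and held-out metrics when
        fitted through :func:`train_qc`
    """

    def __init__(self, C: float = 1.0, threshold: float = 0.5,
                 tol: float = 1e-8, max_iter: int = 5000):
        self.C = C
        self.threshold = threshold
        self.tol = tol
        self.max_iter = max_iter

    # -- fitting ------------------------------------------------------------
    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_order_ = [c for c in FEATURE_COLUMNS if c in X.columns]
            if len(self.feature_order_) < len(FEATURE_COLUMNS):
                missing = set(FEATURE_COLUMNS) - set(self.feature_order_)
                raise ValueError(f"missing feature column(s): {', '.join(sorted(missing))}")
            Xm = _feature_matrix(X, self.feature_order_)
        else:
            Xm = np.asarray(X, dtype=float)
            self.feature_order_ = list(FEATURE_COLUMNS[:Xm.shape[1]])
        y = np.asarray(y).astype(int)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be 0/1")
        if len(np.unique(y)) < 2:
            raise ValueError("training data contains a single class")
        sds = Xm.std(axis=0)
        scale = np.abs(Xm.mean(axis=0)) + 1.0
        for name, sd, sc in zip(self.feature_order_, sds, scale):
            if sd <= 1e-12 * sc:  # constant up to fp rounding
                raise ValueError(f"zero-variance feature: {name}")

        self._scaler = StandardScaler().fit(Xm)
        Z = self._scaler.transform(Xm)
        self._model = LogisticRegression(  # default penalty is L2
            C=self.C, solver="lbfgs",
            tol=self.tol, max_iter=self.max_iter).fit(Z, y)
        self.scaler_mean_ = self._scaler.mean_.copy()
        self.scaler_sd_ = np.sqrt(self._scaler.var_)
        self.coef_ = self._model.coef_.copy()
        self.intercept_ = self._model.intercept_.copy()
        self.classes_ = self._model.classes_
        self.feature_range_ = (Xm.min(axis=0), Xm.max(axis=0))
        self.training_meta_ = {}
        return self

    # -- prediction ---------------------------------------------------------
    def _transform(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        if isinstance(X, pd.DataFrame):
            Xm = _feature_matrix(X, self.feature_order_)
        else:
            Xm = np.asarray(X, dtype=float)
        self._flag_extrapolation(Xm)
        return (Xm - self.scaler_mean_) / self.scaler_sd_

    def _flag_extrapolation(self, Xm: np.ndarray) -> None:
        lo, hi = self.feature_range_
        center = (lo + hi) / 2.0
        half = np.maximum((hi - lo) / 2.0, 1e-12)
        out = (np.abs(Xm - center) > 10.0 * half)
        if out.any():
            rows, cols = np.nonzero(out)
            names = sorted({self.feature_order_[c] for c in cols})
            log.warning(
                "%d value(s) lie outside 10x the training range "
                "(features: %s); rows classified but extrapolating",
                int(out.sum()), ", ".join(names))

    def decision_function(self, X) -> np.ndarray:
        Z = self._transform(X)
        return Z @ self.coef_.ravel() + self.intercept_[0]

    def predict_proba(self, X) -> np.ndarray:
        p1 = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(int)

    # -- persistence --------------------------------------------------------
    def to_json(self) -> str:
        check_is_fitted(self, "coef_")
        payload = {
            "model": "cardiomorph-qc-logistic",
            "feature_order": self.feature_order_,
            "scaler_mean": self.scaler_mean_.tolist(),
            "scaler_sd": self.scaler_sd_.tolist(),
            "weights": self.coef_.ravel().tolist(),
            "intercept": float(self.intercept_[0]),
            "threshold": self.threshold,
            "C": self.C,
            "feature_min": self.feature_range_[0].tolist(),
            "feature_max": self.feature_range_[1].tolist(),
            "training_meta": self.training_meta_,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "QCClassifier":
        d = json.loads(text)
        self = cls(C=d.get("C", 1.0), threshold=d.get("threshold", 0.5))
        self.feature_order_ = list(d["feature_order"])
        self.scaler_mean_ = np.asarray(d["scaler_mean"], dtype=float)
        self.scaler_sd_ = np.asarray(d["scaler_sd"], dtype=float)
        self.coef_ = np.asarray(d["weights"], dtype=float)[None, :]
        self.intercept_ = np.asarray([d["intercept"]], dtype=float)
        self.classes_ = np.array([0, 1])
        self.feature_range_ = (np.asarray(d["feature_min"], dtype=float),
                               np.asarray(d["feature_max"], dtype=float))
        self.training_meta_ = d.get("training_meta", {})
        return self

    @classmethod
    def load(cls, path) -> "QCClassifier":
        with open(path) as fh:
            return cls.from_json(fh.read())


# ---------------------------------------------------------------------------
# operation wrappers

def train_qc(data: pd.DataFrame, test_fraction: float = 0.2,
             seed: int = 0, C: float = 1.0,
             threshold: float = 0.5) -> tuple[QCClassifier, dict]:
    """Train the qualification model on a labelled measurement table.

    ``data`` must carry the eight feature columns plus a 0/1 ``label``
    column.  The split is stratified by label and seeded; held-out metrics
    (accuracy, precision, recall, F1, confusion counts) are returned and
    recorded in ``model.training_meta_``.
    """
    if "label" not in data.columns:
        raise ValueError("labelled table requires a 'label' column")
    if len(data) < 50:
        raise ValueError(f"need >= 50 labelled rows, got {len(data)}")
    y = data["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")

    train_df, test_df = train_test_split(
        data, test_size=test_fraction, random_state=seed, stratify=y)
    model = QCClassifier(C=C, threshold=threshold)
    model.fit(train_df[FEATURE_COLUMNS], train_df["label"].to_numpy())
    metrics = evaluate(model, test_df)
    model.training_meta_ = {
        "n_train": int(len(train_df)),
        "n_test": int(len(test_df)),
        "test_fraction": test_fraction,
        "seed": int(seed),
        "metrics": metrics,
    }
    return model, metrics


def classify(model: QCClassifier, data: pd.DataFrame) -> pd.DataFrame:
    """Append the 0/1 ``qualified`` column; row order preserved.

    Batches of tables get identical preprocessing because the scaler
    statistics are frozen inside the model.
    """
    out = data.copy()
    if len(out) == 0:
        out["qualified"] = pd.Series(dtype=int)
        return out
    out["qualified"] = model.predict(out)
    return out


def evaluate(model: QCClassifier, data: pd.DataFrame) -> dict:
    """Accuracy / precision / recall / F1 and confusion counts on a labelled
    table (both classes must be present)."""
    if "label" not in data.columns:
        raise ValueError("labelled table requires a 'label' column")
    y = data["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("evaluation data contains a single class")
    pred = model.predict(data)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    n = len(y)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return {
        "accuracy": (tp + tn) / n,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "tp": tp, "fp": fp, "tn": tn, "fn": fn, "n": n,
    }
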