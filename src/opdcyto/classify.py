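"""H/L neutrophil discriminators.

Two classifiers are provided, mirroring how the sorted-cell training data
are used downstream:

* a 1D threshold on a single feature (dry mass or average OPD), placed
  where the empirical cumulative distributions of the two classes cross —
  operationally, the value minimizing the balanced misclassification rate
  ``(P(H > t) + P(L < t)) / 2``, since for stochastically ordered samples
  the two CDFs proper only meet at the extremes while the H survival curve
  and the L CDF cross in the interior;
* a logistic model on (dry mass, average OPD) with stratified 5-fold
  cross-validation, features standardized inside each training split.

Orientation is fixed throughout: H cells sit *below* the threshold (they
have the lower dry mass and average OPD); ties go to L.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from opdcyto.errors import DegenerateSeparationError, OrderViolationError
from opdcyto.morphometry import CellFeatures

FEATURE_COLUMNS = {"dry_mass": "dry_mass_pg", "avg_opd": "avg_opd_nm"}


def features_to_frame(features) -> pd.DataFrame:
    """Normalize a list of CellFeatures / dicts, or a DataFrame, to a frame."""
    if isinstance(features, pd.DataFrame):
        return features
    rows = [f.to_dict() if isinstance(f, CellFeatures) else dict(f) for f in features]
    return pd.DataFrame(rows)


@dataclass
class ThresholdModel:
    """1D H/L threshold classifier: predict H iff feature < threshold."""

    feature_name: str
    threshold: float
    n_h: int
    n_l: int
    training_accuracy: float

    @property
    def feature_column(self) -> str:
        return FEATURE_COLUMNS.get(self.feature_name, self.feature_name)

    def predict_values(self, values: NDArray) -> NDArray:
        values = np.asarray(values, dtype=float)
        return np.where(values < self.threshold, "H", "L")

    def predict(self, features) -> NDArray:
        df = features_to_frame(features)
        col = self.feature_column
        if col not in df.columns:
            raise KeyError(f"feature column {col!r} missing")
        return self.predict_values(df[col].to_numpy())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"kind": "threshold", **asdict(self)},
                                         indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdModel":
        d = json.loads(Path(path).read_text())
        d.pop("kind", None)
        return cls(**d)


@dataclass
class LogisticModel:
    """Logistic H/L classifier on (dry mass, average OPD).

    Coefficients act on standardized features; the standardization
    (``mu``, ``sigma`` from the deployment fit) is stored with the model,
    so prediction is deterministic given the model alone.
    """

    feature_columns: list[str]
    coef: list[float]
    intercept: float
    mu: list[float]
    sigma: list[float]
    cv_folds: int
    cv_accuracy: float
    rng_seed: int

    def decision_function(self, x: NDArray) -> NDArray:
        x = np.asarray(x, dtype=float)
        z = (x - np.asarray(self.mu)) / np.asarray(self.sigma)
        return z @ np.asarray(self.coef) + self.intercept

    def predict(self, features) -> NDArray:
        df = features_to_frame(features)
        x = df[self.feature_columns].to_numpy(dtype=float)
        # positive decision value = H; exact ties go to L
        return np.where(self.decision_function(x) > 0, "H", "L")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"kind": "logistic", **asdict(self)},
                                         indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "LogisticModel":
        d = json.loads(Path(path).read_text())
        d.pop("kind", None)
        return cls(**d)


def load_model(path: str | Path):
    d = json.loads(Path(path).read_text())
    kind = d.pop("kind", "threshold")
    return ThresholdModel(**d) if kind == "threshold" else LogisticModel(**d)


def _balanced_error_curve(
    values_h: NDArray, values_l: NDArray
) -> tuple[NDArray, NDArray, NDArray]:
    """Balanced error on every inter-order-statistic gap.

    Returns (distinct sorted combined values v, gap midpoints, balanced
    error of any threshold inside each gap (v[i], v[i+1])).
    """
    hs = np.sort(values_h)
    ls = np.sort(values_l)
    v = np.unique(np.concatenate([hs, ls]))
    mids = 0.5 * (v[:-1] + v[1:])
    frac_h_ge = 1.0 - np.searchsorted(hs, mids) / hs.size
    frac_l_lt = np.searchsorted(ls, mids) / ls.size
    return v, mids, 0.5 * (frac_h_ge + frac_l_lt)


def cdf_intersection_threshold(
    values_h: Sequence[float],
    values_l: Sequence[float],
    feature_name: str = "dry_mass",
    min_per_class: int = 10,
) -> ThresholdModel:
    """Fit the CDF-intersection threshold separating H (low) from L (high).

    The threshold is the crossing of the H survival curve and the L CDF,
    i.e. the minimizer of the balanced misclassification rate
    ``(P(H >= t) + P(L < t)) / 2`` over thresholds between adjacent order
    statistics of the pooled sample. When the minimum is attained on an
    interval of thresholds, its midpoint is returned.
    """
    vh = np.asarray(values_h, dtype=float)
    vl = np.asarray(values_l, dtype=float)
    if vh.size < min_per_class or vl.size < min_per_class:
        raise ValueError(f"need >= {min_per_class} values per class")
    if vh.size == vl.size and np.array_equal(np.sort(vh), np.sort(vl)):
        raise DegenerateSeparationError("identical class samples")
    if vh.mean() >= vl.mean():
        raise OrderViolationError(
            f"mean H ({vh.mean():.3g}) must be below mean L ({vl.mean():.3g})"
        )
    v, mids, err = _balanced_error_curve(vh, vl)
    best = err.min()
    at_min = err <= best + 1e-12
    i = int(np.argmax(at_min))  # first minimizing gap
    j = i
    while j + 1 < at_min.size and at_min[j + 1]:
        j += 1
    threshold = 0.5 * (v[i] + v[j + 1])  # midpoint of the minimizing interval
    pred_h = vh < threshold
    pred_l = vl >= threshold
    train_acc = (pred_h.sum() + pred_l.sum()) / (vh.size + vl.size)
    return ThresholdModel(
        feature_name=feature_name,
        threshold=float(threshold),
        n_h=int(vh.size),
        n_l=int(vl.size),
        training_accuracy=float(train_acc),
    )


def apply_threshold(features, model: ThresholdModel) -> NDArray:
    """Classify cells with a fitted threshold: H iff feature < threshold."""
    return model.predict(features)


def accuracy(predictions: Sequence, labels: Sequence) -> float:
    """Fraction of correct predictions."""
    p = np.asarray(predictions)
    y = np.asarray(labels)
    if p.size != y.size:
        raise ValueError("predictions and labels differ in length")
    if p.size == 0:
        raise ValueError("empty input")
    return float((p == y).mean())


def fit_logistic_cv(
    features,
    k: int = 5,
    seed: int = 0,
    feature_columns: tuple[str, str] = ("dry_mass_pg", "avg_opd_nm"),
) -> LogisticModel:
    """Stratified k-fold cross-validated logistic H/L model.

    Within each fold the features are standardized on the training split
    only; ``cv_accuracy`` is the mean of the fold accuracies. The deployed
    model is refit (scaler and coefficients) on all data. Unregularized
    maximum likelihood.
    """
    df = features_to_frame(features)
    if "label" not in df.columns or df["label"].isna().any():
        raise ValueError("labelled features required")
    y = (df["label"].to_numpy() == "H").astype(int)
    x = df[list(feature_columns)].to_numpy(dtype=float)
    n_h, n_l = int(y.sum()), int((1 - y).sum())
    if n_h == 0 or n_l == 0:
        raise ValueError("both classes must be present")
    if k > min(n_h, n_l):
        raise ValueError(f"k={k} exceeds the smaller class size {min(n_h, n_l)}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_acc = []
    for train, test in skf.split(x, y):
        scaler = StandardScaler().fit(x[train])
        clf = LogisticRegression(C=np.inf, max_iter=1000)
        clf.fit(scaler.transform(x[train]), y[train])
        fold_acc.append(clf.score(scaler.transform(x[test]), y[test]))
    scaler = StandardScaler().fit(x)
    clf = LogisticRegression(C=np.inf, max_iter=1000)
    clf.fit(scaler.transform(x), y)
    return LogisticModel(
        feature_columns=list(feature_columns),
        coef=[float(c) for c in clf.coef_[0]],
        intercept=float(clf.intercept_[0]),
        mu=[float(m) for m in scaler.mean_],
        sigma=[float(s) for s in scaler.scale_],
        cv_folds=k,
        cv_accuracy=float(np.mean(fold_acc)),
        rng_seed=seed,
    )
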