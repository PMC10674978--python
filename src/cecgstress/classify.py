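"""Binary stress classification and its evaluation.

Positive class = higher stress throughout. Metrics with a zero
denominator come back as an explicit undefined marker (None), never as an
exception, and undefined fold values are aggregated separately from the
defined ones. Cross-validation folds are grouped by subject so no
subject's windows straddle the train/test boundary, and normalization
statistics are fitted on training rows only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVC

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "SplitScheme",
    "UNDEFINED",
    "zscore_normalize",
    "compute_metrics",
    "train_classifier",
    "predict",
    "cross_validate",
]

FEATURE_COLUMNS = ["r_value_mv", "hr_bpm", "pnn50", "binen"]
POSITIVE = "high_stress"
NEGATIVE = "low_stress"

#: marker for a metric whose denominator is zero
UNDEFINED = None


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion counts must not all be zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """Six metrics; balanced accuracy in percent, the rest as fractions."""

    balanced_accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    mcc: float | None
    counts: ConfusionCounts | None = None

    def as_dict(self) -> dict:
        d = {
            "balanced_accuracy": self.balanced_accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "mcc": self.mcc,
        }
        if self.counts is not None:
            d["counts"] = {
                "tp": self.counts.tp,
                "fp": self.counts.fp,
                "tn": self.counts.tn,
                "fn": self.counts.fn,
            }
        return d


@dataclass(frozen=True)
class SplitScheme:
    """Subject-grouped cross-validation layout."""

    n_folds: int = 5
    stratified: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else UNDEFINED


def zscore_normalize(
    features: pd.DataFrame,
    columns: list[str] | None = None,
    stats: tuple[pd.Series, pd.Series] | None = None,
) -> tuple[pd.DataFrame, tuple[pd.Series, pd.Series]]:
    """Z-score columns: subtract the mean, divide by the sample SD (ddof=1).

    When ``stats`` is given (fitted on training rows) it is applied as-is,
    so test rows never influence the normalization. A zero-variance column
    raises with the column named.
    """
    cols = FEATURE_COLUMNS if columns is None else columns
    if stats is None:
        if len(features) < 2:
            raise ValueError("need at least 2 rows to fit normalization")
        mean = features[cols].mean()
        sd = features[cols].std(ddof=1)
        zero = [c for c in cols if sd[c] == 0.0 or not np.isfinite(sd[c])]
        if zero:
            raise ValueError(f"zero-variance feature(s): {', '.join(zero)}")
        stats = (mean, sd)
    mean, sd = stats
    out = features.copy()
    out[cols] = (features[cols] - mean) / sd
    return out, stats


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """The six performance measures from raw confusion counts.

    Balanced accuracy is in percent; it is undefined whenever sensitivity
    or specificity is. MCC is undefined when any marginal is empty.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    ppv = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    ba = (
        50.0 * (sens + spec)
        if sens is not UNDEFINED and spec is not UNDEFINED
        else UNDEFINED
    )
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tn * tp - fn * fp) / math.sqrt(denom) if denom > 0 else UNDEFINED
    return MetricsReport(ba, sens, spec, ppv, npv, mcc, counts)


def _knn_k(n_train: int, literal: bool = False) -> int:
    """Rule-of-thumb neighbourhood size: round(sqrt(n)), forced odd.

    ``literal=True`` uses k = n_train (a majority-class vote), kept only
    as an explicit switch.
    """
    if literal:
        return n_train
    k = int(round(math.sqrt(n_train)))
    if k % 2 == 0:
        k += 1
    return max(min(k, n_train), 1)


class _TanhNet:
    """Two-hidden-layer tanh network trained on MSE, thresholded at 0.

    Labels are encoded as ±1 and fitted by a squared-loss backpropagation
    regressor (two hidden layers of 20 tanh units); the sign of the output
    is the class. The 0.5 learning rate occasionally diverges from a bad
    initialization, so the fit restarts from a few derived seeds and keeps
    the run with the lowest training loss — still deterministic per seed.
    """

    N_RESTARTS = 8

    def __init__(self, hidden: int = 20, lr: float = 0.5, max_iter: int = 500, seed: int = 0):
        self.hidden = hidden
        self.lr = lr
        self.max_iter = max_iter
        self.seed = seed
        self.net: MLPRegressor | None = None

    def _make(self, seed: int) -> MLPRegressor:
        return MLPRegressor(
            hidden_layer_sizes=(self.hidden, self.hidden),
            activation="tanh",
            solver="sgd",
            learning_rate_init=self.lr,
            learning_rate="adaptive",
            momentum=0.0,
            max_iter=self.max_iter,
            tol=1e-6,
            n_iter_no_change=25,
            random_state=seed,
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_TanhNet":
        target = np.where(y == 1, 1.0, -1.0)
        best_loss = np.inf
        for k in range(self.N_RESTARTS):
            net = self._make(self.seed + 1000 * k)
            try:
                with warnings.catch_warnings():
                    warnings.filterwarnings("ignore", category=ConvergenceWarning)
                    net.fit(X, target)
            except ValueError:  # non-finite weights from a diverged run
                continue
            if np.isfinite(net.loss_) and net.loss_ < best_loss:
                best_loss = net.loss_
                self.net = net
            if best_loss < 0.05:
                break
        if self.net is None:
            raise RuntimeError("network training diverged on every restart")
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.net.predict(X) > 0.0).astype(int)


def train_classifier(
    kind: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    seed: int = 0,
    knn_literal_k: bool = False,
    svm_kernel: str = "rbf",
):
    """Fit a kNN, SVM or two-hidden-layer ANN on normalized features.

    ``y_train`` is binary with 1 = higher stress. Training data containing
    a single class raises.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    if np.unique(y_train).size < 2:
        raise ValueError("training data must contain both classes")
    if kind == "knn":
        model = KNeighborsClassifier(
            n_neighbors=_knn_k(len(y_train), knn_literal_k), metric="euclidean"
        )
    elif kind == "svm":
        model = SVC(kernel=svm_kernel, C=1.0, gamma="scale", random_state=seed)
    elif kind == "ann":
        model = _TanhNet(seed=seed)
    else:
        raise ValueError(f"unknown classifier kind: {kind!r}")
    return model.fit(X_train, y_train)


def predict(model, X: np.ndarray) -> np.ndarray:
    return np.asarray(model.predict(np.asarray(X, dtype=float)), dtype=int)


def _counts_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return ConfusionCounts(tp, fp, tn, fn)


def _grouped_folds(
    subjects: np.ndarray, n_folds: int, seed: int
) -> list[np.ndarray]:
    """Partition subjects into folds; returns per-fold boolean row masks."""
    uniq = np.unique(subjects)
    if uniq.size < n_folds:
        raise ValueError(
            f"{uniq.size} subjects cannot be split into {n_folds} grouped folds"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(uniq)
    groups = np.array_split(order, n_folds)
    return [np.isin(subjects, g) for g in groups]


def cross_validate(
    features: pd.DataFrame,
    kind: str,
    scheme: SplitScheme = SplitScheme(),
    seed: int | None = None,
    feature_columns: list[str] | None = None,
    **train_kwargs,
) -> dict:
    """Subject-grouped k-fold evaluation of one classifier kind.

    ``features`` needs the four feature columns plus ``label`` and
    ``subject``. Per fold: fit normalization on the training rows, train,
    predict the held-out subjects, compute metrics. Returns per-fold
    reports plus a mean ± SD aggregate; undefined metrics are counted, not
    averaged in.
    """
    cols = FEATURE_COLUMNS if feature_columns is None else feature_columns
    seed = scheme.seed if seed is None else seed
    subjects = features["subject"].to_numpy()
    y = (features["label"] == POSITIVE).to_numpy().astype(int)
    for cls, name in ((1, POSITIVE), (0, NEGATIVE)):
        if np.unique(subjects[y == cls]).size < 2:
            raise ValueError(
                f"need >= 2 subjects with class {name} for a grouped split"
            )

    fold_masks = _grouped_folds(subjects, scheme.n_folds, seed)
    reports: list[MetricsReport] = []
    for i, test_mask in enumerate(fold_masks):
        train_df = features.loc[~test_mask]
        test_df = features.loc[test_mask]
        if test_df.empty:
            continue
        train_norm, stats = zscore_normalize(train_df, cols)
        test_norm, _ = zscore_normalize(test_df, cols, stats=stats)
        model = train_classifier(
            kind,
            train_norm[cols].to_numpy(),
            y[~test_mask],
            seed=seed + i,
            **train_kwargs,
        )
        y_pred = predict(model, test_norm[cols].to_numpy())
        reports.append(compute_metrics(_counts_from_predictions(y[test_mask], y_pred)))

    aggregate: dict[str, dict] = {}
    for metric in ("balanced_accuracy", "sensitivity", "specificity", "ppv", "npv", "mcc"):
        vals = [getattr(r, metric) for r in reports]
        defined = [v for v in vals if v is not UNDEFINED]
        aggregate[metric] = {
            "mean": float(np.mean(defined)) if defined else UNDEFINED,
            "sd": float(np.std(defined)) if defined else UNDEFINED,
            "n_undefined": len(vals) - len(defined),
        }
    return {"folds": reports, "aggregate": aggregate, "kind": kind}
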