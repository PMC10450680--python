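"""Logistic-regression classification of blockade events between two species.

Events are described by three features — I_ex%, log10 dwell time (ms) and the
intra-event fluctuation sigma_b — standardized by the training mean and SD,
and separated by an unregularized maximum-likelihood logistic regression.
Performance is reported as per-class true-positive rate (recall).  A
pre-filter restricts analysis to events with 50% < I_ex% < 90% (strict), which
removes open-pore noise excursions and near-full contaminant blockades.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .detect import EventRecord

__all__ = [
    "FEATURE_NAMES",
    "ClassifierModel",
    "ConfusionSummary",
    "filter_events",
    "event_features",
    "train_classifier",
    "predict",
    "evaluate",
    "stratified_split",
]

FEATURE_NAMES = ("iex_pct", "log10_dwell_ms", "sigma_b")


def filter_events(
    events: list[EventRecord], low: float = 50.0, high: float = 90.0
) -> list[EventRecord]:
    """Keep events with low < I_ex% < high (strict inequalities)."""
    if low >= high:
        raise ValueError("low must be below high")
    return [e for e in events if low < e.iex_pct < high]


def event_features(events: list[EventRecord]) -> np.ndarray:
    """(n, 3) feature matrix: I_ex%, log10 dwell (ms), sigma_b (pA)."""
    return np.array(
        [[e.iex_pct, np.log10(e.dwell_ms), e.sigma_b] for e in events], dtype=float
    )


@dataclass(frozen=True)
class ClassifierModel:
    """Standardized-feature logistic model for two species.

    ``weights`` is (intercept, w_iex, w_logdwell, w_sigmab) on standardized
    features; the linear score is the log-odds of ``classes[1]``.
    """

    classes: tuple[str, str]
    weights: np.ndarray
    feature_means: np.ndarray
    feature_scales: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES
    separation_flag: bool = False

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if not np.all(np.asarray(self.feature_scales) > 0):
            raise ValueError("feature scales must be > 0")


@dataclass(frozen=True)
class ConfusionSummary:
    """2x2 confusion counts (rows = truth, cols = predicted) and per-class
    true-positive rates in percent."""

    classes: tuple[str, str]
    counts: np.ndarray
    tpr_pct: dict = field(default_factory=dict)
    n: int = 0


def train_classifier(labeled_events) -> ClassifierModel:
    """Fit the logistic model on (EventRecord, label) pairs.

    Unregularized maximum likelihood (convex, hence deterministic for a fixed
    data set).  If the classes are perfectly separable the optimizer stops at
    its iteration cap; the model is returned with ``separation_flag`` set and
    a warning is issued.
    """
    events = [e for e, _ in labeled_events]
    labels = np.array([lab for _, lab in labeled_events])
    classes = tuple(sorted(set(labels.tolist())))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    for c in classes:
        if int((labels == c).sum()) < 10:
            raise ValueError(f"need at least 10 events of class {c!r}")
    X = event_features(events)
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=0)
    if np.any(scales <= 0):
        bad = FEATURE_NAMES[int(np.argmin(scales))]
        raise ValueError(f"feature {bad!r} is constant; cannot standardize")
    Z = (X - means) / scales
    y = (labels == classes[1]).astype(int)

    clf = LogisticRegression(penalty=None, solver="lbfgs", max_iter=500, tol=1e-10)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        clf.fit(Z, y)
        hit_cap = any(issubclass(w.category, ConvergenceWarning) for w in caught)
    # perfect training separation <=> the unpenalized MLE is unbounded; the
    # returned weights are then only the point where the optimizer stopped
    sep = hit_cap or bool(np.all(clf.predict(Z) == y))
    if sep:
        warnings.warn(
            "classes appear (near-)perfectly separable; weights capped at the "
            "iteration limit",
            RuntimeWarning,
            stacklevel=2,
        )
    weights = np.concatenate(([clf.intercept_[0]], clf.coef_[0]))
    return ClassifierModel(
        classes=classes,
        weights=weights,
        feature_means=means,
        feature_scales=scales,
        separation_flag=sep,
    )


def predict(
    model: ClassifierModel, events: list[EventRecord]
) -> tuple[list[str], np.ndarray]:
    """Labels and P(classes[1]) for each event.

    Probability 0.5 (zero linear score) resolves to ``classes[0]``: a label
    requires probability strictly above 0.5.
    """
    X = event_features(events)
    Z = (X - model.feature_means) / model.feature_scales
    score = model.weights[0] + Z @ model.weights[1:]
    p = expit(score)
    labels = [model.classes[1] if pi > 0.5 else model.classes[0] for pi in p]
    return labels, p


def evaluate(predicted, truth) -> ConfusionSummary:
    """Confusion counts and per-class TPR (= recall, percent)."""
    predicted = list(predicted)
    truth = list(truth)
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth must have equal length")
    classes = tuple(sorted(set(truth)))
    if len(classes) != 2:
        raise ValueError(f"need exactly two truth classes, got {classes}")
    unknown = set(predicted) - set(classes)
    if unknown:
        raise ValueError(f"predicted labels {sorted(unknown)} not among truth classes")
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((2, 2), dtype=int)
    for p, t in zip(predicted, truth):
        counts[idx[t], idx[p]] += 1
    tpr = {
        c: 100.0 * counts[i, i] / counts[i].sum() if counts[i].sum() else float("nan")
        for i, c in enumerate(classes)
    }
    return ConfusionSummary(classes=classes, counts=counts, tpr_pct=tpr, n=len(truth))


def stratified_split(labeled_events, test_frac: float = 0.2, seed: int = 0):
    """Deterministic stratified train/test split of (event, label) pairs."""
    if not 0.0 < test_frac < 1.0:
        raise ValueError("test_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = np.array([lab for _, lab in labeled_events])
    train, test = [], []
    for c in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(idx.size)]
        n_test = max(1, int(round(test_frac * idx.size)))
        test.extend(labeled_events[i] for i in idx[:n_test])
        train.extend(labeled_events[i] for i in idx[n_test:])
    return train, test
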