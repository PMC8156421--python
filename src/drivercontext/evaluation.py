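"""Metrics, repeated cross-validation, and significance utilities.

Driver is the positive class throughout.  The headline ranking statistic is
the *composite score*, the sum of sensitivity, specificity, PPV and NPV
(range [0, 4]); MCC is computed from the confusion matrix as

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FN)(TN+FP))

with the convention MCC = 0 whenever a denominator factor vanishes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold

from .classification import (
    DRIVER,
    PASSENGER,
    SoftEnsemble,
    _as_labels,
    impurity_select,
)
from .feature_encoding import EncodingSpec, encode_neighborhoods

logger = logging.getLogger("drivercontext")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_from_labels(true_labels, predicted_labels) -> ConfusionMatrix:
    t = _as_labels(true_labels)
    p = _as_labels(predicted_labels)
    if len(t) != len(p):
        raise ValueError("label vectors differ in length")
    return ConfusionMatrix(
        tp=int(np.sum((t == DRIVER) & (p == DRIVER))),
        fp=int(np.sum((t == PASSENGER) & (p == DRIVER))),
        fn=int(np.sum((t == DRIVER) & (p == PASSENGER))),
        tn=int(np.sum((t == PASSENGER) & (p == PASSENGER))),
    )


@dataclass
class MetricsReport:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    mcc: float
    composite: float
    auroc: float | None = None
    ci: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv, "accuracy": self.accuracy,
            "mcc": self.mcc, "composite": self.composite,
        }
        if self.auroc is not None:
            out["auroc"] = self.auroc
        return out


def _safe_rate(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def composite_score(sensitivity: float, specificity: float,
                    ppv: float, npv: float) -> float:
    """Sum of the four rates; the study's headline ranking statistic."""
    return sensitivity + specificity + ppv + npv


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """All confusion-matrix metrics, with zero denominators mapping to 0."""
    sens = _safe_rate(cm.tp, cm.tp + cm.fn)
    spec = _safe_rate(cm.tn, cm.tn + cm.fp)
    ppv = _safe_rate(cm.tp, cm.tp + cm.fp)
    npv = _safe_rate(cm.tn, cm.tn + cm.fn)
    acc = (cm.tp + cm.tn) / cm.total
    den = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fn) * (cm.tn + cm.fp)
    )
    mcc = 0.0 if den == 0 else (cm.tp * cm.tn - cm.fp * cm.fn) / np.sqrt(den)
    return MetricsReport(
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        accuracy=acc, mcc=float(mcc),
        composite=composite_score(sens, spec, ppv, npv),
    )


def auroc(scores, labels) -> float:
    """Rank-based AUROC: P(random driver outscores random passenger)."""
    labels = _as_labels(labels)
    if len(set(labels)) < 2:
        raise ValueError("AUROC requires both classes")
    return float(roc_auc_score((labels == DRIVER).astype(int), np.asarray(scores, float)))


# ---------------------------------------------------------------------------
# Repeated stratified cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CvPipelineConfig:
    """What happens inside each training fold.

    ``encoding`` set -> X is a list of Neighborhood objects and the k-mer
    vocabulary is fitted on the training fold only; ``encoding=None`` -> X is
    already a numeric matrix.  Feature selection and estimator tuning run
    inside the fold as well.
    """

    encoding: EncodingSpec | None = None
    select_mode: str | None = "percentile"
    select_value: float = 30
    estimators: tuple[str, ...] = ("et",)
    tuning_folds: int = 3
    bandwidth_grid: tuple = ()     # empty -> classifier default


@dataclass
class CvResult:
    metric_values: dict[str, list[float]]   # metric -> n_folds*n_repeats values
    medians: dict[str, float]
    ci: dict[str, tuple[float, float]]      # Student-t 95% CI on the mean

    def n_values(self) -> int:
        return len(next(iter(self.metric_values.values())))


def _t_interval(values: np.ndarray, confidence: float = 0.95) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    sem = stats.sem(values)
    if sem == 0:
        return (float(mean), float(mean))
    lo, hi = stats.t.interval(confidence, len(values) - 1, loc=mean, scale=sem)
    return (float(lo), float(hi))


def repeated_cv(
    X,
    labels,
    pipeline_config: CvPipelineConfig | None = None,
    n_folds: int = 10,
    n_repeats: int = 3,
    seed: int = 0,
    instrumentation=None,
) -> CvResult:
    """Repeated stratified k-fold CV with fold-internal fitting.

    Produces exactly ``n_folds * n_repeats`` values per metric (sensitivity,
    specificity, AUROC, MCC), their medians, and Student-t 95% CIs on the
    mean.  Every data-dependent fitting step — vocabulary, feature
    selection, hyperparameter tuning, estimator training — sees only the
    training fold.  ``instrumentation(stage, row_indices)`` is invoked at
    each fitting step with the row indices used, so leak-freedom is
    externally checkable.
    """
    config = pipeline_config or CvPipelineConfig()
    y = _as_labels(labels)
    hook = instrumentation or (lambda stage, idx: None)
    splitter = RepeatedStratifiedKFold(
        n_splits=n_folds, n_repeats=n_repeats, random_state=seed)
    values: dict[str, list[float]] = {
        "sensitivity": [], "specificity": [], "auroc": [], "mcc": []}
    for fold_i, (train_idx, test_idx) in enumerate(splitter.split(np.zeros(len(y)), y)):
        if len(set(y[test_idx])) < 2 or len(set(y[train_idx])) < 2:
            raise ValueError("a fold contains a single class; cannot stratify")
        if config.encoding is not None:
            train_nb = [X[i] for i in train_idx]
            test_nb = [X[i] for i in test_idx]
            hook("fit_vocabulary", train_idx)
            enc_train, vocab = encode_neighborhoods(train_nb, config.encoding)
            enc_test, _ = encode_neighborhoods(test_nb, config.encoding, vocab=vocab)
            X_train, X_test = enc_train.values, enc_test.values
            names = enc_train.column_names
        else:
            X_mat = np.atleast_2d(np.asarray(X, dtype=float))
            X_train, X_test = X_mat[train_idx], X_mat[test_idx]
            names = [f"f{i}" for i in range(X_mat.shape[1])]
        y_train, y_test = y[train_idx], y[test_idx]
        if config.select_mode is not None:
            hook("feature_selection", train_idx)
            selected = impurity_select(
                X_train, y_train, mode=config.select_mode,
                value=config.select_value, seed=seed + fold_i,
                feature_names=names)
            sel = [names.index(s) for s in selected]
            X_train, X_test = X_train[:, sel], X_test[:, sel]
        hook("fit_estimator", train_idx)
        kwargs = {}
        if config.bandwidth_grid:
            kwargs["bandwidth_grid"] = config.bandwidth_grid
        member = SoftEnsemble(list(config.estimators), seed=seed + fold_i,
                              tuning_folds=config.tuning_folds, **kwargs)
        member.fit(X_train, y_train)
        scores = member.score_driver(X_test)
        pred = np.where(scores > 0.5, DRIVER, PASSENGER)
        report = compute_metrics(confusion_from_labels(y_test, pred))
        values["sensitivity"].append(report.sensitivity)
        values["specificity"].append(report.specificity)
        values["mcc"].append(report.mcc)
        values["auroc"].append(auroc(scores, y_test))
    medians = {m: float(np.median(v)) for m, v in values.items()}
    ci = {m: _t_interval(np.asarray(v)) for m, v in values.items()}
    return CvResult(metric_values=values, medians=medians, ci=ci)


# ---------------------------------------------------------------------------
# Bootstrap comparison and window significance
# ---------------------------------------------------------------------------

_METRIC_FUNCS = {
    "sensitivity": lambda r: r.sensitivity,
    "specificity": lambda r: r.specificity,
    "ppv": lambda r: r.ppv,
    "npv": lambda r: r.npv,
    "accuracy": lambda r: r.accuracy,
    "mcc": lambda r: r.mcc,
    "composite": lambda r: r.composite,
}


def _bootstrap_metric(scores, labels, idx, metric, threshold):
    lab = labels[idx]
    if len(set(lab)) < 2:
        return None          # metric undefined on a single-class resample
    if metric == "auroc":
        return auroc(scores[idx], lab)
    pred = np.where(scores[idx] > threshold, DRIVER, PASSENGER)
    return _METRIC_FUNCS[metric](compute_metrics(confusion_from_labels(lab, pred)))


def bootstrap_ci_compare(
    scores_a,
    scores_b,
    labels,
    metric: str = "composite",
    n_boot: int = 1000,
    seed: int = 0,
    threshold: float = 0.5,
    touch_tolerance: float = 1e-12,
) -> dict:
    """Percentile 95% bootstrap CIs for two predictors on one test set.

    The difference is significant when the intervals are disjoint or touch
    at an endpoint (within ``touch_tolerance``).  Resamples on which the
    metric is undefined (e.g. a single-class draw) are redrawn; the redraw
    count is logged.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = _as_labels(labels)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise ValueError("predictors must share one test set")
    rng = np.random.default_rng(seed)
    stats_a, stats_b = [], []
    n_redrawn = 0
    while len(stats_a) < n_boot:
        idx = rng.integers(0, len(labels), len(labels))
        va = _bootstrap_metric(scores_a, labels, idx, metric, threshold)
        vb = _bootstrap_metric(scores_b, labels, idx, metric, threshold)
        if va is None or vb is None:
            n_redrawn += 1
            continue
        stats_a.append(va)
        stats_b.append(vb)
    if n_redrawn:
        logger.info("redrew %d degenerate bootstrap resample(s)", n_redrawn)
    ci_a = tuple(np.percentile(stats_a, [2.5, 97.5]))
    ci_b = tuple(np.percentile(stats_b, [2.5, 97.5]))
    identical = (
        abs(ci_a[0] - ci_b[0]) <= touch_tolerance
        and abs(ci_a[1] - ci_b[1]) <= touch_tolerance
    )
    disjoint_or_touching = not identical and (
        ci_a[1] <= ci_b[0] + touch_tolerance or ci_b[1] <= ci_a[0] + touch_tolerance
    )
    return {
        "ci_a": (float(ci_a[0]), float(ci_a[1])),
        "ci_b": (float(ci_b[0]), float(ci_b[1])),
        "significant": bool(disjoint_or_touching),
        "n_redrawn": n_redrawn,
    }


def compare_windows(
    metric_values_by_window: dict[int, list[float]],
    test: str = "wilcoxon_signed_rank",
) -> pd.DataFrame:
    """Pairwise p-values over all window pairs (x, y) with x < y.

    ``wilcoxon_signed_rank`` requires equal-length paired vectors; identical
    vectors yield p = 1 by convention (no detectable difference).
    """
    windows = sorted(metric_values_by_window)
    rows = []
    for i, x in enumerate(windows):
        for y in windows[i + 1:]:
            vx = np.asarray(metric_values_by_window[x], dtype=float)
            vy = np.asarray(metric_values_by_window[y], dtype=float)
            if test == "wilcoxon_signed_rank":
                if len(vx) != len(vy):
                    raise ValueError("paired test requires equal-length vectors")
                diffs = vx - vy
                if np.all(diffs == 0):
                    p = 1.0
                else:
                    p = float(stats.wilcoxon(vx, vy).pvalue)
            elif test == "mann_whitney_u":
                p = float(stats.mannwhitneyu(vx, vy, alternative="two-sided").pvalue)
            else:
                raise ValueError(f"unknown test {test!r}")
            rows.append({"window_x": x, "window_y": y, "p_value": p})
    return pd.DataFrame(rows)
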