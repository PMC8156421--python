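"""Classifiers and the end-to-end training pipeline.

The generative route fits one Gaussian KDE per mutation class and applies
Bayes' rule with class-fraction priors:

    P(driver | x) = P(x | driver) P(driver) / sum_c P(x | c) P(c)

computed in log space.  The discriminative route wraps sklearn tree and
linear-SVM estimators behind a common fit/score contract.  The deployed
model is, by default, a soft-average ensemble of a linear-kernel SVM and
the KDE classifier, trained on TF-IDF 4-mer features of window-10
neighborhoods merged with descriptive genomic features, after k-NN
imputation, repeated-edited-nearest-neighbor rebalancing, impurity-based
selection of the top 50 features, and a composite-score threshold search
over [0, 1] in steps of 0.001.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import joblib
import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.metrics.pairwise import nan_euclidean_distances
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .density_analysis import KdeModel, fit_kde
from .feature_encoding import (
    EncodingSpec,
    FeatureMatrix,
    KmerVocabulary,
    assemble_features,
    encode_neighborhoods,
)
from .mutation_io import MutationRecord, extract_neighborhoods

logger = logging.getLogger("drivercontext")

DRIVER, PASSENGER = "driver", "passenger"

#: Bandwidth candidates for classifier-internal KDE fits (one decade around 1).
CLASSIFIER_BANDWIDTH_GRID = tuple(np.logspace(-1, 1, 10))

THRESHOLD_GRID = np.round(np.arange(0, 1.0005, 0.001), 3)

#: Default hyperparameter grids for the discriminative estimators.
TREE_GRID = {"n_estimators": [100, 250, 500], "max_depth": [None, 10, 20]}
SVM_GRID = {"C": [0.01, 0.1, 1, 10]}


def _as_labels(labels) -> np.ndarray:
    labels = np.asarray(labels, dtype=object)
    bad = set(labels) - {DRIVER, PASSENGER}
    if bad:
        raise ValueError(f"unknown labels {bad}")
    return labels.astype(str)


# ---------------------------------------------------------------------------
# Generative KDE classifier
# ---------------------------------------------------------------------------

@dataclass
class KdeClassifier:
    """Gaussian-KDE generative classifier over the two mutation classes."""

    class_models: dict[str, KdeModel]
    log_priors: dict[str, float]
    labels: tuple[str, str] = (DRIVER, PASSENGER)

    def posterior_driver(self, x: np.ndarray) -> np.ndarray:
        """P(driver | x) for one vector or a matrix of rows."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        log_joint = np.stack(
            [self.class_models[c].log_density(x) + self.log_priors[c]
             for c in self.labels],
            axis=1,
        )
        log_post = log_joint - logsumexp(log_joint, axis=1, keepdims=True)
        return np.exp(log_post[:, self.labels.index(DRIVER)])

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Hard labels by maximum posterior; exact ties go to passenger."""
        post = self.posterior_driver(x)
        return np.where(post > 0.5, DRIVER, PASSENGER)


def kde_classifier_fit(
    features: np.ndarray,
    labels,
    bandwidth_grid=CLASSIFIER_BANDWIDTH_GRID,
    seed: int | None = 0,
    folds: int = 5,
) -> KdeClassifier:
    """Fit one bandwidth-tuned KDE per class; priors are class fractions."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    labels = _as_labels(labels)
    models, log_priors = {}, {}
    for i, cls in enumerate((DRIVER, PASSENGER)):
        rows = features[labels == cls]
        if len(rows) == 0:
            raise ValueError(f"class {cls!r} absent from training data")
        if len(rows) < folds and len(tuple(bandwidth_grid)) > 1:
            raise ValueError(f"class {cls!r} has fewer rows than CV folds")
        models[cls] = fit_kde(rows, bandwidth_grid, folds=folds,
                              seed=None if seed is None else seed + i)
        log_priors[cls] = float(np.log(len(rows) / len(features)))
    return KdeClassifier(class_models=models, log_priors=log_priors)


def kde_classifier_posterior(model: KdeClassifier, x: np.ndarray) -> np.ndarray:
    return model.posterior_driver(x)


# ---------------------------------------------------------------------------
# Rebalancing and imputation
# ---------------------------------------------------------------------------

def renn_undersample(
    features: np.ndarray,
    labels,
    k: int = 3,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Repeated edited nearest neighbors undersampling of the majority class.

    Each pass removes every majority-class point whose k nearest neighbors
    (excluding itself, among the surviving points) majority-vote it to the
    minority class, and repeats until a pass removes nothing or ``max_iter``
    is reached.  Minority points are never removed.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    labels = _as_labels(labels)
    if len(features) != len(labels):
        raise ValueError("features and labels disagree in length")
    if k >= len(features):
        raise ValueError(f"k={k} must be smaller than the dataset size")
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2:
        raise ValueError("both classes must be present")
    majority = counts.idxmax()
    keep = np.ones(len(features), dtype=bool)
    for _ in range(max_iter):
        idx = np.flatnonzero(keep)
        if len(idx) <= k:
            break
        nn = NearestNeighbors(n_neighbors=k + 1).fit(features[idx])
        _, neigh = nn.kneighbors(features[idx])
        neigh_labels = labels[idx][neigh[:, 1:]]          # drop self
        votes_majority = (neigh_labels == majority).sum(axis=1)
        misclassified = votes_majority < (k + 1) / 2      # strict k-NN vote
        to_remove = idx[misclassified & (labels[idx] == majority)]
        if len(to_remove) == 0:
            break
        keep[to_remove] = False
    return features[keep], labels[keep]


def knn_impute(
    features: np.ndarray,
    gene_keys,
    k: int = 5,
) -> np.ndarray:
    """Fill NaN cells with the mean of the k nearest complete rows.

    Neighbor candidates are restricted to rows of the same gene whenever at
    least k complete same-gene rows exist; otherwise all complete rows are
    used.  Distances are NaN-aware Euclidean over the observed columns.
    """
    X = np.array(features, dtype=float, copy=True)
    gene_keys = np.asarray(gene_keys, dtype=object)
    if np.any(np.all(np.isnan(X), axis=0)):
        raise ValueError("a column is entirely missing; cannot impute")
    complete = ~np.isnan(X).any(axis=1)
    if not complete.any():
        raise ValueError("no complete rows available for imputation")
    incomplete_rows = np.flatnonzero(~complete)
    for row in incomplete_rows:
        same_gene = complete & (gene_keys == gene_keys[row])
        pool = np.flatnonzero(same_gene)
        if len(pool) < k:
            pool = np.flatnonzero(complete)
        dists = nan_euclidean_distances(X[row:row + 1], X[pool])[0]
        nearest = pool[np.argsort(dists, kind="stable")[:k]]
        missing_cols = np.flatnonzero(np.isnan(X[row]))
        X[row, missing_cols] = X[np.ix_(nearest, missing_cols)].mean(axis=0)
    return X


# ---------------------------------------------------------------------------
# Feature selection, thresholding, voting
# ---------------------------------------------------------------------------

def impurity_select(
    features: FeatureMatrix | np.ndarray,
    labels,
    mode: str = "top_n",
    value: float = 50,
    seed: int | None = 0,
    n_estimators: int = 250,
    feature_names=None,
) -> list[str]:
    """Rank features by extremely-randomized-trees impurity importance.

    ``mode="percentile"`` keeps the top ``value`` percent of features;
    ``mode="top_n"`` keeps exactly ``value`` features (clipped with a
    warning if fewer exist).  Returns the kept names in rank order.
    """
    if isinstance(features, FeatureMatrix):
        names = features.column_names
        X = features.values
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        names = list(feature_names) if feature_names is not None else [
            f"f{i}" for i in range(X.shape[1])
        ]
    labels = _as_labels(labels)
    forest = ExtraTreesClassifier(n_estimators=n_estimators, random_state=seed)
    forest.fit(X, labels)
    order = np.argsort(forest.feature_importances_, kind="stable")[::-1]
    if mode == "percentile":
        n_keep = max(1, int(np.ceil(len(names) * value / 100)))
    elif mode == "top_n":
        n_keep = int(value)
        if n_keep > len(names):
            logger.warning("top_n=%d clipped to %d available features", n_keep, len(names))
            n_keep = len(names)
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    return [names[i] for i in order[:n_keep]]


def apply_threshold(scores: np.ndarray, threshold: float) -> np.ndarray:
    """Binarize driver scores: score > threshold -> driver."""
    scores = np.asarray(scores, dtype=float)
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("scores must lie in [0, 1]")
    return np.where(scores > threshold, DRIVER, PASSENGER)


@dataclass(frozen=True)
class VoteRule:
    """How a panel of per-tool binary calls is combined into one call."""

    mode: str                      # "majority" | "at_least_p"
    p: int | None = None
    member_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("majority", "at_least_p"):
            raise ValueError(f"unknown vote mode {self.mode!r}")
        if self.mode == "at_least_p":
            if self.p is None or self.p < 1:
                raise ValueError("at_least_p requires p >= 1")
            if self.member_names and self.p > len(self.member_names):
                raise ValueError("p exceeds the number of panel members")


def vote(calls, rule: VoteRule) -> str:
    """Combine per-member driver/passenger calls (1/0 accepted) into one.

    Majority ties in even panels resolve to driver.
    """
    if any(c is None for c in calls):
        raise ValueError("every panel member must vote; no silent abstention")
    binary = []
    for c in calls:
        if c in (DRIVER, 1, True):
            binary.append(1)
        elif c in (PASSENGER, 0, False):
            binary.append(0)
        else:
            raise ValueError(f"unrecognized call {c!r}")
    if rule.member_names and len(binary) != len(rule.member_names):
        raise ValueError("number of calls differs from the panel size")
    n_driver = sum(binary)
    if rule.mode == "at_least_p":
        if rule.p > len(binary):
            raise ValueError("p exceeds the number of calls")
        return DRIVER if n_driver >= rule.p else PASSENGER
    return DRIVER if n_driver >= len(binary) - n_driver else PASSENGER


def vote_table(calls: pd.DataFrame, rule: VoteRule) -> pd.Series:
    """Apply ``vote`` row-wise to a per-tool call table (columns = tools)."""
    members = list(rule.member_names) or list(calls.columns)
    missing = set(members) - set(calls.columns)
    if missing:
        raise ValueError(f"missing panel member column(s): {sorted(missing)}")
    sub = calls[members]
    if sub.isna().any().any():
        raise ValueError("missing member call(s) in the table")
    return sub.apply(lambda row: vote(list(row), rule), axis=1)


# ---------------------------------------------------------------------------
# Discriminative estimators and the soft ensemble
# ---------------------------------------------------------------------------

def _make_discriminative(name: str, seed: int | None, tuning_folds: int):
    if name == "rf":
        return GridSearchCV(RandomForestClassifier(random_state=seed), TREE_GRID,
                            cv=tuning_folds, scoring="roc_auc")
    if name == "et":
        return GridSearchCV(ExtraTreesClassifier(random_state=seed), TREE_GRID,
                            cv=tuning_folds, scoring="roc_auc")
    if name == "svm":
        # Platt-calibrated linear SVM so the ensemble can soft-average
        # probabilities and the decision threshold stays tunable.
        svm = CalibratedClassifierCV(
            SVC(kernel="linear", random_state=seed), ensemble=False)
        grid = {f"estimator__{k}": v for k, v in SVM_GRID.items()}
        return GridSearchCV(svm, grid, cv=tuning_folds, scoring="roc_auc")
    raise ValueError(f"unknown estimator {name!r}")


class SoftEnsemble:
    """Soft-averaging combiner over member driver-probability scorers."""

    def __init__(self, members: list[str], seed: int | None = 0,
                 tuning_folds: int = 3,
                 bandwidth_grid=CLASSIFIER_BANDWIDTH_GRID):
        self.member_names = list(members)
        self.seed = seed
        self.tuning_folds = tuning_folds
        self.bandwidth_grid = bandwidth_grid
        self._fitted: dict[str, object] = {}

    def fit(self, X: np.ndarray, y) -> "SoftEnsemble":
        y = _as_labels(y)
        for name in self.member_names:
            if name == "kde":
                self._fitted[name] = kde_classifier_fit(
                    X, y, bandwidth_grid=self.bandwidth_grid, seed=self.seed)
            else:
                est = _make_discriminative(name, self.seed, self.tuning_folds)
                est.fit(X, (y == DRIVER).astype(int))
                self._fitted[name] = est
        return self

    def score_driver(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        scores = []
        for name in self.member_names:
            model = self._fitted[name]
            if name == "kde":
                scores.append(model.posterior_driver(X))
            else:
                classes = list(model.classes_)
                scores.append(model.predict_proba(X)[:, classes.index(1)])
        return np.mean(scores, axis=0)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Tunable knobs of the training pipeline (defaults = deployed model)."""

    encoding: EncodingSpec = field(
        default_factory=lambda: EncodingSpec("TF", window_size=10, k=4))
    use_descriptive: bool = True
    impute_k: int = 5
    renn_k: int = 3
    renn_max_iter: int = 100
    select_mode: str = "top_n"
    select_value: float = 50
    estimators: tuple[str, ...] = ("svm", "kde")
    tuning_folds: int = 3
    threshold_objective: str = "composite"    # or "mcc"
    threshold_folds: int = 5
    seed: int = 0


@dataclass
class TrainedModel:
    """All fitted state needed to score new mutations transform-only."""

    config: TrainConfig
    vocabulary: KmerVocabulary | None
    feature_columns: list[str]
    selected_features: list[str]
    ensemble: SoftEnsemble
    decision_threshold: float
    training_reference: np.ndarray        # complete rows for predict-time imputation
    schema_version: int = 1

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "TrainedModel":
        model = joblib.load(path)
        if not isinstance(model, TrainedModel):
            raise TypeError("archive does not contain a trained model")
        return model

    # -- prediction --------------------------------------------------------

    def predict_scores(
        self,
        mutations: list[MutationRecord],
        genome,
        descriptive: pd.DataFrame | None = None,
    ) -> pd.DataFrame:
        """Driver scores and thresholded labels for new mutations."""
        neighborhoods = extract_neighborhoods(
            mutations, genome, self.config.encoding.window_size)
        encoded, _ = encode_neighborhoods(
            neighborhoods, self.config.encoding, vocab=self.vocabulary)
        if self.config.use_descriptive:
            combined, _ = assemble_features(encoded, descriptive)
        else:
            combined, _ = assemble_features(encoded, None)
        frame = combined.to_frame().reindex(columns=self.feature_columns)
        X = frame.to_numpy(dtype=float)
        if np.isnan(X).any():
            X = _impute_against_reference(X, self.training_reference, self.config.impute_k)
        sel = [self.feature_columns.index(name) for name in self.selected_features]
        scores = self.ensemble.score_driver(X[:, sel])
        labels = apply_threshold(scores, self.decision_threshold)
        return pd.DataFrame(
            {"key": frame.index, "driver_score": scores, "label": labels}
        ).set_index("key")


def _impute_against_reference(X: np.ndarray, reference: np.ndarray, k: int) -> np.ndarray:
    X = np.array(X, dtype=float, copy=True)
    for row in np.flatnonzero(np.isnan(X).any(axis=1)):
        dists = nan_euclidean_distances(X[row:row + 1], reference)[0]
        nearest = np.argsort(dists, kind="stable")[:k]
        cols = np.flatnonzero(np.isnan(X[row]))
        X[row, cols] = reference[np.ix_(nearest, cols)].mean(axis=0)
    return X


def _search_threshold(
    X: np.ndarray, y: np.ndarray, config: TrainConfig,
) -> float:
    """Composite-score-maximizing threshold from out-of-fold scores."""
    from .evaluation import confusion_from_labels, compute_metrics

    folds = min(config.threshold_folds,
                int(pd.Series(y).value_counts().min()))
    if folds < 2:
        return 0.5
    oof = np.full(len(y), np.nan)
    splitter = StratifiedKFold(n_splits=folds, shuffle=True,
                               random_state=config.seed)
    for train_idx, test_idx in splitter.split(X, y):
        member = SoftEnsemble(list(config.estimators), seed=config.seed,
                              tuning_folds=config.tuning_folds)
        member.fit(X[train_idx], y[train_idx])
        oof[test_idx] = member.score_driver(X[test_idx])
    best_thr, best_obj = 0.5, -np.inf
    for thr in THRESHOLD_GRID:
        pred = apply_threshold(oof, float(thr))
        report = compute_metrics(confusion_from_labels(y, pred))
        obj = report.composite if config.threshold_objective == "composite" else report.mcc
        if obj > best_obj:
            best_obj, best_thr = obj, float(thr)
    return best_thr


def train_driver_classifier(
    train_mutations: list[MutationRecord],
    genome,
    descriptive: pd.DataFrame | None = None,
    config: TrainConfig | None = None,
) -> TrainedModel:
    """Train the full pipeline on labeled mutations.

    Stages: neighborhood extraction -> encoding (vocabulary fitted here) ->
    descriptive-feature merge -> k-NN imputation -> RENN rebalancing ->
    impurity-based feature selection -> soft-ensemble fit -> threshold search.
    """
    config = config or TrainConfig()
    labeled = [m for m in train_mutations if m.label is not None]
    if not labeled:
        raise ValueError("training requires labeled mutations")
    neighborhoods = extract_neighborhoods(
        labeled, genome, config.encoding.window_size)
    encoded, vocab = encode_neighborhoods(neighborhoods, config.encoding)
    desc = descriptive if config.use_descriptive else None
    combined, missing_mask = assemble_features(encoded, desc)
    key_to_label = {m.key: m.label for m in labeled}
    key_to_gene = {m.key: m.gene for m in labeled}
    y = _as_labels([key_to_label[k] for k in combined.row_keys])
    genes = np.asarray([key_to_gene[k] or "" for k in combined.row_keys], dtype=object)

    X = combined.values
    if missing_mask.any():
        X = knn_impute(np.where(missing_mask, np.nan, X), genes, k=config.impute_k)
    reference = X[~np.isnan(X).any(axis=1)]

    X_bal, y_bal = renn_undersample(X, y, k=config.renn_k,
                                    max_iter=config.renn_max_iter)
    selected = impurity_select(
        X_bal, y_bal, mode=config.select_mode, value=config.select_value,
        seed=config.seed, feature_names=combined.column_names)
    sel_idx = [combined.column_names.index(name) for name in selected]

    ensemble = SoftEnsemble(list(config.estimators), seed=config.seed,
                            tuning_folds=config.tuning_folds)
    ensemble.fit(X_bal[:, sel_idx], y_bal)
    threshold = _search_threshold(X_bal[:, sel_idx], y_bal, config)

    logger.info("trained model: %d features, threshold %.3f", len(selected), threshold)
    return TrainedModel(
        config=config,
        vocabulary=vocab,
        feature_columns=combined.column_names,
        selected_features=selected,
        ensemble=ensemble,
        decision_threshold=threshold,
        training_reference=reference,
    )
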