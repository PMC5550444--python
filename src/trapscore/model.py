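"""The vote-fraction random-forest pathogenicity classifier.

A forest of 1,000 decision trees, each split drawing floor(sqrt(N)) of the N
features, classifies variants as pathogenic (1) or benign (0). The TraP
score of a variant is the fraction of trees voting pathogenic — a score of
0.45 means exactly 450 of 1,000 trees considered the variant damaging — and
is banded into tiers: < 0.459 benign, [0.459, 0.93) possibly damaging,
>= 0.93 probably damaging. The conservation-free model uses 0.66/0.955.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.459, 0.93)
GERPLESS_THRESHOLDS = (0.66, 0.955)
TIERS = ("benign", "possibly_damaging", "probably_damaging")

_ARCHIVE_VERSION = 1


@dataclass(frozen=True)
class TrapScore:
    """Vote fraction in [0, 1] plus its tier label."""

    value: float
    tier: str


def classify(value: float, thresholds: Tuple[float, float] = DEFAULT_THRESHOLDS) -> str:
    """Map a vote fraction onto the benign/possibly/probably damaging tiers."""
    lo, hi = thresholds
    if not (0.0 < lo < hi < 1.0):
        raise ValueError(f"thresholds must be strictly increasing in (0,1): {thresholds}")
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"score {value} outside [0, 1]")
    if value < lo:
        return "benign"
    if value < hi:
        return "possibly_damaging"
    return "probably_damaging"


def vote_fraction(
    estimators: Sequence, X: np.ndarray, classes: Optional[np.ndarray] = None,
    positive=1,
) -> np.ndarray:
    """Fraction of estimators predicting the pathogenic class for each row.

    ``classes`` maps encoded tree outputs back to labels (pass the parent
    forest's ``classes_``); leave None for independently fitted trees that
    predict labels directly.
    """
    X = np.asarray(X, dtype=float)
    votes = np.zeros(X.shape[0])
    for est in estimators:
        pred = est.predict(X)
        if classes is not None:
            pred = np.asarray(classes)[pred.astype(int)]
        votes += pred == positive
    return votes / len(estimators)


class TrapClassifier(BaseEstimator, ClassifierMixin):
    """Random-forest pathogenicity classifier scored by tree-vote fraction.

    Parameters
    ----------
    n_estimators : number of trees (1,000 by default).
    max_features : features drawn per split; "sqrt" gives floor(sqrt(N)).
    class_weight : None by default (no reweighting of the imbalanced
        training classes); "balanced" is available for synthetic
        experiments.
    thresholds : tier boundaries for :meth:`classify_scores`.
    random_state : seed pinning bootstrap draws and split tie-breaks.

    Fitted attributes (trailing underscore): ``forest_``, ``classes_``,
    ``oob_error_``, ``feature_importances_`` (mean decrease in Gini
    impurity), ``feature_names_in_`` when fitted on a DataFrame.
    """

    def __init__(
        self,
        n_estimators: int = 1000,
        max_features: str = "sqrt",
        class_weight=None,
        thresholds: Tuple[float, float] = DEFAULT_THRESHOLDS,
        random_state: Optional[int] = None,
    ):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.class_weight = class_weight
        self.thresholds = thresholds
        self.random_state = random_state

    def fit(self, X, y) -> "TrapClassifier":
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        if np.isnan(X).any():
            raise ValueError("feature matrix contains NaN; impute before fitting")
        labels, counts = np.unique(y, return_counts=True)
        if len(labels) < 2:
            raise ValueError("training set must contain both classes")
        if counts.min() < 2:
            raise ValueError("need at least 2 rows per class")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            oob_score=True,
            bootstrap=True,
            class_weight=self.class_weight,
            random_state=self.random_state,
            n_jobs=1,
        ).fit(X, y)
        self.classes_ = self.forest_.classes_
        self.n_features_in_ = X.shape[1]
        self.oob_error_ = 1.0 - float(self.forest_.oob_score_)
        self.feature_importances_ = self.forest_.feature_importances_
        return self

    def _validate_X(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        if isinstance(X, pd.DataFrame):
            if hasattr(self, "feature_names_in_"):
                expected = list(self.feature_names_in_)
                if list(X.columns) != expected:
                    raise ValueError(
                        f"feature columns {list(X.columns)} do not match the "
                        f"training registry {expected}"
                    )
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return X

    def vote_fractions(self, X) -> np.ndarray:
        """TraP values: pathogenic tree votes / n_estimators (exact /1000)."""
        X = self._validate_X(X)
        return vote_fraction(self.forest_.estimators_, X, classes=self.classes_)

    def predict_proba(self, X) -> np.ndarray:
        p = self.vote_fractions(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.vote_fractions(X) >= 0.5).astype(int)

    def score_variants(self, X) -> List[TrapScore]:
        return [
            TrapScore(value=float(v), tier=classify(float(v), self.thresholds))
            for v in self.vote_fractions(X)
        ]


# ---------------------------------------------------------------------------
# Module-level operation surface (thin wrappers over the estimator)
# ---------------------------------------------------------------------------


def _registry(gerpless: bool) -> List[str]:
    names = list(FEATURE_NAMES)
    if gerpless:
        names.remove("gerp_rs")
    return names


def train(
    features: pd.DataFrame,
    labels: Sequence[int],
    seed: Optional[int] = None,
    gerpless: bool = False,
    class_weight=None,
) -> TrapClassifier:
    """Fit the 1,000-tree forest on the 20-feature registry (19 if gerpless)."""
    names = _registry(gerpless)
    missing = set(names) - set(features.columns)
    if missing:
        raise ValueError(f"feature matrix missing registry columns {sorted(missing)}")
    thresholds = GERPLESS_THRESHOLDS if gerpless else DEFAULT_THRESHOLDS
    clf = TrapClassifier(
        random_state=seed, thresholds=thresholds, class_weight=class_weight
    )
    return clf.fit(features[names], np.asarray(labels))


def train_gerpless(features: pd.DataFrame, labels, seed=None) -> TrapClassifier:
    """The conservation-free model: 19 features, tier thresholds 0.66/0.955."""
    return train(features, labels, seed=seed, gerpless=True)


def score(model: TrapClassifier, features) -> List[TrapScore]:
    return model.score_variants(features)


def feature_importance(model: TrapClassifier) -> pd.DataFrame:
    """Features ordered by descending mean decrease in Gini impurity."""
    check_is_fitted(model, "forest_")
    names = (
        list(model.feature_names_in_)
        if hasattr(model, "feature_names_in_")
        else [f"f{i}" for i in range(model.n_features_in_)]
    )
    df = pd.DataFrame(
        {"feature": names, "importance": model.feature_importances_}
    ).sort_values("importance", ascending=False, kind="stable")
    return df.reset_index(drop=True)


def cross_validate(
    features,
    labels,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    n_estimators: int = 1000,
    stratified: bool = False,
    class_weight=None,
) -> Tuple[List[float], float]:
    """Repeated k-fold cross-validation of the vote-fraction forest.

    Each repeat shuffles the data, splits it into ``folds`` contiguous folds
    (unstratified by default), trains on the remainder and scores the
    held-out fold; the held-out scores of one repeat are pooled into a
    single AUC. Returns (per-repeat AUCs, their mean). A shuffle whose
    training folds lack a class is redrawn with a logged note.
    """
    from .evaluate import roc_auc, ScoredSet

    if isinstance(features, pd.DataFrame):
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n = len(y)
    if min(np.bincount(y.astype(int))) < folds:
        raise ValueError(f"need at least {folds} rows per class for {folds}-fold CV")
    aucs: List[float] = []
    for r in range(repeats):
        rng = np.random.default_rng(seed + r)
        for attempt in range(20):
            splits = _make_splits(y, folds, rng, stratified)
            ok = all(len(np.unique(y[tr])) == 2 for tr, _ in splits)
            if ok:
                break
            logger.info("re-shuffling repeat %d: a training fold lacked a class", r)
        else:  # pragma: no cover - vanishingly unlikely at sane sizes
            raise RuntimeError("could not produce two-class training folds")
        pooled_scores = np.empty(n)
        for tr, te in splits:
            clf = TrapClassifier(
                n_estimators=n_estimators,
                random_state=int(rng.integers(2**31 - 1)),
                class_weight=class_weight,
            ).fit(X[tr], y[tr])
            pooled_scores[te] = clf.vote_fractions(X[te])
        aucs.append(roc_auc(ScoredSet(scores=pooled_scores, labels=y)).auc)
    return aucs, float(np.mean(aucs))


def _make_splits(y: np.ndarray, folds: int, rng: np.random.Generator,
                 stratified: bool):
    n = len(y)
    if stratified:
        fold_of = np.empty(n, dtype=int)
        for cls in np.unique(y):
            idx = rng.permutation(np.flatnonzero(y == cls))
            fold_of[idx] = np.arange(len(idx)) % folds
        return [
            (np.flatnonzero(fold_of != f), np.flatnonzero(fold_of == f))
            for f in range(folds)
        ]
    order = rng.permutation(n)
    bounds = np.linspace(0, n, folds + 1).astype(int)
    out = []
    for i in range(folds):
        te = order[bounds[i] : bounds[i + 1]]
        tr = np.concatenate([order[: bounds[i]], order[bounds[i + 1] :]])
        out.append((tr, te))
    return out


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def _registry_hash(names: Sequence[str]) -> str:
    return hashlib.sha256(",".join(names).encode()).hexdigest()


def save_model(model: TrapClassifier, path) -> None:
    """Persist a fitted model with its registry, thresholds and seed."""
    check_is_fitted(model, "forest_")
    names = (
        list(model.feature_names_in_)
        if hasattr(model, "feature_names_in_")
        else [f"f{i}" for i in range(model.n_features_in_)]
    )
    joblib.dump(
        {
            "format_version": _ARCHIVE_VERSION,
            "registry": names,
            "registry_hash": _registry_hash(names),
            "thresholds": model.thresholds,
            "random_state": model.random_state,
            "model": model,
        },
        path,
    )


def load_model(path) -> TrapClassifier:
    archive = joblib.load(path)
    if archive.get("format_version") != _ARCHIVE_VERSION:
        raise ValueError(f"unsupported model archive version in {path}")
    if _registry_hash(archive["registry"]) != archive["registry_hash"]:
        raise ValueError(f"model archive {path} failed its registry hash check")
    return archive["model"]
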