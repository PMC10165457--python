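"""Feature selection, multiclass ROC and LDA projection for grade panels.

Given a completed, normalized phosphosite table and a group design, this
module ranks candidate marker sites by permutation importance from a
seeded random forest, evaluates feature panels with the Hand-Till
mean-of-pairwise-AUC multiclass ROC convention on cross-validated
discriminant scores, and projects samples onto at most two linear
discriminant axes for supervised visualization.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.covariance import ledoit_wolf
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "ForestFeatureRanker",
    "LDAProjector",
    "rank_auc",
    "multiclass_auc",
    "rf_importance",
    "lda_project",
]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X.astype(float)
    return pd.DataFrame(np.asarray(X, dtype=float))


class ForestFeatureRanker(BaseEstimator):
    """Out-of-bag permutation-importance feature ranking from a seeded
    random forest.

    Importance follows the ranger convention: for each tree, classification
    accuracy on the tree's out-of-bag samples is compared with the accuracy
    after permuting one feature among those samples, and the drops are
    averaged over trees.  Using out-of-bag rather than training samples
    keeps memorized noise from inflating the importance of uninformative
    features.  Defaults: 500 trees, sqrt-features per split.  The ranking
    is deterministic given ``random_state``.

    Attributes
    ----------
    ranking_ : pandas.DataFrame
        Features in descending importance with columns ``importance`` and
        ``importance_sd`` (between-tree standard deviation).
    top_k_ : list
        The ``top_k`` best features (all features if fewer).
    """

    def __init__(
        self,
        top_k: int = 15,
        n_estimators: int = 500,
        max_features: str | float = "sqrt",
        random_state: int | None = None,
    ):
        self.top_k = top_k
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X, y):
        frame = _as_frame(X)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("feature ranking requires at least 2 classes")
        values = frame.to_numpy()
        n_samples, n_features = values.shape
        forest = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            random_state=self.random_state,
        )
        forest.fit(values, y)
        # Trees inside the forest predict encoded class indices.
        y_encoded = np.searchsorted(forest.classes_, y)
        rng = np.random.default_rng(self.random_state)
        drops = np.zeros((self.n_estimators, n_features))
        for t, (tree, inbag) in enumerate(
            zip(forest.estimators_, forest.estimators_samples_)
        ):
            oob = np.setdiff1d(np.arange(n_samples), inbag)
            if len(oob) == 0:
                continue
            X_oob = values[oob]
            y_oob = y_encoded[oob]
            base = np.mean(tree.predict(X_oob) == y_oob)
            for j in range(n_features):
                permuted = X_oob.copy()
                permuted[:, j] = permuted[rng.permutation(len(oob)), j]
                drops[t, j] = base - np.mean(tree.predict(permuted) == y_oob)
        importances = drops.mean(axis=0)
        order = np.argsort(-importances, kind="stable")
        self.forest_ = forest
        self.ranking_ = pd.DataFrame(
            {
                "importance": importances[order],
                "importance_sd": drops.std(axis=0, ddof=1)[order],
            },
            index=frame.columns[order],
        )
        self.top_k_ = list(self.ranking_.index[: self.top_k])
        return self


def rank_auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC of ``scores`` for the positive class.

    ``labels`` is boolean (True = positive).  Ties receive average ranks.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be represented")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _discriminant_direction(X: np.ndarray, y: np.ndarray, pos) -> np.ndarray:
    """Fisher discriminant direction oriented toward class ``pos``.

    The within-class covariance is estimated with Ledoit-Wolf shrinkage so
    the direction stays well defined when features approach or exceed the
    sample count (and degenerates gracefully to the mean-difference
    direction when the within-class scatter vanishes)."""
    mask = y == pos
    mu_pos = X[mask].mean(axis=0)
    mu_neg = X[~mask].mean(axis=0)
    centered = np.vstack([X[mask] - mu_pos, X[~mask] - mu_neg])
    cov, _ = ledoit_wolf(centered, assume_centered=True)
    ridge = 1e-9 * np.trace(cov) / cov.shape[0] + 1e-12
    return np.linalg.solve(
        cov + ridge * np.eye(cov.shape[0]), mu_pos - mu_neg
    )


def _pair_scores(Xp: np.ndarray, yp: np.ndarray, pos, cv: str) -> np.ndarray:
    """1-D discriminant scores for one class pair, oriented toward ``pos``."""
    if cv == "resubstitution":
        return Xp @ _discriminant_direction(Xp, yp, pos)
    if cv != "loo":
        raise ValueError(f"cv must be 'loo' or 'resubstitution', got {cv!r}")
    scores = np.empty(len(yp))
    for i in range(len(yp)):
        mask = np.ones(len(yp), dtype=bool)
        mask[i] = False
        w = _discriminant_direction(Xp[mask], yp[mask], pos)
        scores[i] = Xp[i] @ w
    return scores


def multiclass_auc(
    X,
    y,
    features=None,
    cv: str = "loo",
) -> float:
    """Multiclass AUC: mean of all pairwise rank AUCs (Hand-Till).

    Each unordered class pair is scored by a linear discriminant on the
    feature panel; by default the held-out score of a leave-one-out fit is
    used (``cv='resubstitution'`` scores the training fit and is
    optimistic).  For two classes this reduces to the standard rank-based
    AUC of the cross-validated score.
    """
    frame = _as_frame(X)
    if features is not None:
        frame = frame.loc[:, list(features)]
    y = np.asarray(y)
    classes = list(pd.unique(y))
    if len(classes) < 2:
        raise ValueError("multiclass AUC requires at least 2 classes")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    aucs = []
    values = frame.to_numpy()
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            pair = np.isin(y, [classes[i], classes[j]])
            scores = _pair_scores(values[pair], y[pair], classes[j], cv)
            aucs.append(rank_auc(scores, y[pair] == classes[j]))
    return float(np.mean(aucs))


class LDAProjector(TransformerMixin, BaseEstimator):
    """Supervised LDA projection onto at most two discriminant axes.

    With three groups exactly two axes exist (rank bound: groups - 1).
    When the feature count reaches the sample count the within-class
    scatter is singular and a shrinkage (Ledoit-Wolf) eigen solver is used
    instead, with a warning.  Axis signs are fixed by forcing the
    largest-magnitude loading positive, for reproducible plots.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        frame = _as_frame(X)
        y = np.asarray(y)
        n_classes = len(np.unique(y))
        n_components = min(self.n_components, n_classes - 1)
        if n_components < 1:
            raise ValueError("LDA projection requires at least 2 classes")
        shrink = frame.shape[1] >= frame.shape[0]
        if shrink:
            warnings.warn(
                "within-class scatter is singular (features >= samples); "
                "falling back to shrinkage LDA",
                stacklevel=2,
            )
            lda = LinearDiscriminantAnalysis(
                solver="eigen", shrinkage="auto", n_components=n_components
            )
        else:
            lda = LinearDiscriminantAnalysis(
                solver="svd", n_components=n_components
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # collinearity warnings
            lda.fit(frame.to_numpy(), y)
        scalings = lda.scalings_[:, :n_components]
        signs = np.sign(scalings[np.argmax(np.abs(scalings), axis=0),
                                 np.arange(n_components)])
        signs[signs == 0] = 1.0
        self.lda_ = lda
        self.signs_ = signs
        self.n_components_ = n_components
        self.classes_ = lda.classes_
        return self

    def transform(self, X):
        frame = _as_frame(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords = self.lda_.transform(frame.to_numpy())
        coords = coords[:, : self.n_components_] * self.signs_
        return pd.DataFrame(
            coords,
            index=frame.index,
            columns=[f"LD{k + 1}" for k in range(self.n_components_)],
        )


def rf_importance(
    X, y, top_k: int = 15, seed: int | None = None, **kwargs
) -> pd.DataFrame:
    """Functional wrapper over :class:`ForestFeatureRanker`; returns the
    full descending ranking (use ``.head(top_k)`` attributes for the top
    set, also available as ``ranking.attrs['top_k_']``)."""
    ranker = ForestFeatureRanker(top_k=top_k, random_state=seed, **kwargs)
    ranker.fit(X, y)
    ranking = ranker.ranking_
    ranking.attrs["top_k_"] = ranker.top_k_
    return ranking


def lda_project(X, y, n_components: int = 2) -> pd.DataFrame:
    """Functional wrapper over :class:`LDAProjector`: fit and project."""
    projector = LDAProjector(n_components=n_components)
    coords = projector.fit(X, y).transform(X)
    coords["group"] = np.asarray(y)
    return coords
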