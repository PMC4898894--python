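"""The pair-classification model: a 30-tree random forest over pair features.

Configuration follows the reference protocol: 30 trees, splits chosen by
information gain among 4 randomly drawn candidate features, minimum 10
samples per leaf.  The model's score for a pair is the fraction of trees
voting "interacting" — a continuous value on the exact grid k/30,
k = 0..30 — and a pair is labelled positive iff its score is strictly
greater than the chosen threshold.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .annot_io import AnnotationUniverse, Pair, canonical_pair
from .features import FeatureSchema, PairFeaturizer
from .trainset import LabeledPairSet

_PERSIST_FORMAT = 1


@dataclass(frozen=True)
class ScoredPair:
    """A gene pair with its forest vote score and optional label."""

    pair: Pair
    score: float
    label: bool | None = None


class HiPPIPClassifier(ClassifierMixin, BaseEstimator):
    """Random-forest pair classifier over annotation-derived features.

    Parameters
    ----------
    universe:
        The annotation universe the features are computed from.
    schema:
        Feature schema; defaults to the 8-feature standard schema.
    n_trees:
        Number of trees in the forest (default 30).
    max_features:
        Candidate features drawn at each split (default 4; clipped to the
        number of enabled features).
    min_samples_leaf:
        Minimum samples per leaf node (default 10).
    criterion:
        Split criterion; ``"entropy"`` (information gain) by default.
    bootstrap:
        Whether each tree resamples the training set (default True).
    random_state:
        Seed for all stochastic steps of training.

    Attributes
    ----------
    featurizer_ : PairFeaturizer
        Fitted featurizer, including the training-only domain-pair counts.
    forest_ : RandomForestClassifier
        The fitted forest.
    classes_ : ndarray
        ``[0, 1]``.
    """

    def __init__(
        self,
        universe: AnnotationUniverse | None = None,
        schema: FeatureSchema | None = None,
        n_trees: int = 30,
        max_features: int = 4,
        min_samples_leaf: int = 10,
        criterion: str = "entropy",
        bootstrap: bool = True,
        random_state: int | None = None,
    ):
        self.universe = universe
        self.schema = schema
        self.n_trees = n_trees
        self.max_features = max_features
        self.min_samples_leaf = min_samples_leaf
        self.criterion = criterion
        self.bootstrap = bootstrap
        self.random_state = random_state

    # -- fitting ------------------------------------------------------------

    def fit(self, X: Sequence[Sequence[str]], y: Sequence[int]) -> "HiPPIPClassifier":
        if self.universe is None:
            raise ValueError("HiPPIPClassifier requires an AnnotationUniverse")
        y_arr = np.asarray(y, dtype=int)
        classes = np.unique(y_arr)
        if len(classes) < 2:
            raise ValueError("training data must contain both classes")
        self.featurizer_ = PairFeaturizer(self.universe, self.schema).fit(X, y_arr)
        n_active = len(self.featurizer_.schema_.active_names)
        mtry = min(self.max_features, self.featurizer_.n_features_out_)
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            criterion=self.criterion,
            max_features=mtry,
            min_samples_leaf=self.min_samples_leaf,
            bootstrap=self.bootstrap,
            random_state=self.random_state,
        )
        Xm = self.featurizer_.transform(X)
        self.forest_.fit(Xm, y_arr)
        self.classes_ = self.forest_.classes_
        self.n_features_in_ = n_active
        return self

    # -- scoring ------------------------------------------------------------

    def _vote_scores(self, Xm: np.ndarray) -> np.ndarray:
        """Fraction of trees predicting the positive class (exact k/n_trees)."""
        votes = np.zeros(Xm.shape[0], dtype=float)
        pos_index = int(np.where(self.forest_.classes_ == 1)[0][0])
        for tree in self.forest_.estimators_:
            votes += (tree.predict(Xm) == self.forest_.classes_[pos_index])
        return votes / len(self.forest_.estimators_)

    def decision_scores(self, X: Sequence[Sequence[str]]) -> np.ndarray:
        """Vote-fraction scores in [0, 1] for a sequence of gene pairs."""
        check_is_fitted(self, "forest_")
        Xc = [canonical_pair(*p) for p in X]
        Xm = self.featurizer_.transform(Xc)
        return self._vote_scores(Xm)

    def predict_proba(self, X: Sequence[Sequence[str]]) -> np.ndarray:
        s = self.decision_scores(X)
        return np.column_stack([1.0 - s, s])

    def predict(self, X: Sequence[Sequence[str]], threshold: float = 0.5) -> np.ndarray:
        """Label pairs positive iff score is strictly greater than *threshold*."""
        return (self.decision_scores(X) > threshold).astype(int)

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | os.PathLike) -> Path:
        """Serialize the fitted model (schema + hyperparameters + trees)."""
        check_is_fitted(self, "forest_")
        path = Path(path)
        payload = {
            "format": _PERSIST_FORMAT,
            "params": {
                k: v for k, v in self.get_params().items() if k != "universe"
            },
            "schema": self.featurizer_.schema_,
            "domain_stats": self.featurizer_.domain_stats_,
            "forest": self.forest_,
            "classes": self.classes_,
        }
        joblib.dump(payload, path)
        return path

    @classmethod
    def load(cls, path: str | os.PathLike, universe: AnnotationUniverse) -> "HiPPIPClassifier":
        payload = joblib.load(path)
        if payload.get("format") != _PERSIST_FORMAT:
            raise ValueError(f"unsupported model archive format: {payload.get('format')!r}")
        params = dict(payload["params"])
        params.pop("schema", None)
        obj = cls(universe=universe, schema=payload["schema"], **params)
        featurizer = PairFeaturizer(universe, payload["schema"])
        featurizer.schema_ = payload["schema"]
        featurizer.domain_stats_ = payload["domain_stats"]
        featurizer.n_features_out_ = payload["schema"].n_columns()
        obj.featurizer_ = featurizer
        obj.forest_ = payload["forest"]
        obj.classes_ = payload["classes"]
        obj.n_features_in_ = len(payload["schema"].active_names)
        return obj


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def train(
    train_set: LabeledPairSet,
    universe: AnnotationUniverse,
    schema: FeatureSchema | None = None,
    seed: int | None = None,
    **params,
) -> HiPPIPClassifier:
    """Train a classifier on a labelled pair set."""
    clf = HiPPIPClassifier(universe=universe, schema=schema, random_state=seed, **params)
    return clf.fit(train_set.pairs, train_set.labels)


def score_pairs(
    model: HiPPIPClassifier,
    pairs: Sequence[Sequence[str]],
    threshold: float | None = None,
) -> list[ScoredPair]:
    """Score pairs with the forest vote fraction; optionally label at *threshold*."""
    scores = model.decision_scores(pairs)
    out = []
    for p, s in zip(pairs, scores):
        label = None if threshold is None else bool(s > threshold)
        out.append(ScoredPair(pair=canonical_pair(*p), score=float(s), label=label))
    return out


def classify(scored: Sequence[ScoredPair], threshold: float) -> list[ScoredPair]:
    """Assign labels at *threshold* (positive iff score strictly greater)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return [
        ScoredPair(pair=s.pair, score=s.score, label=bool(s.score > threshold))
        for s in scored
    ]
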