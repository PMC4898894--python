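"""Numeric features of an unordered gene pair.

The information sources are shared GO membership (per aspect, after is_a
propagation), expression correlation, a domain-pair log-odds score fitted on
training data only, genomic co-location and tissue-membership overlap.  The
default schema carries eight features:

==================  =======================================================
``go_bp_shared``    shared propagated biological-process terms (count)
``go_mf_shared``    shared propagated molecular-function terms (count)
``go_cc_shared``    shared propagated cellular-component terms (count)
``coexpression``    Pearson correlation across shared conditions, [-1, 1]
``domain_logodds``  max log-odds of a domain pair in positives vs randoms
``same_chrom``      1 if both genes on the same chromosome else 0
``chrom_log_dist``  log10(midpoint distance + 1) on the same chromosome,
                    capped at 9; missing across chromosomes
``tissue_jaccard``  Jaccard overlap of tissue-membership sets, [0, 1]
==================  =======================================================

Every feature is symmetric in the pair by construction.  Missing information
is encoded as the schema's sentinel value (default 0) together with a boolean
missing mask; the mask can optionally be appended to the numeric matrix.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .annot_io import (
    AnnotationUniverse,
    DomainTable,
    ExpressionMatrix,
    GeneLocusTable,
    GOAnnotationTable,
    Pair,
    TissueTable,
    canonical_pair,
)

DEFAULT_FEATURES = (
    "go_bp_shared",
    "go_mf_shared",
    "go_cc_shared",
    "coexpression",
    "domain_logodds",
    "same_chrom",
    "chrom_log_dist",
    "tissue_jaccard",
)


@dataclass
class FeatureSchema:
    """Ordered feature list with sentinels; fixed at training time."""

    names: tuple[str, ...] = DEFAULT_FEATURES
    enabled: tuple[bool, ...] = ()
    sentinel: float = 0.0
    alpha: float = 1.0          # pseudocount of the domain log-odds
    distance_cap: float = 9.0   # cap on log10 genomic distance (~chromosome scale)
    append_mask: bool = False   # append the missing mask as extra columns

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if not self.enabled:
            self.enabled = tuple(True for _ in self.names)
        if len(self.enabled) != len(self.names):
            raise ValueError("enabled flags must align with feature names")

    @property
    def active_names(self) -> tuple[str, ...]:
        return tuple(n for n, e in zip(self.names, self.enabled) if e)

    def n_columns(self) -> int:
        k = len(self.active_names)
        return 2 * k if self.append_mask else k


@dataclass
class PairFeatureVector:
    """Feature values for one unordered pair, aligned to a schema."""

    pair: Pair
    values: np.ndarray
    missing: np.ndarray
    schema: FeatureSchema = field(repr=False, default_factory=FeatureSchema)


# ---------------------------------------------------------------------------
# individual features
# ---------------------------------------------------------------------------

def go_shared_terms(pair: Sequence[str], go: GOAnnotationTable, aspect: str) -> int:
    """Number of GO terms in *aspect* shared by both genes after is_a propagation.

    Aspect roots are excluded; an unannotated gene contributes an empty set,
    so the count is 0.
    """
    a, b = pair
    return len(go.annotated_closure(a, aspect) & go.annotated_closure(b, aspect))


def coexpression(pair: Sequence[str], expr: ExpressionMatrix) -> float | None:
    """Pearson correlation of the two expression profiles over shared finite
    conditions; None when <2 shared conditions or a profile has zero variance."""
    pa, pb = expr.profile(pair[0]), expr.profile(pair[1])
    if pa is None or pb is None:
        return None
    ok = np.isfinite(pa) & np.isfinite(pb)
    if ok.sum() < 2:
        return None
    xa, xb = pa[ok], pb[ok]
    if np.std(xa) == 0 or np.std(xb) == 0:
        return None
    r = float(np.corrcoef(xa, xb)[0, 1])
    return max(-1.0, min(1.0, r))


class DomainPairStats(BaseEstimator):
    """Counts of unordered domain pairs among training positives vs randoms.

    Fitting reads only the training pairs handed to it (a leakage guard: the
    held-out test labels never enter these counts).  The score of a gene pair
    is the maximum log-odds over the cross-product of their domain sets, with
    pseudocount ``alpha``.
    """

    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def fit(
        self,
        positive_pairs: Iterable[Sequence[str]],
        negative_pairs: Iterable[Sequence[str]],
        domains: DomainTable,
    ) -> "DomainPairStats":
        self.pos_counts_ = self._count(positive_pairs, domains)
        self.neg_counts_ = self._count(negative_pairs, domains)
        return self

    @staticmethod
    def _count(pairs: Iterable[Sequence[str]], domains: DomainTable) -> Counter:
        counts: Counter = Counter()
        for a, b in pairs:
            for da in domains.domains(a):
                for db in domains.domains(b):
                    counts[canonical_pair(da, db)] += 1
        return counts

    def log_odds(self, domains_a: frozenset[str], domains_b: frozenset[str]) -> float | None:
        check_is_fitted(self, "pos_counts_")
        if not domains_a or not domains_b:
            return None
        best = -math.inf
        for da in domains_a:
            for db in domains_b:
                key = canonical_pair(da, db)
                lo = math.log(
                    (self.pos_counts_.get(key, 0) + self.alpha)
                    / (self.neg_counts_.get(key, 0) + self.alpha)
                )
                if lo > best:
                    best = lo
        return best


def domain_cooccurrence(
    pair: Sequence[str], domains: DomainTable, stats: DomainPairStats
) -> float | None:
    """Max log-odds over all domain pairs of the two genes; None if either
    gene carries no domains."""
    return stats.log_odds(domains.domains(pair[0]), domains.domains(pair[1]))


def locus_features(
    pair: Sequence[str], loci: GeneLocusTable, cap: float = 9.0
) -> tuple[float | None, float | None]:
    """(same-chromosome indicator, capped log10 midpoint distance).

    The distance feature is defined only on the same chromosome; across
    chromosomes (or with a missing locus) it is None.
    """
    ma, mb = loci.midpoint(pair[0]), loci.midpoint(pair[1])
    if ma is None or mb is None:
        return None, None
    if ma[0] != mb[0]:
        return 0.0, None
    dist = math.log10(abs(ma[1] - mb[1]) + 1.0)
    return 1.0, min(dist, cap)


def tissue_overlap(pair: Sequence[str], tissues: TissueTable) -> float | None:
    """Jaccard overlap of the two tissue sets; None if either set is empty."""
    ta, tb = tissues.tissues(pair[0]), tissues.tissues(pair[1])
    if not ta or not tb:
        return None
    return len(ta & tb) / len(ta | tb)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _raw_features(
    pair: Pair,
    universe: AnnotationUniverse,
    schema: FeatureSchema,
    stats: DomainPairStats | None,
) -> dict[str, float | None]:
    same, logdist = locus_features(pair, universe.loci, cap=schema.distance_cap)
    out: dict[str, float | None] = {
        "go_bp_shared": float(go_shared_terms(pair, universe.go, "BP")),
        "go_mf_shared": float(go_shared_terms(pair, universe.go, "MF")),
        "go_cc_shared": float(go_shared_terms(pair, universe.go, "CC")),
        "coexpression": coexpression(pair, universe.expr),
        "same_chrom": same,
        "chrom_log_dist": logdist,
        "tissue_jaccard": tissue_overlap(pair, universe.tissues),
    }
    if stats is not None:
        out["domain_logodds"] = domain_cooccurrence(pair, universe.domains, stats)
    else:
        out["domain_logodds"] = None
    return out


def compute_pair_features(
    pair: Sequence[str],
    universe: AnnotationUniverse,
    schema: FeatureSchema | None = None,
    stats: DomainPairStats | None = None,
) -> PairFeatureVector:
    """Assemble the feature vector of one unordered pair in schema order."""
    schema = schema or FeatureSchema()
    a = universe.catalog.canonicalize(pair[0])
    b = universe.catalog.canonicalize(pair[1])
    if a is None:
        raise KeyError(f"symbol {pair[0]!r} not in catalog")
    if b is None:
        raise KeyError(f"symbol {pair[1]!r} not in catalog")
    cpair = canonical_pair(a, b)
    raw = _raw_features(cpair, universe, schema, stats)
    names = schema.active_names
    values = np.empty(len(names), dtype=float)
    missing = np.zeros(len(names), dtype=bool)
    for i, name in enumerate(names):
        v = raw.get(name)
        if v is None:
            values[i] = schema.sentinel
            missing[i] = True
        else:
            values[i] = v
    return PairFeatureVector(pair=cpair, values=values, missing=missing, schema=schema)


class PairFeaturizer(TransformerMixin, BaseEstimator):
    """Transform gene pairs into the numeric feature matrix.

    ``fit`` learns the :class:`DomainPairStats` from the labelled training
    pairs (positives vs random negatives); ``transform`` maps a sequence of
    pairs to an ``(n_pairs, n_features)`` array.  Symmetric by construction:
    pairs are canonicalized before feature computation.
    """

    def __init__(
        self,
        universe: AnnotationUniverse | None = None,
        schema: FeatureSchema | None = None,
    ):
        self.universe = universe
        self.schema = schema

    def fit(self, X: Sequence[Sequence[str]], y: Sequence[int] | None = None) -> "PairFeaturizer":
        if self.universe is None:
            raise ValueError("PairFeaturizer requires an AnnotationUniverse")
        self.schema_ = self.schema or FeatureSchema()
        stats = DomainPairStats(alpha=self.schema_.alpha)
        if y is None:
            # without labels the domain log-odds cannot be fitted; leave unfitted
            stats.fit([], [], self.universe.domains)
        else:
            y_arr = np.asarray(y)
            pos = [p for p, label in zip(X, y_arr) if label == 1]
            neg = [p for p, label in zip(X, y_arr) if label == 0]
            stats.fit(pos, neg, self.universe.domains)
        self.domain_stats_ = stats
        self.n_features_out_ = self.schema_.n_columns()
        return self

    def transform(self, X: Sequence[Sequence[str]]) -> np.ndarray:
        check_is_fitted(self, "domain_stats_")
        n = len(X)
        k = len(self.schema_.active_names)
        values = np.empty((n, k), dtype=float)
        missing = np.zeros((n, k), dtype=bool)
        for i, pair in enumerate(X):
            fv = compute_pair_features(
                pair, self.universe, self.schema_, self.domain_stats_
            )
            values[i] = fv.values
            missing[i] = fv.missing
        if self.schema_.append_mask:
            return np.hstack([values, missing.astype(float)])
        return values

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        check_is_fitted(self, "schema_")
        names = list(self.schema_.active_names)
        if self.schema_.append_mask:
            names += [f"{n}_missing" for n in self.schema_.active_names]
        return np.asarray(names, dtype=object)
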