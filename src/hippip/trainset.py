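"""Labelled training / held-out test pair sets.

Positives are sampled from the known-PPI list; negatives are uniform random
non-self pairs over the catalog, excluding every known PPI (some will be
undiscovered true interactions — a known property of this construction, not
an error).  The reference composition is 20,000 positives mixed with 80,000
random pairs for training, and a 160,000-pair test set at a realistic 0.3%
positive prevalence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np

from .annot_io import GeneCatalog, Pair, PPIEdgeList, canonical_pair

#: Class-balance constants of the reference protocol.
TRAIN_POSITIVES = 20_000
TRAIN_NEGATIVE_RATIO = 4
TEST_TOTAL = 160_000
TEST_POSITIVE_FRACTION = 0.003


@dataclass
class LabeledPairSet:
    """Pairs with binary labels (1 = known interaction, 0 = random pair)."""

    pairs: list[Pair]
    labels: np.ndarray
    provenance: str = ""
    seed: int | None = None
    _index: set[Pair] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.pairs) != len(self.labels):
            raise ValueError("pairs and labels length mismatch")
        self._index = set(self.pairs)
        if len(self._index) != len(self.pairs):
            raise ValueError("duplicate pairs in labelled set")

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        return canonical_pair(*pair) in self._index

    @property
    def positives(self) -> list[Pair]:
        return [p for p, l in zip(self.pairs, self.labels) if l == 1]

    @property
    def negatives(self) -> list[Pair]:
        return [p for p, l in zip(self.pairs, self.labels) if l == 0]


def _possible_pairs(catalog: GeneCatalog) -> int:
    return comb(len(catalog), 2)


def sample_random_pairs(
    catalog: GeneCatalog,
    n: int,
    exclude: PPIEdgeList | set[Pair] | None = None,
    seed: int | None = None,
) -> list[Pair]:
    """Sample *n* distinct unordered non-self pairs uniformly, avoiding *exclude*.

    Deterministic given *seed*.  Raises when the catalog cannot supply *n*
    pairs outside the excluded set.
    """
    excluded: set[Pair] = set()
    if exclude is not None:
        excluded = {canonical_pair(a, b) for a, b in exclude}
    symbols = sorted(catalog.symbols)
    total = _possible_pairs(catalog)
    n_excluded_valid = sum(
        1 for p in excluded if p[0] in catalog.symbols and p[1] in catalog.symbols
    )
    available = total - n_excluded_valid
    if n > available:
        raise ValueError(
            f"cannot sample {n} pairs: only {available} non-excluded pairs exist"
        )
    rng = np.random.default_rng(seed)
    if total <= 4 * max(n, 1) or total <= 200_000:
        # small catalogs: enumerate and choose without replacement
        pool = [p for p in itertools.combinations(symbols, 2) if p not in excluded]
        idx = rng.choice(len(pool), size=n, replace=False)
        return [pool[i] for i in sorted(idx)]
    # large catalogs: rejection-sample indices
    chosen: set[Pair] = set()
    m = len(symbols)
    while len(chosen) < n:
        need = n - len(chosen)
        ii = rng.integers(0, m, size=2 * need + 16)
        jj = rng.integers(0, m, size=2 * need + 16)
        for i, j in zip(ii, jj):
            if i == j:
                continue
            p = canonical_pair(symbols[i], symbols[j])
            if p in excluded or p in chosen:
                continue
            chosen.add(p)
            if len(chosen) == n:
                break
    return sorted(chosen)


def split_known_edges(
    known: PPIEdgeList, test_fraction: float = 0.2, seed: int | None = None
) -> tuple[list[Pair], list[Pair]]:
    """Disjoint random split of known edges into (train, held-out) lists."""
    edges = sorted(known.pairs())
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(edges))
    n_test = int(round(test_fraction * len(edges)))
    test_idx = set(perm[:n_test].tolist())
    train = [e for i, e in enumerate(edges) if i not in test_idx]
    test = [e for i, e in enumerate(edges) if i in test_idx]
    return train, test


def build_training_set(
    known: PPIEdgeList | list[Pair],
    catalog: GeneCatalog,
    positives_n: int = TRAIN_POSITIVES,
    ratio: int = TRAIN_NEGATIVE_RATIO,
    seed: int | None = None,
    exclude: PPIEdgeList | set[Pair] | None = None,
) -> LabeledPairSet:
    """Sample ``positives_n`` known edges plus ``positives_n * ratio`` random
    negatives (none of which is a known PPI).

    *exclude* defaults to the full known edge list; pass a superset to also
    keep negatives out of held-out positives.
    """
    known_pairs = sorted(known.pairs() if isinstance(known, PPIEdgeList) else known)
    if positives_n > len(known_pairs):
        raise ValueError(
            f"requested {positives_n} positives but only {len(known_pairs)} known edges"
        )
    rng = np.random.default_rng(seed)
    pos_idx = rng.choice(len(known_pairs), size=positives_n, replace=False)
    positives = [known_pairs[i] for i in sorted(pos_idx)]
    excl: set[Pair] = {canonical_pair(a, b) for a, b in known_pairs}
    if isinstance(known, PPIEdgeList):
        excl |= known.pairs()
    if exclude is not None:
        excl |= {canonical_pair(a, b) for a, b in exclude}
    negatives = sample_random_pairs(
        catalog, positives_n * ratio, exclude=excl, seed=int(rng.integers(2**31))
    )
    pairs = positives + negatives
    labels = np.array([1] * len(positives) + [0] * len(negatives))
    return LabeledPairSet(pairs, labels, provenance="train", seed=seed)


def build_test_set(
    heldout_positives: list[Pair],
    catalog: GeneCatalog,
    total_n: int = TEST_TOTAL,
    positive_fraction: float = TEST_POSITIVE_FRACTION,
    seed: int | None = None,
    known: PPIEdgeList | None = None,
    train_set: LabeledPairSet | None = None,
) -> LabeledPairSet:
    """Build a held-out test set of ``total_n`` pairs at the stated prevalence.

    Positive count is ``round(total_n * positive_fraction)`` (round half to
    even).  Test pairs are disjoint from the training set; negatives exclude
    every known PPI.
    """
    n_pos = round(total_n * positive_fraction)
    if n_pos > len(heldout_positives):
        raise ValueError(
            f"need {n_pos} held-out positives, only {len(heldout_positives)} available"
        )
    if train_set is not None:
        clash = [p for p in heldout_positives if p in train_set]
        if clash:
            raise ValueError(
                f"{len(clash)} held-out positive(s) overlap the training set, "
                f"e.g. {clash[0]}"
            )
    rng = np.random.default_rng(seed)
    pos_idx = rng.choice(len(heldout_positives), size=n_pos, replace=False)
    positives = [heldout_positives[i] for i in sorted(pos_idx)]
    excl: set[Pair] = set(heldout_positives)
    if known is not None:
        excl |= known.pairs()
    if train_set is not None:
        excl |= set(train_set.pairs)
    negatives = sample_random_pairs(
        catalog, total_n - n_pos, exclude=excl, seed=int(rng.integers(2**31))
    )
    pairs = positives + negatives
    labels = np.array([1] * len(positives) + [0] * len(negatives))
    return LabeledPairSet(pairs, labels, provenance="test", seed=seed)
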