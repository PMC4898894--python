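"""Feature computations against closed forms and brute-force oracles."""

import itertools
import math

import numpy as np
import pytest

from hippip.annot_io import canonical_pair
from hippip.features import (
    DomainPairStats,
    FeatureSchema,
    PairFeaturizer,
    coexpression,
    compute_pair_features,
    domain_cooccurrence,
    go_shared_terms,
    locus_features,
    tissue_overlap,
)


# -- GO shared terms ---------------------------------------------------------

def test_go_shared_propagation_counts(tiny_universe):
    go = tiny_universe.go
    # A and B both annotated to Y; closure {Y, X} (root excluded) -> 2 shared
    assert go_shared_terms(("A", "B"), go, "BP") == 2
    # A closure {Y,X}; C closure {Z}: disjoint below the root
    assert go_shared_terms(("A", "C"), go, "BP") == 0
    # A closure {Y,X}; D closure {X}
    assert go_shared_terms(("A", "D"), go, "BP") == 1
    # unannotated gene -> 0
    assert go_shared_terms(("A", "E"), go, "BP") == 0


def _brute_force_closure(go, gene, aspect):
    out = set()
    frontier = set(go.terms(gene, aspect))
    while frontier:
        term = frontier.pop()
        if term in out:
            continue
        out.add(term)
        frontier |= set(go.parents.get(term, frozenset()))
    return out - set(go.roots)


def test_go_shared_matches_brute_force(small_synth):
    universe, _ = small_synth
    genes = sorted(universe.catalog.symbols)[:10]
    for aspect in ("BP", "MF", "CC"):
        for a, b in itertools.combinations(genes, 2):
            expected = len(
                _brute_force_closure(universe.go, a, aspect)
                & _brute_force_closure(universe.go, b, aspect)
            )
            assert go_shared_terms((a, b), universe.go, aspect) == expected


# -- coexpression ------------------------------------------------------------

def test_coexpression_trivial_and_closed_form(tiny_universe):
    expr = tiny_universe.expr
    assert coexpression(("A", "B"), expr) == pytest.approx(1.0)
    assert coexpression(("A", "C"), expr) == pytest.approx(-1.0)
    assert coexpression(("A", "D"), expr) is None  # zero variance
    assert coexpression(("A", "E"), expr) is None  # absent gene


def test_coexpression_matches_pearson_formula(tiny_universe):
    import pandas as pd
    from hippip.annot_io import ExpressionMatrix

    x = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
    y = np.array([2.0, 3.0, 1.0, 6.0, 4.0])
    expr = ExpressionMatrix(pd.DataFrame([x, y], index=["P", "Q"]))
    num = np.sum((x - x.mean()) * (y - y.mean()))
    den = math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
    assert coexpression(("P", "Q"), expr) == pytest.approx(num / den)


# -- domain log-odds ---------------------------------------------------------

def test_domain_logodds_formula(tiny_universe):
    # (D1, D2) seen in 5 positive pairs, 0 negatives: log((5+1)/(0+1))
    stats = DomainPairStats(alpha=1.0).fit(
        [("A", "B")] * 5, [], tiny_universe.domains  # A={D1}, B={D2}
    )
    score = stats.log_odds(frozenset({"D1"}), frozenset({"D2"}))
    assert score == pytest.approx(math.log(6.0 / 1.0))


def test_domain_logodds_missing_and_unfitted(tiny_universe):
    stats = DomainPairStats().fit([("A", "B")], [("A", "C")], tiny_universe.domains)
    assert domain_cooccurrence(("A", "D"), tiny_universe.domains, stats) is None
    with pytest.raises(Exception):
        DomainPairStats().log_odds(frozenset({"D1"}), frozenset({"D2"}))


def test_domain_logodds_matches_enumeration(small_synth):
    universe, truth = small_synth
    known = sorted(universe.known_ppis.pairs())
    pos, neg = known[: len(known) // 2], known[len(known) // 2:]
    stats = DomainPairStats(alpha=1.0).fit(pos, neg, universe.domains)
    genes = sorted(universe.catalog.symbols)[:12]
    for a, b in itertools.combinations(genes, 2):
        da, db = universe.domains.domains(a), universe.domains.domains(b)
        got = stats.log_odds(da, db)
        if not da or not db:
            assert got is None
            continue
        # exhaustive enumeration over the cross-product of domain sets
        def count(pairs, d1, d2):
            key = canonical_pair(d1, d2)
            return sum(
                1
                for x, y in pairs
                for u in universe.domains.domains(x)
                for v in universe.domains.domains(y)
                if canonical_pair(u, v) == key
            )
        expected = max(
            math.log((count(pos, d1, d2) + 1.0) / (count(neg, d1, d2) + 1.0))
            for d1 in da
            for d2 in db
        )
        assert got == pytest.approx(expected)


def test_domain_stats_no_leakage(small_synth):
    """Fitting on the training split is unaffected by what the test split holds."""
    universe, _ = small_synth
    known = sorted(universe.known_ppis.pairs())
    pos, neg = known[:10], known[10:20]
    s1 = DomainPairStats().fit(pos, neg, universe.domains)
    s2 = DomainPairStats().fit(pos, neg, universe.domains)
    assert s1.pos_counts_ == s2.pos_counts_ and s1.neg_counts_ == s2.neg_counts_
    with_domains = sorted(
        g for g in universe.catalog.symbols if universe.domains.domains(g)
    )
    extra = [(with_domains[0], with_domains[1])]
    s3 = DomainPairStats().fit(pos + extra, neg, universe.domains)
    assert s3.pos_counts_ != s1.pos_counts_  # counts respond only to their own input


# -- locus / tissue ----------------------------------------------------------

def test_locus_features(tiny_universe):
    loci = tiny_universe.loci
    assert locus_features(("A", "D"), loci) == (1.0, 0.0)        # same locus
    same, dist = locus_features(("A", "B"), loci)
    assert same == 1.0 and dist == pytest.approx(math.log10(1001))
    assert locus_features(("A", "C"), loci) == (0.0, None)       # different chrom
    assert locus_features(("A", "E"), loci) == (None, None)      # missing locus


def test_locus_distance_cap():
    from hippip.annot_io import GeneLocusTable

    loci = GeneLocusTable({"A": ("chr1", 0, 2), "B": ("chr1", 10**10, 10**10 + 2)})
    _, dist = locus_features(("A", "B"), loci, cap=9.0)
    assert dist == 9.0


def test_tissue_overlap(tiny_universe):
    t = tiny_universe.tissues
    assert tissue_overlap(("A", "A"), t) == 1.0
    assert tissue_overlap(("A", "C"), t) == 0.0
    assert tissue_overlap(("A", "B"), t) == pytest.approx(0.25)  # {brain}/{4 tissues}
    assert tissue_overlap(("A", "D"), t) is None


# -- assembled vector --------------------------------------------------------

def test_feature_vector_symmetry_and_masks(tiny_universe):
    stats = DomainPairStats().fit([("A", "B")], [("A", "C")], tiny_universe.domains)
    ab = compute_pair_features(("A", "B"), tiny_universe, stats=stats)
    ba = compute_pair_features(("B", "A"), tiny_universe, stats=stats)
    np.testing.assert_array_equal(ab.values, ba.values)
    np.testing.assert_array_equal(ab.missing, ba.missing)
    assert not ab.missing.any()  # A,B fully annotated
    ae = compute_pair_features(("A", "E"), tiny_universe, stats=stats)
    schema = ae.schema
    by_name = dict(zip(schema.active_names, ae.missing))
    assert by_name["coexpression"] and by_name["tissue_jaccard"]
    with pytest.raises(KeyError, match="NOPE"):
        compute_pair_features(("A", "NOPE"), tiny_universe)


def test_featurizer_symmetry_on_random_pairs(small_synth):
    universe, _ = small_synth
    rng = np.random.default_rng(0)
    genes = sorted(universe.catalog.symbols)
    known = sorted(universe.known_ppis.pairs())
    labels = np.array([1] * (len(known) // 2) + [0] * (len(known) - len(known) // 2))
    feat = PairFeaturizer(universe).fit(known, labels)
    pairs = []
    while len(pairs) < 100:
        a, b = rng.choice(genes, size=2, replace=False)
        pairs.append((a, b))
    fwd = feat.transform(pairs)
    rev = feat.transform([(b, a) for a, b in pairs])
    np.testing.assert_array_equal(fwd, rev)


def test_schema_mask_appending(tiny_universe):
    schema = FeatureSchema(append_mask=True)
    feat = PairFeaturizer(tiny_universe, schema).fit([("A", "B")], [1])
    X = feat.transform([("A", "E")])
    k = len(schema.active_names)
    assert X.shape == (1, 2 * k)
    assert set(X[0, k:]) <= {0.0, 1.0}
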