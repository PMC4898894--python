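"""Shared fixtures: a hand-built micro universe for exact-value tests and a
session-scoped default synthetic universe with its trained model."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hippip.annot_io import (
    AnnotationUniverse,
    DomainTable,
    ExpressionMatrix,
    GeneCatalog,
    GeneLocusTable,
    GOAnnotationTable,
    PPIEdgeList,
    TissueTable,
)
from hippip.model import train
from hippip.synth import SynthConfig, generate_universe
from hippip.trainset import build_test_set, build_training_set, split_known_edges


@pytest.fixture(scope="session")
def tiny_universe() -> AnnotationUniverse:
    """Five genes with fully hand-computable annotations.

    BP DAG: ROOT <- X <- Y, ROOT <- Z.  A and B are annotated to Y
    (closure {Y, X}), C to Z (closure {Z}), D to X (closure {X}); E has no
    annotation.  Expression: A == B, C == -A, D constant, E absent.
    """
    parents = {
        "GO:R": frozenset(),
        "GO:X": frozenset({"GO:R"}),
        "GO:Y": frozenset({"GO:X"}),
        "GO:Z": frozenset({"GO:R"}),
        "GO:M": frozenset(),  # MF root (unused annotations)
        "GO:C": frozenset(),  # CC root
    }
    go = GOAnnotationTable(
        {
            "BP": {"A": {"GO:Y"}, "B": {"GO:Y"}, "C": {"GO:Z"}, "D": {"GO:X"}},
            "MF": {},
            "CC": {},
        },
        parents,
    )
    profile = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    expr = ExpressionMatrix(
        pd.DataFrame(
            {
                "A": profile,
                "B": profile,
                "C": -profile,
                "D": np.ones(5),
            }
        ).T.set_axis([f"c{i}" for i in range(5)], axis=1)
    )
    domains = DomainTable(
        {"A": {"D1"}, "B": {"D2"}, "C": {"D1", "D2"}, "D": set(), "E": {"D3"}}
    )
    loci = GeneLocusTable(
        {
            "A": ("chr1", 100, 200),      # mid 150
            "B": ("chr1", 1100, 1200),    # mid 1150, |mid diff| = 1000
            "C": ("chr2", 100, 200),
            "D": ("chr1", 100, 200),      # same locus as A
        }
    )
    tissues = TissueTable(
        {
            "A": {"brain", "liver"},
            "B": {"brain", "lung", "heart"},
            "C": {"kidney"},
            "D": set(),
        }
    )
    known = PPIEdgeList()
    known.add("A", "B")
    known.add("C", "D")
    return AnnotationUniverse(
        catalog=GeneCatalog(frozenset("ABCDE")),
        go=go,
        expr=expr,
        domains=domains,
        loci=loci,
        tissues=tissues,
        known_ppis=known,
    )


@pytest.fixture(scope="session")
def small_synth():
    """A 30-gene synthetic universe for brute-force oracle comparisons."""
    cfg = SynthConfig(
        n_genes=30,
        n_clusters=4,
        go_terms_per_aspect=15,
        n_conditions=10,
        n_domains=8,
        n_tissues=6,
        n_drugs=10,
        edge_density=0.05,
        seed=3,
    )
    return generate_universe(cfg)


@pytest.fixture(scope="session")
def universe7():
    """Default synthetic universe, seed 7 (the reference study conditions)."""
    return generate_universe(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def splits7(universe7):
    universe, _ = universe7
    train_edges, heldout = split_known_edges(universe.known_ppis, 0.2, seed=7)
    train_set = build_training_set(
        PPIEdgeList({e: "known" for e in train_edges}),
        universe.catalog,
        positives_n=len(train_edges),
        ratio=4,
        seed=7,
        exclude=universe.known_ppis.pairs(),
    )
    test_set = build_test_set(
        heldout,
        universe.catalog,
        total_n=30_000,
        positive_fraction=0.003,
        seed=8,
        known=universe.known_ppis,
        train_set=train_set,
    )
    return train_set, test_set, heldout


@pytest.fixture(scope="session")
def model7(universe7, splits7):
    universe, _ = universe7
    train_set, _, _ = splits7
    return train(train_set, universe, seed=7)


@pytest.fixture(scope="session")
def test_scores7(model7, splits7):
    _, test_set, _ = splits7
    return model7.decision_scores(test_set.pairs)
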