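"""Network statistics vs brute-force oracles and closed forms."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from hippip.annot_io import DrugRecord, DrugTargetTable, GeneCatalog, PPIEdgeList
from hippip.netstats import (
    atc_anatomic_categories,
    average_distance,
    distance_drop_test,
    distance_report,
    drug_target_summary,
    hypergeom_overlap,
    shortest_path_histogram,
    term_enrichment,
)


# -- average shortest-path distance -------------------------------------------

def test_average_distance_path_graph():
    g = nx.path_graph(["A", "B", "C"])
    summary = average_distance(g, {"A", "C"})
    assert summary.mean == 2.0
    assert summary.n_connected == 1 and summary.n_disconnected == 0


def test_average_distance_disconnected_pairs_excluded():
    g = nx.Graph()
    g.add_edge("A", "B")
    g.add_edge("C", "D")
    summary = average_distance(g, {"A", "C"})
    assert math.isnan(summary.mean)
    assert summary.n_disconnected == 1
    mixed = average_distance(g, {"A", "B", "C"})
    assert mixed.mean == 1.0 and mixed.n_disconnected == 2
    with pytest.raises(ValueError):
        average_distance(g, {"A"})


def test_average_distance_matches_floyd_warshall():
    rng = np.random.default_rng(17)
    for _ in range(10):
        n = int(rng.integers(5, 16))
        g = nx.gnp_random_graph(n, 0.3, seed=int(rng.integers(2**31)))
        g = nx.relabel_nodes(g, {i: f"G{i}" for i in range(n)})
        fw = nx.floyd_warshall(g)
        genes = list(g.nodes)[: max(3, n // 2)]
        expected = [
            fw[a][b]
            for a, b in itertools.combinations(sorted(genes), 2)
            if fw[a][b] != math.inf
        ]
        summary = average_distance(g, genes)
        if expected:
            assert summary.mean == pytest.approx(float(np.mean(expected)))
        else:
            assert math.isnan(summary.mean)
        n_pairs = math.comb(len(set(genes)), 2)
        assert summary.n_connected + summary.n_disconnected == n_pairs


def test_adding_edges_never_increases_distances():
    rng = np.random.default_rng(23)
    for _ in range(5):
        g = nx.gnp_random_graph(12, 0.25, seed=int(rng.integers(2**31)))
        g = nx.relabel_nodes(g, {i: f"G{i}" for i in range(12)})
        genes = [f"G{i}" for i in range(6)]
        base = dict(nx.all_pairs_shortest_path_length(g))
        g2 = g.copy()
        g2.add_edge("G0", "G11")
        g2.add_edge("G3", "G9")
        after = dict(nx.all_pairs_shortest_path_length(g2))
        for a in genes:
            for b, d in base.get(a, {}).items():
                assert after[a][b] <= d


# -- permutation test ----------------------------------------------------------

def _line_world():
    """Background: a long path; predicted edges shortcut a 'planted' set."""
    genes = [f"G{i:02d}" for i in range(30)]
    g = nx.path_graph(genes)
    planted = [genes[0], genes[10], genes[20], genes[29]]
    predicted = PPIEdgeList()
    for a, b in itertools.combinations(planted, 2):
        predicted.add(a, b, source="predicted", score=0.9)
    return genes, g, planted, predicted


def test_permutation_p_formula_extreme():
    genes, g, planted, predicted = _line_world()
    catalog = GeneCatalog(frozenset(genes))
    res = distance_drop_test(g, predicted, planted, catalog, n_trials=199, seed=0)
    # the planted set is directly shortcut; its drop beats every null draw
    assert res.observed > max(res.null)
    assert res.p_value == pytest.approx(1.0 / 200.0)


def test_permutation_p_at_null_median():
    genes, g, _, predicted = _line_world()
    catalog = GeneCatalog(frozenset(genes))
    rng = np.random.default_rng(2)
    random_set = list(rng.choice(genes, size=4, replace=False))
    res = distance_drop_test(g, predicted, random_set, catalog, n_trials=200, seed=3)
    assert 0.05 < res.p_value <= 1.0  # a random set is not significant


def test_permutation_invariant_to_relabeling():
    genes, g, planted, predicted = _line_world()
    catalog = GeneCatalog(frozenset(genes))
    res1 = distance_drop_test(g, predicted, planted, catalog, n_trials=99, seed=5)
    mapping = {g_: f"X{g_}" for g_ in genes}
    g2 = nx.relabel_nodes(g, mapping)
    pred2 = PPIEdgeList()
    for (a, b), s in predicted.edges.items():
        pred2.add(mapping[a], mapping[b], source=s, score=predicted.scores.get((a, b)))
    catalog2 = GeneCatalog(frozenset(mapping.values()))
    res2 = distance_drop_test(
        g2, pred2, [mapping[p] for p in planted], catalog2, n_trials=99, seed=5
    )
    assert res1.observed == pytest.approx(res2.observed)
    np.testing.assert_allclose(sorted(res1.null), sorted(res2.null))
    assert res1.p_value == res2.p_value


def test_permutation_catalog_too_small():
    genes, g, planted, predicted = _line_world()
    catalog = GeneCatalog(frozenset(genes[:6]))
    with pytest.raises(ValueError, match="catalog"):
        distance_drop_test(g, predicted, planted, catalog, n_trials=10, seed=0)


# -- nearest-member histogram ---------------------------------------------------

def test_shortest_path_histogram():
    g = nx.path_graph(["A", "B", "C", "D"])
    g.add_node("LONER")
    df = shortest_path_histogram(g, ["A", "LONER"], ["B", "D"])
    by_gene = df.set_index("gene")
    assert by_gene.loc["A", "distance"] == 1.0
    assert not by_gene.loc["LONER", "reachable"]
    # self is excluded from the target set
    df2 = shortest_path_histogram(g, ["B"], ["B", "D"])
    assert df2.iloc[0]["distance"] == 2.0
    with pytest.raises(ValueError):
        shortest_path_histogram(g, [], ["B"])


def test_histogram_matches_brute_force(small_synth):
    universe, _ = small_synth
    g = nx.Graph()
    g.add_edges_from(universe.known_ppis.pairs())
    genes = sorted(g.nodes)
    a_set, b_set = genes[:5], genes[5:12]
    df = shortest_path_histogram(g, a_set, b_set).set_index("gene")
    fw = nx.floyd_warshall(g)
    for a in a_set:
        dists = [fw[a][b] for b in b_set if b != a and fw[a][b] != math.inf]
        if dists:
            assert df.loc[a, "distance"] == min(dists)
        else:
            assert not df.loc[a, "reachable"]


# -- hypergeometric overlap / enrichment ---------------------------------------

def test_hypergeom_closed_form():
    row = hypergeom_overlap(set("ABCDE"), set("ABCDE"), 10)
    assert row.p_value == pytest.approx(1.0 / math.comb(10, 5))
    null_row = hypergeom_overlap({"A"}, {"B"}, 10_000)
    assert null_row.overlap == 0 and null_row.p_value == pytest.approx(1.0)
    with pytest.raises(ValueError):
        hypergeom_overlap(set("ABCDEF"), {"A"}, 3)


def test_hypergeom_matches_enumeration():
    """Upper-tail P equals exhaustive enumeration over all draws for M <= 25."""
    rng = np.random.default_rng(8)
    universe = [f"U{i}" for i in range(20)]
    for _ in range(20):
        na, nb = int(rng.integers(1, 10)), int(rng.integers(1, 10))
        a = set(rng.choice(universe, size=na, replace=False))
        b = set(rng.choice(universe, size=nb, replace=False))
        k = len(a & b)
        M = len(universe)
        total = 0
        for draw in itertools.combinations(universe, na):
            if len(set(draw) & b) >= k:
                total += 1
        expected = total / math.comb(M, na)
        row = hypergeom_overlap(a, b, M)
        assert row.p_value == pytest.approx(expected, rel=1e-9)


def test_term_enrichment_extremal_and_composition():
    universe = [f"G{i}" for i in range(15)]
    query = set(universe[:5])
    term_table = {
        g: ({"T_exact"} if g in query else set()) | {"T_all"} for g in universe
    }
    term_table[universe[6]] |= {"T_other"}
    df = term_enrichment(query, term_table, universe, correction="bh")
    assert df.iloc[0]["term"] == "T_exact"  # covers exactly the query: smallest P
    assert "T_other" not in set(df["term"])  # disjoint from query: absent
    # per-term P matches hypergeom_overlap called per term
    for _, row in df.iterrows():
        members = {g for g, ts in term_table.items() if row["term"] in ts}
        expected = hypergeom_overlap(query, members, len(universe)).p_value
        assert row["p_value"] == pytest.approx(expected)
    with pytest.raises(ValueError):
        term_enrichment(query, {}, universe)
    with pytest.raises(ValueError):
        term_enrichment(query, term_table, universe, correction="fancy")


def test_bh_adjustment_monotone():
    universe = [f"G{i}" for i in range(30)]
    rng = np.random.default_rng(3)
    term_table = {
        g: {f"T{j}" for j in rng.choice(8, size=3, replace=False)} for g in universe
    }
    df = term_enrichment(set(universe[:8]), term_table, universe, correction="bh")
    assert (df["p_adjusted"] >= df["p_value"] - 1e-12).all()
    ordered = df.sort_values("p_value")
    assert ordered["p_adjusted"].is_monotonic_increasing


# -- drug-target summaries -------------------------------------------------------

def _drug_graph():
    g = nx.Graph()
    g.add_node("S", role="seed")
    g.add_node("K", role="known-interactor")
    g.add_node("N", role="novel-interactor")
    g.add_edge("S", "K", source="known")
    g.add_edge("S", "N", source="predicted")
    return g


def test_atc_categories():
    assert atc_anatomic_categories(["N05A", "C01"]) == {"N", "C"}
    assert atc_anatomic_categories(["bogus"]) == {"unknown"}


def test_drug_multi_category_and_roles():
    g = _drug_graph()
    table = DrugTargetTable(
        [
            DrugRecord("DrugA", ("N05A", "R06A"), "N"),   # novel, two categories
            DrugRecord("DrugB", ("N02B",), "K"),          # known
            DrugRecord("DrugC", ("C01A",), "K"),
            DrugRecord("DrugC", ("C01A",), "N"),          # both roles
            DrugRecord("DrugD", ("A01A",), "ZZZ"),        # outside the graph
        ]
    )
    summary = drug_target_summary(g, table)
    assert summary.drug_roles == {"DrugA": "novel", "DrugB": "known", "DrugC": "both"}
    cat = summary.by_category.set_index("category")
    assert cat.loc["N", "n_drugs"] == 2          # DrugA and DrugB
    assert cat.loc["N", "n_drugs_novel"] == 1
    assert cat.loc["R", "n_drugs_novel"] == 1    # DrugA counted again under R
    assert cat.loc["C", "n_drugs_both"] == 1
    assert "A" not in cat.index                  # DrugD never hits the graph
    assert summary.targeted_genes["novel-interactor"] == {"N"}


def test_bipartite_sif_export(tmp_path):
    from hippip.netstats import write_bipartite_sif

    g = _drug_graph()
    table = DrugTargetTable(
        [DrugRecord("DrugA", ("N05A",), "N"), DrugRecord("DrugB", ("C01A",), "K")]
    )
    summary = drug_target_summary(g, table)
    out = tmp_path / "drugs.sif"
    write_bipartite_sif(summary, out)
    lines = {tuple(l.split("\t")) for l in out.read_text().splitlines()}
    assert lines == {("DrugA", "targets", "N"), ("DrugB", "targets", "K")}


def test_drug_summary_matches_groupby_oracle(small_synth):
    from hippip.synth import generate_drug_targets

    universe, truth = small_synth
    table = generate_drug_targets(truth, n_drugs=20, seed=6)
    g = nx.Graph()
    roles = {}
    for i, gene in enumerate(sorted(universe.catalog.symbols)):
        role = ["seed", "known-interactor", "novel-interactor"][i % 3]
        g.add_node(gene, role=role)
        roles[gene] = role
    summary = drug_target_summary(g, table)
    # brute-force group-by
    expected: dict[str, int] = {}
    for drug in sorted({r.drug for r in table.records}):
        recs = [r for r in table.records if r.drug == drug]
        cats = set()
        for r in recs:
            cats |= atc_anatomic_categories(r.atc_codes)
        for c in cats:
            expected[c] = expected.get(c, 0) + 1
    got = dict(zip(summary.by_category["category"], summary.by_category["n_drugs"]))
    assert got == expected


def test_distance_report_drop(universe7, model7):
    universe, _ = universe7
    g = nx.Graph()
    g.add_edges_from(universe.known_ppis.pairs())
    predicted = PPIEdgeList()
    genes = sorted(universe.catalog.symbols)[:10]
    report = distance_report(g, predicted, genes, label="no predictions")
    # without predicted edges the two averages coincide and the drop is zero
    assert report.drop == pytest.approx(0.0)
    assert report.with_predicted.mean == report.without_predicted.mean
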