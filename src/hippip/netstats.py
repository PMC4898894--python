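"""Network statistics over the interactome.

Shortest-path averages between gene-set members (with and without predicted
edges, on top of the full known background network), a permutation null for
the distance drop over random gene sets, nearest-member distance histograms,
hypergeometric overlap and term enrichment, and drug-target summaries split
by ATC anatomic category.

All graphs are unweighted and undirected; distances are BFS path lengths.
Disconnected pairs are excluded from averages and reported as counts.
Empirical P values use the add-one estimator P = (1 + #{null >= obs}) / (N + 1),
so P is never exactly 0.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .annot_io import DrugTargetTable, GeneCatalog, Pair, PPIEdgeList

logger = logging.getLogger(__name__)

_ATC_PATTERN = re.compile(r"^[A-Z]\d\d")


# ---------------------------------------------------------------------------
# shortest-path statistics
# ---------------------------------------------------------------------------

@dataclass
class DistanceSummary:
    mean: float  # nan when no connected pair exists
    n_connected: int
    n_disconnected: int


@dataclass
class DistanceReport:
    """Average shortest-path length of a gene set, with vs without predicted edges."""

    label: str
    with_predicted: DistanceSummary
    without_predicted: DistanceSummary

    @property
    def drop(self) -> float:
        return self.without_predicted.mean - self.with_predicted.mean


def average_distance(graph: nx.Graph, gene_set: Iterable[str]) -> DistanceSummary:
    """Mean BFS shortest-path length over connected unordered pairs of the set.

    Genes absent from the graph count as disconnected from everything.
    """
    genes = sorted(set(gene_set))
    if len(genes) < 2:
        raise ValueError("gene set must contain at least 2 genes")
    total = 0
    n_conn = 0
    n_disc = 0
    for i, a in enumerate(genes):
        if a not in graph:
            n_disc += len(genes) - i - 1
            continue
        lengths = nx.single_source_shortest_path_length(graph, a)
        for b in genes[i + 1:]:
            d = lengths.get(b)
            if d is None:
                n_disc += 1
            else:
                total += d
                n_conn += 1
    mean = total / n_conn if n_conn else float("nan")
    return DistanceSummary(mean=mean, n_connected=n_conn, n_disconnected=n_disc)


def _augmented(graph: nx.Graph, extra_edges: Iterable[Pair]) -> nx.Graph:
    g = graph.copy()
    g.add_edges_from(extra_edges)
    return g


def _edges_touching(predicted: PPIEdgeList, genes: set[str]) -> list[Pair]:
    return [p for p in predicted.edges if p[0] in genes or p[1] in genes]


def distance_report(
    graph: nx.Graph,
    predicted: PPIEdgeList,
    gene_set: Iterable[str],
    label: str = "",
) -> DistanceReport:
    """Distance drop for *gene_set* when its predicted edges are added to the
    background graph."""
    genes = set(gene_set)
    with_g = _augmented(graph, _edges_touching(predicted, genes))
    return DistanceReport(
        label=label,
        with_predicted=average_distance(with_g, genes),
        without_predicted=average_distance(graph, genes),
    )


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p_value: float
    seed: int | None = None
    n_trials: int = 0


def distance_drop_test(
    graph: nx.Graph,
    predicted: PPIEdgeList,
    gene_set: Iterable[str],
    catalog: GeneCatalog | Sequence[str],
    n_trials: int = 1000,
    seed: int | None = None,
) -> PermutationResult:
    """Permutation test: is the gene set's distance drop larger than that of
    random gene sets of equal size?

    *predicted* must be a catalog-wide prediction set (every catalog pair
    scored once); the predicted edges of any gene set — observed or random —
    are then the cached edges touching it, which is identical to scanning
    that set with the model.  P = (1 + #{null >= observed}) / (n_trials + 1).
    """
    genes = sorted(set(gene_set))
    symbols = sorted(catalog.symbols if isinstance(catalog, GeneCatalog) else set(catalog))
    if len(symbols) < 2 * len(genes):
        raise ValueError("catalog too small relative to the gene set for a null")
    # the unaugmented background is shared by every trial: solve it once
    base_spl = dict(nx.all_pairs_shortest_path_length(graph))

    def _drop(gene_list) -> float:
        gs = sorted(set(gene_list))
        with_g = _augmented(graph, _edges_touching(predicted, set(gs)))
        with_summary = average_distance(with_g, gs)
        total = n_conn = 0
        for i, a in enumerate(gs):
            lengths = base_spl.get(a, {})
            for b in gs[i + 1:]:
                d = lengths.get(b)
                if d is not None:
                    total += d
                    n_conn += 1
        without_mean = total / n_conn if n_conn else float("nan")
        return without_mean - with_summary.mean

    observed = _drop(genes)
    rng = np.random.default_rng(seed)
    null = np.empty(n_trials, dtype=float)
    for t in range(n_trials):
        rand_set = rng.choice(symbols, size=len(genes), replace=False)
        null[t] = _drop(rand_set)
    finite_null = null[np.isfinite(null)]
    n_ge = int(np.sum(finite_null >= observed)) if np.isfinite(observed) else len(finite_null)
    p = (1 + n_ge) / (n_trials + 1)
    return PermutationResult(
        observed=float(observed), null=null, p_value=p, seed=seed, n_trials=n_trials
    )


def shortest_path_histogram(
    graph: nx.Graph, set_a: Iterable[str], set_b: Iterable[str]
) -> pd.DataFrame:
    """Distance from each A-gene to its nearest B-gene (self excluded).

    Returns one row per A-gene with columns ``gene``, ``distance`` (NaN when
    unreachable) and ``reachable``; unreachable genes go to their own bin and
    are never averaged.
    """
    a_genes = sorted(set(set_a))
    b_genes = set(set_b)
    if not a_genes or not b_genes:
        raise ValueError("both gene sets must be non-empty")
    rows = []
    for a in a_genes:
        targets = b_genes - {a}
        dist = float("nan")
        if a in graph and targets:
            lengths = nx.single_source_shortest_path_length(graph, a)
            hits = [lengths[b] for b in targets if b in lengths]
            if hits:
                dist = float(min(hits))
        rows.append(dict(gene=a, distance=dist, reachable=np.isfinite(dist)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hypergeometric overlap and enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentRow:
    term: str
    overlap: int      # k
    query_size: int   # n drawn
    term_size: int    # K marked
    universe_size: int
    p_value: float
    p_adjusted: float = field(default=float("nan"))


def hypergeom_overlap(
    set_a: Iterable[str], set_b: Iterable[str], universe_size: int, label: str = "overlap"
) -> EnrichmentRow:
    """Upper-tail hypergeometric P of observing at least |A∩B| shared genes
    when |A| genes are drawn from a universe of M with |B| marked."""
    a, b = set(set_a), set(set_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("set larger than the universe")
    k = len(a & b)
    p = float(hypergeom.sf(k - 1, universe_size, len(b), len(a)))
    # extreme overlaps underflow sf to 0.0; keep P in (0, 1]
    p = max(min(p, 1.0), 5e-324)
    return EnrichmentRow(
        term=label,
        overlap=k,
        query_size=len(a),
        term_size=len(b),
        universe_size=universe_size,
        p_value=p,
        p_adjusted=p,
    )


_CORRECTIONS = {"bh": "fdr_bh", "bonferroni": "bonferroni", "none": None}


def term_enrichment(
    genes: Iterable[str],
    term_table: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    correction: str = "bh",
) -> pd.DataFrame:
    """Hypergeometric enrichment of each term among *genes*.

    *term_table* maps gene -> terms; only terms overlapping the query appear,
    sorted by adjusted then raw P.  Correction: Benjamini-Hochberg (default),
    Bonferroni, or none.
    """
    if correction not in _CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}")
    if not term_table:
        raise ValueError("empty term table")
    uni = set(universe)
    query = set(genes) & uni
    term_to_genes: dict[str, set[str]] = {}
    for gene, terms in term_table.items():
        if gene not in uni:
            continue
        for t in terms:
            term_to_genes.setdefault(t, set()).add(gene)
    rows = []
    for term, members in sorted(term_to_genes.items()):
        k = len(query & members)
        if k == 0:
            continue
        p = float(hypergeom.sf(k - 1, len(uni), len(members), len(query)))
        rows.append(
            dict(
                term=term,
                overlap=k,
                query_size=len(query),
                term_size=len(members),
                universe_size=len(uni),
                p_value=max(min(p, 1.0), 5e-324),
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["term", "overlap", "query_size", "term_size", "universe_size", "p_value"],
    )
    if len(df):
        method = _CORRECTIONS[correction]
        if method is None:
            df["p_adjusted"] = df["p_value"]
        else:
            df["p_adjusted"] = multipletests(df["p_value"].to_numpy(), method=method)[1]
        df = df.sort_values(["p_adjusted", "p_value", "term"]).reset_index(drop=True)
    else:
        df["p_adjusted"] = pd.Series(dtype=float)
    return df


# ---------------------------------------------------------------------------
# drug-target summaries
# ---------------------------------------------------------------------------

@dataclass
class DrugTargetSummary:
    """Drug counts per ATC anatomic category, split by target role."""

    by_category: pd.DataFrame  # category, n_drugs, n_drugs_known, n_drugs_novel, n_drugs_both
    drug_roles: dict[str, str]            # drug -> known / novel / both
    targeted_genes: dict[str, set[str]]   # role -> genes of the interactome targeted
    bipartite_edges: list[tuple[str, str]]  # (drug, gene) links into the interactome


def atc_anatomic_categories(codes: Iterable[str]) -> set[str]:
    """First letters of ATC codes; malformed codes map to 'unknown'."""
    cats = set()
    for code in codes:
        code = code.strip().upper()
        if not code:
            continue
        if _ATC_PATTERN.match(code):
            cats.add(code[0])
        else:
            logger.warning("malformed ATC code %r -> category 'unknown'", code)
            cats.add("unknown")
    return cats


def drug_target_summary(graph: nx.Graph, drugs: DrugTargetTable) -> DrugTargetSummary:
    """Cross the interactome with a drug-target table.

    A drug is counted once per anatomic category it belongs to (drugs with
    several ATC codes may land in several categories).  Role is "known" if
    the drug targets only known interactors of the graph, "novel" if only
    novel interactors (or seeds reached solely by predicted edges), "both"
    otherwise.
    """
    roles = nx.get_node_attributes(graph, "role")
    drug_targets: dict[str, set[str]] = {}
    drug_cats: dict[str, set[str]] = {}
    bipartite: list[tuple[str, str]] = []
    for rec in drugs.records:
        if rec.target not in roles:
            continue
        drug_targets.setdefault(rec.drug, set()).add(rec.target)
        drug_cats.setdefault(rec.drug, set()).update(atc_anatomic_categories(rec.atc_codes))
        bipartite.append((rec.drug, rec.target))
    drug_roles: dict[str, str] = {}
    for drug, targets in drug_targets.items():
        hit_known = any(roles[t] in ("known-interactor", "seed") for t in targets)
        hit_novel = any(roles[t] == "novel-interactor" for t in targets)
        drug_roles[drug] = (
            "both" if (hit_known and hit_novel) else "novel" if hit_novel else "known"
        )
    cat_rows: dict[str, dict[str, int]] = {}
    for drug, cats in drug_cats.items():
        role = drug_roles[drug]
        for cat in cats or {"unknown"}:
            row = cat_rows.setdefault(
                cat, dict(n_drugs=0, n_drugs_known=0, n_drugs_novel=0, n_drugs_both=0)
            )
            row["n_drugs"] += 1
            row[f"n_drugs_{role}"] += 1
    by_category = (
        pd.DataFrame(
            [dict(category=c, **row) for c, row in sorted(cat_rows.items())],
            columns=["category", "n_drugs", "n_drugs_known", "n_drugs_novel", "n_drugs_both"],
        )
    )
    targeted: dict[str, set[str]] = {"seed": set(), "known-interactor": set(), "novel-interactor": set()}
    for targets in drug_targets.values():
        for t in targets:
            targeted[roles[t]].add(t)
    return DrugTargetSummary(
        by_category=by_category,
        drug_roles=drug_roles,
        targeted_genes=targeted,
        bipartite_edges=sorted(set(bipartite)),
    )


def write_bipartite_sif(summary: DrugTargetSummary, path) -> None:
    """Export the drug-gene links as a SIF file for network viewers."""
    with open(path, "w") as fh:
        for drug, gene in summary.bipartite_edges:
            fh.write(f"{drug}\ttargets\t{gene}\n")
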