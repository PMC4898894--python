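"""Disease interactome construction.

Each seed gene is paired with every other gene in the catalog and scored by
the trained model; pairs scoring strictly above the threshold (default 0.5)
and not already known are the novel PPIs.  Combined with the previously
known PPIs of the seed genes they form the disease interactome — a union of
stars around the seeds, with per-node roles (seed / known-interactor /
novel-interactor) and per-edge provenance (known / predicted, with score).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .annot_io import AnnotationUniverse, Pair, PPIEdgeList, canonical_pair
from .model import HiPPIPClassifier

logger = logging.getLogger(__name__)

SCAN_THRESHOLD = 0.5
AMBIGUOUS_BAND = (0.4, 0.5)


@dataclass
class SeedGeneSet:
    """Labelled seed-gene lists (e.g. "GWAS", "Historic") with per-gene tags."""

    lists: dict[str, list[str]]

    def __post_init__(self) -> None:
        self.lists = {
            label: [g.upper() for g in genes] for label, genes in self.lists.items()
        }
        for label, genes in self.lists.items():
            if len(set(genes)) != len(genes):
                raise ValueError(f"duplicate genes within seed list {label!r}")

    @property
    def union(self) -> set[str]:
        out: set[str] = set()
        for genes in self.lists.values():
            out |= set(genes)
        return out

    def tags(self) -> dict[str, tuple[str, ...]]:
        """Gene -> sorted tuple of list labels carrying it."""
        t: dict[str, set[str]] = {}
        for label, genes in self.lists.items():
            for g in genes:
                t.setdefault(g, set()).add(label)
        return {g: tuple(sorted(ls)) for g, ls in t.items()}

    @classmethod
    def from_files(cls, **label_to_path) -> "SeedGeneSet":
        lists = {}
        for label, path in label_to_path.items():
            lists[label] = [
                line.strip()
                for line in Path(path).read_text().splitlines()
                if line.strip()
            ]
        return cls(lists)


@dataclass
class ScanResult:
    """Outcome of a genome scan: retained novel edges plus the ambiguous band."""

    predicted: PPIEdgeList
    ambiguous: PPIEdgeList
    n_scored: int
    threshold: float = SCAN_THRESHOLD


def candidate_pairs(seeds: Iterable[str], catalog_symbols: Iterable[str]) -> list[Pair]:
    """All seed x (catalog - seed) pairs, each unordered pair once."""
    seed_set = set(seeds)
    out: set[Pair] = set()
    for s in seed_set:
        for g in catalog_symbols:
            if g != s:
                out.add(canonical_pair(s, g))
    return sorted(out)


def genome_scan(
    seeds: SeedGeneSet | Sequence[str],
    universe: AnnotationUniverse,
    model: HiPPIPClassifier,
    threshold: float = SCAN_THRESHOLD,
    known: PPIEdgeList | None = None,
    ambiguous_band: tuple[float, float] = AMBIGUOUS_BAND,
) -> ScanResult:
    """Score every seed x catalog pair and keep novel predictions above threshold.

    Seeds missing from the catalog are skipped with a warning.  Pairs already
    in the known-PPI set are excluded from the novel output.  Pairs in the
    ambiguous score band (default (0.4, 0.5]) are reported separately and do
    not enter the interactome.
    """
    seed_genes = seeds.union if isinstance(seeds, SeedGeneSet) else set(seeds)
    if not seed_genes:
        raise ValueError("empty seed set")
    resolved: set[str] = set()
    for s in seed_genes:
        c = universe.catalog.canonicalize(s)
        if c is None:
            logger.warning("seed %s not in catalog; skipped", s)
        else:
            resolved.add(c)
    if not resolved:
        raise ValueError("no seed resolves against the catalog")
    known = known if known is not None else universe.known_ppis
    cands = candidate_pairs(resolved, universe.catalog.symbols)
    scores = model.decision_scores(cands)
    predicted = PPIEdgeList()
    ambiguous = PPIEdgeList()
    lo, hi = ambiguous_band
    for pair, score in zip(cands, scores):
        if pair in known:
            continue
        if score > threshold:
            predicted.add(*pair, source="predicted", score=float(score))
        elif lo < score <= hi:
            ambiguous.add(*pair, source="ambiguous", score=float(score))
    return ScanResult(
        predicted=predicted, ambiguous=ambiguous, n_scored=len(cands), threshold=threshold
    )


def full_scan(
    universe: AnnotationUniverse,
    model: HiPPIPClassifier,
    threshold: float = SCAN_THRESHOLD,
) -> PPIEdgeList:
    """Score every catalog pair once; novel predictions above threshold.

    Useful as a reusable prediction cache: the novel partners of any gene set
    are then the cached edges touching it, identical to scanning that set.
    """
    symbols = sorted(universe.catalog.symbols)
    cands = list(itertools.combinations(symbols, 2))
    scores = model.decision_scores(cands)
    predicted = PPIEdgeList()
    for pair, score in zip(cands, scores):
        if score > threshold and pair not in universe.known_ppis:
            predicted.add(*pair, source="predicted", score=float(score))
    return predicted


@dataclass
class InteractomeSummary:
    n_seeds: int
    n_known_edges: int
    n_novel_edges: int
    n_known_interactors: int
    n_novel_interactors: int
    seeds_without_known_ppis: list[str] = field(default_factory=list)
    newly_connected_seeds: list[str] = field(default_factory=list)
    n_novel_edges_of_newly_connected: int = 0


def assemble_interactome(
    seeds: SeedGeneSet | Sequence[str],
    known: PPIEdgeList,
    predicted: PPIEdgeList,
    catalog_symbols: Iterable[str] | None = None,
) -> nx.Graph:
    """Merge known and predicted seed edges into one undirected graph.

    Node roles: seed > known-interactor > novel-interactor.  An edge both
    known and predicted keeps source "known".  Only edges touching a seed
    enter the graph.
    """
    seed_genes = seeds.union if isinstance(seeds, SeedGeneSet) else set(seeds)
    g = nx.Graph()
    if catalog_symbols is not None:
        g.graph["catalog"] = frozenset(catalog_symbols)
    tags = seeds.tags() if isinstance(seeds, SeedGeneSet) else {s: () for s in seed_genes}
    for s in seed_genes:
        g.add_node(s, role="seed", seed_lists=",".join(tags.get(s, ())))
    for (a, b), source in known.edges.items():
        if a in seed_genes or b in seed_genes:
            g.add_edge(a, b, source="known")
    for (a, b), source in predicted.edges.items():
        if a not in seed_genes and b not in seed_genes:
            continue
        if g.has_edge(a, b):  # known wins over predicted
            continue
        g.add_edge(a, b, source="predicted", score=predicted.scores.get((a, b)))
    for n in g.nodes:
        if n in seed_genes:
            g.nodes[n]["role"] = "seed"
            continue
        has_known = any(
            g.edges[n, m].get("source") == "known" for m in g.neighbors(n)
        )
        g.nodes[n]["role"] = "known-interactor" if has_known else "novel-interactor"
    return g


def summarize_interactome(
    graph: nx.Graph, seeds: SeedGeneSet | Sequence[str], known: PPIEdgeList
) -> InteractomeSummary:
    """Headline counts: edges by provenance, interactor roles, and seeds with
    no previously known PPIs that gained novel ones."""
    seed_genes = seeds.union if isinstance(seeds, SeedGeneSet) else set(seeds)
    known_deg = known.degrees()
    n_known = sum(1 for *_, d in graph.edges(data=True) if d["source"] == "known")
    n_novel = graph.number_of_edges() - n_known
    roles = nx.get_node_attributes(graph, "role")
    zero_known = sorted(s for s in seed_genes if known_deg.get(s, 0) == 0)
    newly_connected = []
    novel_of_new = 0
    for s in zero_known:
        if s in graph:
            novel = [
                m for m in graph.neighbors(s)
                if graph.edges[s, m].get("source") == "predicted"
            ]
            if novel:
                newly_connected.append(s)
                novel_of_new += len(novel)
    return InteractomeSummary(
        n_seeds=len(seed_genes),
        n_known_edges=n_known,
        n_novel_edges=n_novel,
        n_known_interactors=sum(1 for r in roles.values() if r == "known-interactor"),
        n_novel_interactors=sum(1 for r in roles.values() if r == "novel-interactor"),
        seeds_without_known_ppis=zero_known,
        newly_connected_seeds=newly_connected,
        n_novel_edges_of_newly_connected=novel_of_new,
    )


def interactome_overlap(graph_a: nx.Graph, graph_b: nx.Graph) -> set[str]:
    """Genes present in both interactome graphs (any role)."""
    cat_a = graph_a.graph.get("catalog")
    cat_b = graph_b.graph.get("catalog")
    if cat_a is not None and cat_b is not None and cat_a != cat_b:
        raise ValueError("interactomes were built over different catalogs")
    return set(graph_a.nodes) & set(graph_b.nodes)
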