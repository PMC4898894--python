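"""Self-contained synthetic annotation universe with a planted interaction rule.

Genes are organised into functional clusters.  Cluster membership drives
every annotation source the way co-functionality does in real data: genes of
a cluster share GO terms (sampled down a random is_a DAG), correlate in
expression (latent-factor model: one factor per cluster), carry the
cluster's signature protein domains and tissue labels.  True interactions
are planted by a rule whose score increases with GO overlap, co-expression
and compatible domain pairs; the observed known-PPI list is a random
subsample of the truth, mirroring the incompleteness of interaction
databases (far more interactions exist than are catalogued).

Everything is deterministic given the config seed, and the universe can be
round-tripped through the standard file formats (GAF, OBO, TSV, BED).
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annot_io import (
    UNIVERSE_FILES,
    AnnotationUniverse,
    DomainTable,
    DrugRecord,
    DrugTargetTable,
    ExpressionMatrix,
    GeneCatalog,
    GeneLocusTable,
    GOAnnotationTable,
    Pair,
    PPIEdgeList,
    TissueTable,
    canonical_pair,
)
from .interactome import SeedGeneSet

_ASPECT_NAMESPACE = {
    "BP": "biological_process",
    "MF": "molecular_function",
    "CC": "cellular_component",
}
_ASPECT_CODE = {"BP": "P", "MF": "F", "CC": "C"}


@dataclass
class SynthConfig:
    """Parameters of the synthetic universe generator.

    The defaults give a desk-scale universe (300 genes) on which a full
    train / evaluate / scan / statistics pipeline runs in well under a
    minute while keeping enough planted signal for the forest to recover.
    """

    n_genes: int = 300
    n_clusters: int = 16
    go_terms_per_aspect: int = 60
    dag_depth: int = 4
    terms_per_gene: int = 2          # direct annotations per aspect from the cluster module
    n_conditions: int = 40
    expression_noise: float = 0.5    # sd of gene-level noise around the cluster factor
    n_domains: int = 36
    n_tissues: int = 15
    n_chromosomes: int = 10
    chromosome_length: int = 100_000_000
    rule_weights: dict = field(
        default_factory=lambda: {"go": 1.0, "coexpr": 1.0, "domain": 1.0}
    )
    edge_density: float = 0.02       # fraction of all pairs that truly interact
    background_edge_fraction: float = 0.08  # extra uniform (cross-cluster) true edges
    noise: float = 0.05              # sd of the noise added to the planted rule score
    observed_fraction: float = 0.85  # fraction of true edges present in known_ppis
    understudied_fraction: float = 0.25  # fraction of genes that are under-studied
    understudied_retention: float = 0.3  # relative observation weight of their edges
    n_drugs: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_genes", "n_clusters", "go_terms_per_aspect", "dag_depth",
            "n_conditions", "n_domains", "n_tissues", "n_chromosomes", "n_drugs",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.edge_density < 1:
            raise ValueError("edge_density must lie in (0, 1)")
        if not 0 <= self.background_edge_fraction < 1:
            raise ValueError("background_edge_fraction must lie in [0, 1)")
        if not 0 < self.observed_fraction <= 1:
            raise ValueError("observed_fraction must lie in (0, 1]")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")


@dataclass
class GroundTruth:
    """The planted truth: all true pairs, of which known_ppis is a subsample."""

    truth: set[Pair]
    known: PPIEdgeList
    clusters: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.known.pairs() <= self.truth:
            raise ValueError("known edges must be a subset of the truth")

    def degrees(self) -> dict[str, int]:
        deg: dict[str, int] = {}
        for a, b in self.truth:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        return deg

    def unobserved_degrees(self) -> dict[str, int]:
        """Per-gene count of true interactions absent from the known list."""
        deg: dict[str, int] = {}
        for a, b in self.truth - self.known.pairs():
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        return deg


# ---------------------------------------------------------------------------
# generator internals
# ---------------------------------------------------------------------------

def _random_dag(
    aspect_index: int, n_terms: int, depth: int, rng: np.random.Generator
) -> tuple[list[str], dict[str, frozenset[str]]]:
    """Random is_a tree of *n_terms* terms rooted at term 0, max depth *depth*."""
    terms = [f"GO:{aspect_index + 1}{i:06d}" for i in range(n_terms)]
    parents: dict[str, frozenset[str]] = {terms[0]: frozenset()}
    depths = {terms[0]: 0}
    for t in terms[1:]:
        eligible = [u for u in parents if depths[u] < depth - 1]
        parent = eligible[rng.integers(len(eligible))]
        parents[t] = frozenset({parent})
        depths[t] = depths[parent] + 1
    return terms, parents


def _pair_index(n: int) -> list[tuple[int, int]]:
    return list(itertools.combinations(range(n), 2))


def generate_universe(config: SynthConfig) -> tuple[AnnotationUniverse, GroundTruth]:
    """Generate the annotation universe and its planted ground truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [f"G{i:04d}" for i in range(1, n + 1)]
    clusters = rng.integers(0, config.n_clusters, size=n)

    # --- GO: per-aspect random DAG, cluster term modules, gene annotations
    parents: dict[str, frozenset[str]] = {}
    annotations: dict[str, dict[str, set[str]]] = {"BP": {}, "MF": {}, "CC": {}}
    for ai, aspect in enumerate(("BP", "MF", "CC")):
        terms, asp_parents = _random_dag(
            ai, config.go_terms_per_aspect, config.dag_depth, rng
        )
        parents.update(asp_parents)
        non_root = terms[1:]
        module_size = max(3, config.terms_per_gene + 2)
        modules = [
            rng.choice(non_root, size=min(module_size, len(non_root)), replace=False)
            for _ in range(config.n_clusters)
        ]
        for gi, g in enumerate(genes):
            module = modules[clusters[gi]]
            k = min(config.terms_per_gene, len(module))
            chosen = set(rng.choice(module, size=k, replace=False).tolist())
            chosen.add(non_root[rng.integers(len(non_root))])  # background annotation
            annotations[aspect][g] = chosen
    go = GOAnnotationTable(annotations, parents)

    # --- expression: latent factor per cluster plus gene noise
    factors = rng.standard_normal((config.n_clusters, config.n_conditions))
    expr_values = factors[clusters] + config.expression_noise * rng.standard_normal(
        (n, config.n_conditions)
    )
    expr = ExpressionMatrix(
        pd.DataFrame(
            np.round(expr_values, 5),
            index=pd.Index(genes),
            columns=[f"cond{j:02d}" for j in range(config.n_conditions)],
        )
    )

    # --- domains: two signature domains per cluster; ~10% of genes domain-free
    domain_pool = [f"D{i:03d}" for i in range(config.n_domains)]
    signature = rng.integers(0, config.n_domains, size=(config.n_clusters, 2))
    compatible: set[Pair] = {
        canonical_pair(domain_pool[a], domain_pool[b]) for a, b in signature
    }
    dom_assign: dict[str, frozenset[str]] = {}
    for gi, g in enumerate(genes):
        if rng.random() < 0.1:
            dom_assign[g] = frozenset()
            continue
        ds = {domain_pool[signature[clusters[gi], rng.integers(2)]]}
        if rng.random() < 0.3:
            ds.add(domain_pool[rng.integers(config.n_domains)])
        dom_assign[g] = frozenset(ds)
    domains = DomainTable(dom_assign)

    # --- tissues: three per cluster plus occasional extras; ~5% empty
    tissue_pool = [f"tissue{i:02d}" for i in range(config.n_tissues)]
    cluster_tissues = [
        set(rng.choice(tissue_pool, size=min(3, config.n_tissues), replace=False).tolist())
        for _ in range(config.n_clusters)
    ]
    tis_assign: dict[str, frozenset[str]] = {}
    for gi, g in enumerate(genes):
        if rng.random() < 0.05:
            tis_assign[g] = frozenset()
            continue
        ts = set(cluster_tissues[clusters[gi]])
        if rng.random() < 0.3:
            ts.add(tissue_pool[rng.integers(config.n_tissues)])
        tis_assign[g] = frozenset(ts)
    tissues = TissueTable(tis_assign)

    # --- loci
    loci: dict[str, tuple[str, int, int]] = {}
    for g in genes:
        chrom = f"chr{int(rng.integers(1, config.n_chromosomes + 1))}"
        start = int(rng.integers(0, config.chromosome_length - 200_000))
        end = start + int(rng.integers(1_000, 200_000))
        loci[g] = (chrom, start, end)
    locus_table = GeneLocusTable(loci)

    # --- planted rule over all pairs
    idx = _pair_index(n)
    go_shared = np.empty(len(idx), dtype=float)
    closures = {
        g: tuple(go.annotated_closure(g, a) for a in ("BP", "MF", "CC")) for g in genes
    }
    for k, (i, j) in enumerate(idx):
        ca, cb = closures[genes[i]], closures[genes[j]]
        go_shared[k] = sum(len(x & y) for x, y in zip(ca, cb))
    corr = np.corrcoef(expr_values)
    coexpr = np.array([corr[i, j] for i, j in idx])
    dom_compat = np.array(
        [
            float(
                any(
                    canonical_pair(da, db) in compatible
                    for da in dom_assign[genes[i]]
                    for db in dom_assign[genes[j]]
                )
            )
            for i, j in idx
        ]
    )
    w = config.rule_weights
    go_norm = go_shared / max(go_shared.max(), 1.0)
    z = (
        w.get("go", 0.0) * go_norm
        + w.get("coexpr", 0.0) * coexpr
        + w.get("domain", 0.0) * dom_compat
    )
    if config.noise > 0:
        z = z + config.noise * rng.standard_normal(len(idx))
    cutoff = np.quantile(z, 1.0 - config.edge_density)
    truth = {
        canonical_pair(genes[i], genes[j])
        for k, (i, j) in enumerate(idx)
        if z[k] > cutoff
    }
    # A minority of true interactions crosses functional modules (real
    # interactomes have a giant connected component, not isolated pathways);
    # these carry no annotation signal by construction.
    n_background = int(round(config.background_edge_fraction * len(truth)))
    if n_background:
        non_edges = [
            canonical_pair(genes[i], genes[j])
            for i, j in idx
            if canonical_pair(genes[i], genes[j]) not in truth
        ]
        bg_idx = rng.choice(len(non_edges), size=n_background, replace=False)
        truth |= {non_edges[i] for i in bg_idx}

    # --- observed (known) edges: biased subsample of the truth.
    # Interaction databases over-represent well-studied genes; a fraction of
    # genes is marked under-studied and their true edges are observed with a
    # proportionally lower weight.  The total count stays exactly
    # round(observed_fraction * |truth|).
    truth_sorted = sorted(truth)
    n_known = int(round(config.observed_fraction * len(truth_sorted)))
    n_under = int(round(config.understudied_fraction * n))
    understudied = set(rng.choice(genes, size=n_under, replace=False).tolist())
    retention = {
        g: (config.understudied_retention if g in understudied else 1.0) for g in genes
    }
    weights = np.array([retention[a] * retention[b] for a, b in truth_sorted])
    known_idx = rng.choice(
        len(truth_sorted), size=n_known, replace=False, p=weights / weights.sum()
    )
    known = PPIEdgeList()
    for i in sorted(known_idx):
        known.add(*truth_sorted[i], source="known")

    catalog = GeneCatalog(frozenset(genes))
    universe = AnnotationUniverse(
        catalog=catalog,
        go=go,
        expr=expr,
        domains=domains,
        loci=locus_table,
        tissues=tissues,
        known_ppis=known,
    )
    ground_truth = GroundTruth(
        truth=truth,
        known=known,
        clusters={g: int(c) for g, c in zip(genes, clusters)},
    )
    return universe, ground_truth


# ---------------------------------------------------------------------------
# seed panels and drug tables
# ---------------------------------------------------------------------------

def make_seed_panel(
    truth: GroundTruth | PPIEdgeList,
    k_gwas: int = 77,
    k_historic: int = 25,
    k_shared: int = 1,
    seed: int | None = None,
    labels: tuple[str, str] = ("GWAS", "Historic"),
) -> SeedGeneSet:
    """Two labelled seed lists of the stated sizes sharing exactly *k_shared*
    genes, preferentially sampled among genes with many true interactions
    that are disproportionately unobserved.

    Disease-gene panels in the motivating setting are under-studied: many
    true partners, few catalogued ones.  Given a :class:`GroundTruth` the
    sampling weight is the gene's unobserved true degree; given a plain edge
    list it falls back to the (observed) degree.  The default panel sizes
    (77 and 25 with one shared gene, 101 distinct) mirror the disease-gene
    panels the pipeline is designed around.
    """
    if k_shared > min(k_gwas, k_historic):
        raise ValueError("k_shared cannot exceed the smaller panel size")
    if isinstance(truth, GroundTruth):
        degrees = truth.degrees()
        weight_of = truth.unobserved_degrees()
        offset = 0.25
    elif isinstance(truth, PPIEdgeList):
        degrees = truth.degrees()
        weight_of = degrees
        offset = 1.0
    else:
        degrees = dict(truth)
        weight_of = degrees
        offset = 1.0
    genes = sorted(degrees)
    n_needed = k_gwas + k_historic - k_shared
    if n_needed > len(genes):
        raise ValueError(
            f"panel needs {n_needed} distinct genes, only {len(genes)} have degree > 0"
        )
    weights = np.array([weight_of.get(g, 0) + offset for g in genes])
    rng = np.random.default_rng(seed)
    chosen = rng.choice(genes, size=n_needed, replace=False, p=weights / weights.sum())
    shared = list(chosen[:k_shared])
    gwas = shared + list(chosen[k_shared:k_gwas])
    historic = shared + list(chosen[k_gwas:])
    return SeedGeneSet({labels[0]: gwas, labels[1]: historic})


def generate_drug_targets(
    truth: GroundTruth,
    n_drugs: int = 60,
    seed: int | None = None,
) -> DrugTargetTable:
    """Synthetic drug-target table: each drug carries 1-2 ATC codes and
    targets 1-3 genes, biased toward high-degree genes."""
    rng = np.random.default_rng(seed)
    degrees = truth.degrees()
    genes = sorted(truth.clusters) if truth.clusters else sorted(degrees)
    weights = np.array([degrees.get(g, 0) + 1.0 for g in genes])
    weights = weights / weights.sum()
    letters = list("ACGJLMNPRSV")
    records: list[DrugRecord] = []
    for d in range(n_drugs):
        name = f"Drug{d + 1:03d}"
        n_codes = int(rng.integers(1, 3))
        codes = tuple(
            f"{letters[rng.integers(len(letters))]}{rng.integers(1, 17):02d}A"
            for _ in range(n_codes)
        )
        n_targets = int(rng.integers(1, 4))
        targets = rng.choice(genes, size=n_targets, replace=False, p=weights)
        for t in targets:
            records.append(DrugRecord(drug=name, atc_codes=codes, target=str(t)))
    return DrugTargetTable(records)


# ---------------------------------------------------------------------------
# file export (round-trips through annot_io readers)
# ---------------------------------------------------------------------------

def write_universe(
    universe: AnnotationUniverse,
    directory: str | os.PathLike,
    drugs: DrugTargetTable | None = None,
    seeds: SeedGeneSet | None = None,
) -> Path:
    """Write the universe to a directory in the standard file formats."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    (d / UNIVERSE_FILES["catalog"]).write_text(
        "".join(f"{g}\n" for g in sorted(universe.catalog.symbols))
    )
    with open(d / UNIVERSE_FILES["known_ppis"], "w") as fh:
        fh.write("gene1\tgene2\n")
        for a, b in sorted(universe.known_ppis.pairs()):
            fh.write(f"{a}\t{b}\n")
    _write_obo(universe.go, d / UNIVERSE_FILES["obo"])
    _write_gaf(universe.go, d / UNIVERSE_FILES["gaf"])
    universe.expr.data.to_csv(d / UNIVERSE_FILES["expression"], sep="\t", index_label="gene")
    with open(d / UNIVERSE_FILES["domains"], "w") as fh:
        fh.write("gene\tdomain\n")
        for g in sorted(universe.domains.genes()):
            for dom in sorted(universe.domains.domains(g)):
                fh.write(f"{g}\t{dom}\n")
    with open(d / UNIVERSE_FILES["loci"], "w") as fh:
        for g in sorted(universe.loci.genes()):
            chrom, start, end = universe.loci.locus(g)
            fh.write(f"{chrom}\t{start}\t{end}\t{g}\n")
    with open(d / UNIVERSE_FILES["tissues"], "w") as fh:
        fh.write("gene\ttissue\n")
        for g in sorted(universe.tissues.genes()):
            for t in sorted(universe.tissues.tissues(g)):
                fh.write(f"{g}\t{t}\n")
    if drugs is not None:
        with open(d / UNIVERSE_FILES["drugs"], "w") as fh:
            fh.write("drug\tatc_codes\ttarget\n")
            for rec in drugs.records:
                fh.write(f"{rec.drug}\t{','.join(rec.atc_codes)}\t{rec.target}\n")
    if seeds is not None:
        for label, gene_list in seeds.lists.items():
            (d / f"seeds_{label.lower()}.txt").write_text(
                "".join(f"{g}\n" for g in gene_list)
            )
    return d


def _write_obo(go: GOAnnotationTable, path: Path) -> None:
    namespace_of: dict[str, str] = {}
    for aspect, table in go.annotations.items():
        for terms in table.values():
            for t in terms:
                namespace_of[t] = _ASPECT_NAMESPACE[aspect]
                for anc in go.ancestors(t):
                    namespace_of.setdefault(anc, _ASPECT_NAMESPACE[aspect])
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go\n")
        for term in sorted(go.parents):
            fh.write(f"\n[Term]\nid: {term}\nname: synthetic term {term}\n")
            fh.write(f"namespace: {namespace_of.get(term, 'biological_process')}\n")
            for p in sorted(go.parents[term]):
                fh.write(f"is_a: {p} ! synthetic term {p}\n")


def _write_gaf(go: GOAnnotationTable, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for aspect in ("BP", "MF", "CC"):
            code = _ASPECT_CODE[aspect]
            for gene in sorted(go.annotations[aspect]):
                for term in sorted(go.annotations[aspect][gene]):
                    fields = [
                        "SYNT", gene, gene, "involved_in", term, "SYNT:0000001",
                        "IEA", "", code, "", "", "protein", "taxon:9606",
                        "20240101", "SYNT", "", "",
                    ]
                    fh.write("\t".join(fields) + "\n")
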