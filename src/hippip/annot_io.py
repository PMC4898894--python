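"""Readers, writers and in-memory containers for every annotation source.

Gene identity throughout the package is the HGNC-style symbol, upper-cased on
ingest.  All tabular inputs are plain tab-separated text; GO annotations come
in GAF 2.x (parsed with :mod:`Bio.UniProt.GOA`) with the is_a hierarchy read
from a minimal OBO file (parsed with :mod:`obonet`).  Locus coordinates are
stored 0-based half-open (BED convention).
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio.UniProt import GOA

logger = logging.getLogger(__name__)

Pair = tuple[str, str]

#: GO aspect codes of the GAF "Aspect" column mapped to ontology branch names.
_ASPECT_CODES = {"P": "BP", "F": "MF", "C": "CC"}
ASPECTS = ("BP", "MF", "CC")

_HEADER_TOKENS = {
    "gene", "gene1", "gene2", "genea", "geneb", "symbol", "symbol1", "symbol2",
    "protein", "protein1", "protein2", "interactor", "interactor_a",
    "interactor_b", "source", "target", "score",
}


def canonical_pair(a: str, b: str) -> Pair:
    """Return the unordered pair (a, b) in canonical (sorted) order."""
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GeneCatalog:
    """The universe of candidate genes, with optional alias resolution."""

    symbols: frozenset[str]
    aliases: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("GeneCatalog requires a non-empty symbol set")
        self.symbols = frozenset(s.upper() for s in self.symbols)
        self.aliases = {a.upper(): c.upper() for a, c in dict(self.aliases).items()}
        for alias, canon in self.aliases.items():
            if canon not in self.symbols:
                raise ValueError(f"alias {alias!r} maps to unknown symbol {canon!r}")
            if alias in self.symbols and alias != canon:
                raise ValueError(f"symbol {alias!r} cannot also be an alias of {canon!r}")

    def canonicalize(self, symbol: str) -> str | None:
        """Resolve *symbol* to its canonical form, or None if unresolvable."""
        s = symbol.upper()
        if s in self.symbols:
            return s
        return self.aliases.get(s)

    def __contains__(self, symbol: str) -> bool:
        return self.canonicalize(symbol) is not None

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(sorted(self.symbols))


@dataclass
class PPIEdgeList:
    """A set of unordered gene-symbol pairs with a provenance tag per edge.

    ``scores`` carries the prediction score for predicted edges; known edges
    have no score.
    """

    edges: dict[Pair, str] = field(default_factory=dict)
    scores: dict[Pair, float] = field(default_factory=dict)

    def add(self, a: str, b: str, source: str = "known", score: float | None = None) -> bool:
        if a == b:
            raise ValueError(f"self-pair {a!r} not allowed")
        p = canonical_pair(a, b)
        new = p not in self.edges
        self.edges[p] = source
        if score is not None:
            self.scores[p] = score
        return new

    def __contains__(self, pair: Sequence[str]) -> bool:
        a, b = pair
        return canonical_pair(a, b) in self.edges

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)

    def pairs(self) -> set[Pair]:
        return set(self.edges)

    def degrees(self) -> dict[str, int]:
        deg: dict[str, int] = {}
        for a, b in self.edges:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        return deg

    def genes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out


class GOAnnotationTable:
    """Gene -> GO term annotations, partitioned by aspect, plus the is_a DAG.

    Annotations are propagated up the is_a hierarchy on demand; the aspect
    roots (terms with no is_a parent) are excluded from propagated sets so
    that trivially shared roots never count as shared annotation.
    """

    def __init__(
        self,
        annotations: Mapping[str, Mapping[str, Iterable[str]]],
        parents: Mapping[str, Iterable[str]],
    ) -> None:
        # annotations: aspect -> gene -> set of term ids
        self.annotations: dict[str, dict[str, frozenset[str]]] = {
            asp: {g.upper(): frozenset(ts) for g, ts in annotations.get(asp, {}).items()}
            for asp in ASPECTS
        }
        self.parents: dict[str, frozenset[str]] = {
            t: frozenset(ps) for t, ps in parents.items()
        }
        dag = nx.DiGraph()
        for t, ps in self.parents.items():
            dag.add_node(t)
            for p in ps:
                dag.add_edge(t, p)  # child -> parent
        if not nx.is_directed_acyclic_graph(dag):
            raise ValueError("GO is_a relation contains a cycle")
        self._dag = dag
        self.roots: frozenset[str] = frozenset(
            t for t in dag.nodes if dag.out_degree(t) == 0
        )
        for asp in ASPECTS:
            for g, terms in self.annotations[asp].items():
                missing = terms - set(dag.nodes)
                if missing:
                    raise ValueError(
                        f"gene {g} annotated to term(s) absent from the DAG: {sorted(missing)}"
                    )
        self._closure_cache: dict[tuple[str, str], frozenset[str]] = {}
        self._anc_cache: dict[str, frozenset[str]] = {}

    def ancestors(self, term: str) -> frozenset[str]:
        """is_a ancestors of *term*, excluding the term itself."""
        cached = self._anc_cache.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self._dag, term))
            self._anc_cache[term] = cached
        return cached

    def terms(self, gene: str, aspect: str) -> frozenset[str]:
        """Directly annotated terms of *gene* in *aspect*."""
        return self.annotations[aspect].get(gene.upper(), frozenset())

    def annotated_closure(self, gene: str, aspect: str) -> frozenset[str]:
        """All terms of *gene* in *aspect* after is_a propagation, roots excluded."""
        key = (gene.upper(), aspect)
        cached = self._closure_cache.get(key)
        if cached is None:
            out: set[str] = set()
            for t in self.terms(gene, aspect):
                out.add(t)
                out |= self.ancestors(t)
            cached = frozenset(out - self.roots)
            self._closure_cache[key] = cached
        return cached

    def genes(self) -> set[str]:
        out: set[str] = set()
        for asp in ASPECTS:
            out |= set(self.annotations[asp])
        return out

    def n_annotations(self) -> int:
        return sum(len(ts) for asp in ASPECTS for ts in self.annotations[asp].values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GOAnnotationTable):
            return NotImplemented
        return self.annotations == other.annotations and self.parents == other.parents


@dataclass
class ExpressionMatrix:
    """Gene x condition matrix of real-valued expression measurements."""

    data: pd.DataFrame  # index: gene symbols, columns: condition labels

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene symbols in expression matrix")
        self.data.index = self.data.index.str.upper()

    def profile(self, gene: str) -> np.ndarray | None:
        g = gene.upper()
        if g not in self.data.index:
            return None
        return self.data.loc[g].to_numpy(dtype=float)

    @property
    def conditions(self) -> list[str]:
        return list(self.data.columns)

    def genes(self) -> set[str]:
        return set(self.data.index)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass
class DomainTable:
    """Gene -> set of protein-domain identifiers (opaque strings)."""

    assignments: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self.assignments = {
            g.upper(): frozenset(ds) for g, ds in self.assignments.items()
        }

    def domains(self, gene: str) -> frozenset[str]:
        return self.assignments.get(gene.upper(), frozenset())

    def genes(self) -> set[str]:
        return set(self.assignments)


@dataclass
class GeneLocusTable:
    """Gene -> (chromosome, start, end); 0-based half-open coordinates."""

    loci: dict[str, tuple[str, int, int]]

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, int, int]] = {}
        for g, (chrom, start, end) in self.loci.items():
            if start >= end:
                raise ValueError(f"locus of {g}: start {start} >= end {end}")
            clean[g.upper()] = (chrom, int(start), int(end))
        self.loci = clean

    def locus(self, gene: str) -> tuple[str, int, int] | None:
        return self.loci.get(gene.upper())

    def midpoint(self, gene: str) -> tuple[str, float] | None:
        loc = self.locus(gene)
        if loc is None:
            return None
        chrom, start, end = loc
        return chrom, (start + end) / 2.0

    def genes(self) -> set[str]:
        return set(self.loci)


@dataclass
class TissueTable:
    """Gene -> set of tissue labels (case-normalized to lower case)."""

    membership: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self.membership = {
            g.upper(): frozenset(t.lower() for t in ts)
            for g, ts in self.membership.items()
        }

    def tissues(self, gene: str) -> frozenset[str]:
        return self.membership.get(gene.upper(), frozenset())

    def genes(self) -> set[str]:
        return set(self.membership)


@dataclass(frozen=True)
class DrugRecord:
    drug: str
    atc_codes: tuple[str, ...]
    target: str


@dataclass
class DrugTargetTable:
    """Drug <-> target-gene links with ATC classification codes."""

    records: list[DrugRecord]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        clean: list[DrugRecord] = []
        for r in self.records:
            key = (r.drug, r.target.upper())
            if key in seen:
                continue
            seen.add(key)
            clean.append(DrugRecord(r.drug, tuple(r.atc_codes), r.target.upper()))
        self.records = clean

    def targets_of(self, drug: str) -> set[str]:
        return {r.target for r in self.records if r.drug == drug}

    def drugs(self) -> set[str]:
        return {r.drug for r in self.records}

    def genes(self) -> set[str]:
        return {r.target for r in self.records}

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class AnnotationUniverse:
    """All per-gene annotation sources, keyed by canonical gene symbol."""

    catalog: GeneCatalog
    go: GOAnnotationTable
    expr: ExpressionMatrix
    domains: DomainTable
    loci: GeneLocusTable
    tissues: TissueTable
    known_ppis: PPIEdgeList

    def __post_init__(self) -> None:
        referenced = (
            self.go.genes()
            | self.expr.genes()
            | self.domains.genes()
            | self.loci.genes()
            | self.tissues.genes()
            | self.known_ppis.genes()
        )
        stray = referenced - self.catalog.symbols
        if stray:
            raise ValueError(
                f"{len(stray)} gene(s) referenced by annotation tables are missing "
                f"from the catalog, e.g. {sorted(stray)[:5]}"
            )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _looks_like_header(fields: Sequence[str]) -> bool:
    return any(f.strip().lower() in _HEADER_TOKENS for f in fields)


def read_ppi_edges(
    path: str | os.PathLike,
    catalog: GeneCatalog | None = None,
    source: str = "known",
) -> PPIEdgeList:
    """Read a tab-delimited edge list (2-column TSV or 3-column SIF).

    Duplicate and reversed edges collapse to one; self-pairs and symbols not
    resolvable against *catalog* (when given) are dropped with logged counts.
    """
    path = Path(path)
    raw = path.read_text().splitlines()
    rows: list[tuple[int, list[str]]] = []
    for lineno, line in enumerate(raw, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: fewer than 2 tab-separated columns")
        rows.append((lineno, fields))
    if not rows:
        raise ValueError(f"{path}: empty edge-list file")
    if _looks_like_header(rows[0][1]):
        rows = rows[1:]
        if not rows:
            raise ValueError(f"{path}: edge-list file contains only a header")
    # SIF detection: constant lowercase relation token in the middle column
    is_sif = all(
        len(f) >= 3 and f[1] == rows[0][1][1] and f[1].islower() for _, f in rows
    ) and len(rows[0][1]) >= 3
    cols = (0, 2) if is_sif else (0, 1)

    edges = PPIEdgeList()
    n_self = 0
    n_unresolved = 0
    for lineno, fields in rows:
        a, b = fields[cols[0]].strip().upper(), fields[cols[1]].strip().upper()
        if catalog is not None:
            ca, cb = catalog.canonicalize(a), catalog.canonicalize(b)
            if ca is None or cb is None:
                n_unresolved += 1
                continue
            a, b = ca, cb
        if a == b:
            n_self += 1
            continue
        edges.add(a, b, source=source)
    if n_self:
        logger.warning("%s: dropped %d self-pair(s)", path, n_self)
    if n_unresolved:
        logger.warning("%s: dropped %d edge(s) with unresolvable symbols", path, n_unresolved)
    return edges


def read_obo_isa(path: str | os.PathLike) -> dict[str, frozenset[str]]:
    """Parse an OBO file and return the term -> is_a-parents map."""
    import obonet

    graph = obonet.read_obo(os.fspath(path))
    parents: dict[str, frozenset[str]] = {}
    for term in graph.nodes:
        ps = frozenset(
            v for _, v, key in graph.out_edges(term, keys=True) if key == "is_a"
        )
        parents[term] = ps
    return parents


def read_gaf(
    path: str | os.PathLike,
    parents: Mapping[str, Iterable[str]] | None = None,
) -> GOAnnotationTable:
    """Read a GAF 2.x annotation file into a :class:`GOAnnotationTable`.

    Rows with a NOT qualifier are excluded; duplicate (gene, term, aspect)
    rows collapse.  When *parents* is None the DAG is flat (every annotated
    term is its own root-less node), which suffices for counting direct terms.
    """
    path = Path(path)
    text = path.read_text()
    data_linenos = [
        lineno
        for lineno, line in enumerate(text.splitlines(), start=1)
        if line.strip() and not line.startswith("!")
    ]
    annotations: dict[str, dict[str, set[str]]] = {a: {} for a in ASPECTS}
    terms_seen: set[str] = set()
    with io.StringIO(text) as handle:
        for i, rec in enumerate(GOA.gafiterator(handle)):
            lineno = data_linenos[i] if i < len(data_linenos) else -1
            qualifiers = rec.get("Qualifier") or []
            if any(q.strip().upper().startswith("NOT") for q in qualifiers if q):
                continue
            aspect_code = rec["Aspect"].strip()
            if aspect_code not in _ASPECT_CODES:
                raise ValueError(
                    f"{path}:{lineno}: malformed aspect code {aspect_code!r} "
                    f"(expected one of P/F/C)"
                )
            aspect = _ASPECT_CODES[aspect_code]
            gene = rec["DB_Object_Symbol"].strip().upper()
            term = rec["GO_ID"].strip()
            annotations[aspect].setdefault(gene, set()).add(term)
            terms_seen.add(term)
    if parents is None:
        parents = {t: frozenset() for t in terms_seen}
    else:
        parents = dict(parents)
        for t in terms_seen:
            parents.setdefault(t, frozenset())
    return GOAnnotationTable(annotations, parents)


def read_expression_matrix(path: str | os.PathLike) -> ExpressionMatrix:
    """Read a TSV expression matrix: header of condition labels, gene rows."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression value ({exc})") from exc
    return ExpressionMatrix(df)


def read_domains(path: str | os.PathLike) -> DomainTable:
    """Read a two-column TSV (gene, domain), one assignment per row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    gene_col, dom_col = df.columns[:2]
    table: dict[str, set[str]] = {}
    for gene, dom in zip(df[gene_col], df[dom_col]):
        table.setdefault(str(gene), set()).add(str(dom))
    return DomainTable({g: frozenset(ds) for g, ds in table.items()})


def read_loci(path: str | os.PathLike) -> GeneLocusTable:
    """Read a BED-like loci file (chrom, start, end, symbol); first record wins."""
    loci: dict[str, tuple[str, int, int]] = {}
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 BED columns")
            chrom, start, end, symbol = fields[0], int(fields[1]), int(fields[2]), fields[3].upper()
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            if symbol in loci:
                n_dup += 1
                continue
            loci[symbol] = (chrom, start, end)
    if n_dup:
        logger.warning("%s: %d duplicate locus record(s) ignored (first wins)", path, n_dup)
    return GeneLocusTable(loci)


def read_tissues(path: str | os.PathLike) -> TissueTable:
    """Read a two-column TSV (gene, tissue), one membership per row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    gene_col, tis_col = df.columns[:2]
    table: dict[str, set[str]] = {}
    for gene, tis in zip(df[gene_col], df[tis_col]):
        table.setdefault(str(gene), set()).add(str(tis))
    return TissueTable({g: frozenset(ts) for g, ts in table.items()})


def read_drug_targets(path: str | os.PathLike) -> DrugTargetTable:
    """Read a TSV of (drug, comma-separated ATC codes, target gene)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    drug_col, atc_col, gene_col = df.columns[:3]
    records = [
        DrugRecord(
            drug=str(row[drug_col]).strip(),
            atc_codes=tuple(
                c.strip() for c in str(row[atc_col]).split(",") if c.strip()
            ),
            target=str(row[gene_col]).strip(),
        )
        for _, row in df.iterrows()
    ]
    return DrugTargetTable(records)


#: Conventional file names inside a universe directory.
UNIVERSE_FILES = {
    "catalog": "catalog.txt",
    "known_ppis": "known_ppis.tsv",
    "gaf": "go_annotations.gaf",
    "obo": "go_ontology.obo",
    "expression": "expression.tsv",
    "domains": "domains.tsv",
    "loci": "loci.bed",
    "tissues": "tissues.tsv",
    "drugs": "drug_targets.tsv",
}


def read_universe(directory: str | os.PathLike) -> AnnotationUniverse:
    """Assemble an :class:`AnnotationUniverse` from a standard directory layout."""
    d = Path(directory)
    symbols = {
        line.strip().upper()
        for line in (d / UNIVERSE_FILES["catalog"]).read_text().splitlines()
        if line.strip()
    }
    catalog = GeneCatalog(frozenset(symbols))
    parents = read_obo_isa(d / UNIVERSE_FILES["obo"])
    return AnnotationUniverse(
        catalog=catalog,
        go=read_gaf(d / UNIVERSE_FILES["gaf"], parents=parents),
        expr=read_expression_matrix(d / UNIVERSE_FILES["expression"]),
        domains=read_domains(d / UNIVERSE_FILES["domains"]),
        loci=read_loci(d / UNIVERSE_FILES["loci"]),
        tissues=read_tissues(d / UNIVERSE_FILES["tissues"]),
        known_ppis=read_ppi_edges(d / UNIVERSE_FILES["known_ppis"], catalog=catalog),
    )


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

def write_network(
    graph: nx.Graph,
    prefix: str | os.PathLike,
    overwrite: bool = False,
) -> dict[str, Path]:
    """Export an interactome graph for network viewers.

    Writes ``<prefix>.sif`` (``gene<TAB>pp<TAB>gene``), ``<prefix>.nodes.tsv``
    (node role: seed / known-interactor / novel-interactor) and
    ``<prefix>.edges.tsv`` (edge source known/predicted plus score).
    """
    if graph.number_of_edges() == 0:
        raise ValueError("refusing to export an empty graph")
    prefix = Path(prefix)
    out = {
        "sif": prefix.with_suffix(".sif"),
        "nodes": prefix.parent / (prefix.name + ".nodes.tsv"),
        "edges": prefix.parent / (prefix.name + ".edges.tsv"),
    }
    for p in out.values():
        if p.exists() and not overwrite:
            raise FileExistsError(f"{p} exists; pass overwrite=True to replace")
    prefix.parent.mkdir(parents=True, exist_ok=True)
    edges = sorted(canonical_pair(a, b) for a, b in graph.edges)
    with open(out["sif"], "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\tpp\t{b}\n")
    with open(out["nodes"], "w") as fh:
        fh.write("gene\trole\n")
        for n in sorted(graph.nodes):
            fh.write(f"{n}\t{graph.nodes[n].get('role', 'interactor')}\n")
    with open(out["edges"], "w") as fh:
        fh.write("gene1\tgene2\tsource\tscore\n")
        for a, b in edges:
            data = graph.edges[a, b]
            score = data.get("score")
            fh.write(
                f"{a}\t{b}\t{data.get('source', 'known')}\t"
                f"{'' if score is None else f'{score:.6g}'}\n"
            )
    return out
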