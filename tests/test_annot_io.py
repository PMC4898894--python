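"""Reader/writer contracts: dedup, canonicalization, format round-trips."""

import networkx as nx
import pytest

from hippip.annot_io import (
    GeneCatalog,
    canonical_pair,
    read_drug_targets,
    read_expression_matrix,
    read_gaf,
    read_loci,
    read_ppi_edges,
    read_tissues,
    read_universe,
    write_network,
)
from hippip.synth import generate_drug_targets, write_universe


def test_edge_list_dedup_and_self_pairs(tmp_path):
    p = tmp_path / "edges.tsv"
    p.write_text("A\tB\nB\tA\nA\tA\n")
    edges = read_ppi_edges(p)
    assert edges.pairs() == {("A", "B")}


def test_edge_list_distinct_rows(tmp_path):
    p = tmp_path / "edges.tsv"
    p.write_text("A\tB\nC\tD\nE\tF\n")
    assert len(read_ppi_edges(p)) == 3


def test_edge_list_header_skipped_and_errors(tmp_path):
    p = tmp_path / "edges.tsv"
    p.write_text("gene1\tgene2\nA\tB\n")
    assert read_ppi_edges(p).pairs() == {("A", "B")}
    (tmp_path / "empty.tsv").write_text("")
    with pytest.raises(ValueError, match="empty"):
        read_ppi_edges(tmp_path / "empty.tsv")
    bad = tmp_path / "bad.tsv"
    bad.write_text("A\tB\nC\n")
    with pytest.raises(ValueError, match=":2"):
        read_ppi_edges(bad)


def test_alias_pairs_collapse(tmp_path):
    catalog = GeneCatalog(frozenset({"GRM3", "DISC1"}), aliases={"MGLUR3": "GRM3"})
    p = tmp_path / "edges.tsv"
    p.write_text("GRM3\tDISC1\nmGluR3\tDISC1\n")
    edges = read_ppi_edges(p, catalog=catalog)
    assert edges.pairs() == {canonical_pair("GRM3", "DISC1")}


def test_unresolvable_symbols_dropped(tmp_path):
    catalog = GeneCatalog(frozenset({"A", "B"}))
    p = tmp_path / "edges.tsv"
    p.write_text("A\tB\nA\tZZZ\n")
    assert read_ppi_edges(p, catalog=catalog).pairs() == {("A", "B")}


def test_reader_idempotence(tmp_path):
    p = tmp_path / "edges.tsv"
    p.write_text("A\tB\nC\tD\n")
    assert read_ppi_edges(p).pairs() == read_ppi_edges(p).pairs()


GAF_HEADER = "!gaf-version: 2.2\n"


def _gaf_row(gene, term, aspect, qualifier="involved_in"):
    fields = [
        "SYNT", gene, gene, qualifier, term, "REF:1", "IEA", "", aspect,
        "", "", "protein", "taxon:9606", "20240101", "SYNT", "", "",
    ]
    return "\t".join(fields) + "\n"


def test_gaf_aspect_partition(tmp_path):
    p = tmp_path / "a.gaf"
    p.write_text(GAF_HEADER + _gaf_row("A", "GO:0000001", "P") + _gaf_row("A", "GO:0000002", "C"))
    table = read_gaf(p)
    assert table.terms("A", "BP") == {"GO:0000001"}
    assert table.terms("A", "CC") == {"GO:0000002"}
    assert table.terms("A", "MF") == frozenset()


def test_gaf_not_qualifier_excluded(tmp_path):
    p = tmp_path / "a.gaf"
    p.write_text(GAF_HEADER + _gaf_row("A", "GO:0000001", "P", qualifier="NOT|involved_in"))
    assert read_gaf(p).n_annotations() == 0


def test_gaf_malformed_aspect(tmp_path):
    p = tmp_path / "a.gaf"
    p.write_text(GAF_HEADER + _gaf_row("A", "GO:0000001", "Q"))
    with pytest.raises(ValueError, match="aspect"):
        read_gaf(p)


def test_gaf_count_matches_line_scan(tmp_path):
    rows = [("A", "GO:0000001", "P"), ("A", "GO:0000002", "P"), ("B", "GO:0000001", "F"),
            ("B", "GO:0000003", "C"), ("A", "GO:0000001", "P")]  # one duplicate
    p = tmp_path / "a.gaf"
    p.write_text(GAF_HEADER + "".join(_gaf_row(*r) for r in rows))
    distinct = len(set(rows))
    assert read_gaf(p).n_annotations() == distinct


def test_expression_reader(tmp_path):
    p = tmp_path / "expr.tsv"
    header = "gene\t" + "\t".join(f"c{i}" for i in range(10))
    lines = [header] + [f"G{i}\t" + "\t".join("1.5" for _ in range(10)) for i in range(5)]
    p.write_text("\n".join(lines) + "\n")
    assert read_expression_matrix(p).data.shape == (5, 10)
    bad = tmp_path / "bad.tsv"
    bad.write_text("gene\tc1\tc2\nA\t1.0\toops\n")
    with pytest.raises(ValueError, match="non-numeric"):
        read_expression_matrix(bad)


def test_locus_reader(tmp_path):
    p = tmp_path / "loci.bed"
    p.write_text("chr1\t100\t200\tA\n")
    assert read_loci(p).locus("A") == ("chr1", 100, 200)
    bad = tmp_path / "bad.bed"
    bad.write_text("chr1\t200\t100\tA\n")
    with pytest.raises(ValueError, match="start"):
        read_loci(bad)


def test_locus_first_record_wins(tmp_path):
    p = tmp_path / "loci.bed"
    p.write_text("chr1\t100\t200\tA\nchr2\t5\t10\tA\n")
    assert read_loci(p).locus("A") == ("chr1", 100, 200)


def test_drug_reader(tmp_path):
    p = tmp_path / "drugs.tsv"
    p.write_text("drug\tatc_codes\ttarget\nDrugX\tN05A,C01\tGENE1\n")
    table = read_drug_targets(p)
    assert len(table) == 1
    assert table.records[0].atc_codes == ("N05A", "C01")


def test_tissue_labels_case_normalized(tmp_path):
    p = tmp_path / "tissues.tsv"
    p.write_text("gene\ttissue\nA\tBrain\nA\tbrain\n")
    assert read_tissues(p).tissues("A") == {"brain"}


def test_write_network_round_trip(tmp_path):
    g = nx.Graph()
    g.add_node("S", role="seed")
    g.add_node("K", role="known-interactor")
    g.add_node("N", role="novel-interactor")
    g.add_edge("S", "K", source="known")
    g.add_edge("S", "N", source="predicted", score=0.8)
    files = write_network(g, tmp_path / "net")
    sif_edges = read_ppi_edges(files["sif"])
    assert sif_edges.pairs() == {canonical_pair(a, b) for a, b in g.edges}
    node_lines = files["nodes"].read_text().splitlines()[1:]
    roles = dict(line.split("\t") for line in node_lines)
    assert roles == {"S": "seed", "K": "known-interactor", "N": "novel-interactor"}
    edge_lines = files["edges"].read_text().splitlines()[1:]
    sources = {line.split("\t")[2] for line in edge_lines}
    assert sources == {"known", "predicted"}
    with pytest.raises(FileExistsError):
        write_network(g, tmp_path / "net")


def test_universe_directory_round_trip(tmp_path, small_synth):
    universe, truth = small_synth
    drugs = generate_drug_targets(truth, n_drugs=5, seed=1)
    write_universe(universe, tmp_path / "u", drugs=drugs)
    back = read_universe(tmp_path / "u")
    assert back.catalog.symbols == universe.catalog.symbols
    assert back.known_ppis.pairs() == universe.known_ppis.pairs()
    assert back.go == universe.go
    assert back.expr.data.shape == universe.expr.data.shape
    # long-format TSVs cannot express empty sets; non-empty entries round-trip
    assert back.domains.assignments == {
        g: d for g, d in universe.domains.assignments.items() if d
    }
    assert back.loci.loci == universe.loci.loci
    assert back.tissues.membership == {
        g: t for g, t in universe.tissues.membership.items() if t
    }
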