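"""Readers and writers: validation, coordinate conventions, round-trips."""

import networkx as nx
import pytest

from mycometab.data_io import (
    read_annotation_table,
    read_gene_catalog,
    read_multialignments,
    read_network,
    read_pathway_table,
    read_reaction_table,
    write_annotation_table,
    write_gene_fasta,
    write_network,
    write_pathway_table,
    write_reaction_table,
)
from mycometab.types import (
    AnnotationTable,
    GeneCatalog,
    GeneModel,
    Organism,
    ReactionRecord,
    ec_match,
)


@pytest.fixture()
def tiny_catalog():
    return GeneCatalog(
        [
            GeneModel("g1", Organism.A, 1000),
            GeneModel("g2", Organism.A, 2000),
            GeneModel("g3", Organism.B, 500),
        ]
    )


def write_sam(path, catalog, records):
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for g in catalog:
            fh.write(f"@SQ\tSN:{g.gene_id}\tLN:{g.length_bp}\n")
        for rid, flag, ref, pos in records:
            seq = "A" * 10
            if flag & 4:
                fh.write(f"{rid}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*\n")
            else:
                fh.write(f"{rid}\t{flag}\t{ref}\t{pos}\t255\t10M\t*\t0\t0\t{seq}\t*\n")


class TestGeneCatalog:
    def test_single_record_fasta(self, tmp_path):
        p = tmp_path / "a.fasta"
        write_gene_fasta({"g1": "A" * 1000}, p)
        cat = read_gene_catalog([(p, Organism.A)])
        assert len(cat) == 1
        assert cat["g1"].length_bp == 1000
        assert cat["g1"].organism is Organism.A

    def test_duplicate_id_across_files_rejected(self, tmp_path):
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_gene_fasta({"g1": "ACGT"}, p1)
        write_gene_fasta({"g1": "ACGTAC"}, p2)
        with pytest.raises(ValueError, match="duplicate"):
            read_gene_catalog([(p1, Organism.A), (p2, Organism.B)])

    def test_fixture_catalog_totals_match_plan(self, small_experiment, small_plan):
        totals = small_experiment.catalog.organism_totals
        assert totals[Organism.A] == small_plan.n_genes_a
        assert totals[Organism.B] == small_plan.n_genes_b

    def test_invalid_gene_model(self):
        with pytest.raises(ValueError):
            GeneModel("g", Organism.A, 0)
        with pytest.raises(ValueError):
            GeneModel("", Organism.A, 10)


class TestAnnotationTable:
    def test_lines_accumulate_into_sets(self, tmp_path, tiny_catalog):
        p = tmp_path / "ec.tsv"
        p.write_text("g1\t3.2.1.26\ng1\t1.4.1.2\n# comment\ng2\t2.7.1.1\n")
        t = read_annotation_table(p, "EC", tiny_catalog)
        assert t.codes_of("g1") == {"3.2.1.26", "1.4.1.2"}
        assert t.codes_of("g2") == {"2.7.1.1"}

    def test_unknown_gene_strict_mode_names_gene(self, tmp_path, tiny_catalog):
        p = tmp_path / "go.tsv"
        p.write_text("g9\tGO:0005351\n")
        with pytest.raises(ValueError, match="g9"):
            read_annotation_table(p, "GO", tiny_catalog)

    def test_unknown_gene_warn_mode_skips(self, tmp_path, tiny_catalog):
        p = tmp_path / "go.tsv"
        p.write_text("g9\tGO:0005351\ng1\tGO:0005351\n")
        with pytest.warns(UserWarning):
            t = read_annotation_table(p, "GO", tiny_catalog, on_unknown="warn")
        assert t.entries.keys() == {"g1"}

    def test_malformed_code_reported_with_line(self, tmp_path, tiny_catalog):
        p = tmp_path / "ec.tsv"
        p.write_text("g1\t3.2.1.26\ng2\tnot-an-ec\n")
        with pytest.raises(ValueError, match=":2"):
            read_annotation_table(p, "EC", tiny_catalog)

    def test_round_trip(self, tmp_path, tiny_catalog):
        t = AnnotationTable(kind="EC")
        t.add("g1", "3.2.1.26")
        t.add("g1", "1.4.1.-")
        t.add("g3", "2.7.1.1")
        p = tmp_path / "ec.tsv"
        write_annotation_table(t, p)
        back = read_annotation_table(p, "EC", tiny_catalog)
        assert back.entries == t.entries

    def test_ec_wildcard_matching(self):
        assert ec_match("1.4.1.-", "1.4.1.2")
        assert not ec_match("1.4.1.2", "1.4.2.2")
        assert ec_match("3.2.1.26", "3.2.1.26")


class TestMultiAlignments:
    def test_pos_converted_to_zero_based(self, tmp_path, tiny_catalog):
        p = tmp_path / "a.sam"
        write_sam(p, tiny_catalog, [("r1", 0, "g1", 11)])
        aln = read_multialignments(p, tiny_catalog)
        (loc,) = aln.reads["r1"]
        assert (loc.gene_id, loc.start, loc.strand) == ("g1", 10, "+")

    def test_multiread_grouped(self, tmp_path, tiny_catalog):
        p = tmp_path / "a.sam"
        write_sam(p, tiny_catalog, [("r2", 0, "g1", 5), ("r2", 256, "g2", 9)])
        aln = read_multialignments(p, tiny_catalog)
        assert len(aln.reads["r2"]) == 2

    def test_duplicate_locations_collapse(self, tmp_path, tiny_catalog):
        p = tmp_path / "a.sam"
        write_sam(p, tiny_catalog, [("r1", 0, "g1", 5), ("r1", 256, "g1", 5)])
        aln = read_multialignments(p, tiny_catalog)
        assert len(aln.reads["r1"]) == 1

    def test_unmapped_counted_without_candidates(self, tmp_path, tiny_catalog):
        p = tmp_path / "a.sam"
        write_sam(p, tiny_catalog, [("r1", 0, "g1", 5), ("r9", 4, "*", 0)])
        aln = read_multialignments(p, tiny_catalog)
        assert aln.total_reads_in_library == 2
        assert aln.n_mapped == 1
        assert "r9" not in aln.reads

    def test_unknown_reference_rejected(self, tmp_path, tiny_catalog):
        p = tmp_path / "a.sam"
        with open(p, "w") as fh:
            fh.write("@SQ\tSN:gX\tLN:100\n")
            fh.write("r1\t0\tgX\t1\t255\t10M\t*\t0\t0\tAAAAAAAAAA\t*\n")
        with pytest.raises(ValueError, match="gX"):
            read_multialignments(p, tiny_catalog)

    def test_fixture_candidate_counts_match_plant(self, small_experiment, tmp_path):
        lib = small_experiment.libraries[0]
        p = tmp_path / "rep.sam"
        lib.write_sam(p, small_experiment.catalog)
        aln = read_multialignments(p, small_experiment.catalog)
        planted = dict(
            zip(lib.read_truth["read_id"], lib.read_truth["n_candidates"])
        )
        for rid, locs in aln.reads.items():
            assert len(locs) == planted[rid]


class TestReactionAndPathwayTables:
    def test_parse_invertase_line(self, tmp_path):
        p = tmp_path / "rx.tsv"
        p.write_text("R1\t3.2.1.26\tC00089\tC00031;C00095\tI\n")
        (rec,) = read_reaction_table(p)
        assert rec.ec_set == {"3.2.1.26"}
        assert rec.substrates == {"C00089"}
        assert rec.products == {"C00031", "C00095"}
        assert not rec.reversible

    def test_duplicate_reaction_rejected(self, tmp_path):
        p = tmp_path / "rx.tsv"
        p.write_text("R1\t1.1.1.1\tC1\tC2\tI\nR1\t1.1.1.2\tC3\tC4\tR\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_reaction_table(p)

    def test_substrate_product_overlap_rejected_by_default(self):
        with pytest.raises(ValueError, match="both sides"):
            ReactionRecord("R1", frozenset({"1.1.1.1"}), frozenset({"C1"}),
                           frozenset({"C1", "C2"}))
        rec = ReactionRecord("R1", frozenset({"1.1.1.1"}), frozenset({"C1"}),
                             frozenset({"C1", "C2"}), allow_overlap=True)
        assert "C1" in rec.products

    def test_round_trip(self, tmp_path, toy):
        p = tmp_path / "rx.tsv"
        write_reaction_table(toy.reactions, p)
        back = read_reaction_table(p)
        assert back == toy.reactions
        pw = tmp_path / "pw.tsv"
        write_pathway_table(toy.pathways, pw)
        assert read_pathway_table(pw) == toy.pathways

    def test_empty_field_rejected(self, tmp_path):
        p = tmp_path / "rx.tsv"
        p.write_text("R1\t\tC1\tC2\tI\n")
        with pytest.raises(ValueError):
            read_reaction_table(p)


class TestNetworkExport:
    @pytest.fixture()
    def toy_graph(self):
        g = nx.DiGraph()
        g.add_node("C00089", sugar=True)
        g.add_node("C00031", sugar=True)
        g.add_edge("C00089", "C00031", reaction_id="R1", ec="3.2.1.26", provenance="A_only")
        return g

    def test_sif_line_shape(self, tmp_path, toy_graph):
        (p,) = write_network(toy_graph, tmp_path / "net", "sif")
        assert p.read_text().splitlines() == ["C00089\tR1:3.2.1.26\tC00031"]

    @pytest.mark.parametrize("fmt", ["graphml", "tsv"])
    def test_round_trip_isomorphic_with_attributes(self, tmp_path, toy_graph, fmt):
        write_network(toy_graph, tmp_path / "net", fmt)
        back = read_network(tmp_path / "net", fmt)
        assert set(back.nodes) == set(toy_graph.nodes)
        assert set(back.edges) == set(toy_graph.edges)
        e = back.edges["C00089", "C00031"]
        assert e["reaction_id"] == "R1" and e["ec"] == "3.2.1.26"

    def test_empty_network_writes_empty_files(self, tmp_path):
        for fmt in ("sif", "graphml", "tsv"):
            files = write_network(nx.DiGraph(), tmp_path / f"empty_{fmt}", fmt)
            assert all(f.exists() for f in files)

    def test_unknown_format_rejected(self, tmp_path, toy_graph):
        with pytest.raises(ValueError, match="format"):
            write_network(toy_graph, tmp_path / "net", "dot")
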