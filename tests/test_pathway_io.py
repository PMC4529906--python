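"""Containers, KGML reading and the chain report notation."""

import gzip

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from subpathnet import (
    EdgeConflictError,
    ExpressionDataset,
    KgmlParseError,
    NotationParseError,
    SignedPathwayGraph,
    Subpathway,
    ValidationError,
    format_subpathway_notation,
    load_inflammation_terms,
    parse_subpathway_notation,
    read_fold_change_table,
    read_gmt,
    read_kgml,
    read_network_sif,
    write_network_sif,
)

KGML_TEMPLATE = """<?xml version="1.0"?>
<pathway name="path:hsa99999" title="Test pathway" org="hsa">
{entries}
{relations}
</pathway>
"""


def kgml(tmp_path, entries, relations, name="p.xml"):
    path = tmp_path / name
    path.write_text(KGML_TEMPLATE.format(entries=entries, relations=relations))
    return path


ENTRY = '<entry id="{id}" name="hsa:{id}" type="{type}"><graphics name="{genes}"/></entry>'
REL = '<relation entry1="{a}" entry2="{b}" type="PPrel"><subtype name="{sub}" value="x"/></relation>'


class TestReadKgml:
    def test_activation_and_inhibition_map_to_signs(self, tmp_path):
        path = kgml(
            tmp_path,
            "\n".join(
                ENTRY.format(id=i, type="gene", genes=g)
                for i, g in enumerate(["A", "B", "C"], 1)
            ),
            REL.format(a=1, b=2, sub="activation")
            + REL.format(a=2, b=3, sub="inhibition"),
        )
        g = read_kgml(path)
        assert g.pathway_id == "hsa99999"
        assert g.nodes == {"A", "B", "C"}
        assert g.edges == {("A", "B", 1), ("B", "C", -1)}

    def test_multi_gene_entry_is_split_per_gene(self, tmp_path):
        path = kgml(
            tmp_path,
            ENTRY.format(id=1, type="gene", genes="G1, G2")
            + ENTRY.format(id=2, type="gene", genes="X"),
            REL.format(a=1, b=2, sub="activation"),
        )
        g = read_kgml(path)
        assert g.edges == {("G1", "X", 1), ("G2", "X", 1)}

    def test_unsigned_subtypes_dropped(self, tmp_path):
        path = kgml(
            tmp_path,
            ENTRY.format(id=1, type="gene", genes="A")
            + ENTRY.format(id=2, type="gene", genes="B"),
            REL.format(a=1, b=2, sub="binding/association"),
        )
        g = read_kgml(path)
        assert g.nodes == {"A", "B"} and g.edges == set()

    def test_map_entries_and_self_loops_dropped(self, tmp_path):
        path = kgml(
            tmp_path,
            ENTRY.format(id=1, type="gene", genes="A")
            + ENTRY.format(id=2, type="map", genes="SOME MAP")
            + ENTRY.format(id=3, type="gene", genes="A"),
            REL.format(a=1, b=2, sub="activation")
            + REL.format(a=1, b=3, sub="activation"),
        )
        g = read_kgml(path)
        assert g.nodes == {"A"} and g.edges == set()

    def test_malformed_xml_reports_byte_offset(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text("<pathway><entry></pathway>")
        with pytest.raises(KgmlParseError, match="byte offset"):
            read_kgml(path)

    def test_conflicting_signs_name_the_pair(self, tmp_path):
        path = kgml(
            tmp_path,
            ENTRY.format(id=1, type="gene", genes="A")
            + ENTRY.format(id=2, type="gene", genes="B"),
            REL.format(a=1, b=2, sub="activation")
            + REL.format(a=1, b=2, sub="inhibition"),
        )
        with pytest.raises(EdgeConflictError, match="A.*B"):
            read_kgml(path)


class TestContainers:
    def test_graph_rejects_self_loop_and_conflicts(self):
        with pytest.raises(ValidationError):
            SignedPathwayGraph("p", "", {"A"}, {("A", "A", 1)})
        with pytest.raises(EdgeConflictError):
            SignedPathwayGraph(
                "p", "", {"A", "B"}, {("A", "B", 1), ("A", "B", -1)}
            )
        with pytest.raises(ValidationError):
            SignedPathwayGraph("p", "", {"A"}, {("A", "B", 1)})

    def test_subpathway_invariants(self):
        with pytest.raises(ValidationError):
            Subpathway("p", ("A",), ())
        with pytest.raises(ValidationError):
            Subpathway("p", ("A", "B", "A"), (1, 1))
        with pytest.raises(ValidationError):
            Subpathway("p", ("A", "B"), (1, 1))

    def test_dataset_uppercases_and_validates(self):
        ds = ExpressionDataset("d1", "other", {"wnt3": 3.147})
        assert ds.fold_changes == {"WNT3": 3.147}
        with pytest.raises(ValidationError):
            ExpressionDataset("d1", "other", {"A": -1.0})
        with pytest.raises(ValidationError):
            ExpressionDataset("d1", "other", {"a": 1.0, "A": 2.0})


class TestNotation:
    def test_two_node_chain(self):
        sub, fcs = parse_subpathway_notation("SDC2 (3.091) <- TNC (9.557)")
        assert sub.nodes == ("TNC", "SDC2")
        assert sub.signs == (1,)
        assert fcs == {"TNC": 9.557, "SDC2": 3.091}

    def test_three_node_chain_with_divides_glyph(self):
        sub, fcs = parse_subpathway_notation(
            "PTCH1 (1.863) <- GLI2 (2.878) ∣- CSNK1G1 (0.587)"
        )
        assert sub.nodes == ("CSNK1G1", "GLI2", "PTCH1")
        assert sub.signs == (-1, 1)
        assert fcs == {"CSNK1G1": 0.587, "GLI2": 2.878, "PTCH1": 1.863}

    def test_single_gene_rejected(self):
        with pytest.raises(ValidationError):
            parse_subpathway_notation("X (1.0)")

    def test_malformed_token_reports_column(self):
        with pytest.raises(NotationParseError, match="column"):
            parse_subpathway_notation("SDC2 (3.091) <- TNC")

    def test_repeated_gene_rejected(self):
        with pytest.raises(ValidationError, match="repeated"):
            parse_subpathway_notation("A (2.0) <- B (0.5) <- A (2.0)")

    def test_universe_restricts_symbols(self):
        with pytest.raises(NotationParseError, match="unknown gene"):
            parse_subpathway_notation(
                "SDC2 (3.091) <- TNC (9.557)", universe={"SDC2"}
            )

    def test_format_emits_ascii_pipe(self):
        sub = Subpathway("hsa04340", ("CSNK1G1", "GLI2", "PTCH1"), (-1, 1))
        fcs = {"CSNK1G1": 0.587, "GLI2": 2.878, "PTCH1": 1.863}
        assert (
            format_subpathway_notation(sub, fcs)
            == "PTCH1 (1.863) <- GLI2 (2.878) |- CSNK1G1 (0.587)"
        )

    def test_format_missing_fold_change_names_gene(self):
        sub = Subpathway("p", ("A", "B"), (1,))
        with pytest.raises(KeyError, match="B"):
            format_subpathway_notation(sub, {"A": 2.0})

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        nodes=st.lists(
            st.from_regex(r"[A-Z][A-Z0-9]{0,5}", fullmatch=True),
            min_size=2, max_size=8, unique=True,
        ),
        data=st.data(),
    )
    def test_format_parse_roundtrip_property(self, nodes, data):
        signs = tuple(data.draw(st.sampled_from((1, -1))) for _ in nodes[:-1])
        fcs = {
            g: data.draw(
                st.floats(min_value=0.01, max_value=1000.0, allow_nan=False)
            )
            for g in nodes
        }
        sub = Subpathway("p", tuple(nodes), signs)
        text = format_subpathway_notation(sub, fcs)
        back, back_fcs = parse_subpathway_notation(text, pathway_id="p")
        assert back == sub and back_fcs == fcs

    def test_roundtrip_all_reported_chains(self, reported_chains):
        assert len(reported_chains) == 13
        for row in reported_chains:
            sub, fcs = parse_subpathway_notation(
                row.subpathway, pathway_id=row.kegg_pathway
            )
            assert format_subpathway_notation(sub, fcs) == row.subpathway


class TestTables:
    def test_fold_change_table(self, tmp_path):
        p = tmp_path / "fc.tsv"
        p.write_text("WNT3\t3.147\nGSK3B\t0.735\n")
        ds = read_fold_change_table(p, dataset_id="d")
        assert ds.fold_changes == {"WNT3": 3.147, "GSK3B": 0.735}

    def test_fold_change_header_and_gzip(self, tmp_path):
        p = tmp_path / "fc.tsv.gz"
        with gzip.open(p, "wt") as fh:
            fh.write("gene\tratio\nWNT3\t3.147\n")
        assert read_fold_change_table(p).fold_changes == {"WNT3": 3.147}

    def test_empty_table_warns(self, tmp_path, caplog):
        p = tmp_path / "fc.tsv"
        p.write_text("")
        with caplog.at_level("WARNING"):
            ds = read_fold_change_table(p)
        assert len(ds) == 0 and "empty" in caplog.text

    @pytest.mark.parametrize(
        "content", ["A\t2.0\nA\t3.0\n", "A\t-1.0\n", "A\t0\n"]
    )
    def test_bad_tables_rejected(self, tmp_path, content):
        p = tmp_path / "fc.tsv"
        p.write_text(content)
        with pytest.raises(ValidationError):
            read_fold_change_table(p)

    def test_gmt_roundtrip(self, tmp_path):
        p = tmp_path / "c.gmt"
        p.write_text("Chemokine\tna\tPTPN6\tIRAK3\tFLT3\tBAD\tCD36\n")
        cats = read_gmt(p)
        assert cats == {"Chemokine": {"PTPN6", "IRAK3", "FLT3", "BAD", "CD36"}}

    def test_bundled_inflammation_terms_cover_16_genes(self):
        cats = load_inflammation_terms()
        assert len(cats) == 5
        assert len(set().union(*cats.values())) == 16

    def test_sif_roundtrip(self, tmp_path, chain_graph):
        p = tmp_path / "n.sif"
        write_network_sif(chain_graph, p)
        lines = p.read_text().splitlines()
        assert "A\tactivates\tB" in lines
        back = read_network_sif(p)
        assert back.edges == chain_graph.edges
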