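"""Tripartite container, validation rules, and GML/TSV round trips."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from polynet import (
    EdgeTable,
    NodeKind,
    TripartiteNetwork,
    ValidationError,
    read_edge_table,
    read_gml,
    validate,
    write_edge_table,
    write_gml,
)

from oracles import random_edge_lists


def make_net(dg, ga):
    return TripartiteNetwork.from_edge_lists(dg, ga)


class TestContainer:
    def test_layer_partition_is_total(self, toy2):
        assert len(toy2.drugs) + len(toy2.go_terms) + len(toy2.adrs) == toy2.n_nodes

    @pytest.mark.parametrize(
        "src_kind,dst_kind",
        [
            (NodeKind.ADR, NodeKind.GO),
            (NodeKind.GO, NodeKind.DRUG),
            (NodeKind.DRUG, NodeKind.ADR),
            (NodeKind.DRUG, NodeKind.DRUG),
            (NodeKind.ADR, NodeKind.ADR),
        ],
    )
    def test_forbidden_layer_pairs_rejected(self, src_kind, dst_kind):
        net = TripartiteNetwork()
        net.add_node("u", src_kind)
        net.add_node("v", dst_kind)
        with pytest.raises(ValidationError, match="only drug->go and"):
            net.add_edge("u", "v")

    def test_case_insensitive_label_collision(self):
        net = TripartiteNetwork()
        net.add_node("Aspirin", NodeKind.DRUG)
        with pytest.raises(ValidationError, match="collides"):
            net.add_node("aspirin", NodeKind.DRUG)

    def test_re_adding_node_with_other_kind_fails(self):
        net = TripartiteNetwork()
        net.add_node("x", NodeKind.DRUG)
        with pytest.raises(ValidationError, match="already present"):
            net.add_node("x", NodeKind.GO)

    def test_duplicate_edges_collapse_by_summing_weights(self):
        net = TripartiteNetwork()
        net.add_node("d", NodeKind.DRUG)
        net.add_node("g", NodeKind.GO)
        net.add_edge("d", "g", 1.5)
        with pytest.warns(UserWarning, match="duplicate edge"):
            net.add_edge("d", "g", 2.0)
        assert net.edge_weight("d", "g") == pytest.approx(3.5)
        assert net.n_edges == 1

    def test_negative_weight_rejected(self):
        net = TripartiteNetwork()
        net.add_node("d", NodeKind.DRUG)
        net.add_node("g", NodeKind.GO)
        with pytest.raises(ValidationError, match="negative weight"):
            net.add_edge("d", "g", -0.5)


class TestValidate:
    def test_toy_network_is_clean(self, toy2):
        assert validate(toy2, strict=True) == []

    def test_isolated_go_flagged_only_in_strict_mode(self):
        net = make_net([("X", "A")], [("B", "1")])
        net.add_node("C", NodeKind.GO)
        assert validate(net) == []
        strict = validate(net, strict=True)
        assert any("'C'" in v for v in strict)
        # A lacks an ADR edge, B lacks a drug edge
        assert any("'A'" in v and "ADR" in v for v in strict)
        assert any("'B'" in v and "drug" in v for v in strict)

    def test_random_corruption_matches_independent_recheck(self, rng):
        _d, _g, _a, dg, ga = random_edge_lists(rng)
        net = make_net(dg, ga)
        strict = validate(net, strict=True)
        # independent re-check straight off the edge lists
        go_with_drug = {g for _x, g in dg}
        go_with_adr = {g for g, _x in ga}
        gos = net.go_terms
        expect_bad = sorted(
            (gos - go_with_drug) | (gos - go_with_adr)
        )
        flagged = sorted({v.split("'")[1] for v in strict if "GO node" in v})
        assert flagged == expect_bad


class TestGmlRoundTrip:
    def test_minimal_valid_path(self, tmp_path):
        net = make_net([("X", "A")], [("A", "1")])
        p = tmp_path / "m.gml"
        write_gml(net, p)
        back = read_gml(p)
        assert back == net
        assert back.kind("X") is NodeKind.DRUG
        assert back.kind("A") is NodeKind.GO
        assert back.kind("1") is NodeKind.ADR

    def test_forbidden_edge_in_gml_rejected(self, tmp_path):
        text = (
            'graph [\n  directed 1\n'
            '  node [ id 0 label "1" type "adr" ]\n'
            '  node [ id 1 label "A" type "go" ]\n'
            '  edge [ source 0 target 1 ]\n]\n'
        )
        p = tmp_path / "bad.gml"
        p.write_text(text)
        with pytest.raises(ValidationError, match="adr->go"):
            read_gml(p)

    def test_empty_network(self, tmp_path):
        p = tmp_path / "empty.gml"
        write_gml(TripartiteNetwork(), p)
        back = read_gml(p)
        assert back.n_nodes == 0 and back.n_edges == 0

    def test_two_drug_toy_counts(self, toy2, tmp_path):
        assert toy2.n_nodes == 13
        assert toy2.n_edges == 13

    def test_byte_reproducible_output(self, toy2, tmp_path):
        p1, p2 = tmp_path / "a.gml", tmp_path / "b.gml"
        write_gml(toy2, p1)
        write_gml(toy2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_round_trip_preserves_everything(self, seed, tmp_path):
        rng = np.random.default_rng(seed)
        _d, _g, _a, dg, ga = random_edge_lists(rng)
        dg = [(u, v, float(rng.integers(1, 5))) for u, v in dg]
        net = make_net(dg, ga)
        p = tmp_path / "rt.gml"
        write_gml(net, p)
        assert read_gml(p) == net

    def test_missing_kind_attribute_inferred_structurally(self, tmp_path):
        text = (
            'graph [\n  directed 1\n'
            '  node [ id 0 label "X" ]\n'
            '  node [ id 1 label "A" ]\n'
            '  node [ id 2 label "r1" ]\n'
            '  edge [ source 0 target 1 ]\n'
            '  edge [ source 1 target 2 ]\n]\n'
        )
        p = tmp_path / "untyped.gml"
        p.write_text(text)
        with pytest.warns(UserWarning, match="inferred"):
            net = read_gml(p)
        assert net.kind("X") is NodeKind.DRUG
        assert net.kind("A") is NodeKind.GO
        assert net.kind("r1") is NodeKind.ADR

    def test_unknown_extra_attributes_tolerated(self, tmp_path):
        text = (
            'graph [\n  directed 1\n'
            '  node [ id 0 label "X" type "drug" colour "purple" ]\n'
            '  node [ id 1 label "A" type "go" namespace "bp" ]\n'
            '  node [ id 2 label "r1" type "adr" ]\n'
            '  edge [ source 0 target 1 evidence "paea" ]\n'
            '  edge [ source 1 target 2 ]\n]\n'
        )
        p = tmp_path / "extra.gml"
        p.write_text(text)
        net = read_gml(p)
        assert net.n_nodes == 3 and net.n_edges == 2

    def test_malformed_gml_is_a_parse_error(self, tmp_path):
        p = tmp_path / "broken.gml"
        p.write_text("graph [ node [ id")
        with pytest.raises(ValidationError, match="cannot parse"):
            read_gml(p)


class TestEdgeTable:
    def test_two_row_tsv_defaults_to_unit_weights(self, tmp_path):
        p = tmp_path / "ga.tsv"
        p.write_text("source\ttarget\nGO:1\theadache\nGO:2\tnausea\n")
        t = read_edge_table(p, (NodeKind.GO, NodeKind.ADR))
        assert len(t) == 2
        assert all(w == 1.0 for _u, _v, w in t.rows())

    def test_duplicate_rows_rejected_with_listing(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("source\ttarget\nGO:1\tx\nGO:1\tx\n")
        with pytest.raises(ValidationError, match="GO:1->x"):
            read_edge_table(p, (NodeKind.GO, NodeKind.ADR))

    def test_negative_weight_rejected(self, tmp_path):
        p = tmp_path / "neg.tsv"
        p.write_text("source\ttarget\tweight\nGO:1\tx\t-2\n")
        with pytest.raises(ValidationError, match="negative"):
            read_edge_table(p, (NodeKind.GO, NodeKind.ADR))

    def test_csv_dialect_and_write_round_trip(self, tmp_path):
        t = EdgeTable.from_pairs(
            [("a", "g1", 2.0), ("b", "g2")], (NodeKind.DRUG, NodeKind.GO)
        )
        p = tmp_path / "t.csv"
        write_edge_table(t, p)
        back = read_edge_table(p, (NodeKind.DRUG, NodeKind.GO))
        assert list(back.rows()) == list(t.rows())

    def test_layer_pair_must_be_valid(self):
        with pytest.raises(ValidationError, match="not"):
            EdgeTable.from_pairs([("a", "b")], (NodeKind.ADR, NodeKind.GO))


@given(
    st.lists(
        st.tuples(
            st.sampled_from(["d0", "d1", "d2"]),
            st.sampled_from(["g0", "g1", "g2", "g3"]),
        ),
        min_size=1,
        max_size=8,
        unique=True,
    ),
    st.lists(
        st.tuples(
            st.sampled_from(["g0", "g1", "g2", "g3"]),
            st.sampled_from(["a0", "a1"]),
        ),
        min_size=1,
        max_size=6,
        unique=True,
    ),
)
def test_round_trip_property(tmp_path_factory, dg, ga):
    """write_gml followed by read_gml preserves nodes, edges and weights."""
    net = TripartiteNetwork.from_edge_lists(dg, ga)
    p = tmp_path_factory.mktemp("rt") / "net.gml"
    write_gml(net, p)
    assert read_gml(p) == net
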