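"""Network data model, IO, ontology reconciliation and pathway conversion."""

import itertools

import networkx as nx
import numpy as np
import pytest

from anchornet.errors import NetworkFormatError, OntologyError, PathwayError
from anchornet.network_io import (
    Interaction,
    InteractionNetwork,
    MethodOntology,
    extract_anchors_terminals,
    lowest_common_method,
    merge_networks,
    pathway_to_network,
    PathwayGraph,
    read_edge_list,
    read_kgml,
    write_network,
)


def net_of(*edges):
    return InteractionNetwork(Interaction(*e) for e in edges)


class TestInteraction:
    def test_endpoints_canonicalized(self):
        it = Interaction("b", "a", 0.5)
        assert (it.u, it.v) == ("a", "b")

    @pytest.mark.parametrize("u,v,c", [
        ("a", "a", 0.5),        # self loop
        ("a", "b", 0.0),        # zero confidence
        ("a", "b", 1.5),        # confidence > 1
        ("a", "b", -0.1),
        ("", "b", 0.5),         # empty id
        ("a b", "c", 0.5),      # whitespace in id
    ])
    def test_invalid_rejected(self, u, v, c):
        with pytest.raises(NetworkFormatError):
            Interaction(u, v, c)


class TestEdgeListIO:
    def test_undirected_dedup(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A\tB\t0.9\nB\tA\t0.9\n")
        net = read_edge_list(p)
        assert net.number_of_edges() == 1
        assert net.confidence("A", "B") == 0.9

    def test_self_loop_names_line(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A\tA\t0.5\n")
        with pytest.raises(NetworkFormatError, match=":1"):
            read_edge_list(p)

    def test_duplicate_keeps_max_and_warns(self, tmp_path, caplog):
        p = tmp_path / "net.tsv"
        p.write_text("A\tB\t0.9\nA\tB\t0.4\n")
        with caplog.at_level("WARNING"):
            net = read_edge_list(p)
        assert net.number_of_edges() == 1
        assert net.confidence("A", "B") == 0.9
        assert any("duplicate" in r.message for r in caplog.records)

    @pytest.mark.parametrize("line", ["A\tB", "A\tB\tnope", "A\tB\t1.7"])
    def test_malformed_line_rejects_file(self, tmp_path, line):
        p = tmp_path / "net.tsv"
        p.write_text("A\tB\t0.5\n" + line + "\n")
        with pytest.raises(NetworkFormatError, match=":2"):
            read_edge_list(p)

    def test_header_detected(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("u\tv\tconfidence\nA\tB\t0.5\n")
        assert read_edge_list(p).number_of_edges() == 1

    def test_single_edge_writes_one_data_line(self, tmp_path):
        p = tmp_path / "out.tsv"
        write_network(net_of(("a", "b", 0.7)), p)
        lines = p.read_text().splitlines()
        assert len(lines) == 2  # header + 1 edge

    def test_empty_network_round_trips(self, tmp_path):
        p = tmp_path / "empty.tsv"
        write_network(InteractionNetwork(), p)
        assert read_edge_list(p).number_of_edges() == 0

    def test_round_trip_identity(self, tmp_path, rng):
        edges = [(f"g{i}", f"g{i + 1 + int(rng.integers(1, 4))}",
                  float(rng.uniform(0.01, 1.0))) for i in range(20)]
        net = InteractionNetwork(
            Interaction(u, v, c, source="x", method_term="MI:0018")
            for u, v, c in edges)
        p = tmp_path / "rt.tsv"
        write_network(net, p)
        back = read_edge_list(p)
        assert back == net  # nodes, edges, confidences, exactly

    def test_sif_output(self, tmp_path):
        p = tmp_path / "out.sif"
        write_network(net_of(("a", "b", 0.7), ("b", "c", 0.5)), p,
                      format="sif")
        lines = p.read_text().splitlines()
        assert lines == ["a\tpp\tb", "b\tpp\tc"]
        assert (tmp_path / "out.sif.attrs").exists()


class TestLowestCommonMethod:
    # ontology fixture: MI:0001 -> MI:0045 -> {MI:0401, MI:0090};
    # MI:0018 under MI:0090; MI:0006 under both MI:0401 and MI:0090.

    def test_reflexive(self, ontology):
        assert lowest_common_method("MI:0018", "MI:0018", ontology) == "MI:0018"

    def test_forced_parent(self, ontology):
        assert lowest_common_method("MI:0401", "MI:0090",
                                    ontology) == "MI:0045"

    def test_diamond_picks_deepest(self, ontology):
        # MI:0006 is under both branches; vs MI:0018 the deepest common
        # ancestor is MI:0090 (depth 2), not MI:0045 (depth 1).
        assert lowest_common_method("MI:0006", "MI:0018",
                                    ontology) == "MI:0090"

    def test_unknown_term_raises(self, ontology):
        with pytest.raises(OntologyError, match="MI:9999"):
            lowest_common_method("MI:9999", "MI:0018", ontology)

    def test_matches_brute_force_on_random_dags(self, rng):
        """Implementation vs exhaustive common-ancestor enumeration."""
        for _ in range(25):
            n = int(rng.integers(4, 31))
            terms = [f"T{i}" for i in range(n)]
            is_a = {terms[0]: set()}
            for i in range(1, n):
                k = int(rng.integers(1, min(i, 3) + 1))
                parents = rng.choice(i, size=k, replace=False)
                is_a[terms[i]] = {terms[j] for j in parents}
            ont = MethodOntology(is_a)

            g = nx.DiGraph()
            for t, ps in is_a.items():
                g.add_node(t)
                g.add_edges_from((t, p) for p in ps)

            def depth(t):
                return max((len(p) - 1 for p in
                            nx.all_simple_paths(g, t, terms[0])), default=0)

            a, b = (terms[i] for i in rng.choice(n, size=2, replace=False))
            common = (nx.descendants(g, a) | {a}) & (nx.descendants(g, b) | {b})
            expected = min(common, key=lambda t: (-depth(t), t))
            assert lowest_common_method(a, b, ont) == expected


class TestMergeNetworks:
    def test_disjoint_union(self, ontology):
        n1 = net_of(("a", "b", 0.5))
        n2 = net_of(("c", "d", 0.6))
        merged = merge_networks(n1, n2, ontology)
        assert merged.number_of_edges() == 2

    def test_shared_pair_gets_lca_method(self, ontology):
        n1 = InteractionNetwork([Interaction("a", "b", 0.6, "intact",
                                             "MI:0018")])
        n2 = InteractionNetwork([Interaction("a", "b", 0.8, "biogrid",
                                             "MI:0006")])
        merged = merge_networks(n1, n2, ontology)
        it = merged.interaction("a", "b")
        assert it.method_term == "MI:0090"
        assert it.confidence == 0.8
        assert it.source == "both"

    def test_commutative_on_edges_and_confidence(self, ontology, rng):
        def rand_net(seed):
            r = np.random.default_rng(seed)
            edges = {}
            for _ in range(15):
                i, j = sorted(r.choice(8, size=2, replace=False))
                edges[(f"p{i}", f"p{j}")] = Interaction(
                    f"p{i}", f"p{j}", float(r.uniform(0.1, 1)),
                    method_term=["MI:0018", "MI:0006", "MI:0401"][
                        int(r.integers(3))])
            return InteractionNetwork(edges.values())

        n1, n2 = rand_net(1), rand_net(2)
        ab = merge_networks(n1, n2, ontology)
        ba = merge_networks(n2, n1, ontology)
        assert {it.pair for it in ab.interactions()} == \
               {it.pair for it in ba.interactions()}
        for it in ab.interactions():
            other = ba.interaction(*it.pair)
            assert other.confidence == it.confidence
            assert other.method_term == it.method_term


class TestPathwayConversion:
    def test_group_of_three_becomes_clique(self):
        pw = PathwayGraph(
            name="p", nodes=[("G", "group")],
            group_members={"G": ["A", "B", "C"]})
        net = pathway_to_network(pw)
        assert net.number_of_edges() == 3
        assert all(it.confidence == 0.6 for it in net.interactions())
        assert all(it.source == "kegg" for it in net.interactions())

    def test_compound_dropped_without_bridging(self):
        pw = PathwayGraph(
            name="p",
            nodes=[("A", "protein"), ("C", "compound"), ("B", "protein")],
            directed_edges=[("A", "C"), ("C", "B")])
        net = pathway_to_network(pw)
        assert net.number_of_edges() == 0
        assert "C" not in net.nodes

    def test_group_incident_edge_reattached_to_members(self):
        pw = PathwayGraph(
            name="p",
            nodes=[("A", "protein"), ("G", "group")],
            group_members={"G": ["B", "C"]},
            directed_edges=[("A", "G")])
        net = pathway_to_network(pw)
        pairs = {it.pair for it in net.interactions()}
        assert pairs == {("A", "B"), ("A", "C"), ("B", "C")}

    def test_empty_group_rejected(self):
        with pytest.raises(PathwayError):
            PathwayGraph(name="p", nodes=[("G", "group")], group_members={})

    def test_custom_confidence(self):
        pw = PathwayGraph(name="p", nodes=[("A", "protein"), ("B", "protein")],
                          directed_edges=[("A", "B")])
        net = pathway_to_network(pw, kegg_confidence=0.42)
        assert net.confidence("A", "B") == 0.42


class TestAnchorsTerminals:
    def chain(self, *names):
        return PathwayGraph(
            name="chain", nodes=[(n, "protein") for n in names],
            directed_edges=[(a, b) for a, b in itertools.pairwise(names)])

    def test_chain(self):
        anchors, terminals = extract_anchors_terminals(self.chain("a", "b", "c"))
        assert anchors == {"a"} and terminals == {"c"}

    def test_fanout(self):
        pw = PathwayGraph(
            name="fan",
            nodes=[("a", "protein"), ("b", "protein"), ("c", "protein")],
            directed_edges=[("a", "b"), ("a", "c")])
        anchors, terminals = extract_anchors_terminals(pw)
        assert anchors == {"a"} and terminals == {"b", "c"}

    def test_isolated_node_excluded_and_logged(self, caplog):
        pw = PathwayGraph(
            name="iso",
            nodes=[("a", "protein"), ("b", "protein"), ("c", "protein"),
                   ("d", "protein")],
            directed_edges=[("a", "b"), ("b", "c")])
        with caplog.at_level("WARNING"):
            anchors, terminals = extract_anchors_terminals(pw)
        assert anchors == {"a"} and terminals == {"c"}
        assert any("isolated" in r.message for r in caplog.records)

    def test_no_terminals_is_error(self):
        pw = PathwayGraph(
            name="cycle",
            nodes=[("a", "protein"), ("b", "protein")],
            directed_edges=[("a", "b"), ("b", "a")])
        with pytest.raises(PathwayError, match="unusable"):
            extract_anchors_terminals(pw)

    def test_anchors_terminals_disjoint_property(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 10))
            names = [f"x{i}" for i in range(n)]
            edges = [(names[i], names[j])
                     for i in range(n) for j in range(n)
                     if i != j and rng.random() < 0.3]
            pw = PathwayGraph(name="r",
                              nodes=[(x, "protein") for x in names],
                              directed_edges=edges)
            try:
                anchors, terminals = extract_anchors_terminals(pw)
            except PathwayError:
                continue
            assert not anchors & terminals


class TestKGML:
    def test_counts_match_hand_count(self, kgml_file):
        pw = read_kgml(kgml_file)
        kinds = {}
        for _, kind in pw.nodes:
            kinds[kind] = kinds.get(kind, 0) + 1
        # hand count of the fixture: 5 genes, 1 compound, 1 group of 2
        assert kinds == {"protein": 5, "compound": 1, "group": 1}
        assert pw.group_members["group_6"] == ["toy:D", "toy:E"]
        assert len(pw.directed_edges) == 5

    def test_relations_become_directed_edges(self, tmp_path):
        p = tmp_path / "two.kgml"
        p.write_text(
            '<?xml version="1.0"?><pathway name="p">'
            '<entry id="1" name="g:A" type="gene"/>'
            '<entry id="2" name="g:B" type="gene"/>'
            '<relation entry1="1" entry2="2"/></pathway>')
        pw = read_kgml(p)
        assert [k for _, k in pw.nodes] == ["protein", "protein"]
        assert pw.directed_edges == [("g:A", "g:B")]

    def test_dangling_relation_rejected(self, tmp_path):
        p = tmp_path / "bad.kgml"
        p.write_text(
            '<?xml version="1.0"?><pathway name="p">'
            '<entry id="1" name="g:A" type="gene"/>'
            '<relation entry1="1" entry2="99"/></pathway>')
        with pytest.raises(NetworkFormatError, match="99"):
            read_kgml(p)

    def test_malformed_xml_rejected(self, tmp_path):
        p = tmp_path / "broken.kgml"
        p.write_text("<pathway><entry ")
        with pytest.raises(NetworkFormatError, match="parse"):
            read_kgml(p)

    def test_full_fixture_conversion(self, kgml_file):
        pw = read_kgml(kgml_file)
        net = pathway_to_network(pw)
        # compound never survives conversion
        assert "cpd:C00001" not in net.nodes
        assert all(it.confidence == 0.6 for it in net.interactions())
        anchors, terminals = extract_anchors_terminals(pw)
        assert anchors == {"toy:A"}
        assert terminals == {"toy:F"}
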