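"""Gene mapping, over-representation, and network hub scoring."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from oamethyl.io import CpGAnnotation
from oamethyl.network import (
    GeneSetCollection,
    classify_effector_status,
    composite_node_score,
    hypergeometric_ora,
    load_edge_list,
    map_cpg_to_genes,
)
from oracles import betweenness_oracle, hypergeom_tail_oracle


def annotation():
    return CpGAnnotation(
        probes=pd.DataFrame({
            "cpg_id": ["cg1", "cg2", "cg3", "cg4"],
            "chrom": ["chr1"] * 4,
            "pos": [100, 200, 300, 400]}),
        links=pd.DataFrame({
            "cpg_id": ["cg1", "cg1", "cg2"],
            "gene": ["B", "A", "A"],
            "tss_pos": [90, 95, 210],
            "strand": ["+", "-", "+"]}))


class TestGeneMapping:
    def test_union_sorted_and_unmapped_reported(self):
        genes, unmapped = map_cpg_to_genes(["cg1", "cg2", "cg3"], annotation())
        assert genes == ["A", "B"]
        assert unmapped == ["cg3"]

    def test_unknown_probe_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            map_cpg_to_genes(["cg1", "cgX"], annotation())

    def test_effector_status_partition(self):
        genes = [f"G{i}" for i in range(10)]
        validated = {"G0", "G1", "G2", "OTHER"}
        database = {"G2", "G3", "G4"}  # G2 double-listed counts as validated
        counts = classify_effector_status(genes, validated, database)
        assert counts == (3, 2, 5)
        assert sum(counts) == len(genes)

    def test_reported_breakdown_180_genes(self):
        genes = [f"G{i:03d}" for i in range(180)]
        validated = set(genes[:91])
        database = set(genes[91:132])
        counts = classify_effector_status(genes, validated, database)
        assert counts == (91, 41, 48)


class TestHypergeometricOra:
    def test_exact_closed_form_p(self):
        # query of 5 inside a set of 5 over a universe of 20:
        # p = 1 / C(20,5)
        universe = [f"G{i}" for i in range(20)]
        coll = GeneSetCollection(sets={"S": set(universe[:5])},
                                 descriptions={"S": ""})
        table = hypergeometric_ora(universe[:5], coll, universe)
        expected = 1.0 / math.comb(20, 5)
        assert abs(table["p_value"].iloc[0] - expected) < 1e-12

    def test_zero_overlap_gives_p_one(self):
        universe = [f"G{i}" for i in range(20)]
        coll = GeneSetCollection(sets={"S": set(universe[10:15])},
                                 descriptions={})
        table = hypergeometric_ora(universe[:5], coll, universe)
        assert table["p_value"].iloc[0] == 1.0

    def test_matches_comb_summation_oracle(self):
        rng = np.random.default_rng(5)
        universe = [f"G{i}" for i in range(60)]
        query = list(rng.choice(universe, size=12, replace=False))
        sets = {f"S{j}": set(rng.choice(universe,
                                        size=int(rng.integers(5, 25)),
                                        replace=False))
                for j in range(8)}
        coll = GeneSetCollection(sets=sets, descriptions={})
        table = hypergeometric_ora(query, coll, universe).set_index("set_name")
        for name, members in sets.items():
            ref = hypergeom_tail_oracle(
                k=len(members & set(query)), M=60, n=len(query),
                N=len(members))
            assert abs(table.loc[name, "p_value"] - ref) < 1e-12

    def test_query_outside_background_rejected(self):
        coll = GeneSetCollection(sets={"S": {"A"}}, descriptions={})
        with pytest.raises(ValueError, match="subset"):
            hypergeometric_ora(["Z"], coll, ["A", "B"])

    def test_empty_background_rejected(self):
        coll = GeneSetCollection(sets={"S": {"A"}}, descriptions={})
        with pytest.raises(ValueError, match="background"):
            hypergeometric_ora([], coll, [])

    def test_sorted_by_adjusted_p(self):
        universe = [f"G{i}" for i in range(30)]
        coll = GeneSetCollection(
            sets={"HIT": set(universe[:6]), "MISS": set(universe[20:26])},
            descriptions={})
        table = hypergeometric_ora(universe[:6], coll, universe)
        assert list(table["set_name"]) == ["HIT", "MISS"]
        assert (table["adj_p"].diff().dropna() >= 0).all()


class TestEdgeList:
    def write(self, tmp_path, rows):
        path = tmp_path / "edges.tsv"
        path.write_text("node_a\tnode_b\tcombined_score\n"
                        + "".join(f"{a}\t{b}\t{s}\n" for a, b, s in rows))
        return path

    def test_threshold_inclusive_at_500(self, tmp_path):
        path = self.write(tmp_path, [("A", "B", 499), ("B", "C", 500),
                                     ("C", "D", 900)])
        graph = load_edge_list(path)
        assert set(map(frozenset, graph.edges())) \
            == {frozenset({"B", "C"}), frozenset({"C", "D"})}

    def test_duplicate_undirected_edge_keeps_max(self, tmp_path):
        path = self.write(tmp_path, [("A", "B", 600), ("B", "A", 800)])
        graph = load_edge_list(path)
        assert graph.number_of_edges() == 1
        assert graph["A"]["B"]["combined_score"] == 800

    def test_self_loop_dropped(self, tmp_path):
        path = self.write(tmp_path, [("A", "A", 900), ("A", "B", 900)])
        graph = load_edge_list(path)
        assert list(map(sorted, graph.edges())) == [["A", "B"]]

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("node_a\tnode_b\tcombined_score\n"
                        "A\tB\t600\nA\tC\tnot_a_number\n")
        with pytest.raises(ValueError, match="line 3"):
            load_edge_list(path)


class TestCompositeScore:
    @staticmethod
    def scored(edges):
        g = nx.Graph()
        g.add_edges_from((a, b, {"combined_score": 900}) for a, b in edges)
        return g

    def test_star_center_scores_one_leaves_zero(self):
        g = self.scored([("C", f"L{i}") for i in range(4)])
        table = composite_node_score(g).set_index("node")
        assert table.loc["C", "composite"] == 1.0
        for i in range(4):
            assert table.loc[f"L{i}", "composite"] == 0.0

    def test_path_middle_has_all_betweenness(self):
        g = self.scored([("A", "B"), ("B", "C")])
        table = composite_node_score(g).set_index("node")
        assert table.loc["B", "betweenness_c"] == 1.0
        assert table.loc["A", "betweenness_c"] == 0.0
        assert table.index[0] == "B"

    def test_betweenness_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(11)
        for trial in range(10):
            n = int(rng.integers(5, 12))
            g = nx.gnp_random_graph(n, 0.4, seed=trial)
            g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
            nx.set_edge_attributes(g, 900, "combined_score")
            if g.number_of_edges() == 0:
                continue
            table = composite_node_score(g, top_k=n).set_index("node")
            ref = betweenness_oracle(g)
            for node, val in ref.items():
                assert abs(table.loc[node, "betweenness_c"] - val) < 1e-12

    def test_weights_must_sum_to_one(self):
        g = self.scored([("A", "B")])
        with pytest.raises(ValueError, match="sum to 1"):
            composite_node_score(g, w_degree=0.7, w_between=0.5)

    def test_top_k_truncation_and_tie_break(self):
        g = self.scored([("A", "B"), ("C", "D")])
        table = composite_node_score(g, top_k=2)
        # all four nodes tie (constant centralities -> 0); id breaks ties
        assert list(table["node"]) == ["A", "B"]

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            composite_node_score(nx.Graph())
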