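"""Synthetic cohort, interaction-network, and gene-set generators."""

import numpy as np
import pytest

from oamethyl.cohort import (
    SimulationConfig,
    generate_cohort,
    generate_gene_sets,
    generate_interaction_network,
    write_edge_list,
)
from oamethyl.network import load_edge_list
from oracles import betweenness_oracle, hypergeom_tail_oracle


class TestCohortShapes:
    def test_dimensions_labels_and_batches(self, small_cohort):
        matrix, annotation, truth = small_cohort
        assert matrix.values.shape == (500, 90)
        assert int(np.sum(matrix.labels)) == 60
        assert len(set(matrix.batch)) == 3
        assert len(annotation.probes) == 500
        assert len(truth.dm_cpg_ids) == 40
        assert len(truth.effector_genes) == 15

    def test_values_in_unit_interval(self, small_cohort):
        matrix, _, _ = small_cohort
        assert np.nanmin(matrix.values) >= 0.0
        assert np.nanmax(matrix.values) <= 1.0

    def test_same_seed_identical_cohort(self):
        cfg = SimulationConfig(n_cases=10, n_controls=8, n_cpg=100, n_dm=10,
                               seed=3)
        m1, a1, t1 = generate_cohort(cfg)
        m2, a2, t2 = generate_cohort(cfg)
        np.testing.assert_array_equal(m1.values, m2.values)
        assert t1.dm_cpg_ids == t2.dm_cpg_ids
        assert a1.links.equals(a2.links)

    def test_different_seeds_differ(self):
        cfg = dict(n_cases=10, n_controls=8, n_cpg=100, n_dm=10)
        m1, _, _ = generate_cohort(SimulationConfig(**cfg, seed=1))
        m2, _, _ = generate_cohort(SimulationConfig(**cfg, seed=2))
        assert not np.array_equal(m1.values, m2.values)

    def test_missing_rate_produces_nans(self):
        cfg = SimulationConfig(n_cases=10, n_controls=8, n_cpg=200, n_dm=10,
                               missing_rate=0.05, seed=4)
        matrix, _, _ = generate_cohort(cfg)
        frac = np.isnan(matrix.values).mean()
        assert 0.02 < frac < 0.09

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="n_dm"):
            SimulationConfig(n_cpg=10, n_dm=11)
        with pytest.raises(ValueError, match="delta_beta"):
            SimulationConfig(delta_beta=0.0)
        with pytest.raises(ValueError, match="missing_rate"):
            SimulationConfig(missing_rate=1.0)


class TestPlantedEffect:
    def test_planted_delta_beta_recovered(self):
        # Monte-Carlo check of the planted |Δβ| on the noise-free means:
        # with 600 samples per group and concentration 60 the group-mean
        # standard error is ~0.0025, so a ±0.03 band around 0.25 is wide
        deltas = []
        for seed in range(5):
            cfg = SimulationConfig(n_cases=600, n_controls=600, n_cpg=300,
                                   n_dm=30, delta_beta=0.25,
                                   batch_shift_sd=0.0, seed=seed)
            matrix, _, truth = generate_cohort(cfg)
            labels = np.asarray(matrix.labels)
            idx = [matrix.cpg_ids.index(c) for c in truth.dm_cpg_ids]
            gap = (matrix.values[idx][:, labels == 1].mean(axis=1)
                   - matrix.values[idx][:, labels == 0].mean(axis=1))
            deltas.append(np.abs(gap).mean())
        assert 0.22 < float(np.median(deltas)) < 0.28

    def test_both_directions_planted(self):
        cfg = SimulationConfig(n_cases=200, n_controls=200, n_cpg=300,
                               n_dm=40, batch_shift_sd=0.0, seed=6)
        matrix, _, truth = generate_cohort(cfg)
        labels = np.asarray(matrix.labels)
        idx = [matrix.cpg_ids.index(c) for c in truth.dm_cpg_ids]
        gap = (matrix.values[idx][:, labels == 1].mean(axis=1)
               - matrix.values[idx][:, labels == 0].mean(axis=1))
        assert (gap > 0.1).sum() >= 10
        assert (gap < -0.1).sum() >= 10

    def test_unplanted_probes_have_no_effect(self):
        cfg = SimulationConfig(n_cases=300, n_controls=300, n_cpg=300,
                               n_dm=20, batch_shift_sd=0.0, seed=7)
        matrix, _, truth = generate_cohort(cfg)
        labels = np.asarray(matrix.labels)
        planted = set(truth.dm_cpg_ids)
        idx = [i for i, c in enumerate(matrix.cpg_ids) if c not in planted]
        gap = (matrix.values[idx][:, labels == 1].mean(axis=1)
               - matrix.values[idx][:, labels == 0].mean(axis=1))
        assert np.abs(gap).max() < 0.05

    def test_planted_probes_link_to_effectors(self, small_cohort):
        _, annotation, truth = small_cohort
        linked = set(
            annotation.links[annotation.links["gene"]
                             .isin(truth.effector_genes)]["cpg_id"])
        n_linked_dm = len(linked & set(truth.dm_cpg_ids))
        # half of the planted probes sit in effector TSS windows
        assert n_linked_dm >= len(truth.dm_cpg_ids) // 2


class TestInteractionNetwork:
    def test_hub_degree_exceeds_3x_median(self):
        genes = [f"G{i:03d}" for i in range(40)]
        graph, hubs = generate_interaction_network(genes, n_hubs=3, seed=1)
        non_hubs = [g for g in genes if g not in hubs]
        med = float(np.median([graph.degree(n) for n in non_hubs]))
        assert all(graph.degree(h) >= 3 * med for h in hubs)
        assert len(hubs) == 3

    def test_hubs_have_top_betweenness(self):
        genes = [f"G{i:03d}" for i in range(24)]
        graph, hubs = generate_interaction_network(genes, n_hubs=2, seed=2)
        bet = betweenness_oracle(graph)
        top2 = sorted(bet, key=lambda n: -bet[n])[:2]
        assert set(top2) == set(hubs)

    def test_scores_within_range(self):
        graph, _ = generate_interaction_network(
            [f"G{i}" for i in range(20)], n_hubs=2,
            combined_score_range=(500, 700), seed=3)
        scores = [d["combined_score"] for _, _, d in graph.edges(data=True)]
        assert min(scores) >= 500 and max(scores) <= 700

    def test_infeasible_hub_count_rejected(self):
        with pytest.raises(ValueError, match="n_hubs|hubs"):
            generate_interaction_network(["A", "B"], n_hubs=3)

    def test_edge_list_round_trip(self, tmp_path):
        graph, _ = generate_interaction_network(
            [f"G{i}" for i in range(15)], n_hubs=2, seed=4)
        path = tmp_path / "edges.tsv"
        write_edge_list(graph, path)
        back = load_edge_list(path, min_score=0)
        assert set(map(frozenset, back.edges())) \
            == set(map(frozenset, graph.edges()))


class TestGeneSets:
    GENES = [f"G{i:03d}" for i in range(200)]

    def test_counts_and_membership(self):
        coll, enriched, query = generate_gene_sets(
            self.GENES, n_sets=20, enriched_fraction=0.2, seed=1)
        assert len(coll.sets) == 20
        assert len(enriched) == 4
        universe = set(self.GENES)
        for members in coll.sets.values():
            assert members <= universe
            assert 10 <= len(members) <= 30

    def test_enriched_sets_are_query_heavy(self):
        coll, enriched, query = generate_gene_sets(
            self.GENES, n_sets=20, enriched_fraction=0.2, seed=2)
        q = set(query)
        for name in enriched:
            share = len(coll.sets[name] & q) / len(coll.sets[name])
            assert share >= 0.5

    def test_enrichment_is_statistically_detectable(self):
        coll, enriched, query = generate_gene_sets(
            self.GENES, n_sets=10, enriched_fraction=0.1, seed=3)
        q = set(query)
        name = enriched[0]
        members = coll.sets[name]
        p = hypergeom_tail_oracle(
            k=len(members & q), M=len(self.GENES), n=len(q), N=len(members))
        assert p < 1e-6

    def test_gmt_round_trip(self, tmp_path):
        coll, _, _ = generate_gene_sets(self.GENES, n_sets=8,
                                        enriched_fraction=0.25, seed=4)
        path = tmp_path / "sets.gmt"
        coll.write_gmt(path)
        back = type(coll).read_gmt(path)
        assert back.sets == coll.sets
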