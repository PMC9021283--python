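import itertools
import math

import pytest

from sescreen import (DrugProfile, GeneSet, Interactome, classify_mode,
                      drug_action_map, extract_moa_subnetwork,
                      mode_counts_by_cluster, screen_drugs)
from sescreen.proximity import ProximityResult
from sescreen.screen import apply_disease_criterion, apply_side_effect_criterion
from sescreen.similarity import assemble_network


def prox(drug, set_id, p, z):
    return ProximityResult(drug, set_id, p, z, 0.0, 1.0, 10, 0, 1, 0)


class TestDiseaseCriterion:
    def test_threshold_rule(self):
        results = [prox("keep", "D", 1.0, -2.0), prox("drop", "D", 1.0, -1.0),
                   prox("edge", "D", 1.0, -1.65), prox("near", "D", 1.0, -1.64)]
        kept = apply_disease_criterion(results, "D")
        assert kept == {"keep", "edge"}   # -1.65 is inclusive

    def test_unknown_disease_errors(self):
        with pytest.raises(ValueError):
            apply_disease_criterion([prox("d", "D", 1.0, -2.0)], "X")

    def test_constructed_counts(self):
        results = [prox(f"d{i}", "D", 1.0, -2.0 if i < 8 else -1.0)
                   for i in range(20)]
        assert len(apply_disease_criterion(results, "D")) == 8


class TestSideEffectCriterion:
    def test_rules(self):
        kept = {"a", "b", "c", "d"}
        se = [prox("a", "S", 0.5, -2.0), prox("b", "S", 0.5, -2.0),
              prox("c", "S", 0.5, -1.0), prox("d", "S", 0.5, -2.0)]
        as_se = {"a": 0.7, "b": 0.5, "c": 0.9, "d": 0.3}
        removed, retained = apply_side_effect_criterion(kept, se, as_se)
        # a: significant & 0.7 -> removed; b: boundary 0.5 inclusive -> removed
        # c: not significant -> retained despite high AS; d: AS < 0.5 -> retained
        assert removed == {"a", "b"} and retained == {"c", "d"}

    def test_raising_cutoff_never_grows_removed(self):
        kept = {"a", "b"}
        se = [prox("a", "S", 0.5, -2.0), prox("b", "S", 0.5, -2.0)]
        as_se = {"a": 0.7, "b": 0.55}
        removed_lo, _ = apply_side_effect_criterion(kept, se, as_se, as_cutoff=0.5)
        removed_hi, _ = apply_side_effect_criterion(kept, se, as_se, as_cutoff=0.6)
        assert removed_hi <= removed_lo


class TestClassifyMode:
    def test_se_proximal_disease_distal_quadrant(self):
        assert classify_mode(0.8, 0.3) == "proximal_distal"

    def test_boundary_both_inclusive(self):
        assert classify_mode(0.5, 0.5) == "proximal_proximal"

    def test_missing_se_is_distal(self):
        assert classify_mode(None, 0.8) == "distal_proximal"

    def test_grid_matches_truth_table(self):
        grid = [0.0, 0.49, 0.5, 0.51, 1.0]
        for as_se, as_dis in itertools.product(grid, grid):
            se_p = as_se >= 0.5
            dis_p = as_dis >= 0.5
            expected = {(True, False): "proximal_distal",
                        (True, True): "proximal_proximal",
                        (False, True): "distal_proximal",
                        (False, False): "distal_distal"}[(se_p, dis_p)]
            assert classify_mode(as_se, as_dis) == expected


def make_screen_inputs():
    """Hand-built proximity results for one disease and one side effect."""
    results = [
        # disease axis
        prox("close_both", "D", 0.0, -3.0), prox("close_dis", "D", 0.0, -3.0),
        prox("close_se", "D", 3.0, -1.0), prox("far", "D", 3.0, -0.5),
        prox("borderline", "D", 1.0, -1.65),
        # side-effect axis
        prox("close_both", "S", 0.0, -3.0), prox("close_dis", "S", 3.0, -0.5),
        prox("close_se", "S", 0.0, -3.0), prox("far", "S", 3.0, -0.2),
        prox("borderline", "S", 3.0, -1.0),
    ]
    network = assemble_network(results)
    return results, network


class TestScreenDrugs:
    def test_verdict_partition_and_modes(self):
        results, network = make_screen_inputs()
        records, (report,) = screen_drugs(results, network, "D", ["S"])
        by_drug = {r.drug_id: r for r in records}
        assert by_drug["close_both"].verdict == "removed_criterion2"
        assert by_drug["close_both"].mode == "proximal_proximal"
        assert by_drug["close_dis"].verdict == "retained"
        assert by_drug["close_dis"].mode == "distal_proximal"
        assert by_drug["close_se"].verdict == "removed_criterion1"
        assert by_drug["close_se"].mode == "proximal_distal"
        assert by_drug["far"].verdict == "removed_criterion1"
        assert by_drug["far"].mode == "distal_distal"
        assert by_drug["borderline"].verdict == "retained"   # z = -1.65 kept
        # every record has exactly one verdict and one mode
        assert report.n_predicted == report.n_removed + report.n_retained
        assert report.n_predicted == 3 and report.n_removed == 1

    def test_criterion_order_independence(self):
        results, network = make_screen_inputs()
        records, _ = screen_drugs(results, network, "D", ["S"])
        kept1 = apply_disease_criterion(results, "D")
        as_se = {r.drug_id: r.as_se for r in records if r.as_se is not None}
        se_results = [r for r in results if r.set_id == "S"]
        removed2, _ = apply_side_effect_criterion(kept1, se_results, as_se)
        pipeline_removed = {r.drug_id for r in records
                            if r.verdict == "removed_criterion2"}
        assert pipeline_removed == removed2 & kept1

    def test_multiple_side_effects_union(self):
        results, _ = make_screen_inputs()
        extra = [prox(d, "S2", 3.0, -0.3) for d in
                 ["close_both", "close_dis", "close_se", "far", "borderline"]]
        network = assemble_network(results + extra)
        records, reports = screen_drugs(results + extra, network, "D",
                                        ["S", "S2"])
        assert {rep.side_effect_id for rep in reports} == {"S", "S2"}
        # S2 proximities are all non-significant: removes nobody
        s2 = [r for r in records if r.side_effect_id == "S2"]
        assert all(r.verdict != "removed_criterion2" for r in s2)


class TestDrugActionMap:
    def test_coordinates_and_strata(self):
        results, network = make_screen_inputs()
        records, _ = screen_drugs(results, network, "D", ["S"])
        table = drug_action_map(records)
        row = table[table["drug"] == "close_both"].iloc[0]
        rec = next(r for r in records if r.drug_id == "close_both")
        assert row["y_one_minus_as_se"] == pytest.approx(1.0 - rec.as_se)
        assert row["stratum"] == "significant"
        far = table[table["drug"] == "far"].iloc[0]
        assert far["stratum"] == "not_significant"
        # quadrant tallies equal classify_mode tallies
        assert table["mode"].value_counts().to_dict() == {
            m: sum(r.mode == m for r in records)
            for m in table["mode"].unique()}


class TestModeCountsByCluster:
    def test_single_cluster_equals_global_tally(self):
        results, network = make_screen_inputs()
        records, _ = screen_drugs(results, network, "D", ["S"])
        table = mode_counts_by_cluster(network, records)
        total = table[["proximal_distal", "proximal_proximal",
                       "distal_proximal", "distal_distal"]].sum().sum()
        assert total == len(records)


class TestMoaSubnetwork:
    def test_ramipril_style_toy(self):
        inter = Interactome.from_edges([
            ("ACE", "BDKRB1"), ("BDKRB1", "MEP1A"), ("MEP1A", "deep"),
            ("ACE", "other")])
        drug = DrugProfile("ramipril", frozenset({"ACE", "BDKRB1"}))
        asthma = GeneSet("asthma", frozenset({"ACE", "BDKRB1"}), "side_effect")
        cardio = GeneSet("cardio", frozenset({"MEP1A", "deep"}))
        sub, roles = extract_moa_subnetwork(drug, cardio, asthma, inter)
        assert roles["BDKRB1"] == {"target", "side_effect"}
        assert roles["ACE"] == {"target", "side_effect"}
        assert "MEP1A" in sub and roles["MEP1A"] == {"disease"}
        assert "deep" not in sub    # disease gene not adjacent to a target

    def test_isolated_targets_only(self):
        inter = Interactome.from_edges([("t1", "x"), ("a", "b")])
        drug = DrugProfile("d", frozenset({"t1"}))
        dis = GeneSet("D", frozenset({"a"}))
        se = GeneSet("S", frozenset({"b"}), "side_effect")
        sub, roles = extract_moa_subnetwork(drug, dis, se, inter)
        assert set(sub.nodes) == {"t1"} and roles["t1"] == {"target"}

    def test_roles_match_brute_force_set_algebra(self):
        import networkx as nx
        import numpy as np
        g = nx.gnp_random_graph(40, 0.12, seed=9)
        inter = Interactome(nx.relabel_nodes(g, {n: f"g{n}" for n in g}))
        rng = np.random.default_rng(2)
        nodes = sorted(inter.nodes)
        targets = set(rng.choice(nodes, 4, replace=False))
        dis = set(rng.choice(nodes, 8, replace=False))
        se = set(rng.choice(nodes, 8, replace=False))
        sub, roles = extract_moa_subnetwork(
            DrugProfile("d", frozenset(targets)),
            GeneSet("D", frozenset(dis)),
            GeneSet("S", frozenset(se), "side_effect"), inter)
        adj = inter.adjacency
        nbrs = set().union(*(adj[t] for t in targets))
        expect_nodes = (targets | (dis & nbrs) | (se & nbrs) |
                        {v for v in nbrs - dis - se - targets if adj[v] & dis})
        assert set(sub.nodes) == expect_nodes
        for n in sub.nodes:
            expected_roles = set()
            if n in targets:
                expected_roles.add("target")
            if n in dis:
                expected_roles.add("disease")
            if n in se:
                expected_roles.add("side_effect")
            if n in nbrs - dis - se - targets and adj[n] & dis:
                expected_roles.add("bridge")
            assert roles[n] == expected_roles
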