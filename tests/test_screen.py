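"""Three-round screen: round semantics, oracle equivalence, IO."""

import json

import numpy as np
import pytest

from lisnet import (
    MissingPredictionError,
    PpiNetwork,
    ScreenConfig,
    export_network,
    read_network,
    round1,
    round2,
    round3,
    run_screen,
    simulate_screen_scenario,
    write_manifest,
)

import networkx as nx


class TestRound1:
    def test_empty_candidate_set(self):
        sc = simulate_screen_scenario(seed=0)
        g1, edges, failed = round1(sc.bait, [], sc.provider)
        assert g1 == set() and edges == [] and failed == set()

    def test_planted_direct_interactors_recovered_exactly(self):
        sc = simulate_screen_scenario(seed=1)
        g1, edges, failed = round1(sc.bait, sc.candidates, sc.provider)
        assert g1 == set(sc.truth.planted_direct)
        assert g1 | failed == set(sc.candidates)
        assert all(rnd == 1 and u == sc.bait for u, _, _, _, rnd in edges)

    def test_absent_predictions_fall_into_failed_set(self, caplog):
        sc = simulate_screen_scenario(seed=2)
        victim = sorted(sc.truth.planted_direct)[0]
        sc.provider.absent_pairs.add(frozenset((sc.bait, victim)))
        with caplog.at_level("WARNING", logger="lisnet.screen"):
            g1, _, failed = round1(sc.bait, sc.candidates, sc.provider)
        assert victim in failed and victim not in g1
        assert any("no predictions" in r.message for r in caplog.records)

    def test_strict_policy_raises_on_missing(self):
        sc = simulate_screen_scenario(seed=2)
        victim = sorted(sc.truth.planted_direct)[0]
        sc.provider.absent_pairs.add(frozenset((sc.bait, victim)))
        with pytest.raises(MissingPredictionError):
            round1(sc.bait, sc.candidates, sc.provider, ScreenConfig(strict=True))


class TestRound2:
    def test_bridge_gains_single_edge_to_its_group1_partner(self):
        sc = simulate_screen_scenario(n_direct=2, n_bridge=1, n_decoy=2, seed=3)
        g1, _, failed = round1(sc.bait, sc.candidates, sc.provider)
        g2, edges = round2(g1, failed, sc.provider)
        (bridge,) = sc.truth.planted_bridge
        assert g2 == {bridge}
        bridge_edges = [(u, v) for u, v, *_ in edges if bridge in (u, v)]
        assert bridge_edges == [(sc.truth.planted_bridge[bridge], bridge)]

    def test_empty_failed_set_can_still_add_intra_group1_edges(self):
        sc = simulate_screen_scenario(n_direct=3, n_bridge=0, n_decoy=0, seed=4)
        # plant an intra-group1 contact as well
        sc.provider.planted_pairs.add(frozenset(("direct01", "direct02")))
        g1, _, failed = round1(sc.bait, sc.candidates, sc.provider)
        assert failed == set()
        g2, edges = round2(g1, failed, sc.provider)
        assert g2 == set()
        assert {(u, v) for u, v, *_ in edges} == {("direct01", "direct02")}

    def test_candidate_passing_two_group1_members_gets_two_edges(self):
        sc = simulate_screen_scenario(n_direct=2, n_bridge=1, n_decoy=0, seed=5)
        sc.provider.planted_pairs.add(frozenset(("bridge01", "direct02")))
        g1, _, failed = round1(sc.bait, sc.candidates, sc.provider)
        g2, edges = round2(g1, failed, sc.provider)
        assert g2 == {"bridge01"}
        assert len([e for e in edges if "bridge01" in e[:2]]) == 2


class TestRound3:
    def test_empty_remaining(self):
        sc = simulate_screen_scenario(n_direct=2, n_bridge=0, n_decoy=0, seed=6)
        g3, edges = round3(set(), [sc.bait, "direct01", "direct02"], sc.provider)
        assert g3 == set() and edges == []

    def test_planted_tertiary_contact_joins_group3(self):
        sc = simulate_screen_scenario(n_direct=2, n_bridge=1, n_decoy=1, n_tertiary=1, seed=7)
        net = run_screen(sc.bait, sc.candidates, sc.provider)
        groups = net.groups
        assert groups["group3"] == set(sc.truth.planted_tertiary)
        (tert,) = sc.truth.planted_tertiary
        assert net.graph.edges[tert, sc.truth.planted_tertiary[tert]]["round"] == 3

    def test_decoys_excluded_entirely(self):
        sc = simulate_screen_scenario(seed=8)
        net = run_screen(sc.bait, sc.candidates, sc.provider)
        assert not (set(net.graph.nodes) & set(sc.truth.decoys))


class TestRunScreen:
    def test_minimal_planted_scenario(self):
        """bait + direct P1,P2 + bridge P3 (via P1) + decoy P4."""
        sc = simulate_screen_scenario(n_direct=2, n_bridge=1, n_decoy=1, seed=9)
        net = run_screen(sc.bait, sc.candidates, sc.provider)
        assert net.groups == {
            "bait": {sc.bait},
            "group1": {"direct01", "direct02"},
            "group2": {"bridge01"},
            "group3": set(),
        }
        assert "decoy01" not in net.graph

    def test_all_pass_round1_leaves_later_groups_empty(self):
        sc = simulate_screen_scenario(n_direct=4, n_bridge=0, n_decoy=0, seed=10)
        net = run_screen(sc.bait, sc.candidates, sc.provider)
        assert net.groups["group2"] == set() and net.groups["group3"] == set()

    def test_pair_evaluation_budget(self):
        """Evaluated pairs never exceed |C| + |G1||F| + C(|G1|,2) + |R||core|."""
        sc = simulate_screen_scenario(seed=11)
        net = run_screen(sc.bait, sc.candidates, sc.provider)
        g = net.groups
        c = len(sc.candidates)
        g1, g2 = len(g["group1"]), len(g["group2"])
        f = c - g1
        r = c - g1 - g2
        core = 1 + g1 + g2
        bound = c + g1 * f + g1 * (g1 - 1) // 2 + r * core
        assert net.manifest["n_pair_evaluations"] <= bound

    def test_network_invariants_validate(self):
        sc = simulate_screen_scenario(n_tertiary=1, seed=12)
        net = run_screen(sc.bait, sc.candidates, sc.provider)
        net.validate()  # group disjointness, threshold edges, connectivity
        assert nx.is_connected(net.graph)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_all_pairs_oracle(self, seed, screen_oracle, edge_map):
        """Staged rounds equal the oracle that scores all pairs first
        and applies round semantics by breadth order from the bait."""
        rng = np.random.default_rng(seed)
        n_direct = int(rng.integers(0, 4))
        sc = simulate_screen_scenario(
            n_direct=n_direct,
            n_bridge=int(rng.integers(0, 3)) if n_direct else 0,
            n_decoy=int(rng.integers(0, 5)),
            seed=seed,
        )
        net = run_screen(sc.bait, sc.candidates, sc.provider)
        o_groups, o_edges = screen_oracle(sc.bait, sc.candidates, sc.provider)
        assert net.groups == o_groups
        assert edge_map(net) == o_edges

    def test_determinism_byte_identical_manifests(self, tmp_path):
        paths = []
        for i in range(2):
            sc = simulate_screen_scenario(seed=13)
            net = run_screen(sc.bait, sc.candidates, sc.provider)
            paths.append(write_manifest(net, tmp_path / f"m{i}.json"))
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_recovery_matches_truth_over_many_seeds(self):
        for seed in range(20):
            sc = simulate_screen_scenario(seed=seed)
            net = run_screen(sc.bait, sc.candidates, sc.provider)
            g = net.groups
            assert g["group1"] == set(sc.truth.planted_direct)
            assert g["group2"] == set(sc.truth.planted_bridge)
            assert g["group3"] == set()


class TestExport:
    @pytest.fixture
    def network(self):
        sc = simulate_screen_scenario(n_direct=3, n_bridge=2, n_decoy=2, seed=14)
        return run_screen(sc.bait, sc.candidates, sc.provider)

    @pytest.mark.parametrize("fmt", ["graphml", "tsv"])
    def test_lossless_round_trip(self, network, tmp_path, fmt):
        path = export_network(network, tmp_path / f"net.{fmt}")
        back = read_network(path)
        assert set(back.graph.nodes(data="group")) == set(network.graph.nodes(data="group"))
        for u, v, d in network.graph.edges(data=True):
            bd = back.graph.edges[u, v]
            assert bd["round"] == d["round"]
            assert bd["lis"] == pytest.approx(d["lis"])
            assert bd["lia"] == pytest.approx(d["lia"])

    def test_tsv_edge_count_matches_network(self, network, tmp_path):
        import pandas as pd

        path = export_network(network, tmp_path / "net.tsv")
        df = pd.read_csv(path, sep="\t")
        assert (df["record"] == "edge").sum() == network.graph.number_of_edges()

    def test_bait_only_network_every_format(self, tmp_path):
        sc = simulate_screen_scenario(n_direct=0, n_bridge=0, n_decoy=2, seed=15)
        net = run_screen(sc.bait, sc.candidates, sc.provider)
        assert net.graph.number_of_nodes() == 1
        for fmt in ["graphml", "tsv", "sif"]:
            path = export_network(net, tmp_path / f"solo.{fmt}")
            assert path.exists()
        back = read_network(tmp_path / "solo.tsv")
        assert set(back.graph.nodes) == {sc.bait}

    def test_sif_lists_edges(self, network, tmp_path):
        path = export_network(network, tmp_path / "net.sif")
        lines = [l for l in path.read_text().splitlines() if "\tpp\t" in l]
        assert len(lines) == network.graph.number_of_edges()

    def test_unknown_format_rejected(self, network, tmp_path):
        with pytest.raises(ValueError):
            export_network(network, tmp_path / "net.xyz")

    def test_edge_weight_attribute_is_lis(self, network, tmp_path):
        path = export_network(network, tmp_path / "net.graphml")
        back = nx.read_graphml(path)
        for _, _, d in back.edges(data=True):
            assert d["weight"] == pytest.approx(d["lis"])
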