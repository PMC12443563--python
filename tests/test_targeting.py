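import networkx as nx
import numpy as np
import pytest

from dysfunctome.montage import edge_admissible
from dysfunctome.nbs import NetworkComponent
from dysfunctome.targeting import (
    DysfunctomeProfile,
    NoAdmissibleEdgeError,
    edge_betweenness,
    normalized_ranking,
    priority_table,
    select_both_targets,
    select_target,
)

from conftest import brute_force_ebc


def comp_from_edges(edges):
    return NetworkComponent(edges=tuple(tuple(sorted(e)) for e in edges))


class TestEdgeBetweenness:
    def test_path_graph_raw_counts(self):
        ebc = edge_betweenness(comp_from_edges([("A", "B"), ("B", "C"), ("C", "D")]))
        assert ebc[("A", "B")] == pytest.approx(3.0)
        assert ebc[("B", "C")] == pytest.approx(4.0)
        assert ebc[("C", "D")] == pytest.approx(3.0)

    def test_star_and_cycle_symmetry(self):
        star = edge_betweenness(comp_from_edges([("h", x) for x in "abcd"]))
        assert len(set(np.round(list(star.values()), 9))) == 1
        cyc = edge_betweenness(
            comp_from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("a", "d")])
        )
        assert len(set(np.round(list(cyc.values()), 9))) == 1

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            G = nx.gnp_random_graph(8, 0.4, seed=int(rng.integers(1 << 31)))
            if G.number_of_edges() == 0 or not nx.is_connected(G):
                continue
            G = nx.relabel_nodes(G, {i: f"n{i}" for i in G.nodes})
            comp = comp_from_edges(G.edges)
            mine = edge_betweenness(comp)
            ref = brute_force_ebc(G)
            for e, v in ref.items():
                assert mine[e] == pytest.approx(v, abs=1e-9)

    def test_empty_component_rejected(self):
        with pytest.raises(ValueError):
            edge_betweenness(NetworkComponent(edges=()))


class TestNormalizedRanking:
    def test_three_values_both_directions(self):
        vals = {("a", "b"): 1.0, ("c", "d"): 2.0, ("e", "f"): 3.0}
        up = normalized_ranking(vals, "higher_is_better")
        assert [up[e] for e in vals] == [0.0, 0.5, 1.0]
        down = normalized_ranking(vals, "lower_is_better")
        assert [down[e] for e in vals] == [1.0, 0.5, 0.0]

    def test_all_equal_gives_half(self):
        vals = {("a", "b"): 2.0, ("c", "d"): 2.0, ("e", "f"): 2.0}
        assert set(normalized_ranking(vals).values()) == {0.5}

    def test_single_edge_maps_to_one(self):
        assert normalized_ranking({("a", "b"): 7.0}) == {("a", "b"): 1.0}

    def test_mean_rank_conservation(self):
        rng = np.random.default_rng(2)
        vals = {(f"a{i}", f"b{i}"): float(v) for i, v in enumerate(rng.uniform(0, 1, 9))}
        ranks = normalized_ranking(vals)
        assert np.mean(list(ranks.values())) == pytest.approx(0.5)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            normalized_ranking({("a", "b"): np.nan, ("c", "d"): 1.0})


def make_profile(edges, weights, sid="S001"):
    comp = comp_from_edges(edges)
    return DysfunctomeProfile(
        subject_id=sid, component=comp, weights=dict(zip(comp.edges, weights))
    )


class TestPriorityTable:
    def test_equal_weights_reduce_to_centrality_order(self):
        prof = make_profile([("A", "B"), ("B", "C"), ("C", "D")], [0.4, 0.4, 0.4])
        tbl = priority_table(prof, "restoration")
        assert tbl.iloc[0]["edge"] == ("B", "C")  # max centrality
        assert np.allclose(tbl["connectivity_ranking"], 0.5)
        assert np.allclose(tbl["priority_index"], tbl["centrality_ranking"] / 2 + 0.25)

    def test_central_and_weak_edge_wins_restoration(self):
        prof = make_profile([("A", "B"), ("B", "C"), ("C", "D")], [0.9, 0.1, 0.5])
        tbl = priority_table(prof, "restoration")
        assert tbl.iloc[0]["edge"] == ("B", "C")
        assert tbl.iloc[0]["priority_index"] == 1.0

    def test_restoration_plus_enhancement_identity(self):
        rng = np.random.default_rng(5)
        edges = [("A", "B"), ("B", "C"), ("C", "D"), ("B", "D"), ("D", "E")]
        prof = make_profile(edges, rng.permutation([0.1, 0.25, 0.5, 0.7, 0.9]))
        rest = priority_table(prof, "restoration").set_index("edge")
        enh = priority_table(prof, "enhancement").set_index("edge")
        for e in rest.index:
            assert rest.loc[[e], "priority_index"].item() + enh.loc[
                [e], "priority_index"
            ].item() == pytest.approx(rest.loc[[e], "centrality_ranking"].item() + 0.5)

    def test_priorities_bounded(self):
        rng = np.random.default_rng(6)
        edges = [(f"n{i}", f"n{i + 1}") for i in range(7)]
        prof = make_profile(edges, rng.uniform(0, 1, 7))
        for principle in ("restoration", "enhancement"):
            tbl = priority_table(prof, principle)
            assert tbl["priority_index"].between(0, 1).all()


class TestSelectTarget:
    def test_admissible_top_edge_depth_zero(self, grid_montage):
        prof = make_profile([("g00", "g55"), ("g55", "g05"), ("g05", "g50")], [0.1, 0.5, 0.9])
        sel = select_target(prof, "restoration", grid_montage)
        assert sel.fallback_depth == 0
        ok, _ = edge_admissible(grid_montage, sel.target_edge, 3)
        assert ok

    def test_fallback_skips_inadmissible_top_edge(self, grid_montage):
        # g22-g24 are two steps apart (shared ring member) -> inadmissible;
        # give that edge both max centrality and min weight so it tops priority
        edges = [("g22", "g24"), ("g24", "g55"), ("g55", "g00"), ("g00", "g22")]
        prof = make_profile(edges, [0.05, 0.5, 0.6, 0.7])
        sel = select_target(prof, "restoration", grid_montage)
        assert sel.fallback_depth >= 1
        assert sel.target_edge != ("g22", "g24")
        top_edge = sel.table.iloc[0]
        assert not top_edge["admissible"]

    def test_matches_brute_force_argmax(self, grid_montage):
        rng = np.random.default_rng(41)
        labels = grid_montage.labels
        for trial in range(100):
            nodes = rng.choice(len(labels), size=6, replace=False)
            g = nx.random_labeled_tree(6, seed=int(rng.integers(1 << 31)))
            edges = [(labels[nodes[a]], labels[nodes[b]]) for a, b in g.edges]
            prof = make_profile(edges, rng.uniform(0, 1, len(edges)))
            principle = ("restoration", "enhancement")[trial % 2]
            tbl = priority_table(prof, principle)
            admissible = tbl[
                [edge_admissible(grid_montage, e, 3)[0] for e in tbl["edge"]]
            ]
            if admissible.empty:
                with pytest.raises(NoAdmissibleEdgeError):
                    select_target(prof, principle, grid_montage)
                continue
            sel = select_target(prof, principle, grid_montage)
            best = admissible["priority_index"].max()
            assert sel.table[sel.table["edge"] == sel.target_edge][
                "priority_index"
            ].item() == pytest.approx(best)
            # fallback depth counts exactly the higher-priority inadmissible rows
            assert sel.fallback_depth == int((~sel.table["admissible"][: sel.fallback_depth]).sum())

    def test_edge_input_order_invariance(self, grid_montage):
        rng = np.random.default_rng(43)
        edges = [("g00", "g33"), ("g33", "g55"), ("g55", "g02"), ("g02", "g40")]
        weights = rng.uniform(0, 1, 4)
        sel_a = select_target(make_profile(edges, weights), "enhancement", grid_montage)
        order = [2, 0, 3, 1]
        sel_b = select_target(
            make_profile([edges[i] for i in order], weights[order]),
            "enhancement",
            grid_montage,
        )
        assert sel_a.target_edge == sel_b.target_edge

    def test_exhaustion_error_lists_violations(self, grid_montage):
        prof = make_profile([("g00", "g01")], [0.5])
        with pytest.raises(NoAdmissibleEdgeError, match="ring"):
            select_target(prof, "restoration", grid_montage)


class TestSelectBothTargets:
    def test_anti_aligned_profile_gives_distinct_edges(self, grid_montage):
        # 5-node path: the two middle edges tie for max centrality but carry
        # opposite weights, so the principles must diverge
        edges = [("g00", "g05"), ("g05", "g50"), ("g50", "g55"), ("g55", "g22")]
        prof = make_profile(edges, [0.9, 0.1, 0.9, 0.1])
        rest, enh = select_both_targets(prof, grid_montage)
        assert rest.target_edge == ("g05", "g50")
        assert enh.target_edge == ("g50", "g55")

    def test_dominant_edge_overlap_warns(self, grid_montage):
        # double star: the bridge edge carries 9 shortest-path pairs while the
        # four leaf edges tie at 5, so at median weight the bridge tops the
        # priority index under *both* principles — overlap is possible and warned
        edges = [
            ("g11", "g44"),  # bridge at median weight
            ("g00", "g11"),
            ("g02", "g11"),
            ("g35", "g44"),
            ("g44", "g53"),
        ]
        prof = make_profile(edges, [0.5, 0.1, 0.3, 0.7, 0.9])
        with pytest.warns(UserWarning, match="same edge"):
            rest, enh = select_both_targets(prof, grid_montage)
        assert rest.target_edge == enh.target_edge == ("g11", "g44")

    def test_deterministic(self, grid_montage):
        edges = [("g00", "g05"), ("g05", "g50"), ("g50", "g55"), ("g55", "g22")]
        prof = make_profile(edges, [0.9, 0.1, 0.9, 0.1])
        a = select_both_targets(prof, grid_montage)
        b = select_both_targets(prof, grid_montage)
        assert (a[0].target_edge, a[1].target_edge) == (b[0].target_edge, b[1].target_edge)
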