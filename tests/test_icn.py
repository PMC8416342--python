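"""Intra-individual covariance networks, screening, betweenness, hubs."""

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icnet import (
    HUB_PRESET_FIGURE,
    HUB_PRESET_RESULTS,
    HubCriteria,
    ICNModel,
    centrality_association,
    generate_cohort,
    graph_screen,
    hub_test_config,
    icn_weights,
    identify_hubs,
    plant_hub_item,
    proportional_threshold,
    rank_betweenness,
    select_sparsity,
    zscore_items,
)
from icnet.icn import NoQualifyingSparsityError, ScreenCriteria, _threshold_adjacency
from icnet.survey import ANALYSIS_COLUMNS


# --------------------------------------------------------------------------
# constructed weight matrices for sparsity selection

def ring_weights(p, rng, shortcuts=8):
    """Weights decaying with ring distance plus a few strong shortcuts:
    every proportional threshold is a connected, clustered small world."""
    idx = np.arange(p)
    d = np.abs(idx[:, None] - idx[None, :])
    d = np.minimum(d, p - d)
    W = 1.0 / (1.0 + d) + 0.001 * rng.random((p, p))
    W = (W + W.T) / 2
    for _ in range(shortcuts):
        u, v = rng.integers(0, p, 2)
        if u != v:
            W[u, v] = W[v, u] = 0.9
    np.fill_diagonal(W, 1.0)
    return W


def split_weights(p, rng):
    """Two ring modules whose only bridges rank between the K=0.13 and
    K=0.14 cutoffs: fails connectedness below 0.14, passes at 0.14."""
    half = p // 2
    idx = np.arange(p)
    W = np.zeros((p, p))
    for blk in (slice(0, half), slice(half, p)):
        i = idx[blk]
        db = np.abs(i[:, None] - i[None, :])
        db = np.minimum(db, half - db)
        W[blk, blk] = 1.0 / (1.0 + db)
    W += 0.0005 * rng.random((p, p))
    W = (W + W.T) / 2
    for blk0 in (0, half):
        for _ in range(4):
            u, v = rng.integers(blk0, blk0 + half, 2)
            if u != v:
                W[u, v] = W[v, u] = 0.9
    n_pairs = p * (p - 1) // 2
    iu, ju = np.triu_indices(p, 1)
    vals = np.sort(W[iu, ju])[::-1]
    m13, m14 = round(0.13 * n_pairs), round(0.14 * n_pairs)
    w_bridge = (vals[m13 + 2] + vals[m14 - 2]) / 2
    for _ in range(3):
        u, v = rng.integers(0, half), rng.integers(half, p)
        W[u, v] = W[v, u] = w_bridge
    np.fill_diagonal(W, 1.0)
    return W


def brute_betweenness(g):
    """Geodesic-enumeration betweenness oracle."""
    nodes = sorted(g.nodes())
    bc = dict.fromkeys(nodes, 0.0)
    for s, t in combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            bc[v] += sum(v in p for p in paths) / len(paths)
    return np.array([bc[v] for v in nodes])


class TestZScores:
    def test_simple_value(self):
        cohort = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        z = zscore_items(cohort, ["a"])
        assert z["a"].tolist() == [-1.0, 0.0, 1.0]

    def test_cohort_moments(self, small_cohort):
        z = zscore_items(small_cohort, ANALYSIS_COLUMNS)
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_constant_item_error_names_item(self):
        cohort = pd.DataFrame({"a": [1, 2, 3], "b": [4, 4, 4]})
        with pytest.raises(ValueError, match="b"):
            zscore_items(cohort, ["a", "b"])

    def test_two_pass_oracle(self, small_cohort):
        z = zscore_items(small_cohort, ANALYSIS_COLUMNS).to_numpy()
        X = small_cohort[list(ANALYSIS_COLUMNS)].to_numpy(dtype=float)
        for j in range(X.shape[1]):
            m = sum(X[:, j]) / len(X)
            sd = (sum((x - m) ** 2 for x in X[:, j]) / (len(X) - 1)) ** 0.5
            assert np.allclose(z[:, j], (X[:, j] - m) / sd, atol=1e-12)


class TestWeights:
    def test_closed_forms(self):
        assert icn_weights(np.array([0.3, 0.3]))[0, 1] == pytest.approx(1.0)
        assert icn_weights(np.array([0.0, 1.0]))[0, 1] == pytest.approx(
            np.exp(-1), abs=1e-12)
        W = icn_weights(np.array([0.0, 1.0, -1.0]))
        assert W[0, 1] == pytest.approx(np.exp(-1))
        assert W[0, 2] == pytest.approx(np.exp(-1))
        assert W[1, 2] == pytest.approx(np.exp(-4))

    @given(st.floats(-3, 3), st.floats(-3, 3), st.floats(-3, 3))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_and_translation_invariant(self, za, zb, c):
        w = icn_weights(np.array([za, zb]))[0, 1]
        w_shift = icn_weights(np.array([za + c, zb + c]))[0, 1]
        assert w == pytest.approx(w_shift, rel=1e-9)
        w_wider = icn_weights(np.array([za, zb + abs(zb - za) + 0.5]))[0, 1]
        if zb >= za:
            assert w_wider <= w

    def test_symmetry_and_range(self, rng):
        W = icn_weights(rng.standard_normal(43))
        assert np.allclose(W, W.T)
        assert (W > 0).all() and (W <= 1).all()


class TestThreshold:
    def test_edge_counts(self, rng):
        W = icn_weights(rng.standard_normal(43))
        assert proportional_threshold(W, 0.14).number_of_edges() == 126
        assert proportional_threshold(W, 1.0).number_of_edges() == 903
        for k in (0.05, 0.1, 0.2):
            assert proportional_threshold(W, k).number_of_edges() == round(k * 903)

    def test_matches_sort_oracle_for_distinct_weights(self, rng):
        p = 20
        W = rng.random((p, p))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 1.0)
        k = 0.2
        m = round(k * p * (p - 1) / 2)
        pairs = sorted(combinations(range(p), 2), key=lambda e: -W[e])
        expected = set(pairs[:m])
        got = set(map(tuple, map(sorted, proportional_threshold(W, k).edges())))
        assert got == expected

    def test_zero_edge_k_rejected(self):
        W = np.eye(4)
        with pytest.raises(ValueError, match="zero edges"):
            proportional_threshold(W, 0.01)

    def test_tie_break_lexicographic(self):
        W = np.ones((4, 4))  # all weights tied
        g = proportional_threshold(W, 0.5)  # 3 of 6 edges
        assert sorted(g.edges()) == [(0, 1), (0, 2), (0, 3)]


class TestGraphScreen:
    def test_complete_graph(self):
        s = graph_screen(nx.complete_graph(10), n_null=3, seed=0)
        assert s.connectedness == 1.0

    def test_two_cliques_connectedness_and_modularity(self):
        g = nx.disjoint_union(nx.complete_graph(21), nx.complete_graph(22))
        s = graph_screen(g, n_null=3, seed=0)
        assert s.connectedness == pytest.approx(22 / 43)
        # closed-form Q of the two-clique partition: ~0.4989
        m = 210 + 231
        q_expected = (210 / m - (420 / (2 * m)) ** 2) + (231 / m - (462 / (2 * m)) ** 2)
        assert s.modularity == pytest.approx(q_expected, abs=0.02)

    def test_small_world_sigma_above_one(self):
        g = nx.connected_watts_strogatz_graph(43, 4, 0.1, seed=2)
        s = graph_screen(g, n_null=10, seed=0)
        assert s.sigma is not None and s.sigma > 1

    def test_deterministic_given_seed(self, rng):
        g = proportional_threshold(icn_weights(rng.standard_normal(43)), 0.14)
        assert graph_screen(g, n_null=5, seed=3) == graph_screen(g, n_null=5, seed=3)

    def test_no_edges_rejected(self):
        with pytest.raises(ValueError):
            graph_screen(nx.empty_graph(5), n_null=2, seed=0)

    def test_non_isolated_mode(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        g.add_node(6)
        s = graph_screen(g, n_null=2, seed=0, connectedness_mode="non_isolated")
        assert s.connectedness == pytest.approx(6 / 7)


class TestSelectSparsity:
    def test_all_pass_returns_grid_minimum(self, rng):
        mats = [ring_weights(100, rng) for _ in range(10)]
        k, rates = select_sparsity(mats, k_grid=[0.05, 0.1, 0.14], n_null=4, seed=1)
        assert k == 0.05
        assert rates.iloc[0]["pass_rate"] == 1.0

    def test_constructed_cohort_first_passes_at_014(self, rng):
        mats = [ring_weights(100, rng) for _ in range(18)]
        mats += [split_weights(100, rng) for _ in range(2)]
        grid = [round(k, 2) for k in np.arange(0.05, 0.2001, 0.01)]
        k, rates = select_sparsity(mats, k_grid=grid, n_null=4, seed=1)
        assert k == 0.14
        below = rates[rates["K"] < 0.14]["pass_rate"]
        assert (below <= 0.95).all()

    def test_unreachable_fraction_raises_with_table(self, rng):
        mats = [ring_weights(100, rng) for _ in range(3)]
        # one respondent whose graph is always fragmented
        degenerate = np.eye(100)
        degenerate[0, 1] = degenerate[1, 0] = 0.9
        mats.append(degenerate + 1e-6 * rng.random((100, 100)))
        criteria = ScreenCriteria(participant_fraction=1.0)
        with pytest.raises(NoQualifyingSparsityError) as err:
            select_sparsity(mats, k_grid=[0.05, 0.1], criteria=criteria,
                            n_null=3, seed=0)
        assert list(err.value.pass_rates.columns) == ["K", "pass_rate"]


class TestRankBetweenness:
    def test_star_graph(self):
        g = nx.star_graph(4)  # center 0, leaves 1..4
        bet, ranks = rank_betweenness(g)
        assert bet[0] == pytest.approx(6.0)  # C(4,2) geodesics through hub
        assert ranks[0] == 1
        assert (ranks[1:] == 2).all()  # ties share the minimum rank

    def test_path_graph(self):
        bet, ranks = rank_betweenness(nx.path_graph(3))
        assert bet[1] == pytest.approx(1.0)
        assert ranks[1] == 1

    def test_matches_geodesic_enumeration_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 21))
            g = nx.gnp_random_graph(n, 0.3, seed=int(rng.integers(10 ** 6)))
            bet, ranks = rank_betweenness(g)
            assert np.allclose(bet, brute_betweenness(g), atol=1e-9)
            expected_ranks = np.array([1 + (bet > b).sum() for b in bet])
            assert (ranks == expected_ranks).all()


class TestIdentifyHubs:
    def test_constructed_prevalent_item_is_hub(self, rng):
        n, p = 100, 43
        ranks = np.array([rng.permutation(p) + 1 for _ in range(n)])
        ranks[:60, 0] = 1  # item 0 at top rank in 60% of respondents
        table = identify_hubs(ranks, [f"v{i}" for i in range(p)])
        assert table.iloc[0]["item"] == "v0"
        assert bool(table.iloc[0]["is_hub"])

    def test_shuffled_ranks_yield_no_hubs(self, rng):
        base = np.tile(np.arange(1, 44), (454, 1))
        false_positive = 0
        for _ in range(50):
            ranks = rng.permuted(base, axis=1)
            false_positive += identify_hubs(ranks, range(43))["is_hub"].any()
        assert false_positive == 0

    def test_figure_preset_is_laxer(self, rng):
        n, p = 200, 43
        ranks = np.array([rng.permutation(p) + 1 for _ in range(n)])
        ranks[:60, 5] = 3  # rank 3 in 30% of respondents
        strict = identify_hubs(ranks, range(p), HUB_PRESET_RESULTS)
        lax = identify_hubs(ranks, range(p), HUB_PRESET_FIGURE)
        assert not strict.set_index("item").loc[5, "is_hub"]
        assert lax.set_index("item").loc[5, "is_hub"]

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            HubCriteria(rank_threshold=0)
        with pytest.raises(ValueError):
            HubCriteria(prevalence_threshold=0.0)


class TestBridgeMechanism:
    def test_two_clique_bridge_wins_betweenness(self):
        """A node joining two otherwise-disconnected cliques has top
        betweenness rank, and identify_hubs flags it across respondents."""
        g = nx.disjoint_union(nx.complete_graph(10), nx.complete_graph(10))
        bridge = 20
        g.add_node(bridge)
        g.add_edge(0, bridge)
        g.add_edge(10, bridge)
        bet, ranks = rank_betweenness(g)
        assert ranks[bridge] == 1
        profiles = np.tile(ranks, (30, 1))
        table = identify_hubs(profiles, range(21))
        hubs = set(table.loc[table["is_hub"], "item"])
        assert bridge in hubs

    def test_planted_hub_coupling_signature(self):
        """Through the full pipeline, a planted item's similarity and
        thresholded degree to its two blocks rise monotonically with the
        coupling strength."""
        block_idx = [i for i, c in enumerate(ANALYSIS_COLUMNS)
                     if c.startswith(("pss", "phq"))]
        j = ANALYSIS_COLUMNS.index("att1")
        stats = {}
        for strength in (1e-9, 0.5, 1.0):
            cfg = plant_hub_item(hub_test_config(), "att1", strength,
                                 ("stress", "depression"))
            cohort = generate_cohort(cfg, seed=11)
            model = ICNModel(cohort)
            w = np.mean([W[j, block_idx].mean() for W in model.weight_matrices()])
            deg = np.mean([
                _threshold_adjacency(W, 0.14)[j, block_idx].sum()
                for W in model.weight_matrices()])
            stats[strength] = (w, deg)
        assert stats[1e-9][0] < stats[0.5][0] < stats[1.0][0]
        assert stats[1e-9][1] < stats[1.0][1]
        assert stats[1.0][0] - stats[1e-9][0] > 0.15

    def test_two_planted_hubs_both_couple(self):
        """Two hubs planted on different block pairs each attach to their
        own blocks more strongly than five unplanted decoy items."""
        cfg = hub_test_config()
        cfg = plant_hub_item(cfg, "att1", 1.0, ("stress", "depression"))
        cfg = plant_hub_item(cfg, "att2", 1.0, ("stress", "anxiety"))
        cohort = generate_cohort(cfg, seed=13)
        model = ICNModel(cohort)
        items = list(model.items)

        def block_weight(item, prefixes):
            j = items.index(item)
            idx = [i for i, c in enumerate(items) if c.startswith(prefixes)]
            return np.mean([W[j, idx].mean() for W in model.weight_matrices()])

        decoys = ("att5", "att6", "gad2", "st_read", "od_social")
        w1 = block_weight("att1", ("pss", "phq"))
        w2 = block_weight("att2", ("pss", "gad"))
        for decoy in decoys:
            assert w1 > block_weight(decoy, ("pss", "phq"))
            assert w2 > block_weight(decoy, ("pss", "gad"))


class TestAssociations:
    def test_perfect_monotone(self):
        ranks = np.arange(1, 11).reshape(-1, 1)
        totals = pd.DataFrame({"pss_total": np.arange(10) * 2.0})
        out = centrality_association(ranks, ["item"], totals)
        assert out.iloc[0]["rho"] == pytest.approx(1.0)
        rev = centrality_association(ranks[::-1], ["item"], totals)
        assert rev.iloc[0]["rho"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        x = rng.integers(1, 8, 10).astype(float)
        y = rng.normal(size=10)
        out = centrality_association(x.reshape(-1, 1), ["item"],
                                     pd.DataFrame({"s": y}))

        def ranks_of(v):
            order = np.argsort(v, kind="stable")
            r = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                k = i
                while k < len(v) and sv[k] == sv[i]:
                    k += 1
                r[order[i:k]] = (i + k + 1) / 2
                i = k
            return r

        rx, ry = ranks_of(x), ranks_of(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert out.iloc[0]["rho"] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_flagged(self):
        ranks = np.full((10, 1), 3)
        totals = pd.DataFrame({"s": np.arange(10.0)})
        out = centrality_association(ranks, ["item"], totals)
        assert bool(out.iloc[0]["degenerate"]) and not bool(out.iloc[0]["significant"])

    def test_significance_threshold(self, rng):
        n = 300
        x = rng.normal(size=n)
        ranks = np.argsort(np.argsort(x)).reshape(-1, 1) + 1
        strong = pd.DataFrame({"s": -x + 0.5 * rng.normal(size=n)})
        out = centrality_association(ranks, ["item"], strong)
        assert bool(out.iloc[0]["significant"])
        assert out.iloc[0]["rho"] < -0.3


class TestICNModelPipeline:
    def test_fixed_k_fit_is_deterministic(self, small_cohort):
        res1 = ICNModel(small_cohort).fit(k=0.14, seed=5, n_null=3)
        res2 = ICNModel(small_cohort).fit(k=0.14, seed=5, n_null=3)
        assert np.array_equal(res1.ranks, res2.ranks)
        assert res1.hub_items() == res2.hub_items()
        pd.testing.assert_frame_equal(res1.associations(), res2.associations())

    def test_rank_rows_are_valid(self, small_cohort):
        res = ICNModel(small_cohort).fit(k=0.14)
        assert res.ranks.shape == (len(small_cohort), 43)
        assert res.ranks.min() == 1
        assert res.ranks.max() <= 43
        # minimum (competition) ranks: rank r implies >= r-1 better items
        for row, bets in zip(res.ranks, res.betweenness):
            for r, b in zip(row, bets):
                assert (bets > b).sum() == r - 1
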