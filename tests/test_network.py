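"""Contact matrices, heatmaps, sociograms, centralities, core/periphery."""
from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from sociobadge import (
    Sociogram,
    betweenness_centrality,
    centrality_report,
    contact_matrix,
    core_periphery_fit,
    daily_profession_totals,
    degree_centrality,
    eigenvector_centrality,
    make_roster,
    profession_heatmap,
    threshold_graph,
)
from sociobadge._util import TZ
from sociobadge.network import ContactMatrix


def interactions_frame(rows, day="2024-01-01"):
    """rows: (badge_a, badge_b, duration_min)"""
    t0 = pd.Timestamp(day, tz=TZ)
    return pd.DataFrame(
        {
            "badge_a": [min(a, b) for a, b, _ in rows],
            "badge_b": [max(a, b) for a, b, _ in rows],
            "start": [t0 + pd.Timedelta(minutes=5 * i) for i in range(len(rows))],
            "end": [
                t0 + pd.Timedelta(minutes=5 * i + d)
                for i, (_, _, d) in enumerate(rows)
            ],
            "duration_min": [d for _, _, d in rows],
        }
    )


def graph_from_edges(nodes, edges, weights=None):
    w = weights or {e: 1.0 for e in edges}
    return Sociogram(list(nodes), {tuple(sorted(e)): w[e] for e in edges})


class TestContactMatrix:
    def test_single_interaction(self):
        roster = make_roster({"nurse": 2})
        a, b = roster.badge_ids()
        cm = contact_matrix(interactions_frame([(a, b, 10.0)]), roster)
        assert cm.matrix.loc[a, b] == 10.0
        assert cm.matrix.loc[b, a] == 10.0
        assert cm.matrix.values.sum() == 20.0

    def test_empty(self):
        roster = make_roster({"nurse": 3})
        cm = contact_matrix(interactions_frame([]), roster)
        assert (cm.matrix.values == 0).all()

    def test_unknown_badge_rejected(self):
        roster = make_roster({"nurse": 2})
        with pytest.raises(ValueError, match="unknown badge"):
            contact_matrix(interactions_frame([("X1", "X2", 1.0)]), roster)

    def test_matches_brute_force(self, small_sim):
        cm = contact_matrix(small_sim.active, small_sim.roster)
        rng = np.random.default_rng(0)
        ids = small_sim.roster.badge_ids()
        for _ in range(25):
            a, b = rng.choice(ids, size=2, replace=False)
            mask = (
                (small_sim.active["badge_a"] == min(a, b))
                & (small_sim.active["badge_b"] == max(a, b))
            )
            assert cm.matrix.loc[a, b] == pytest.approx(
                small_sim.active[mask]["duration_min"].sum()
            )

    def test_symmetric_zero_diagonal(self, small_sim):
        cm = contact_matrix(small_sim.active, small_sim.roster)
        assert np.allclose(cm.matrix.values, cm.matrix.values.T)
        assert (np.diag(cm.matrix.values) == 0).all()

    def test_asymmetric_rejected(self):
        m = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="symmetric"):
            ContactMatrix(m)


class TestProfessionHeatmap:
    def test_single_nurse_pair(self):
        roster = make_roster({"nurse": 2, "resident": 1})
        a, b = roster.by_profession("nurse")
        cm = contact_matrix(interactions_frame([(a, b, 10.0)]), roster)
        pm = profession_heatmap(cm, roster)
        assert pm.values.loc["nurse", "nurse"] == 10.0
        assert pm.display.loc["nurse", "nurse"] == pytest.approx(np.log10(11.0))

    def test_single_member_intra_cell_is_na(self, small_sim):
        roster = make_roster({"nurse": 2, "resident": 1, "pharmacist": 1})
        cm = contact_matrix(interactions_frame([]), roster)
        pm = profession_heatmap(cm, roster)
        assert bool(pm.na_mask.loc["resident", "resident"])
        assert bool(pm.na_mask.loc["pharmacist", "pharmacist"])
        assert not bool(pm.na_mask.loc["nurse", "nurse"])
        assert np.isnan(pm.display.loc["resident", "resident"])

    def test_conservation_and_group_sum_oracle(self, small_sim):
        cm = contact_matrix(small_sim.active, small_sim.roster)
        pm = profession_heatmap(cm, small_sim.roster)
        upper = np.triu(cm.matrix.values, k=1).sum()
        # every cell counted once: intra cells + each inter cell once
        total = sum(
            pm.values.loc[p, q]
            for p, q in itertools.combinations_with_replacement(
                pm.values.index, 2
            )
        )
        assert total == pytest.approx(upper, rel=1e-9)
        # spot-check one inter cell against a brute-force group sum
        prof = small_sim.roster.profession_of()
        want = sum(
            dur
            for a, b, dur in zip(
                small_sim.active["badge_a"],
                small_sim.active["badge_b"],
                small_sim.active["duration_min"],
            )
            if {prof[a], prof[b]} == {"nurse", "attending_physician"}
        )
        assert pm.values.loc["nurse", "attending_physician"] == pytest.approx(want)

    def test_person_minutes_doubles(self, small_sim):
        cm = contact_matrix(small_sim.active, small_sim.roster)
        pair = profession_heatmap(cm, small_sim.roster, unit="pair_minutes")
        person = profession_heatmap(cm, small_sim.roster, unit="person_minutes")
        assert np.allclose(person.values.values, 2.0 * pair.values.values)


class TestThresholdGraph:
    def test_above_max_is_edgeless(self, small_sim):
        cm = contact_matrix(small_sim.active, small_sim.roster)
        g = threshold_graph(cm, cm.matrix.values.max() + 1.0)
        assert g.edges == {}
        assert g.nodes == small_sim.roster.badge_ids()

    def test_zero_threshold_links_positive_entries(self):
        roster = make_roster({"nurse": 3})
        a, b, c = roster.badge_ids()
        cm = contact_matrix(interactions_frame([(a, b, 2.0)]), roster)
        g = threshold_graph(cm, 0.0)
        assert set(g.edges) == {(a, b)}
        assert c in g.nodes

    def test_nesting_chain(self, small_sim):
        cm = contact_matrix(small_sim.active, small_sim.roster)
        thresholds = [1.0, 3.0, 4.0, 30.0, 150.0, 180.0]
        edge_sets = [set(threshold_graph(cm, t).edges) for t in thresholds]
        for bigger, smaller in zip(edge_sets, edge_sets[1:]):
            assert bigger >= smaller


def random_sociogram(rng, n, p=0.35):
    nodes = [f"v{i}" for i in range(n)]
    edges = {}
    for i, j in itertools.combinations(range(n), 2):
        if rng.uniform() < p:
            edges[(nodes[i], nodes[j])] = 1.0
    return Sociogram(nodes, edges)


class TestDegree:
    def test_star(self):
        g = graph_from_edges(
            ["h", "a", "b", "c", "d"],
            [("h", x) for x in "abcd"],
        )
        deg = degree_centrality(g)
        assert deg.loc["h", "degree"] == 4
        assert deg.loc["a", "degree"] == 1
        assert deg.loc["h", "degree_norm"] == pytest.approx(1.0)

    def test_complete_graph_normalized_one(self):
        nodes = list("abcd")
        g = graph_from_edges(nodes, list(itertools.combinations(nodes, 2)))
        deg = degree_centrality(g)
        assert np.allclose(deg["degree_norm"], 1.0)

    def test_row_sum_oracle(self):
        rng = np.random.default_rng(12)
        g = random_sociogram(rng, 10)
        deg = degree_centrality(g)
        adj = g.adjacency()
        assert np.allclose(deg["degree"].values, adj.sum(axis=1))


class TestEigenvector:
    def test_path_of_three_closed_form(self):
        g = graph_from_edges(list("abc"), [("a", "b"), ("b", "c")])
        scores, converged = eigenvector_centrality(g)
        assert converged
        assert scores["a"] == pytest.approx(0.5, abs=1e-4)
        assert scores["b"] == pytest.approx(0.7071, abs=1e-4)
        assert scores["c"] == pytest.approx(0.5, abs=1e-4)

    def test_complete_graph_uniform(self):
        nodes = list("abcde")
        g = graph_from_edges(nodes, list(itertools.combinations(nodes, 2)))
        scores, _ = eigenvector_centrality(g)
        assert np.allclose(scores.values, 1 / np.sqrt(5), atol=1e-8)

    def test_edgeless_rejected(self):
        g = Sociogram(list("abc"), {})
        with pytest.raises(ValueError, match="edgeless"):
            eigenvector_centrality(g)

    def test_outside_largest_component_scores_zero(self):
        g = graph_from_edges(list("abcde"), [("a", "b"), ("b", "c"), ("d", "e")])
        scores, _ = eigenvector_centrality(g)
        assert scores["d"] == 0.0
        assert scores["e"] == 0.0
        assert np.isclose((scores**2).sum(), 1.0)

    def test_dense_eigensolver_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            g = random_sociogram(rng, 8, p=0.5)
            if not g.edges:
                continue
            scores, _ = eigenvector_centrality(g)
            comp = g.components()[0]
            idx = {v: i for i, v in enumerate(comp)}
            a = np.zeros((len(comp), len(comp)))
            for (u, v) in g.edges:
                if u in idx and v in idx:
                    a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1.0
            w, vecs = np.linalg.eigh(a)
            lead = np.abs(vecs[:, np.argmax(w)])
            got = scores[comp].values
            assert np.max(np.abs(got - lead)) < 1e-6


def brute_betweenness(g: Sociogram) -> dict[str, float]:
    """Exhaustive shortest-path enumeration oracle."""
    nb = g.neighbors()
    bc = {v: 0.0 for v in g.nodes}
    for s, t in itertools.combinations(g.nodes, 2):
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for v in frontier:
                for w in nb[v]:
                    if w not in dist:
                        dist[w] = dist[v] + 1
                        nxt.append(w)
            frontier = nxt
        if t not in dist:
            continue
        paths: list[list[str]] = []

        def dfs(v, path):
            if v == t:
                paths.append(path)
                return
            for w in nb[v]:
                if dist.get(w) == dist[v] + 1 and dist[w] <= dist[t]:
                    dfs(w, path + [w])

        dfs(s, [s])
        for p in paths:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(paths)
    return bc


class TestBetweenness:
    def test_path_of_three(self):
        g = graph_from_edges(list("abc"), [("a", "b"), ("b", "c")])
        btw = betweenness_centrality(g)
        assert btw.loc["b", "betweenness"] == 1.0
        assert btw.loc["a", "betweenness"] == 0.0

    def test_star_hub_counts_all_leaf_pairs(self):
        leaves = list("abcde")
        g = graph_from_edges(["h"] + leaves, [("h", x) for x in leaves])
        btw = betweenness_centrality(g)
        assert btw.loc["h", "betweenness"] == 10.0  # C(5, 2)
        # normalization denominator (n-1)(n-2)/2 = 10 for n = 6
        assert btw.loc["h", "betweenness_norm"] == pytest.approx(1.0)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            g = random_sociogram(rng, 8, p=0.4)
            got = betweenness_centrality(g)["betweenness"]
            want = brute_betweenness(g)
            for v in g.nodes:
                assert got[v] == pytest.approx(want[v], abs=1e-9)

    def test_networkx_cross_check(self):
        rng = np.random.default_rng(21)
        g = random_sociogram(rng, 12, p=0.3)
        got = betweenness_centrality(g)["betweenness"]
        want = nx.betweenness_centrality(g.to_networkx(), normalized=False)
        for v in g.nodes:
            assert got[v] == pytest.approx(want[v], abs=1e-9)


def brute_core_periphery(g: Sociogram):
    """Exhaustive partition oracle scored with scipy's Pearson r."""
    adj = g.adjacency()
    n = g.n
    best = (-np.inf, None)
    for bits in range(1, 2**n - 1):
        core = np.array([(bits >> i) & 1 for i in range(n)], dtype=bool)
        obs, ideal = [], []
        for i, j in itertools.combinations(range(n), 2):
            if core[i] and core[j]:
                obs.append(adj[i, j])
                ideal.append(1.0)
            elif not core[i] and not core[j]:
                obs.append(adj[i, j])
                ideal.append(0.0)
        if len(set(ideal)) < 2 or len(set(obs)) < 2:
            continue
        r = pearsonr(obs, ideal).statistic
        if r > best[0]:
            best = (r, core)
    return best


class TestCorePeriphery:
    def test_ideal_pattern_scores_one(self):
        clique = list("abcd")
        pendants = list("wxyz")
        edges = list(itertools.combinations(clique, 2)) + [
            (c, p) for c, p in zip(clique, pendants)
        ]
        g = graph_from_edges(clique + pendants, edges)
        fit = core_periphery_fit(g)
        assert fit.score == pytest.approx(1.0)
        assert set(fit.core[fit.core].index) == set(clique)
        assert not fit.degenerate

    def test_matching_graph_against_exhaustive_oracle(self):
        nodes = list("abcdef")
        g = graph_from_edges(nodes, [("a", "b"), ("c", "d"), ("e", "f")])
        fit = core_periphery_fit(g)
        want_score, _ = brute_core_periphery(g)
        assert fit.score == pytest.approx(want_score, abs=1e-9)
        assert fit.score < 0.6  # a matching has no real core

    def test_exhaustive_matches_scipy_oracle(self):
        rng = np.random.default_rng(30)
        for _ in range(5):
            g = random_sociogram(rng, 8, p=0.4)
            if not g.edges:
                continue
            fit = core_periphery_fit(g)
            want_score, _ = brute_core_periphery(g)
            assert fit.score == pytest.approx(want_score, abs=1e-9)

    def test_greedy_close_to_exhaustive(self):
        rng = np.random.default_rng(17)
        g = random_sociogram(rng, 10, p=0.4)
        exact = core_periphery_fit(g, method="exhaustive")
        greedy = core_periphery_fit(g, method="greedy", n_restarts=20, seed=1)
        assert greedy.score >= 0.95 * exact.score

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            core_periphery_fit(graph_from_edges(list("ab"), [("a", "b")]))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(40)
        g = random_sociogram(rng, 18, p=0.3)
        f1 = core_periphery_fit(g, method="greedy", seed=3)
        f2 = core_periphery_fit(g, method="greedy", seed=3)
        assert f1.score == f2.score
        assert (f1.core == f2.core).all()


class TestCentralityReport:
    def test_hand_computed_path_graph(self):
        roster = make_roster({"nurse": 3, "attending_physician": 2})
        n1, n2, n3 = roster.by_profession("nurse")
        d1, d2 = roster.by_profession("attending_physician")
        # path d1 - n1 - n2 - n3 - d2
        g = graph_from_edges(
            roster.badge_ids(),
            [(d1, n1), (n1, n2), (n2, n3), (n3, d2)],
            weights={(d1, n1): 5.0, (n1, n2): 9.0, (n2, n3): 9.0, (n3, d2) : 5.0},
        )
        rep = centrality_report(g, roster)
        t = rep.table
        assert t.loc[n2, "degree"] == 2
        # P5 betweenness: middle 4, inner 3, ends 0
        assert t.loc[n2, "betweenness"] == 4.0
        assert t.loc[n1, "betweenness"] == 3.0
        assert t.loc[d1, "betweenness"] == 0.0
        # P5 leading eigenvector: sin(k*pi/6)/sqrt(3)
        want = np.array([0.5, np.sqrt(3) / 2, 1.0, np.sqrt(3) / 2, 0.5]) / np.sqrt(3)
        got = t.loc[[d1, n1, n2, n3, d2], "eigenvector"].values
        assert np.allclose(got, want, atol=1e-6)
        # nurses hold the middle: better (smaller) median rank everywhere
        s = rep.profession_summary
        for m in ("degree", "eigenvector", "betweenness"):
            assert (
                s.loc["nurse", f"median_rank_{m}"]
                < s.loc["attending_physician", f"median_rank_{m}"]
            )

    def test_top3_flags_by_strength(self):
        roster = make_roster({"nurse": 4})
        a, b, c, d = roster.by_profession("nurse")
        g = graph_from_edges(
            roster.badge_ids(),
            [(a, b), (b, c), (c, d)],
            weights={(a, b): 100.0, (b, c): 50.0, (c, d): 10.0},
        )
        rep = centrality_report(g, roster)
        flagged = set(rep.table[rep.table["top3_nurse"]].index)
        assert flagged == {a, b, c}  # strengths 100, 150, 60, 10

    def test_single_profession_summary_covers_all(self):
        roster = make_roster({"nurse": 3})
        a, b, c = roster.badge_ids()
        g = graph_from_edges([a, b, c], [(a, b), (b, c)])
        rep = centrality_report(g, roster)
        assert list(rep.profession_summary.index) == ["nurse"]


class TestDailyProfessionTotals:
    def test_interprofessional_counted_for_both(self):
        roster = make_roster({"nurse": 1, "attending_physician": 1})
        n, d = roster.by_profession("nurse")[0], roster.by_profession(
            "attending_physician"
        )[0]
        totals = daily_profession_totals(interactions_frame([(n, d, 10.0)]), roster)
        assert totals.loc["2024-01-01", "nurse"] == 10.0
        assert totals.loc["2024-01-01", "attending_physician"] == 10.0

    def test_empty(self):
        roster = make_roster({"nurse": 2})
        totals = daily_profession_totals(interactions_frame([]), roster)
        assert totals.empty

    def test_matches_brute_force(self, small_sim):
        totals = daily_profession_totals(small_sim.active, small_sim.roster)
        prof = small_sim.roster.profession_of()
        want: dict[tuple[str, str], float] = {}
        for row in small_sim.active.itertuples():
            day = row.start.strftime("%Y-%m-%d")
            for badge in (row.badge_a, row.badge_b):
                key = (day, prof[badge])
                want[key] = want.get(key, 0.0) + row.duration_min
        for (day, p), v in want.items():
            assert totals.loc[day, p] == pytest.approx(v)
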