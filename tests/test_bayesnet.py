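"""Bayesian-network engine: scoring, search, CPTs, exact inference."""

import math

import numpy as np
import pandas as pd
import pytest

from lymphmap.bayesnet import (
    Cpt,
    Dag,
    DiscreteBayesianNetwork,
    InconsistentEvidenceError,
    ScoreCache,
    bic_score,
    brute_force_posterior,
    enumerate_dags,
    fit_cpts,
    hill_climb,
    posterior_query,
    _validate_data,
)


def random_network(rng, k):
    """Random binary DAG + CPTs over k nodes (test helper)."""
    nodes = [f"v{j}" for j in range(k)]
    order = rng.permutation(k)
    dag = Dag(nodes)
    for a in range(k):
        for b in range(a + 1, k):
            if rng.random() < 0.4:
                dag.add_edge(nodes[order[a]], nodes[order[b]])
    cpts = {}
    for v in nodes:
        ps = dag.parents(v)
        q = 2 ** len(ps)
        t = rng.uniform(0.05, 0.95, (q, 1))
        cpts[v] = Cpt(v, ps, 2, (2,) * len(ps), np.hstack([1 - t, t]))
    return dag, cpts


class TestDag:
    def test_cycle_rejected(self):
        dag = Dag("abc", [("a", "b"), ("b", "c")])
        with pytest.raises(ValueError, match="cycle"):
            dag.add_edge("c", "a")

    def test_self_loop_and_duplicate_rejected(self):
        dag = Dag("ab", [("a", "b")])
        with pytest.raises(ValueError):
            dag.add_edge("a", "a")
        with pytest.raises(ValueError):
            dag.add_edge("a", "b")

    def test_topological_order_respects_edges(self):
        dag = Dag("abcd", [("c", "a"), ("a", "b"), ("d", "b")])
        order = dag.topological_order()
        for u, v in dag.edges:
            assert order.index(u) < order.index(v)


class TestBicScore:
    def test_single_binary_variable_closed_form(self):
        # 10 observations, 5 ones, empty graph: 10 ln(1/2) - (ln 10)/2
        data = pd.DataFrame({"a": [1] * 5 + [0] * 5})
        expected = 10 * math.log(0.5) - math.log(10) / 2
        assert bic_score(Dag(["a"]), data) == pytest.approx(expected, abs=1e-9)

    def test_perfectly_correlated_pair_edge_gain(self):
        # copying edge recovers n ln 2 likelihood at one extra parameter
        a = np.array([0] * 50 + [1] * 50)
        data = pd.DataFrame({"a": a, "b": a})
        gain = bic_score(Dag("ab", [("a", "b")]), data) - bic_score(Dag("ab"), data)
        assert gain == pytest.approx(100 * math.log(2) - math.log(100) / 2, abs=1e-9)

    def test_edge_from_constant_variable_never_helps(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame({"c": np.zeros(50, dtype=int),
                             "y": (rng.random(50) < 0.5).astype(int)})
        assert bic_score(Dag("cy", [("c", "y")]), data) < bic_score(Dag("cy"), data)

    def test_column_mismatch_raises(self):
        data = pd.DataFrame({"x": [0, 1], "y": [1, 0]})
        with pytest.raises(ValueError, match="match"):
            bic_score(Dag(["a", "b"]), data)

    def test_decomposability_cache_consistency(self):
        # a cached local score must equal recomputation after random mutations
        rng = np.random.default_rng(3)
        X = (rng.random((200, 5)) < 0.5).astype(int)
        Xv, names, cards = _validate_data(pd.DataFrame(X, columns=list("abcde")))
        cache = ScoreCache(Xv, cards)
        for _ in range(100):
            j = int(rng.integers(5))
            ps = frozenset(int(p) for p in rng.choice(5, rng.integers(0, 3), replace=False)
                           if p != j)
            first = cache.local(j, ps)
            fresh = ScoreCache(Xv, cards).local(j, ps)
            assert first == pytest.approx(fresh, abs=1e-9)


class TestEnumerateDags:
    @pytest.mark.parametrize("k, count", [(1, 1), (2, 3), (3, 25), (4, 543)])
    def test_known_dag_counts(self, k, count):
        dags = enumerate_dags(k)
        assert len(dags) == count
        assert len({frozenset(d.edges) for d in dags}) == count

    def test_guard_above_four_nodes(self):
        with pytest.raises(ValueError, match="guard|4"):
            enumerate_dags(5)


class TestHillClimb:
    def test_planted_chain_attains_enumeration_optimum(self):
        rng = np.random.default_rng(5)
        n = 500
        a = (rng.random(n) < 0.5).astype(int)
        b = np.where(rng.random(n) < 0.9, a, 1 - a)
        c = np.where(rng.random(n) < 0.9, b, 1 - b)
        data = pd.DataFrame({"a": a, "b": b, "c": c})
        best = max(bic_score(d, data) for d in enumerate_dags(list("abc")))
        got = bic_score(hill_climb(data, seed=0), data)
        assert got == pytest.approx(best, abs=1e-6)

    def test_independent_coins_yield_empty_graph(self):
        # with n = 2000 independent fair coins the BIC penalty should win
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            data = pd.DataFrame((rng.random((2000, 4)) < 0.5).astype(int),
                                columns=list("abcd"))
            if not hill_climb(data, seed=seed).edges:
                hits += 1
        assert hits >= 48  # >= 95% of 50 replicates

    def test_score_at_least_empty_graph(self, small_cohort):
        from lymphmap.simulate import ZONE_COLS
        data = small_cohort[ZONE_COLS]
        dag = hill_climb(data, seed=1)
        assert bic_score(dag, data) >= bic_score(Dag(list(data.columns)), data) - 1e-9

    def test_max_indegree_respected(self):
        rng = np.random.default_rng(9)
        a = (rng.random(400) < 0.5).astype(int)
        b = (rng.random(400) < 0.5).astype(int)
        c = (a ^ b) & 1
        data = pd.DataFrame({"a": a, "b": b, "c": np.where(rng.random(400) < 0.95, c, 1 - c)})
        dag = hill_climb(data, seed=0, max_indegree=1)
        assert all(len(dag.parents(v)) <= 1 for v in dag.nodes)

    def test_deterministic_given_seed(self, small_cohort):
        from lymphmap.simulate import ZONE_COLS
        data = small_cohort[ZONE_COLS]
        d1 = hill_climb(data, restarts=3, seed=42)
        d2 = hill_climb(data, restarts=3, seed=42)
        assert d1.edges == d2.edges


class TestFitCpts:
    def test_mle_and_laplace_counts(self):
        data = pd.DataFrame({"p": [1, 1, 1, 1, 0, 0], "c": [1, 1, 1, 0, 0, 0]})
        dag = Dag(["p", "c"], [("p", "c")])
        mle = fit_cpts(dag, data, alpha=0.0)
        assert mle["c"].prob(1, (1,)) == pytest.approx(0.75)
        lap = fit_cpts(dag, data, alpha=1.0)
        assert lap["c"].prob(1, (1,)) == pytest.approx(4 / 6)

    def test_rows_normalized_and_unseen_uniform(self, caplog):
        import logging
        data = pd.DataFrame({"p": [0, 0, 0], "c": [1, 0, 1]})
        dag = Dag(["p", "c"], [("p", "c")])
        with caplog.at_level(logging.WARNING, logger="lymphmap.bayesnet"):
            cpts = fit_cpts(dag, data, alpha=0.0)
        assert np.allclose(cpts["c"].table.sum(axis=1), 1.0)
        assert cpts["c"].prob(1, (1,)) == pytest.approx(0.5)  # unseen config
        assert "unseen" in caplog.text


class TestInference:
    def test_chain_query_returns_cpt_entry(self):
        dag = Dag("AB", [("A", "B")])
        cpts = {
            "A": Cpt("A", (), 2, (), [[0.3, 0.7]]),
            "B": Cpt("B", ("A",), 2, (2,), [[0.9, 0.1], [0.2, 0.8]]),
        }
        assert posterior_query(dag, cpts, "B", 1, {"A": 1}) == pytest.approx(0.8, abs=1e-12)

    def test_v_structure_explaining_away(self):
        # P(A=1 | C=1) = P(A=1,C=1)/P(C=1) = 0.25 / 0.3 = 5/6 by enumeration
        dag = Dag("ABC", [("A", "C"), ("B", "C")])
        cpts = {
            "A": Cpt("A", (), 2, (), [[0.5, 0.5]]),
            "B": Cpt("B", (), 2, (), [[0.5, 0.5]]),
            "C": Cpt("C", ("A", "B"), 2, (2, 2),
                     [[0.9, 0.1], [0.9, 0.1], [0.9, 0.1], [0.1, 0.9]]),
        }
        expected = brute_force_posterior(dag, cpts, "A", 1, {"C": 1})
        assert expected == pytest.approx(5 / 6, abs=1e-12)
        assert posterior_query(dag, cpts, "A", 1, {"C": 1}) == pytest.approx(expected, abs=1e-9)

    def test_matches_brute_force_on_random_networks(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            k = int(rng.integers(2, 7))
            dag, cpts = random_network(rng, k)
            tgt = dag.nodes[int(rng.integers(k))]
            evidence = {
                v: int(rng.integers(2))
                for v in dag.nodes
                if v != tgt and rng.random() < 0.4
            }
            ve = posterior_query(dag, cpts, tgt, 1, evidence)
            bf = brute_force_posterior(dag, cpts, tgt, 1, evidence)
            assert ve == pytest.approx(bf, abs=1e-9)

    def test_states_sum_to_one_given_markov_blanket(self):
        rng = np.random.default_rng(11)
        dag, cpts = random_network(rng, 5)
        tgt = dag.nodes[2]
        evidence = {v: 1 for v in dag.nodes if v != tgt}
        total = sum(posterior_query(dag, cpts, tgt, s, evidence) for s in (0, 1))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_zero_probability_evidence_raises(self):
        dag = Dag("AB", [("A", "B")])
        cpts = {
            "A": Cpt("A", (), 2, (), [[1.0, 0.0]]),
            "B": Cpt("B", ("A",), 2, (2,), [[0.5, 0.5], [0.5, 0.5]]),
        }
        with pytest.raises(InconsistentEvidenceError):
            posterior_query(dag, cpts, "B", 1, {"A": 1})


class TestEstimator:
    def test_fit_sets_attributes_and_queries(self, small_cohort):
        from lymphmap.simulate import ZONE_COLS
        bn = DiscreteBayesianNetwork(random_state=0).fit(small_cohort[ZONE_COLS])
        assert hasattr(bn, "dag_") and hasattr(bn, "cpts_")
        p = bn.query("zone_05", 1, {"zone_03": 1})
        assert 0.0 <= p <= 1.0

    def test_get_set_params_roundtrip(self):
        bn = DiscreteBayesianNetwork(restarts=2, alpha=0.5)
        params = bn.get_params()
        assert params["restarts"] == 2
        bn2 = DiscreteBayesianNetwork().set_params(**params)
        assert bn2.alpha == 0.5
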