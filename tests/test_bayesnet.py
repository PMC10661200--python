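"""CPT estimation, exact inference, d-separation, and cross-validated AUC."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from gmcausal.bayesnet import (
    DiscreteBayesNet,
    ZeroEvidenceError,
    crossval_auc,
    d_separated,
    fit_cpts,
    joint_probability,
    query,
    sample,
)

from helpers import enumerate_conditional, random_discrete_bn


def _chain_bn(p_a1=0.4, p_b1_a0=0.2, p_b1_a1=0.9):
    bn = fit_cpts(nx.DiGraph([("A", "B")]), pd.DataFrame({"A": [], "B": []}),
                  1.0, {"A": 2, "B": 2})
    bn.cpts["A"] = np.array([1 - p_a1, p_a1])
    bn.cpts["B"] = np.array([[1 - p_b1_a0, p_b1_a0], [1 - p_b1_a1, p_b1_a1]])
    return bn


class TestFitCpts:
    def test_dirichlet_posterior_mean_by_hand(self):
        data = pd.DataFrame({"A": [0] * 30 + [1] * 70})
        bn = fit_cpts(_single_node_dag(), data, pseudocount=1.0, cardinalities={"A": 2})
        assert bn.cpts["A"] == pytest.approx(np.array([31 / 102, 71 / 102]))

    def test_empty_data_gives_uniform_tables(self):
        dag = nx.DiGraph([("A", "B")])
        bn = fit_cpts(dag, pd.DataFrame({"A": [], "B": []}), 1.0, {"A": 2, "B": 3})
        assert bn.cpts["A"] == pytest.approx([0.5, 0.5])
        assert bn.cpts["B"] == pytest.approx(np.full((2, 3), 1 / 3))

    def test_state_outside_cardinality_rejected(self):
        dag = nx.DiGraph()
        dag.add_node("A")
        with pytest.raises(ValueError, match="cardinality"):
            fit_cpts(dag, pd.DataFrame({"A": [0, 3]}), 1.0, {"A": 2})

    def test_rows_sum_to_one_on_random_data(self, rng):
        dag = nx.DiGraph([("A", "C"), ("B", "C")])
        data = pd.DataFrame({
            "A": rng.integers(0, 2, 500),
            "B": rng.integers(0, 3, 500),
            "C": rng.integers(0, 4, 500),
        })
        bn = fit_cpts(dag, data, 0.5, {"A": 2, "B": 3, "C": 4})
        assert np.allclose(bn.cpts["C"].sum(axis=-1), 1.0, atol=1e-12)

    def test_parameter_recovery_at_large_n(self, rng):
        # well-observed parent combinations recover the true CPT within L-inf 0.02
        truth = random_discrete_bn(np.random.default_rng(42), d_max=4, card_max=3)
        data = sample(truth, 100_000, seed=5)
        fitted = fit_cpts(truth.dag(), data, 1.0, truth.cardinalities)
        counts = {}
        for node in truth.variables:
            pars = truth.parents[node]
            if not pars:
                assert np.max(np.abs(fitted.cpts[node] - truth.cpts[node])) <= 0.02
                continue
            grouped = data.groupby(list(pars)).size()
            for combo, n_obs in grouped.items():
                combo = combo if isinstance(combo, tuple) else (combo,)
                if n_obs >= 500:
                    err = np.max(np.abs(fitted.cpts[node][combo] - truth.cpts[node][combo]))
                    assert err <= 0.02


def _single_node_dag():
    dag = nx.DiGraph()
    dag.add_node("A")
    return dag


class TestJointProbability:
    def test_single_node(self):
        bn = fit_cpts(_single_node_dag(), pd.DataFrame({"A": []}), 1.0, {"A": 2})
        bn.cpts["A"] = np.array([0.3, 0.7])
        assert joint_probability(bn, {"A": 1}) == pytest.approx(0.7)

    def test_chain_product(self):
        bn = _chain_bn()
        assert joint_probability(bn, {"A": 1, "B": 1}) == pytest.approx(0.36)

    def test_full_joint_sums_to_one(self, rng):
        bn = random_discrete_bn(rng)
        import itertools
        total = sum(
            joint_probability(bn, dict(zip(bn.variables, combo)))
            for combo in itertools.product(*(range(bn.cardinalities[v]) for v in bn.variables))
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_incomplete_assignment_rejected(self):
        bn = _chain_bn()
        with pytest.raises(ValueError, match="missing"):
            joint_probability(bn, {"A": 1})


class TestQuery:
    def test_chain_marginal(self):
        bn = _chain_bn()
        assert query(bn, "B").distribution[1] == pytest.approx(0.48, abs=1e-12)

    def test_root_without_evidence_returns_prior(self):
        bn = _chain_bn()
        assert query(bn, "A").distribution == pytest.approx([0.6, 0.4])

    def test_markov_property_cpt_row(self):
        bn = _chain_bn()
        assert query(bn, "B", {"A": 1}).distribution == pytest.approx([0.1, 0.9])

    def test_zero_probability_evidence_raises(self):
        bn = _chain_bn(p_a1=1.0)
        with pytest.raises(ZeroEvidenceError):
            query(bn, "B", {"A": 0})

    def test_variable_elimination_matches_enumeration_on_random_networks(self):
        # 200 random small networks, random targets and evidence
        rng = np.random.default_rng(777)
        for _ in range(200):
            bn = random_discrete_bn(rng, d_max=6, card_max=3)
            target = bn.variables[int(rng.integers(len(bn.variables)))]
            others = [v for v in bn.variables if v != target]
            rng.shuffle(others)
            evidence = {
                v: int(rng.integers(bn.cardinalities[v]))
                for v in others[: int(rng.integers(0, len(others) + 1))]
            }
            expected = enumerate_conditional(bn, target, evidence)
            if expected.sum() == 0:
                continue
            got = query(bn, target, evidence).distribution
            assert np.max(np.abs(got - expected)) < 1e-10


class TestDSeparation:
    def test_chain_blocked_by_middle(self):
        g = nx.DiGraph([("A", "B"), ("B", "C")])
        assert d_separated(g, "A", "C", {"B"})
        assert not d_separated(g, "A", "C", set())

    def test_collider_opened_by_conditioning(self):
        g = nx.DiGraph([("A", "C"), ("B", "C")])
        assert d_separated(g, "A", "B", set())
        assert not d_separated(g, "A", "B", {"C"})

    def test_default_model_gmv_sbp_separated_by_shared_parents(self, default_model):
        g = default_model.graph()
        assert d_separated(g, "gmv", "sbp", {"age", "sex", "bmi"})
        assert not d_separated(g, "gmv", "sbp", set())

    def test_unknown_node_rejected(self):
        g = nx.DiGraph([("A", "B")])
        with pytest.raises(ValueError):
            d_separated(g, "A", "Z", set())

    def test_agrees_with_partial_correlation_on_default_model(self, default_model, default_cohort_20k):
        # graphical independence <=> vanishing adjusted association in data
        rng = np.random.default_rng(101)
        g = default_model.graph()
        nodes = list(default_model.nodes)
        checked = 0
        while checked < 20:
            x, y = rng.choice(nodes, size=2, replace=False)
            given = [v for v in nodes if v not in (x, y) and rng.random() < 0.4]
            sep = d_separated(g, x, y, set(given))
            Z = np.column_stack(
                [np.ones(len(default_cohort_20k))]
                + [default_cohort_20k[v].to_numpy(dtype=float) for v in given]
            )
            resid = lambda v: v - Z @ np.linalg.lstsq(Z, v, rcond=None)[0]
            r = np.corrcoef(
                resid(default_cohort_20k[x].to_numpy(dtype=float)),
                resid(default_cohort_20k[y].to_numpy(dtype=float)),
            )[0, 1]
            if sep:
                assert abs(r) <= 0.05, (x, y, given, r)
            checked += 1


class TestCrossvalAuc:
    def test_deterministic_child_scores_one(self, rng):
        par = rng.integers(0, 2, 2_000)
        data = pd.DataFrame({"P": par, "C": par})
        auc = crossval_auc(nx.DiGraph([("P", "C")]), data, folds=10, seed=0)
        assert auc.loc[auc.node == "C", "mean_auc"].iloc[0] == pytest.approx(1.0)

    def test_independent_child_scores_half(self, rng):
        data = pd.DataFrame({
            "P": rng.integers(0, 2, 20_000),
            "C": rng.integers(0, 2, 20_000),
        })
        auc = crossval_auc(nx.DiGraph([("P", "C")]), data, folds=10, seed=0)
        assert auc.loc[auc.node == "C", "mean_auc"].iloc[0] == pytest.approx(0.5, abs=0.02)

    def test_root_nodes_skipped_and_seed_reproducible(self, rng):
        data = pd.DataFrame({
            "P": rng.integers(0, 2, 1_000),
            "C": rng.integers(0, 4, 1_000),
        })
        dag = nx.DiGraph([("P", "C")])
        a = crossval_auc(dag, data, folds=5, seed=3)
        b = crossval_auc(dag, data, folds=5, seed=3)
        assert set(a.node) == {"C"}
        pd.testing.assert_frame_equal(a, b)


class TestSample:
    def test_marginals_match_cpts(self):
        bn = _chain_bn()
        data = sample(bn, 50_000, seed=1)
        assert data["A"].mean() == pytest.approx(0.4, abs=0.01)
        assert data["B"].mean() == pytest.approx(0.48, abs=0.01)
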