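"""Ground-truth structural model, ancestral sampling, and marginal calibration."""

import numpy as np
import pandas as pd
import pytest

from gmcausal.preprocess import DiscretizationMap
from gmcausal.schema import BINARY, CONTINUOUS
from gmcausal.synth import (
    FEMALE_N,
    MALE_N,
    TABLE1,
    TOTAL_N,
    CyclicModelError,
    StructuralModel,
    build_default_model,
    calibrate_to_marginals,
    simulate,
    simulate_table1_cohort,
    table1_targets,
)


class TestDefaultModel:
    def test_gmv_parents_are_the_five_causal_factors(self, default_model):
        assert set(default_model.parents("gmv")) == {"age", "sex", "smoking", "bmi", "bfp"}

    def test_sbp_and_gmv_share_parents_but_no_edge(self, default_model):
        edges = default_model.edges()
        assert ("sbp", "gmv") not in edges and ("gmv", "sbp") not in edges
        shared = set(default_model.parents("sbp")) & set(default_model.parents("gmv"))
        assert {"age", "sex", "bmi"} <= shared

    def test_age_and_sex_are_roots_and_sinks_have_no_children(self, default_model):
        children_of = lambda n: [c for (p, c) in default_model.edges() if p == n]
        parents_of = default_model.parents
        assert parents_of("age") == [] and parents_of("sex") == []
        for sink in ("gmv", "pa", "sbp"):
            assert children_of(sink) == []

    def test_model_is_acyclic_and_serializes_roundtrip(self, default_model):
        default_model.validate()  # acyclicity among other invariants
        restored = StructuralModel.from_json(default_model.to_json())
        assert restored.weights == default_model.weights
        assert restored.noise_scales == default_model.noise_scales

    def test_cyclic_model_rejected(self):
        with pytest.raises(CyclicModelError):
            StructuralModel(
                nodes=["a", "b"],
                kinds={"a": CONTINUOUS, "b": CONTINUOUS},
                weights={("a", "b"): 1.0, ("b", "a"): 1.0},
                noise_scales={"a": 1.0, "b": 1.0},
            )

    def test_invalid_noise_scale_rejected(self):
        with pytest.raises(ValueError, match="noise scale"):
            StructuralModel(["x"], {"x": CONTINUOUS}, {}, {"x": 0.0})


class TestSimulate:
    def test_single_node_mean_matches_standard_error_bound(self):
        model = StructuralModel(["x"], {"x": CONTINUOUS}, {}, {"x": 1.0})
        table = simulate(model, 100_000, seed=11)
        assert abs(table["x"].mean()) < 0.02  # 3 / sqrt(n) safety margin

    def test_seeded_determinism(self, default_model):
        a = simulate(default_model, 500, seed=7)
        b = simulate(default_model, 500, seed=7)
        pd.testing.assert_frame_equal(a, b)
        assert a.to_csv() == b.to_csv()

    def test_linear_effect_recovered_by_ols(self):
        model = StructuralModel(
            ["x", "y"], {"x": CONTINUOUS, "y": CONTINUOUS},
            {("x", "y"): 2.0}, {"x": 1.0, "y": 1.0},
        )
        t = simulate(model, 100_000, seed=3)
        slope = np.polyfit(t["x"], t["y"], 1)[0]
        assert abs(slope - 2.0) < 0.03

    def test_closed_form_means_of_continuous_nodes(self, default_model, default_cohort_20k):
        # independent oracle: propagate exact means through the linear system
        means = {}
        sigmoid = lambda z: 1.0 / (1.0 + np.exp(-z))
        for node in default_model.topological_order():
            eta = default_model.intercepts.get(node, 0.0) + sum(
                default_model.weights[(p, node)] * means[p]
                for p in default_model.parents(node)
            )
            means[node] = eta if default_model.kinds[node] == CONTINUOUS else sigmoid(eta)
        n = len(default_cohort_20k)
        for node, kind in default_model.kinds.items():
            if kind != CONTINUOUS:
                continue
            sd = default_cohort_20k[node].std()
            assert abs(default_cohort_20k[node].mean() - means[node]) < 3 * sd / np.sqrt(n)

    def test_ground_truth_conditional_independence_of_gmv_and_sbp(self, default_cohort_20k):
        # partial correlation given {age, sex, bmi} should vanish by d-separation
        Z = np.column_stack([
            np.ones(len(default_cohort_20k)),
            default_cohort_20k[["age", "sex", "bmi"]].to_numpy(),
        ])
        resid = lambda v: v - Z @ np.linalg.lstsq(Z, v, rcond=None)[0]
        r = np.corrcoef(
            resid(default_cohort_20k["gmv"].to_numpy(dtype=float)),
            resid(default_cohort_20k["sbp"].to_numpy(dtype=float)),
        )[0, 1]
        assert abs(r) <= 0.05

    def test_binary_columns_contain_only_01(self, default_cohort_20k):
        for col in ("sex", "smoking"):
            assert set(np.unique(default_cohort_20k[col])) <= {0, 1}

    def test_exact_binary_count(self, default_model):
        t = simulate(default_model, 1000, seed=5, exact_binary={"sex": 400})
        assert int(t["sex"].sum()) == 400


class TestTable1:
    def test_printed_counts_sum_to_printed_totals(self):
        for var, row in TABLE1.items():
            assert sum(row["male"]) == MALE_N, var
            assert sum(row["female"]) == FEMALE_N, var
        assert MALE_N + FEMALE_N == TOTAL_N

    def test_calibrated_cohort_reproduces_male_age_counts(self):
        cohort = simulate_table1_cohort(seed=1)
        dmap = DiscretizationMap({"age": TABLE1["age"]["edges"]})
        states = dmap.assign("age", cohort.loc[cohort["sex"] == 1, "age"])
        counts = np.bincount(states, minlength=4)
        assert counts.tolist() == [2450, 2376, 2998, 3222]

    def test_calibrated_cohort_reproduces_all_marginals(self):
        cohort = simulate_table1_cohort(seed=2)
        targets, edges = table1_targets()
        for var, row in TABLE1.items():
            if var == "sex":
                continue
            for sex_key, expected in (("male", row["male"]), ("female", row["female"])):
                values = cohort.loc[cohort["sex"] == (1 if sex_key == "male" else 0), var]
                if row["edges"] is None:
                    counts = np.bincount(values.astype(int), minlength=2)
                else:
                    counts = np.bincount(
                        DiscretizationMap({var: row["edges"]}).assign(var, values),
                        minlength=4,
                    )
                assert counts.tolist() == list(expected), (var, sex_key)


class TestCalibrate:
    def test_forced_assignment_one_row_per_state(self):
        table = pd.DataFrame({"x": [10.0, 2.0, 30.0, 4.0]})
        out = calibrate_to_marginals(
            table, {"x": (1, 1, 1, 1)}, {"x": (1.0, 2.0, 3.0)}, sex_col=None
        )
        dmap = DiscretizationMap({"x": (1.0, 2.0, 3.0)})
        assert sorted(dmap.assign("x", out["x"])) == [0, 1, 2, 3]

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"x": rng.normal(size=100)})
        out = calibrate_to_marginals(
            table, {"x": (25, 25, 25, 25)}, {"x": (-1.0, 0.0, 1.0)}, sex_col=None
        )
        assert (np.argsort(table["x"].to_numpy(), kind="stable")
                == np.argsort(out["x"].to_numpy(), kind="stable")).all()

    def test_fixed_point_keeps_state_membership(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame({"x": rng.normal(size=40)})
        edges = {"x": (-0.6, 0.0, 0.6)}
        dmap = DiscretizationMap(edges)
        before = dmap.assign("x", table["x"])
        counts = tuple(np.bincount(before, minlength=4))
        out = calibrate_to_marginals(table, {"x": counts}, edges, sex_col=None)
        assert (dmap.assign("x", out["x"]) == before).all()

    def test_inconsistent_totals_rejected(self):
        table = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="sum"):
            calibrate_to_marginals(table, {"x": (1, 1, 1, 1)}, {"x": (1.0, 2.0, 3.0)}, sex_col=None)
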