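"""Synthetic cohort generation from a ground-truth structural causal model.

The real study population (a UK Biobank imaging cohort of 22,793 subjects)
cannot be redistributed, so every downstream stage of this package is
exercised on cohorts drawn from an explicit structural causal model (SCM)
whose graph mirrors the published causal structure for these variables:
age, sex, smoking, waist-to-hip ratio (WHR), BMI, body fat percentage
(BFP), physical activity (PA), systolic blood pressure (SBP) and
normalized gray matter volume (GMV).

The SCM is linear-Gaussian for continuous nodes and logistic-Bernoulli for
binary nodes, sampled ancestrally in topological order.  Variables are
generated on a standardized (roughly unit-variance) scale;
:func:`calibrate_to_marginals` maps a simulated cohort onto natural units
so that its discretized per-sex state counts exactly reproduce the
published marginal table (:data:`TABLE1`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .schema import BINARY, CONTINUOUS, DEFAULT_SCHEMA

__all__ = [
    "StructuralModel",
    "build_default_model",
    "simulate",
    "calibrate_to_marginals",
    "simulate_table1_cohort",
    "table1_targets",
    "TABLE1",
    "MALE_N",
    "FEMALE_N",
    "TOTAL_N",
]

#: Published per-sex totals of the reference cohort.
MALE_N = 11_046
FEMALE_N = 11_747
TOTAL_N = 22_793

#: Published marginal statistics of the discretized cohort: quartile bin
#: edges (three edges -> four states; binary variables have two states and
#: no edges) and per-sex state counts.  Sex is 1 = male.  Physical activity
#: edges are in the units printed with the source table.
TABLE1: dict[str, dict] = {
    "age": {
        "edges": (58.0, 64.0, 70.0),
        "male": (2450, 2376, 2998, 3222),
        "female": (3113, 2913, 3194, 2527),
    },
    "bmi": {
        "edges": (23.3, 25.6, 28.3),
        "male": (1785, 2883, 3314, 3064),
        "female": (3913, 2815, 2382, 2637),
    },
    "bfp": {
        "edges": (24.7, 30.0, 36.2),
        "male": (5076, 3976, 1784, 210),
        "female": (622, 1701, 3924, 5500),
    },
    "whr": {
        "edges": (0.80, 0.87, 0.93),
        "male": (235, 1693, 3957, 5161),
        "female": (5459, 4003, 1729, 556),
    },
    "pa": {
        "edges": (40.0, 70.0, 120.0),
        "male": (2563, 2631, 2736, 3116),
        "female": (2841, 2959, 2667, 3280),
    },
    "sbp": {
        "edges": (125.0, 137.0, 150.0),
        "male": (1817, 2774, 3238, 3217),
        "female": (3809, 2826, 2572, 2540),
    },
    "smoking": {
        "edges": None,
        "male": (6793, 4253),
        "female": (7941, 3806),
    },
    "gmv": {
        "edges": (761.5, 793.3, 826.5),
        "male": (3903, 3108, 2498, 1537),
        "female": (1795, 2590, 3200, 4162),
    },
}


class CyclicModelError(ValueError):
    """Raised when a structural model's edge set contains a directed cycle."""


@dataclass
class StructuralModel:
    """Linear-Gaussian / logistic structural causal model.

    Attributes
    ----------
    nodes : list of str
        Variable names, in a fixed order (also the column order of
        simulated cohorts).
    kinds : dict
        Per-node measurement kind, ``"continuous"`` or ``"binary"``.
    weights : dict
        Edge weights keyed by ``(parent, child)``.
    noise_scales : dict
        Standard deviation of the additive Gaussian noise of each
        continuous node (dimensionless, standardized scale).
    intercepts : dict
        Per-node offset; for binary nodes this is the logit intercept.
    """

    nodes: list[str]
    kinds: dict[str, str]
    weights: dict[tuple[str, str], float]
    noise_scales: dict[str, float]
    intercepts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        declared = set(self.nodes)
        if len(declared) != len(self.nodes):
            raise ValueError("duplicate node names")
        for node, kind in self.kinds.items():
            if node not in declared:
                raise ValueError(f"kind declared for unknown node {node!r}")
            if kind not in (CONTINUOUS, BINARY):
                raise ValueError(f"unknown kind {kind!r} for node {node!r}")
        for parent, child in self.weights:
            if parent not in declared or child not in declared:
                raise ValueError(f"edge ({parent!r}, {child!r}) references undeclared node")
        for node, scale in self.noise_scales.items():
            if scale <= 0:
                raise ValueError(f"noise scale of {node!r} must be positive, got {scale}")
        if not nx.is_directed_acyclic_graph(self.graph()):
            raise CyclicModelError("structural model contains a directed cycle")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (parent, child), w in self.weights.items():
            g.add_edge(parent, child, weight=w)
        return g

    def topological_order(self) -> list[str]:
        order = list(nx.topological_sort(self.graph()))
        # keep the declared order among unconstrained nodes for reproducibility
        rank = {n: i for i, n in enumerate(order)}
        return sorted(self.nodes, key=lambda n: rank[n])

    def parents(self, node: str) -> list[str]:
        return [p for (p, c) in self.weights if c == node]

    def edges(self) -> set[tuple[str, str]]:
        return set(self.weights)

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "nodes": self.nodes,
            "kinds": self.kinds,
            "edges": [
                {"parent": p, "child": c, "weight": w}
                for (p, c), w in sorted(self.weights.items())
            ],
            "noise_scales": self.noise_scales,
            "intercepts": self.intercepts,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "StructuralModel":
        payload = json.loads(text)
        return cls(
            nodes=list(payload["nodes"]),
            kinds=dict(payload["kinds"]),
            weights={(e["parent"], e["child"]): float(e["weight"]) for e in payload["edges"]},
            noise_scales={k: float(v) for k, v in payload["noise_scales"].items()},
            intercepts={k: float(v) for k, v in payload.get("intercepts", {}).items()},
        )


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def build_default_model() -> StructuralModel:
    """Ground-truth SCM mirroring the published causal structure.

    Gray matter volume has exactly five parents — age, sex, smoking, BMI and
    BFP — with effect magnitudes 0.58, 0.33, 0.12, 0.10 and 0.07 on the
    standardized scale, signed so that higher age, male sex, smoking, BMI
    and BFP all lower GMV (the atrophy direction).  SBP shares the parents
    age, sex and BMI with GMV but has no edge to or from it, so the two are
    d-separated given {age, sex, BMI}: correlated but causally independent.
    WHR acts on GMV only indirectly through BMI and BFP, and physical
    activity is a sink driven by sex and BFP.

    Binary intercepts reproduce the reference cohort's male fraction
    (11,046 / 22,793) and ever-smoker fraction (8,059 / 22,793).
    """
    nodes = [v.name for v in DEFAULT_SCHEMA]
    kinds = {v.name: v.kind for v in DEFAULT_SCHEMA}
    weights = {
        ("sex", "whr"): 0.90,
        ("sex", "bmi"): 0.15,
        ("whr", "bmi"): 0.50,
        ("sex", "bfp"): -1.20,
        ("whr", "bfp"): 0.40,
        ("sex", "pa"): 0.20,
        ("bfp", "pa"): -0.30,
        ("age", "sbp"): 0.40,
        ("sex", "sbp"): 0.30,
        ("bmi", "sbp"): 0.30,
        ("age", "gmv"): -0.58,
        ("sex", "gmv"): -0.33,
        ("smoking", "gmv"): -0.12,
        ("bmi", "gmv"): -0.10,
        ("bfp", "gmv"): -0.07,
    }
    noise_scales = {
        "age": 1.0,
        "whr": 0.90,
        "bmi": 0.85,
        "bfp": 0.80,
        "pa": 0.95,
        "sbp": 0.85,
        "gmv": 0.75,
    }
    intercepts = {
        "sex": _logit(MALE_N / TOTAL_N),
        "smoking": _logit((4253 + 3806) / TOTAL_N),
    }
    return StructuralModel(nodes, kinds, weights, noise_scales, intercepts)


def simulate(
    model: StructuralModel,
    n: int,
    seed: int,
    exact_binary: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Draw a cohort of ``n`` subjects by ancestral sampling.

    Continuous nodes follow ``intercept + sum(weight * parent) + N(0, scale)``;
    binary nodes are Bernoulli with a logistic link on the same linear
    predictor.  Identical ``(model, n, seed)`` arguments yield bit-identical
    tables.

    Parameters
    ----------
    exact_binary : mapping, optional
        ``{node: k}`` forces a binary node to contain exactly ``k`` ones,
        assigned to the rows with the largest ``p_i - u_i`` margin (for a
        root this is a seeded uniform choice of ``k`` rows).  Used to build
        cohorts whose sex totals match the published table exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    model.validate()
    exact_binary = dict(exact_binary or {})
    for node, k in exact_binary.items():
        if model.kinds.get(node) != BINARY:
            raise ValueError(f"exact_binary applies to binary nodes, not {node!r}")
        if not 0 <= k <= n:
            raise ValueError(f"exact count {k} for {node!r} out of range for n={n}")

    rng = np.random.default_rng(seed)
    columns: dict[str, np.ndarray] = {}
    for node in model.topological_order():
        eta = np.full(n, model.intercepts.get(node, 0.0))
        for parent in model.parents(node):
            eta = eta + model.weights[(parent, node)] * columns[parent]
        if model.kinds[node] == CONTINUOUS:
            columns[node] = eta + rng.normal(0.0, model.noise_scales[node], size=n)
        else:
            p = 1.0 / (1.0 + np.exp(-eta))
            u = rng.random(n)
            if node in exact_binary:
                values = np.zeros(n, dtype=np.int64)
                top = np.argsort(u - p, kind="stable")[: exact_binary[node]]
                values[top] = 1
                columns[node] = values
            else:
                columns[node] = (u < p).astype(np.int64)
    return pd.DataFrame({node: columns[node] for node in model.nodes})


def _state_intervals(edges: Sequence[float]) -> list[tuple[float, float]]:
    """Half-open value intervals for the four states of a 3-edge binning.

    The open-ended extreme bins are given a finite synthetic width equal to
    that of the neighbouring interior bin, so calibrated values stay on a
    realistic scale.
    """
    e0, e1, e2 = edges
    if not (e0 < e1 < e2):
        raise ValueError("bin edges must be strictly increasing")
    return [(e0 - (e1 - e0), e0), (e0, e1), (e1, e2), (e2, e2 + (e2 - e1))]


def _counts_for_stratum(target, stratum_key: int):
    if isinstance(target, Mapping):
        key_aliases = {1: ("male", 1), 0: ("female", 0)}
        for alias in key_aliases[stratum_key]:
            if alias in target:
                return tuple(int(c) for c in target[alias])
        raise ValueError(f"no target counts for stratum {stratum_key}")
    return tuple(int(c) for c in target)


def calibrate_to_marginals(
    table: pd.DataFrame,
    targets: Mapping[str, object],
    edges: Mapping[str, Sequence[float]] | None = None,
    sex_col: str | None = "sex",
) -> pd.DataFrame:
    """Monotonically reassign values so discretized counts match targets.

    For each continuous variable, within each sex stratum (or over the
    whole table when ``sex_col`` is None or the targets are unstratified),
    rows are ranked by their current value (stable sort) and the lowest
    ranks are assigned to state 0, the next block to state 1, and so on,
    according to the target counts.  Values are then rewritten to evenly
    spaced points inside the corresponding bin interval, which preserves
    the within-stratum rank order and makes the discretized counts exact.

    Binary variables (two target counts) are calibrated by minimal
    deterministic flipping: existing ones are kept preferentially and
    earlier rows fill any remainder.

    Raises
    ------
    ValueError
        If target counts do not sum to the stratum sizes, or reference
        unknown variables.
    """
    out = table.copy()
    edges = dict(edges or {})

    for var, target in targets.items():
        if var not in out.columns:
            raise ValueError(f"unknown variable {var!r} in calibration targets")
        stratified = isinstance(target, Mapping)
        if stratified and (sex_col is None or sex_col not in out.columns):
            raise ValueError("stratified targets require a sex column")
        if stratified:
            strata = [(k, out[sex_col].to_numpy() == k) for k in (0, 1)]
        else:
            strata = [(None, np.ones(len(out), dtype=bool))]

        for key, mask in strata:
            counts = _counts_for_stratum(target, key) if stratified else tuple(int(c) for c in target)
            if sum(counts) != int(mask.sum()):
                raise ValueError(
                    f"target counts for {var!r} sum to {sum(counts)} "
                    f"but the stratum has {int(mask.sum())} rows"
                )
            values = out.loc[mask, var].to_numpy(dtype=float)
            if len(counts) == 2 and var not in edges:
                ones = int(counts[1])
                current = values >= 0.5
                new = np.zeros(len(values), dtype=np.int64)
                keep = np.flatnonzero(current)[:ones]
                new[keep] = 1
                deficit = ones - len(keep)
                if deficit > 0:
                    fill = np.flatnonzero(~current)[:deficit]
                    new[fill] = 1
                out.loc[mask, var] = new
                continue
            if var not in edges:
                raise ValueError(f"continuous variable {var!r} needs bin edges")
            intervals = _state_intervals(edges[var])
            if len(counts) != len(intervals):
                raise ValueError(f"expected {len(intervals)} counts for {var!r}")
            order = np.argsort(values, kind="stable")
            new = np.empty_like(values)
            start = 0
            for (lo, hi), c in zip(intervals, counts):
                block = order[start : start + c]
                if c:
                    new[block] = lo + (np.arange(c) + 0.5) * (hi - lo) / c
                start += c
            out.loc[mask, var] = new
    return out


def table1_targets() -> tuple[dict[str, dict[int, tuple[int, ...]]], dict[str, tuple[float, ...]]]:
    """Per-sex target counts and bin edges from the published marginal table."""
    targets: dict[str, dict[int, tuple[int, ...]]] = {}
    edges: dict[str, tuple[float, ...]] = {}
    for var, row in TABLE1.items():
        targets[var] = {1: tuple(row["male"]), 0: tuple(row["female"])}
        if row["edges"] is not None:
            edges[var] = tuple(row["edges"])
    return targets, edges


def simulate_table1_cohort(seed: int, model: StructuralModel | None = None) -> pd.DataFrame:
    """Cohort of 22,793 subjects whose discretized per-sex marginals
    exactly reproduce the published table.

    The default SCM is sampled with exactly 11,046 males, then every
    non-sex variable is calibrated to the published per-sex state counts
    with :func:`calibrate_to_marginals`.  The joint dependence structure of
    the SCM is preserved up to the monotone recalibration.
    """
    model = model or build_default_model()
    table = simulate(model, TOTAL_N, seed, exact_binary={"sex": MALE_N})
    targets, edges = table1_targets()
    targets = {var: t for var, t in targets.items() if var != "sex"}
    return calibrate_to_marginals(table, targets, edges)
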