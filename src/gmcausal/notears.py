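"""Acyclicity-constrained continuous structure discovery (NOTEARS).

Learns a weighted directed graph from a cohort table by minimizing a
least-squares reconstruction loss over real d x d matrices subject to the
smooth acyclicity constraint

    h(W) = trace(exp(W o W)) - d = 0,

where ``o`` is the elementwise product.  ``h`` is non-negative,
differentiable, and zero exactly when the nonzero pattern of ``W`` is
acyclic, which turns combinatorial DAG search into a continuous program
solved with an augmented-Lagrangian outer loop around L-BFGS-B.

Prior knowledge enters as an :class:`EdgeMask` of forbidden (parent, child)
pairs whose weights are pinned to exactly zero throughout the optimization
— here, that the exogenous demographics (age, sex) have no parents and the
outcome (gray matter volume) has no children.  Because the constrained
optimum may retain residual near-cycles, :func:`prune_to_dag` removes weak
edges until the graph is strictly acyclic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from .schema import DEFAULT_SCHEMA, VariableSchema

__all__ = [
    "EdgeMask",
    "WeightedGraph",
    "acyclicity_h",
    "learn_structure",
    "prune_to_dag",
    "structure_metrics",
    "StructureLearningError",
]


class StructureLearningError(RuntimeError):
    """Raised when the augmented-Lagrangian loop fails to reach the
    acyclicity tolerance; carries the final constraint value."""

    def __init__(self, h_value: float):
        super().__init__(f"structure learning did not converge: h(W) = {h_value:.3e}")
        self.h_value = h_value


@dataclass(frozen=True)
class EdgeMask:
    """Set of forbidden directed edges (weights constrained to zero)."""

    forbidden: frozenset[tuple[str, str]] = frozenset()

    @classmethod
    def from_schema(cls, schema: Iterable[VariableSchema] = DEFAULT_SCHEMA) -> "EdgeMask":
        """Mask implied by role constraints: variables that may not have
        parents forbid all incoming edges; variables that may not have
        children forbid all outgoing edges."""
        schema = list(schema)
        names = [v.name for v in schema]
        forbidden: set[tuple[str, str]] = set()
        for v in schema:
            if not v.may_have_parents:
                forbidden.update((other, v.name) for other in names if other != v.name)
            if not v.may_have_children:
                forbidden.update((v.name, other) for other in names if other != v.name)
        return cls(frozenset(forbidden))

    def as_matrix(self, variables: Sequence[str]) -> np.ndarray:
        """Boolean d x d matrix, True where the edge i -> j is forbidden.
        The diagonal is always forbidden."""
        index = {v: i for i, v in enumerate(variables)}
        for parent, child in self.forbidden:
            if parent not in index or child not in index:
                raise ValueError(f"mask references unknown variable in ({parent!r}, {child!r})")
        d = len(variables)
        m = np.eye(d, dtype=bool)
        for parent, child in self.forbidden:
            m[index[parent], index[child]] = True
        return m


@dataclass
class WeightedGraph:
    """Real-valued adjacency over named variables; ``W[i, j]`` is the
    weight of the edge ``variables[i] -> variables[j]``."""

    variables: list[str]
    W: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        d = len(self.variables)
        if self.W.shape != (d, d):
            raise ValueError(f"W must be {d}x{d}, got {self.W.shape}")

    def edges(self, tol: float = 0.0) -> dict[tuple[str, str], float]:
        out = {}
        for i, p in enumerate(self.variables):
            for j, c in enumerate(self.variables):
                if i != j and abs(self.W[i, j]) > tol:
                    out[(p, c)] = float(self.W[i, j])
        return out

    def to_digraph(self, tol: float = 0.0) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        for (p, c), w in self.edges(tol).items():
            g.add_edge(p, c, weight=w)
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_digraph())

    # -- export ------------------------------------------------------------

    def to_adjacency_csv(self) -> str:
        return pd.DataFrame(self.W, index=self.variables, columns=self.variables).to_csv()

    def to_edge_json(self) -> str:
        edges = [
            {"parent": p, "child": c, "weight": w}
            for (p, c), w in sorted(self.edges().items())
        ]
        return json.dumps({"variables": self.variables, "edges": edges}, indent=2)

    def to_dot(self) -> str:
        """GraphViz DOT with pen width proportional to |weight|."""
        wmax = max((abs(w) for w in self.edges().values()), default=1.0)
        lines = ["digraph causal {", "  rankdir=TB;"]
        for v in self.variables:
            lines.append(f'  "{v}";')
        for (p, c), w in sorted(self.edges().items()):
            width = 0.5 + 4.0 * abs(w) / wmax
            lines.append(f'  "{p}" -> "{c}" [penwidth={width:.2f}, label="{w:.2f}"];')
        lines.append("}")
        return "\n".join(lines)


# --------------------------------------------------------------------------
# acyclicity functional


def acyclicity_h(W: np.ndarray) -> float:
    """Smooth acyclicity measure: trace(exp(W o W)) - d.

    Zero exactly when the support of ``W`` is acyclic, strictly positive
    otherwise; differentiable everywhere with gradient
    ``exp(W o W)^T o 2W``.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"W must be a square matrix, got shape {W.shape}")
    E = scipy.linalg.expm(W * W)
    return float(np.trace(E) - W.shape[0])


def _h_and_grad(W: np.ndarray) -> tuple[float, np.ndarray]:
    E = scipy.linalg.expm(W * W)
    return float(np.trace(E) - W.shape[0]), E.T * (2.0 * W)


# --------------------------------------------------------------------------
# structure learning


def learn_structure(
    X: pd.DataFrame | np.ndarray,
    mask: EdgeMask | None = None,
    l1_penalty: float = 0.05,
    h_tolerance: float = 1e-8,
    variables: Sequence[str] | None = None,
    max_outer: int = 100,
    rho_max: float = 1e16,
    inner_gtol: float = 1e-6,
) -> WeightedGraph:
    """Fit a weighted causal graph by acyclicity-constrained least squares.

    Minimizes ``(1/2n) ||X - X W||_F^2 + l1_penalty ||W||_1`` subject to
    ``h(W) <= h_tolerance``.  The augmented Lagrangian increases the
    penalty parameter geometrically (x10) whenever the constraint does not
    shrink by 4x, and updates the multiplier each round; the inner problem
    is solved by L-BFGS-B over a positive/negative weight split so the L1
    term stays smooth.  Initialization is W = 0, so runs are reproducible
    without seeds.  Masked entries are held at exactly zero via bounds.

    Continuous columns are expected on comparable (standardized) scales;
    binary indicator columns enter as 0/1.  All columns are centered
    internally: the loss has no intercept term, so uncentered columns
    would otherwise force spurious mean-explaining edges between them.
    Centering leaves the Bernoulli scale of binary columns intact.
    """
    if isinstance(X, pd.DataFrame):
        variables = list(X.columns)
        data = X.to_numpy(dtype=float)
    else:
        data = np.asarray(X, dtype=float)
        if variables is None:
            variables = [f"x{i}" for i in range(data.shape[1])]
        variables = list(variables)
    n, d = data.shape
    if n <= d:
        raise ValueError(f"need more rows than variables (n={n}, d={d})")
    sds = data.std(axis=0)
    if np.any(sds == 0):
        bad = [variables[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"zero-variance column(s): {bad}")
    if l1_penalty < 0:
        raise ValueError("l1_penalty must be non-negative")
    data = data - data.mean(axis=0)

    mask_m = (mask or EdgeMask()).as_matrix(variables)
    d2 = d * d
    bounds = []
    for _ in range(2):  # positive part then negative part
        for i in range(d):
            for j in range(d):
                bounds.append((0.0, 0.0) if mask_m[i, j] else (0.0, None))

    rho, alpha, h_val = 1.0, 0.0, np.inf
    w_est = np.zeros(2 * d2)
    cov = data.T @ data / n

    def _objective(z, rho, alpha):
        W = (z[:d2] - z[d2:]).reshape(d, d)
        resid_grad = cov @ W - cov  # (1/n) X^T (XW - X)
        loss = 0.5 / n * np.sum((data - data @ W) ** 2)
        h, Gh = _h_and_grad(W)
        obj = loss + 0.5 * rho * h * h + alpha * h + l1_penalty * z.sum()
        G = resid_grad + (rho * h + alpha) * Gh
        grad = np.concatenate([(G + l1_penalty).ravel(), (-G + l1_penalty).ravel()])
        return obj, grad

    for _ in range(max_outer):
        w_new, h_new = None, None
        while rho < rho_max:
            sol = scipy.optimize.minimize(
                _objective,
                w_est,
                args=(rho, alpha),
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": 1000, "gtol": inner_gtol, "ftol": 1e-12},
            )
            w_new = sol.x
            h_new = acyclicity_h((w_new[:d2] - w_new[d2:]).reshape(d, d))
            if h_new > 0.25 * h_val:
                rho *= 10.0
            else:
                break
        w_est, h_val = w_new, h_new
        alpha += rho * h_val
        if h_val <= h_tolerance or rho >= rho_max:
            break
    if h_val > h_tolerance:
        raise StructureLearningError(h_val)

    W = (w_est[:d2] - w_est[d2:]).reshape(d, d)
    W[mask_m] = 0.0  # exact zeros (bounds already enforce this)
    return WeightedGraph(variables, W)


# --------------------------------------------------------------------------
# pruning to a DAG


def prune_to_dag(graph: WeightedGraph, floor: float = 0.01) -> WeightedGraph:
    """Remove weak edges until the graph is a strict DAG.

    First zeroes every entry with ``|weight| < floor``; then, while a
    directed cycle remains, deletes the smallest-|weight| edge that lies
    inside a strongly connected component (ties broken lexicographically
    by (parent, child) name).
    """
    W = graph.W.copy()
    W[np.abs(W) < floor] = 0.0
    index = {v: i for i, v in enumerate(graph.variables)}
    g = WeightedGraph(graph.variables, W).to_digraph()
    while not nx.is_directed_acyclic_graph(g):
        cyclic_edges = []
        for comp in nx.strongly_connected_components(g):
            if len(comp) < 2:
                continue
            for p, c in g.edges(comp):
                if p in comp and c in comp:
                    cyclic_edges.append((abs(g[p][c]["weight"]), p, c))
        _, p, c = min(cyclic_edges)
        g.remove_edge(p, c)
        W[index[p], index[c]] = 0.0
    return WeightedGraph(graph.variables, W)


# --------------------------------------------------------------------------
# benchmarking against a known structure


def _edge_set(obj) -> set[tuple[str, str]]:
    if isinstance(obj, WeightedGraph):
        return set(obj.edges())
    return set(obj.edges())  # StructuralModel and nx.DiGraph both expose edges()


def structure_metrics(learned, truth) -> dict[str, float]:
    """Compare a learned graph with a reference structure.

    Returns the structural Hamming distance (missing + extra + reversed
    edges, a reversal counting once), directed-edge precision/recall, and
    skeleton (undirected) precision/recall.
    """
    learned_vars = set(learned.variables) if isinstance(learned, WeightedGraph) else set(learned.nodes)
    truth_vars = set(truth.variables) if isinstance(truth, WeightedGraph) else set(truth.nodes)
    if learned_vars != truth_vars:
        raise ValueError("learned and reference graphs have different variable sets")

    le, te = _edge_set(learned), _edge_set(truth)
    reversed_edges = {(p, c) for (p, c) in le if (c, p) in te and (p, c) not in te}
    extra = {e for e in le if e not in te and e not in reversed_edges}
    missing = {e for e in te if e not in le and (e[1], e[0]) not in le}
    shd = len(missing) + len(extra) + len(reversed_edges)

    tp = len(le & te)
    precision = tp / len(le) if le else (1.0 if not te else 0.0)
    recall = tp / len(te) if te else 1.0

    lsk = {frozenset(e) for e in le}
    tsk = {frozenset(e) for e in te}
    stp = len(lsk & tsk)
    skeleton_precision = stp / len(lsk) if lsk else (1.0 if not tsk else 0.0)
    skeleton_recall = stp / len(tsk) if tsk else 1.0

    return {
        "shd": float(shd),
        "precision": precision,
        "recall": recall,
        "skeleton_precision": skeleton_precision,
        "skeleton_recall": skeleton_recall,
        "n_learned_edges": float(len(le)),
        "n_true_edges": float(len(te)),
    }
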