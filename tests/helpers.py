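"""Shared test utilities: independent oracles and random-model builders.

The enumeration oracle here deliberately avoids the package's inference
code paths: it walks all full assignments with direct CPT lookups.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd

from gmcausal.bayesnet import DiscreteBayesNet


def random_discrete_bn(rng: np.random.Generator, d_max: int = 6, card_max: int = 3) -> DiscreteBayesNet:
    """Random DAG (edge prob. 0.4 over a random order) with Dirichlet CPTs."""
    d = int(rng.integers(2, d_max + 1))
    names = [f"v{i}" for i in range(d)]
    order = rng.permutation(d)
    parents: dict[str, tuple[str, ...]] = {}
    for pos, idx in enumerate(order):
        earlier = [names[j] for j in order[:pos]]
        chosen = [p for p in earlier if rng.random() < 0.4]
        parents[names[idx]] = tuple(chosen)
    cards = {v: int(rng.integers(2, card_max + 1)) for v in names}
    cpts = {}
    for v in names:
        shape = tuple(cards[p] for p in parents[v]) + (cards[v],)
        cpts[v] = rng.dirichlet(np.ones(cards[v]), size=shape[:-1]).reshape(shape)
    return DiscreteBayesNet(names, parents, cards, cpts)


def enumerate_conditional(bn: DiscreteBayesNet, target: str, evidence: dict) -> np.ndarray:
    """Brute-force p(target | evidence) by summing the full joint."""
    free = [v for v in bn.variables if v != target and v not in evidence]
    dist = np.zeros(bn.cardinalities[target])
    for t_state in range(bn.cardinalities[target]):
        total = 0.0
        for combo in itertools.product(*(range(bn.cardinalities[v]) for v in free)):
            assignment = dict(zip(free, combo))
            assignment[target] = t_state
            assignment.update(evidence)
            p = 1.0
            for node in bn.variables:
                idx = tuple(assignment[q] for q in bn.parents[node]) + (assignment[node],)
                p *= bn.cpts[node][idx]
            total += p
        dist[t_state] = total
    z = dist.sum()
    return dist / z if z > 0 else dist


def has_cycle_dfs(W: np.ndarray, tol: float = 0.0) -> bool:
    """Depth-first-search cycle detection on the nonzero pattern of W."""
    d = W.shape[0]
    adj = [list(np.flatnonzero(np.abs(W[i]) > tol)) for i in range(d)]
    color = [0] * d  # 0 white, 1 gray, 2 black

    def visit(u: int) -> bool:
        color[u] = 1
        for v in adj[u]:
            if color[v] == 1 or (color[v] == 0 and visit(v)):
                return True
        color[u] = 2
        return False

    return any(color[u] == 0 and visit(u) for u in range(d))


def random_sparse_matrix(rng: np.random.Generator, d: int, p_edge: float = 0.25) -> np.ndarray:
    """Random weighted adjacency with entries 0 or +-[0.5, 2.0]."""
    mask = rng.random((d, d)) < p_edge
    np.fill_diagonal(mask, False)
    signs = rng.choice([-1.0, 1.0], size=(d, d))
    mags = rng.uniform(0.5, 2.0, size=(d, d))
    return np.where(mask, signs * mags, 0.0)
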