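"""Independent brute-force oracles used to check the implementation.

Everything here deliberately avoids the code paths under test: exact
rational arithmetic for the hypergeometric tail, a literal step-up loop
for BH, exhaustive DAG enumeration for Markov equivalence classes and
IDA adjustment sets, and residual-based partial correlation.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from functools import lru_cache
from math import comb

import numpy as np


def exact_hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact rational."""
    total = comb(N, n)
    acc = 0
    for x in range(k, min(n, K) + 1):
        if n - x > N - K:
            continue
        acc += comb(K, x) * comb(N - K, n - x)
    return Fraction(acc, total)


def stepup_bh(pvals) -> np.ndarray:
    """Literal Benjamini–Hochberg step-up: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def residual_partial_correlation(X: np.ndarray, i: int, j: int, S) -> float:
    """rho(i, j | S) as the correlation of regression residuals."""
    S = list(S)
    xi, xj = X[i], X[j]
    if S:
        Z = np.column_stack([X[s] for s in S] + [np.ones(X.shape[1])])
        xi = xi - Z @ np.linalg.lstsq(Z, xi, rcond=None)[0]
        xj = xj - Z @ np.linalg.lstsq(Z, xj, rcond=None)[0]
    return float(np.corrcoef(xi, xj)[0, 1])


# ---------------------------------------------------------------------------
# DAG / Markov equivalence class enumeration
# ---------------------------------------------------------------------------

def _is_acyclic(nodes, edges) -> bool:
    remaining = set(nodes)
    out = {v: {b for a, b in edges if a == v} for v in nodes}
    while remaining:
        leaves = [v for v in remaining if not (out[v] & remaining)]
        if not leaves:
            return False
        remaining -= set(leaves)
    return True


def all_dags(nodes: tuple[str, ...]):
    """Every labeled DAG on ``nodes`` as a frozenset of directed edges."""
    pairs = list(itertools.combinations(nodes, 2))
    dags = []
    for states in itertools.product((0, 1, 2), repeat=len(pairs)):
        edges = set()
        for (a, b), s in zip(pairs, states):
            if s == 1:
                edges.add((a, b))
            elif s == 2:
                edges.add((b, a))
        if _is_acyclic(nodes, edges):
            dags.append(frozenset(edges))
    return dags


def dag_vstructures(nodes, edges) -> frozenset:
    adj = {frozenset(e) for e in edges}
    vs = set()
    parents = {v: sorted(a for a, b in edges if b == v) for v in nodes}
    for k in nodes:
        for i, j in itertools.combinations(parents[k], 2):
            if frozenset((i, j)) not in adj:
                vs.add((i, j, k))
    return frozenset(vs)


@lru_cache(maxsize=None)
def markov_equivalence_classes(nodes: tuple[str, ...]):
    """Group all DAGs on ``nodes`` by (skeleton, v-structures).

    Returns a list of (cpdag_directed, cpdag_undirected, members) where the
    CPDAG is the orientation consensus of the class members — an oracle
    route entirely independent of the Meek-rule implementation.
    """
    groups: dict[tuple, list[frozenset]] = {}
    for edges in all_dags(nodes):
        skeleton = frozenset(frozenset(e) for e in edges)
        key = (skeleton, dag_vstructures(nodes, edges))
        groups.setdefault(key, []).append(edges)
    out = []
    for (skeleton, _), members in groups.items():
        directed = set()
        undirected = set()
        for e in skeleton:
            a, b = tuple(sorted(e))
            orientations = {((a, b) in m) for m in members}
            if len(orientations) == 1:
                directed.add((a, b) if orientations == {True} else (b, a))
            else:
                undirected.add(frozenset((a, b)))
        out.append((frozenset(directed), frozenset(undirected), tuple(members)))
    return out


def class_parent_sets(members, x: str) -> set[frozenset]:
    """Distinct parent sets of ``x`` across all DAGs of an equivalence class."""
    return {frozenset(a for a, b in m if b == x) for m in members}


def ols_coefficient(X: np.ndarray, pos: dict, x: str, y: str, Z) -> float:
    """Coefficient of x in the regression of y on [x] + Z (with intercept)."""
    cols = [X[pos[x]]] + [X[pos[z]] for z in Z] + [np.ones(X.shape[1])]
    M = np.column_stack(cols)
    beta = np.linalg.lstsq(M, X[pos[y]], rcond=None)[0]
    return float(beta[0])
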