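"""Causal effect estimation: PC-stable CPDAG discovery plus local IDA.

The observational causal-effect stage estimates, for each candidate
lncRNA–mRNA pair, the multiset of total causal effects of the lncRNA on
the mRNA that are compatible with the data:

1. A CPDAG (completed partially directed acyclic graph, representing a
   Markov equivalence class of DAGs) is learned over the candidate genes
   with the PC-stable algorithm: level-wise conditional-independence
   pruning with adjacency sets frozen per level (hence order-independent),
   Gaussian CI tests via Fisher-z-transformed partial correlations,
   v-structure orientation from separating sets, and Meek rules R1–R4.
2. Local IDA (intervention calculus when the DAG is absent) enumerates
   every parent set of the lncRNA consistent with the CPDAG and reads the
   effect off the lncRNA's coefficient in the least-squares regression of
   the mRNA on the lncRNA plus that parent set.  If the mRNA itself enters
   the adjustment set the effect for that set is 0.

The summary statistic is the conventional IDA lower bound: the
minimum-absolute element of the multiset, carrying its sign (ties broken
by smaller parent set, then lexicographic set order).  Causal sufficiency
is assumed, as the method requires — the shared miRNAs are latent in
rRNA-depleted long-RNA data, so summaries are screening scores, not
unbiased effect estimates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm

from .expression import ExpressionMatrix

_COND_MAX = 1e10  # condition-number ceiling before a regression is deemed rank-deficient


@dataclass
class CiTestConfig:
    """Per-test significance level and conditioning-set cap for PC.

    ``alpha`` is the two-sided level of the Fisher-z Gaussian CI test;
    ``max_cond_size`` bounds |S| (None = unbounded).  Defaults keep
    high-dimensional skeletons sparse.
    """

    alpha: float = 0.01
    max_cond_size: int | None = 3

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.max_cond_size is not None and self.max_cond_size < 0:
            raise ValueError("max_cond_size must be >= 0 or None")


class Cpdag:
    """Mixed graph of directed and undirected edges over named nodes."""

    def __init__(
        self,
        nodes: Sequence[str],
        directed: Iterable[tuple[str, str]] = (),
        undirected: Iterable[tuple[str, str]] = (),
    ):
        self.nodes = list(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node ids")
        node_set = set(self.nodes)
        self.directed: set[tuple[str, str]] = set()
        self.undirected: set[frozenset[str]] = set()
        for a, b in directed:
            self._check_nodes(a, b, node_set)
            self.directed.add((a, b))
        for a, b in undirected:
            self._check_nodes(a, b, node_set)
            self.undirected.add(frozenset((a, b)))
        self._validate()

    @staticmethod
    def _check_nodes(a: str, b: str, node_set: set[str]) -> None:
        if a == b:
            raise ValueError(f"self-loop at {a!r}")
        if a not in node_set or b not in node_set:
            raise ValueError(f"edge ({a}, {b}) references unknown node")

    def _validate(self) -> None:
        for a, b in self.directed:
            if (b, a) in self.directed:
                raise ValueError(f"both orientations present for ({a}, {b})")
            if frozenset((a, b)) in self.undirected:
                raise ValueError(f"edge ({a}, {b}) both directed and undirected")

    # -- queries -----------------------------------------------------------
    def adjacent(self, a: str, b: str) -> bool:
        return (
            (a, b) in self.directed
            or (b, a) in self.directed
            or frozenset((a, b)) in self.undirected
        )

    def parents(self, v: str) -> set[str]:
        return {a for a, b in self.directed if b == v}

    def children(self, v: str) -> set[str]:
        return {b for a, b in self.directed if a == v}

    def siblings(self, v: str) -> set[str]:
        """Undirected neighbors."""
        return {next(iter(e - {v})) for e in self.undirected if v in e}

    def neighbors(self, v: str) -> set[str]:
        return self.parents(v) | self.children(v) | self.siblings(v)

    @property
    def n_edges(self) -> int:
        return len(self.directed) + len(self.undirected)

    def copy(self) -> "Cpdag":
        return Cpdag(self.nodes, self.directed, [tuple(e) for e in self.undirected])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cpdag):
            return NotImplemented
        return (
            set(self.nodes) == set(other.nodes)
            and self.directed == other.directed
            and self.undirected == other.undirected
        )


@dataclass(frozen=True)
class CausalEffect:
    """IDA output for one (lncRNA, mRNA) pair.

    ``effects`` holds one value per locally valid parent set (deterministic
    order: by parent-set size, then lexicographic); ``summary`` is the
    signed minimum-absolute element.
    """

    lnc_id: str
    mrna_id: str
    effects: tuple[float, ...]
    summary: float
    n_parent_sets: int


# ---------------------------------------------------------------------------
# Gaussian CI machinery
# ---------------------------------------------------------------------------

def _corr_matrix(data: ExpressionMatrix) -> tuple[np.ndarray, dict[str, int]]:
    arr = data.values.to_numpy()
    sd = arr.std(axis=1)
    if np.any(sd == 0):
        flat = [g for g, s in zip(data.gene_ids, sd) if s == 0]
        raise ValueError(f"constant expression rows: {flat[:5]}")
    corr = np.corrcoef(arr)
    return corr, {g: i for i, g in enumerate(data.gene_ids)}


def _partial_corr_from_matrix(
    corr: np.ndarray, i: int, j: int, S: Sequence[int]
) -> float:
    idx = [i, j, *S]
    sub = corr[np.ix_(idx, idx)]
    if np.linalg.cond(sub) > _COND_MAX:
        raise ValueError("singular (collinear) conditioning set in partial correlation")
    prec = np.linalg.inv(sub)
    rho = -prec[0, 1] / math.sqrt(prec[0, 0] * prec[1, 1])
    if abs(rho) > 1 + 1e-10:
        raise ValueError(f"partial correlation {rho} outside [-1, 1]")
    return float(np.clip(rho, -1.0, 1.0))


def partial_correlation(
    data: ExpressionMatrix, i: str, j: str, S: Iterable[str] = ()
) -> float:
    """Partial correlation ρ(i, j | S) by correlation-matrix sub-inversion."""
    S = list(S)
    if i == j:
        raise ValueError("i and j must differ")
    if i in S or j in S:
        raise ValueError("conditioning set must exclude i and j")
    if len(S) > data.n_samples - 4:
        raise ValueError(
            f"|S|={len(S)} too large for n_samples={data.n_samples} (need |S| <= n-4)"
        )
    corr, pos = _corr_matrix(data)
    return _partial_corr_from_matrix(corr, pos[i], pos[j], [pos[s] for s in S])


def fisher_z_pvalue(rho: float, n: int, cond_size: int = 0) -> tuple[float, float]:
    """(z statistic, two-sided p) of the Fisher-z Gaussian CI test.

    z = sqrt(n − |S| − 3) · atanh(ρ); ρ = ±1 saturates to p = 0.
    """
    dof = n - cond_size - 3
    if dof < 1:
        raise ValueError(f"need n - |S| - 3 >= 1 (n={n}, |S|={cond_size})")
    if abs(rho) >= 1.0:
        return math.copysign(math.inf, rho), 0.0
    z = math.sqrt(dof) * math.atanh(rho)
    return z, float(2.0 * norm.sf(abs(z)))


def ci_test(
    data: ExpressionMatrix,
    i: str,
    j: str,
    S: Iterable[str],
    cfg: CiTestConfig,
) -> tuple[float, float, bool]:
    """Fisher-z CI test: returns (statistic, p, independent)."""
    S = list(S)
    rho = partial_correlation(data, i, j, S)
    z, p = fisher_z_pvalue(rho, data.n_samples, len(S))
    return z, p, p > cfg.alpha


# ---------------------------------------------------------------------------
# PC-stable skeleton + orientation
# ---------------------------------------------------------------------------

def pc_stable_cpdag(data: ExpressionMatrix, cfg: CiTestConfig | None = None) -> Cpdag:
    """Estimate the CPDAG of the genes in ``data`` with PC-stable.

    At each level the adjacency sets are frozen before any edge removal,
    making the skeleton independent of variable ordering.  V-structures
    with conflicting orientation demands are left undirected (a
    deterministic, order-independent resolution); Meek rules are then run
    to closure.
    """
    cfg = cfg or CiTestConfig()
    genes = data.gene_ids
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    if data.n_samples < 10:
        raise ValueError(f"need n_samples >= 10, got {data.n_samples}")
    if data.n_samples - 3 < 1:
        raise ValueError("too few samples for level-0 Fisher-z tests")
    corr, pos = _corr_matrix(data)
    n = data.n_samples

    adj: dict[str, set[str]] = {g: set(genes) - {g} for g in genes}
    sepset: dict[frozenset[str], set[str]] = {}

    level = 0
    while True:
        if cfg.max_cond_size is not None and level > cfg.max_cond_size:
            break
        if n - level - 3 < 1:
            break
        frozen = {g: set(neigh) for g, neigh in adj.items()}
        if all(len(neigh) - 1 < level for neigh in frozen.values()):
            break
        # lexicographic pair order makes sepset choices canonical, so the
        # result is invariant to the input variable ordering
        for i, j in itertools.combinations(sorted(genes), 2):
            if j not in adj[i]:
                continue
            removed = False
            seen: set[tuple[str, ...]] = set()
            for base in (frozen[i] - {j}, frozen[j] - {i}):
                if removed or len(base) < level:
                    continue
                for S in itertools.combinations(sorted(base), level):
                    if S in seen:
                        continue
                    seen.add(S)
                    rho = _partial_corr_from_matrix(
                        corr, pos[i], pos[j], [pos[s] for s in S]
                    )
                    _, p = fisher_z_pvalue(rho, n, level)
                    if p > cfg.alpha:
                        adj[i].discard(j)
                        adj[j].discard(i)
                        sepset[frozenset((i, j))] = set(S)
                        removed = True
                        break
                if removed:
                    break
        level += 1

    skeleton = {frozenset((i, j)) for i in genes for j in adj[i]}

    # v-structures: i - k - j with i, j nonadjacent and k outside sepset(i, j)
    demanded: set[tuple[str, str]] = set()
    for k in genes:
        for i, j in itertools.combinations(sorted(adj[k]), 2):
            if j in adj[i]:
                continue
            sep = sepset.get(frozenset((i, j)))
            if sep is not None and k not in sep:
                demanded.add((i, k))
                demanded.add((j, k))
    # conflicting demands (both orientations) leave the edge undirected
    directed = {(a, b) for a, b in demanded if (b, a) not in demanded}
    undirected = {e for e in skeleton if not _is_directed(directed, e)}

    g = Cpdag(genes, directed, [tuple(sorted(e)) for e in undirected])
    _apply_meek_rules(g)
    return g


def _is_directed(directed: set[tuple[str, str]], e: frozenset[str]) -> bool:
    a, b = tuple(e)
    return (a, b) in directed or (b, a) in directed


def _orient(g: Cpdag, a: str, b: str) -> bool:
    """Turn undirected a−b into a→b; no-op unless the edge is undirected."""
    e = frozenset((a, b))
    if e not in g.undirected:
        return False
    g.undirected.discard(e)
    g.directed.add((a, b))
    return True


def _apply_meek_rules(g: Cpdag) -> None:
    """Meek rules R1–R4, iterated to closure (deterministic order)."""
    changed = True
    while changed:
        changed = False
        for e in sorted(g.undirected, key=lambda e: tuple(sorted(e))):
            a, b = tuple(sorted(e))
            for x, y in ((a, b), (b, a)):
                if _meek_applies(g, x, y):
                    changed = _orient(g, x, y) or changed
                    break
    # closure reached


def _meek_applies(g: Cpdag, a: str, b: str) -> bool:
    """Would any of R1–R4 orient a−b as a→b?"""
    # R1: c→a, a−b, c and b nonadjacent  =>  a→b
    for c in g.parents(a):
        if not g.adjacent(c, b):
            return True
    # R2: a→c→b with a−b  =>  a→b
    if g.children(a) & g.parents(b):
        return True
    # R3: a−c, a−d, c→b, d→b, c and d nonadjacent  =>  a→b
    sibs = g.siblings(a)
    into_b = g.parents(b)
    cands = sorted(sibs & into_b)
    for c, d in itertools.combinations(cands, 2):
        if not g.adjacent(c, d):
            return True
    # R4: a−d, d→c, c→b, a adjacent to c  =>  a→b
    for d in sibs:
        for c in g.children(d):
            if (c, b) in g.directed and g.adjacent(a, c):
                return True
    return False


def cpdag_from_dag(nodes: Sequence[str], edges: Iterable[tuple[str, str]]) -> Cpdag:
    """CPDAG (Markov equivalence class representative) of a DAG.

    Keeps exactly the v-structure orientations and completes with Meek
    rules; every other edge becomes undirected.
    """
    edges = set(edges)
    parents: dict[str, set[str]] = {v: set() for v in nodes}
    for a, b in edges:
        parents[b].add(a)
    adjacent = {frozenset(e) for e in edges}
    directed: set[tuple[str, str]] = set()
    for k in nodes:
        for i, j in itertools.combinations(sorted(parents[k]), 2):
            if frozenset((i, j)) not in adjacent:
                directed.add((i, k))
                directed.add((j, k))
    undirected = [tuple(sorted(e)) for e in adjacent if not _is_directed(directed, e)]
    g = Cpdag(list(nodes), directed, undirected)
    _apply_meek_rules(g)
    return g


# ---------------------------------------------------------------------------
# local IDA
# ---------------------------------------------------------------------------

def _regression_effect(
    cov: np.ndarray, pos: dict[str, int], x: str, y: str, Z: Sequence[str]
) -> float:
    """Coefficient of x in the least-squares regression of y on [x] + Z."""
    idx = [pos[x], *[pos[z] for z in Z]]
    sub = cov[np.ix_(idx, idx)]
    if np.linalg.cond(sub) > _COND_MAX:
        raise np.linalg.LinAlgError("rank-deficient adjustment regression")
    beta = np.linalg.solve(sub, cov[idx, pos[y]])
    return float(beta[0])


def _valid_parent_sets(g: Cpdag, x: str) -> list[tuple[str, ...]]:
    """All S ⊆ sib(x) whose promotion to parents creates no new v-structure at x."""
    pa = sorted(g.parents(x))
    sibs = sorted(g.siblings(x))
    out: list[tuple[str, ...]] = []
    for size in range(len(sibs) + 1):
        for S in itertools.combinations(sibs, size):
            ok = True
            for s in S:
                for t in itertools.chain(S, pa):
                    if t != s and not g.adjacent(s, t):
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                out.append(S)
    return out


def ida_local(
    data: ExpressionMatrix, g: Cpdag, x: str, y: str
) -> CausalEffect:
    """Multiset of possible total causal effects of ``x`` on ``y`` (local IDA).

    One effect per locally valid parent set pa(x) ∪ S (S ⊆ undirected
    neighbors of x); the effect is 0 for sets containing ``y``.  The
    summary is the signed minimum-absolute element.
    """
    if x == y:
        raise ValueError("x and y must differ")
    for v in (x, y):
        if v not in g.nodes:
            raise KeyError(f"node {v!r} not in CPDAG")
    cov = np.cov(data.values.to_numpy())
    cov = np.atleast_2d(cov)
    pos = {gname: i for i, gname in enumerate(data.gene_ids)}
    pa = sorted(g.parents(x))
    results: list[tuple[float, tuple[str, ...]]] = []
    failures: list[str] = []
    for S in _valid_parent_sets(g, x):
        adjustment = sorted(set(pa) | set(S))
        if y in adjustment:
            results.append((0.0, S))
            continue
        try:
            eff = _regression_effect(cov, pos, x, y, adjustment)
        except np.linalg.LinAlgError:
            failures.append(f"S={S}")
            continue
        results.append((eff, S))
    if not results:
        raise ValueError(
            f"all adjustment regressions for ({x}, {y}) rank-deficient: {failures}"
        )
    results.sort(key=lambda r: (len(r[1]), r[1]))
    best_eff, _ = min(results, key=lambda r: (abs(r[0]), len(r[1]), r[1]))
    return CausalEffect(
        lnc_id=x,
        mrna_id=y,
        effects=tuple(eff for eff, _ in results),
        summary=best_eff,
        n_parent_sets=len(results),
    )


def estimate_pair_effects(
    data: ExpressionMatrix,
    pairs: Sequence,
    cfg: CiTestConfig | None = None,
) -> list[CausalEffect]:
    """CPDAG over the union of candidate-pair genes, then local IDA per pair.

    ``pairs`` is any sequence with ``lnc_id``/``mrna_id`` attributes (e.g.
    :class:`~spongenet.sharing.CandidatePair`).  The CPDAG is built once and
    is read-only afterwards, so pairs are safe to evaluate concurrently;
    this implementation evaluates them serially in input order.
    """
    cfg = cfg or CiTestConfig()
    gene_union = sorted({p.lnc_id for p in pairs} | {p.mrna_id for p in pairs})
    missing = [g for g in gene_union if g not in set(data.gene_ids)]
    if missing:
        raise KeyError(f"pair genes absent from expression data: {missing[:5]}")
    sub = data.subset(gene_union)
    g = pc_stable_cpdag(sub, cfg)
    return [ida_local(sub, g, p.lnc_id, p.mrna_id) for p in pairs]


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def cpdag_to_networkx(g: Cpdag):
    """CPDAG as a networkx DiGraph with a boolean ``directed`` edge attribute.

    Undirected edges are stored once, endpoints in sorted order.
    """
    import networkx as nx

    out = nx.DiGraph()
    out.add_nodes_from(g.nodes)
    for a, b in sorted(g.directed):
        out.add_edge(a, b, directed=True)
    for e in sorted(g.undirected, key=lambda e: tuple(sorted(e))):
        a, b = tuple(sorted(e))
        out.add_edge(a, b, directed=False)
    return out


def write_cpdag_graphml(g: Cpdag, path) -> None:
    import networkx as nx

    nx.write_graphml(cpdag_to_networkx(g), path)


EFFECT_COLUMNS = ("lnc_id", "mrna_id", "effect_summary", "n_parent_sets", "effects")


def write_effects(effects: Sequence[CausalEffect], path) -> None:
    """Tab-separated effect table; the full multiset is semicolon-joined."""
    from pathlib import Path

    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(EFFECT_COLUMNS) + "\n")
        for e in effects:
            joined = ";".join(f"{v:.6g}" for v in e.effects)
            fh.write(
                f"{e.lnc_id}\t{e.mrna_id}\t{e.summary:.6g}\t{e.n_parent_sets}\t{joined}\n"
            )


def read_effects(path) -> list[CausalEffect]:
    from pathlib import Path

    out: list[CausalEffect] = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            effs = tuple(float(v) for v in f[4].split(";")) if f[4] else ()
            out.append(CausalEffect(f[0], f[1], effs, float(f[2]), int(f[3])))
    return out
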