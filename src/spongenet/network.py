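"""Sponge-network assembly: correlation-called edges and hub lncRNAs.

Each candidate pair's Pearson correlation on the transformed expression
matrix is tested with the Fisher z-transform p-value (the
``corPvalueFisher`` convention: z = sqrt(n−3)·atanh(r), two-sided normal
p), the p-values are BH-adjusted jointly across all candidate pairs, and
edges with adjusted p below the cutoff (default 0.05) — optionally also
requiring a positive correlation and/or a causal-effect floor — form the
bipartite lncRNA–mRNA sponge network.  Hub lncRNAs are the top fraction
(default 20%) by degree.

ceRNA co-regulation predicts positive lncRNA–mRNA correlation, so
``require_positive_r`` defaults to True.  A causal-effect floor is
available via ``effect_min`` but disabled by default: the IDA summary is
the minimum-absolute effect over the equivalence class, which is exactly 0
whenever the pair's edge is undirected in the CPDAG — the typical case
when the association is carried by latent shared miRNAs — so a strict
positive-effect gate would discard precisely the sponge signal.  Effect
summaries are always reported as edge annotations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .causal import CausalEffect
from .expression import ExpressionMatrix
from .sharing import CandidatePair, bh_adjust


@dataclass(frozen=True)
class SpongeEdge:
    """A called sponge interaction with its supporting statistics."""

    lnc_id: str
    mrna_id: str
    r: float
    p_cor: float
    q_cor: float
    effect_summary: float
    k_shared: int


class SpongeNetwork:
    """Bipartite lncRNA–mRNA network with per-node degrees."""

    def __init__(self, edges: Sequence[SpongeEdge]):
        keys = [(e.lnc_id, e.mrna_id) for e in edges]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (lnc, mRNA) edges")
        self.edges: list[SpongeEdge] = list(edges)
        self.lnc_degree: dict[str, int] = {}
        self.mrna_degree: dict[str, int] = {}
        for e in self.edges:
            self.lnc_degree[e.lnc_id] = self.lnc_degree.get(e.lnc_id, 0) + 1
            self.mrna_degree[e.mrna_id] = self.mrna_degree.get(e.mrna_id, 0) + 1

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def lnc_ids(self) -> list[str]:
        return sorted(self.lnc_degree)

    @property
    def mrna_ids(self) -> list[str]:
        return sorted(self.mrna_degree)


@dataclass(frozen=True)
class HubSet:
    """Top-degree lncRNAs (ordered by degree desc, then id)."""

    hubs: tuple[str, ...]
    fraction: float


def cor_pvalue_fisher(r: float, n: int) -> float:
    """Two-sided correlation p-value from the Fisher z-transform.

    p = 2(1 − Φ(sqrt(n−3)·|atanh(r)|)); symmetric in ±r, p(0) = 1, and
    |r| = 1 saturates to 0.
    """
    if abs(r) > 1:
        raise ValueError(f"|r| <= 1 violated (r={r})")
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    if abs(r) == 1.0:
        return 0.0
    z = math.sqrt(n - 3) * math.atanh(abs(r))
    return float(2.0 * norm.sf(z))


def call_edges(
    data: ExpressionMatrix,
    pairs: Sequence[CandidatePair],
    effects: Sequence[CausalEffect],
    q_max: float = 0.05,
    effect_min: float | None = None,
    require_positive_r: bool = True,
) -> SpongeNetwork:
    """Call sponge edges from candidate pairs on the shared transformed matrix.

    Retains pairs with BH-adjusted correlation p (``q_cor``) strictly below
    ``q_max``, plus ``r > 0`` if ``require_positive_r`` and
    ``effect_summary > effect_min`` if ``effect_min`` is not None.
    """
    if not (0 < q_max <= 1):
        raise ValueError(f"q_max must be in (0, 1], got {q_max}")
    eff_by_key = {(e.lnc_id, e.mrna_id): e for e in effects}
    pair_keys = {(p.lnc_id, p.mrna_id) for p in pairs}
    orphan_pairs = sorted(pair_keys - set(eff_by_key))
    orphan_effects = sorted(set(eff_by_key) - pair_keys)
    if orphan_pairs or orphan_effects:
        raise ValueError(
            f"pair/effect key mismatch; pairs without effects: {orphan_pairs[:5]}, "
            f"effects without pairs: {orphan_effects[:5]}"
        )
    if not pairs:
        return SpongeNetwork([])
    n = data.n_samples
    rs, ps = [], []
    for p in pairs:
        x = data.row(p.lnc_id)
        y = data.row(p.mrna_id)
        r = float(np.corrcoef(x, y)[0, 1])
        rs.append(r)
        ps.append(cor_pvalue_fisher(r, n))
    qs = bh_adjust(ps)
    edges = []
    for p, r, p_cor, q_cor in zip(pairs, rs, ps, qs):
        eff = eff_by_key[(p.lnc_id, p.mrna_id)]
        if q_cor >= q_max:
            continue
        if require_positive_r and r <= 0:
            continue
        if effect_min is not None and not (eff.summary > effect_min):
            continue
        edges.append(
            SpongeEdge(
                p.lnc_id, p.mrna_id, r, float(p_cor), float(q_cor),
                eff.summary, p.k_shared,
            )
        )
    return SpongeNetwork(edges)


def select_hubs(net: SpongeNetwork, fraction: float = 0.2) -> HubSet:
    """Top-degree lncRNAs: max(1, floor(fraction · L)) of the L lncRNA nodes.

    Degree descending, ties broken lexicographically on id.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if net.n_edges == 0:
        raise ValueError("cannot select hubs from an empty network")
    ranked = sorted(net.lnc_degree.items(), key=lambda kv: (-kv[1], kv[0]))
    n_hubs = max(1, math.floor(fraction * len(ranked)))
    return HubSet(tuple(g for g, _ in ranked[:n_hubs]), fraction)


def degree_table(net: SpongeNetwork) -> list[tuple[str, str, int]]:
    """(node id, class, degree) rows, lncRNAs first, each sorted by id."""
    rows = [(g, "lncRNA", d) for g, d in sorted(net.lnc_degree.items())]
    rows += [(g, "mRNA", d) for g, d in sorted(net.mrna_degree.items())]
    return rows


EDGE_COLUMNS = ("lnc_id", "mrna_id", "r", "p_cor", "q_cor", "effect_summary", "k_shared")


def write_edges(net: SpongeNetwork, path: str | Path) -> None:
    """Tab-separated edge table, sorted by (q_cor, lnc_id, mrna_id)."""
    ordered = sorted(net.edges, key=lambda e: (e.q_cor, e.lnc_id, e.mrna_id))
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(EDGE_COLUMNS) + "\n")
        for e in ordered:
            fh.write(
                f"{e.lnc_id}\t{e.mrna_id}\t{e.r:.6g}\t{e.p_cor:.6g}\t"
                f"{e.q_cor:.6g}\t{e.effect_summary:.6g}\t{e.k_shared}\n"
            )


def read_edges(path: str | Path) -> SpongeNetwork:
    edges = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            edges.append(
                SpongeEdge(f[0], f[1], float(f[2]), float(f[3]), float(f[4]),
                           float(f[5]), int(f[6]))
            )
    return SpongeNetwork(edges)


def write_hubs(hubset: HubSet, net: SpongeNetwork, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("#lnc_id\tdegree\n")
        for g in hubset.hubs:
            fh.write(f"{g}\t{net.lnc_degree[g]}\n")


def network_to_networkx(net: SpongeNetwork):
    """Sponge network as a networkx Graph with node ``cls`` and edge stats."""
    import networkx as nx

    g = nx.Graph()
    for lnc in net.lnc_ids:
        g.add_node(lnc, cls="lncRNA")
    for mrna in net.mrna_ids:
        g.add_node(mrna, cls="mRNA")
    for e in net.edges:
        g.add_edge(
            e.lnc_id, e.mrna_id, r=e.r, p_cor=e.p_cor, q_cor=e.q_cor,
            effect_summary=e.effect_summary, k_shared=e.k_shared,
        )
    return g


def write_network_graphml(net: SpongeNetwork, path: str | Path) -> None:
    import networkx as nx

    nx.write_graphml(network_to_networkx(net), path)
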