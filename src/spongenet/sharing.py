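"""Shared-miRNA enrichment between lncRNA–mRNA pairs.

A candidate sponge pair is a lncRNA and an mRNA whose evidence-supported
miRNA regulator sets overlap more than chance predicts.  Significance is
the hypergeometric upper tail: drawing ``n`` miRNAs (the lncRNA's
regulators) without replacement from a universe of ``N`` miRNAs of which
``K`` regulate the mRNA, the p-value is P(X ≥ k) for the observed overlap
``k``.  P-values are Benjamini–Hochberg adjusted across all candidate
pairs and thresholded on the adjusted value.

The upper tail is accumulated in log space (gammaln + logsumexp), so deep
tails stay accurate instead of collapsing to 0 through ``1 − cdf``
cancellation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .interactions import InteractionSet


@dataclass(frozen=True)
class CandidatePair:
    """One lncRNA–mRNA pair with its shared-miRNA overlap statistics.

    ``k_shared`` miRNAs are shared; ``n_lnc`` target the lncRNA, ``K_mrna``
    the mRNA, out of a pooled universe of ``N_universe`` miRNAs.
    ``q_hyper`` is NaN until BH adjustment fills it.
    """

    lnc_id: str
    mrna_id: str
    k_shared: int
    n_lnc: int
    K_mrna: int
    N_universe: int
    p_hyper: float
    q_hyper: float = float("nan")


def _log_binom(n: int, k) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def log_hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """log P(X ≥ k) for X ~ Hypergeometric(N, K, n)."""
    _check_hypergeom_args(k, n, K, N)
    if k <= max(0, n + K - N):
        return 0.0
    hi = min(n, K)
    xs = np.arange(k, hi + 1)
    log_terms = _log_binom(K, xs) + _log_binom(N - K, n - xs) - _log_binom(N, n)
    return float(logsumexp(log_terms))


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X ≥ k): chance of sharing at least ``k`` of ``n`` drawn miRNAs.

    ``N`` is the miRNA universe size, ``K`` the number regulating the mRNA,
    ``n`` the number regulating the lncRNA (the two margins are symmetric).
    """
    return float(min(1.0, np.exp(log_hypergeom_upper_tail(k, n, K, N))))


def _check_hypergeom_args(k: int, n: int, K: int, N: int) -> None:
    if N < 1:
        raise ValueError(f"N >= 1 violated (N={N})")
    if not (0 <= n <= N):
        raise ValueError(f"0 <= n <= N violated (n={n}, N={N})")
    if not (0 <= K <= N):
        raise ValueError(f"0 <= K <= N violated (K={K}, N={N})")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"0 <= k <= min(n, K) violated (k={k}, n={n}, K={K})")


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enumerate_candidates(
    s: InteractionSet,
    lnc_ids: Iterable[str],
    mrna_ids: Iterable[str],
    min_shared: int = 1,
) -> list[CandidatePair]:
    """All (lncRNA, mRNA) pairs sharing at least ``min_shared`` evidence miRNAs.

    ``p_hyper`` is filled from the hypergeometric upper tail with
    N = pooled miRNA universe of ``s``; ``q_hyper`` is left for
    :func:`adjust_candidates`.
    """
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")
    lnc_ids, mrna_ids = sorted(set(lnc_ids)), sorted(set(mrna_ids))
    for gid, want in [(g, "lncRNA") for g in lnc_ids] + [
        (g, "mRNA") for g in mrna_ids
    ]:
        if not s.has_target(gid):
            raise KeyError(f"{want} {gid!r} has no interaction evidence")
        if s.target_class_of(gid) != want:
            raise ValueError(
                f"{gid!r} has target_class {s.target_class_of(gid)}, expected {want}"
            )
    N = len(s.mirna_universe)
    pairs: list[CandidatePair] = []
    for lnc in lnc_ids:
        mirnas_l = s.mirnas_of(lnc)
        for mrna in mrna_ids:
            mirnas_m = s.mirnas_of(mrna)
            k = len(mirnas_l & mirnas_m)
            if k < min_shared:
                continue
            p = hypergeom_upper_tail(k, len(mirnas_l), len(mirnas_m), N)
            pairs.append(
                CandidatePair(lnc, mrna, k, len(mirnas_l), len(mirnas_m), N, p)
            )
    return pairs


def adjust_candidates(pairs: Sequence[CandidatePair]) -> list[CandidatePair]:
    """Fill ``q_hyper`` by BH adjustment across the whole candidate family."""
    if not pairs:
        return []
    q = bh_adjust([p.p_hyper for p in pairs])
    return [replace(pair, q_hyper=float(qi)) for pair, qi in zip(pairs, q)]


def filter_candidates(
    pairs: Sequence[CandidatePair], q_max: float = 0.05
) -> list[CandidatePair]:
    """Keep pairs with ``q_hyper < q_max`` (strict), preserving input order."""
    if not (0 < q_max <= 1):
        raise ValueError(f"q_max must be in (0, 1], got {q_max}")
    for p in pairs:
        if np.isnan(p.q_hyper):
            raise ValueError(
                f"pair ({p.lnc_id}, {p.mrna_id}) lacks q_hyper; "
                "run adjust_candidates first"
            )
    return [p for p in pairs if p.q_hyper < q_max]


CANDIDATE_COLUMNS = (
    "lnc_id", "mrna_id", "k_shared", "n_lnc", "K_mrna",
    "N_universe", "p_hyper", "q_hyper",
)


def write_candidates(pairs: Sequence[CandidatePair], path: str | Path) -> None:
    """Tab-separated candidate table, sorted by (q_hyper, lnc_id, mrna_id)."""
    ordered = sorted(pairs, key=lambda p: (p.q_hyper, p.lnc_id, p.mrna_id))
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(CANDIDATE_COLUMNS) + "\n")
        for p in ordered:
            fh.write(
                f"{p.lnc_id}\t{p.mrna_id}\t{p.k_shared}\t{p.n_lnc}\t{p.K_mrna}\t"
                f"{p.N_universe}\t{p.p_hyper:.6g}\t{p.q_hyper:.6g}\n"
            )


def read_candidates(path: str | Path) -> list[CandidatePair]:
    pairs: list[CandidatePair] = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            pairs.append(
                CandidatePair(
                    f[0], f[1], int(f[2]), int(f[3]), int(f[4]),
                    int(f[5]), float(f[6]), float(f[7]),
                )
            )
    return pairs
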