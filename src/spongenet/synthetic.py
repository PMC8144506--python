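"""Ground-truth sponge-system simulator.

Generates linear-Gaussian structural equation models of the ceRNA
mechanism — latent miRNA regulators shared between lncRNAs and mRNAs
(which induce positive lncRNA–mRNA correlation without any direct edge),
optional direct lncRNA→mRNA coupling — together with the noisy
miRNA–target evidence tables the pipeline consumes, and a machine-readable
truth for scoring.

miRNAs are exogenous in the SEM and their expression rows are *not*
emitted: in rRNA-depleted long-RNA sequencing the miRNAs are unobserved,
so they act as latent confounders exactly as in the real data.  Expression
is simulated on the Gaussian scale (no count layer) and is meant to be
consumed with transform mode ``none``.

Pools of miRNAs used for pair-shared parents, lncRNA-private parents and
mRNA-private parents are kept disjoint, so the set of true sponge pairs is
exactly the planned sharing plan — no accidental cross-class sharing
contaminates precision/recall scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, GeneAnnotation, write_annotation, write_expression
from .interactions import InteractionRecord, InteractionSet, write_interactions


def _default_sharing() -> dict[tuple[str, str], int]:
    # three strongly coupled sponge pairs (5 shared miRNA regulators each)
    return {
        ("LNC01", "MRNA01"): 5,
        ("LNC02", "MRNA02"): 5,
        ("LNC03", "MRNA03"): 5,
    }


@dataclass
class SpongeSystemSpec:
    """Parameters of a synthetic sponge system.

    ``sharing`` maps (lncRNA, mRNA) pairs to the planned count of shared
    miRNA regulators; ``direct_pairs`` lists pairs that additionally get a
    direct lncRNA→mRNA edge with coefficient ``direct_effect``.  The
    default 22-sample design mirrors the study's cohort size.
    """

    n_mirna: int = 30
    n_lnc: int = 12
    n_mrna: int = 20
    n_samples: int = 22
    sharing: dict[tuple[str, str], int] = field(default_factory=_default_sharing)
    direct_pairs: tuple[tuple[str, str], ...] = ()
    n_private_parents: int = 1
    repression_strength: float = -0.8
    direct_effect: float = 0.0
    noise_sd: float = 1.0
    fp_rate: float = 0.05
    fn_rate: float = 0.05
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("n_mirna", "n_lnc", "n_mrna"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")
        if not (0 <= self.fp_rate < 1) or not (0 <= self.fn_rate < 1):
            raise ValueError("fp_rate and fn_rate must lie in [0, 1)")
        if self.repression_strength >= 0:
            raise ValueError("repression_strength must be negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_private_parents < 0:
            raise ValueError("n_private_parents must be >= 0")
        if any(v < 0 for v in self.sharing.values()):
            raise ValueError("sharing counts must be >= 0")

    @property
    def mirna_ids(self) -> list[str]:
        return [f"MIR{i:02d}" for i in range(1, self.n_mirna + 1)]

    @property
    def lnc_ids(self) -> list[str]:
        return [f"LNC{i:02d}" for i in range(1, self.n_lnc + 1)]

    @property
    def mrna_ids(self) -> list[str]:
        return [f"MRNA{i:02d}" for i in range(1, self.n_mrna + 1)]


def null_spec(**overrides) -> SpongeSystemSpec:
    """A system with no sharing and no direct effects (all genes independent
    across the lncRNA/mRNA divide)."""
    overrides.setdefault("sharing", {})
    overrides.setdefault("direct_pairs", ())
    return SpongeSystemSpec(**overrides)


@dataclass
class SyntheticTruth:
    """The generating SEM: weighted DAG plus the true pair sets."""

    mirna_ids: list[str]
    lnc_ids: list[str]
    mrna_ids: list[str]
    edges: dict[tuple[str, str], float]  # (parent, child) -> coefficient
    true_sponge_pairs: set[tuple[str, str]]
    true_direct_pairs: dict[tuple[str, str], float]

    def parents_of(self, node: str) -> dict[str, float]:
        return {p: w for (p, c), w in self.edges.items() if c == node}

    def mirna_targets(self, target_class: str) -> list[tuple[str, str]]:
        pool = set(self.lnc_ids if target_class == "lncRNA" else self.mrna_ids)
        return sorted(
            (p, c) for (p, c) in self.edges
            if p in set(self.mirna_ids) and c in pool
        )


def _draw_coef(rng: np.random.Generator, mean: float) -> float:
    coef = rng.normal(mean, 0.1 * abs(mean))
    return min(coef, -0.05)  # keep repression strictly negative


def generate_truth(spec: SpongeSystemSpec) -> SyntheticTruth:
    """Build the weighted DAG realizing ``spec`` (deterministic per seed)."""
    genes = set(spec.lnc_ids) | set(spec.mrna_ids)
    for (lnc, mrna) in list(spec.sharing) + list(spec.direct_pairs):
        if lnc not in set(spec.lnc_ids) or mrna not in set(spec.mrna_ids):
            raise ValueError(f"pair ({lnc}, {mrna}) references unknown genes")
    demand = sum(spec.sharing.values())
    n_pools = 2 if spec.n_private_parents > 0 else 0
    if demand + n_pools > spec.n_mirna:
        raise ValueError(
            f"sharing demand {demand} (+{n_pools} private pools) exceeds "
            f"n_mirna={spec.n_mirna}"
        )
    rng = np.random.default_rng([spec.seed, 11])
    shuffled = list(rng.permutation(spec.mirna_ids))
    edges: dict[tuple[str, str], float] = {}
    cursor = 0
    sponge_pairs: set[tuple[str, str]] = set()
    for pair in sorted(spec.sharing):
        count = spec.sharing[pair]
        if count == 0:
            continue
        common = shuffled[cursor:cursor + count]
        cursor += count
        lnc, mrna = pair
        for m in common:
            edges[(m, lnc)] = _draw_coef(rng, spec.repression_strength)
            edges[(m, mrna)] = _draw_coef(rng, spec.repression_strength)
        sponge_pairs.add(pair)
    leftovers = shuffled[cursor:]
    if spec.n_private_parents > 0:
        # planted sponge-pair genes are purely shared-regulated (maximal
        # regulator overlap, the sponge signal itself); every other gene
        # gets private parents from a class-specific pool
        paired = {g for pair in sponge_pairs for g in pair}
        half = max(1, len(leftovers) // 2)
        lnc_pool, mrna_pool = leftovers[:half], leftovers[half:]
        if not lnc_pool or not mrna_pool:
            raise ValueError("not enough miRNAs left for private parent pools")
        for gene_list, pool in ((spec.lnc_ids, lnc_pool), (spec.mrna_ids, mrna_pool)):
            k = min(spec.n_private_parents, len(pool))
            for g in gene_list:
                if g in paired:
                    continue
                chosen = rng.choice(len(pool), size=k, replace=False)
                for idx in sorted(chosen):
                    edges[(pool[idx], g)] = _draw_coef(rng, spec.repression_strength)
    direct: dict[tuple[str, str], float] = {}
    for (lnc, mrna) in sorted(set(spec.direct_pairs)):
        edges[(lnc, mrna)] = spec.direct_effect
        direct[(lnc, mrna)] = spec.direct_effect
    return SyntheticTruth(
        mirna_ids=list(spec.mirna_ids),
        lnc_ids=list(spec.lnc_ids),
        mrna_ids=list(spec.mrna_ids),
        edges=edges,
        true_sponge_pairs=sponge_pairs,
        true_direct_pairs=direct,
    )


def simulate_expression(truth: SyntheticTruth, spec: SpongeSystemSpec) -> ExpressionMatrix:
    """Topological-order linear-Gaussian sampling; miRNA rows are withheld.

    Each node is the weighted sum of its parents plus N(0, noise_sd) noise;
    exogenous miRNAs are pure noise terms.  Returned matrix rows are
    lncRNAs then mRNAs, on the Gaussian scale (use transform mode
    ``none``).
    """
    rng = np.random.default_rng([spec.seed, 23])
    order = truth.mirna_ids + truth.lnc_ids + truth.mrna_ids
    values: dict[str, np.ndarray] = {}
    for node in order:
        x = rng.normal(0.0, spec.noise_sd, size=spec.n_samples)
        for parent, w in sorted(truth.parents_of(node).items()):
            x = x + w * values[parent]
        values[node] = x
    samples = [f"S{i:02d}" for i in range(1, spec.n_samples + 1)]
    rows = truth.lnc_ids + truth.mrna_ids
    df = pd.DataFrame([values[g] for g in rows], index=rows, columns=samples)
    return ExpressionMatrix(df)


def annotation_for(truth: SyntheticTruth) -> GeneAnnotation:
    biotypes = {g: "lncRNA" for g in truth.lnc_ids}
    biotypes.update({g: "mRNA" for g in truth.mrna_ids})
    return GeneAnnotation(biotypes)


def emit_evidence(
    truth: SyntheticTruth, spec: SpongeSystemSpec
) -> tuple[InteractionSet, InteractionSet]:
    """Noisy (miRNA–lncRNA, miRNA–mRNA) evidence tables.

    Each true miRNA→target edge yields one record, deleted with probability
    ``fn_rate``; round(fp_rate × n_true) spurious records are drawn without
    replacement from the non-edges of the same class.  Deterministic per
    seed.
    """
    rng = np.random.default_rng([spec.seed, 37])
    out = []
    for target_class, targets in (("lncRNA", truth.lnc_ids), ("mRNA", truth.mrna_ids)):
        true_edges = truth.mirna_targets(target_class)
        keep = rng.random(len(true_edges)) >= spec.fn_rate
        records = [
            InteractionRecord(m, t, target_class, "synthetic_truth")
            for (m, t), k in zip(true_edges, keep) if k
        ]
        non_edges = sorted(
            (m, t)
            for m in truth.mirna_ids
            for t in targets
            if (m, t) not in truth.edges
        )
        n_fp = int(round(spec.fp_rate * len(true_edges)))
        n_fp = min(n_fp, len(non_edges))
        if n_fp:
            chosen = rng.choice(len(non_edges), size=n_fp, replace=False)
            records += [
                InteractionRecord(*non_edges[i], target_class, "synthetic_fp")
                for i in sorted(chosen)
            ]
        if not records:
            raise ValueError(f"no {target_class} evidence survived fn_rate")
        out.append(InteractionSet(records))
    return out[0], out[1]


def write_truth(truth: SyntheticTruth, edges_path: str | Path, pairs_path: str | Path) -> None:
    """Truth as two tab-separated tables: weighted edges and true pairs."""
    with Path(edges_path).open("w", encoding="utf-8") as fh:
        fh.write("#parent\tchild\tcoefficient\n")
        for (p, c) in sorted(truth.edges):
            fh.write(f"{p}\t{c}\t{truth.edges[(p, c)]:.10g}\n")
    with Path(pairs_path).open("w", encoding="utf-8") as fh:
        fh.write("#lnc_id\tmrna_id\tkind\tcoefficient\n")
        for (lnc, mrna) in sorted(truth.true_sponge_pairs):
            fh.write(f"{lnc}\t{mrna}\tsponge\t0\n")
        for (lnc, mrna), w in sorted(truth.true_direct_pairs.items()):
            fh.write(f"{lnc}\t{mrna}\tdirect\t{w:.10g}\n")


def read_true_pairs(pairs_path: str | Path) -> set[tuple[str, str]]:
    pairs: set[tuple[str, str]] = set()
    with Path(pairs_path).open(encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            pairs.add((f[0], f[1]))
    return pairs


def end_to_end_fixture(spec: SpongeSystemSpec, outdir: str | Path) -> dict[str, Path]:
    """Write a complete, self-consistent input bundle plus the truth.

    Produces expression/annotation/evidence files in the pipeline dialects,
    the truth tables, and a ready-to-run pipeline config (low-expression
    filter off and transform ``none``, since the matrix is Gaussian-scale).
    Byte-identical for a fixed spec.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = generate_truth(spec)
    expr = simulate_expression(truth, spec)
    ann = annotation_for(truth)
    ev_lnc, ev_mrna = emit_evidence(truth, spec)
    paths = {
        "expression": outdir / "expression.tsv",
        "annotation": outdir / "annotation.tsv",
        "evidence_lnc": outdir / "evidence_lncRNA.tsv",
        "evidence_mrna": outdir / "evidence_mRNA.tsv",
        "truth_edges": outdir / "truth_edges.tsv",
        "truth_pairs": outdir / "truth_pairs.tsv",
        "config": outdir / "config.txt",
    }
    write_expression(expr, paths["expression"])
    write_annotation(ann, paths["annotation"])
    write_interactions(ev_lnc, paths["evidence_lnc"])
    write_interactions(ev_mrna, paths["evidence_mrna"])
    write_truth(truth, paths["truth_edges"], paths["truth_pairs"])
    config_lines = [
        f"expression = {paths['expression']}",
        f"annotation = {paths['annotation']}",
        f"evidence = {paths['evidence_lnc']},{paths['evidence_mrna']}",
        "min_total = 0",
        "transform = none",
        f"seed = {spec.seed}",
    ]
    paths["config"].write_text("\n".join(config_lines) + "\n", encoding="utf-8")
    return paths
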