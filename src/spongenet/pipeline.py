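"""End-to-end orchestration: filter → candidates → causal effects → network.

Stages mirror the four-step sponge-network construction: (a) integrate
miRNA–target evidence, (b) call candidate lncRNA–mRNA pairs by shared-
miRNA enrichment, (c) estimate IDA causal effects over the candidate
genes, (d) call edges by BH-adjusted Fisher correlation p-values and pick
hub lncRNAs by degree.  Every intermediate table is written, a manifest
records config, input digests and per-stage counts, and identical config
plus inputs yield byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from . import expression as expr_mod
from . import interactions as int_mod
from . import sharing as sharing_mod
from . import causal as causal_mod
from . import network as net_mod

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, with the study's stated constants as defaults
    (low-expression total < 100 removed, BH-adjusted p < 0.05, top-20% hubs)."""

    expression: str = ""
    annotation: str = ""
    evidence: tuple[str, ...] = ()
    min_total: float = 100.0
    transform: str = "log2p1"
    min_shared: int = 1
    sharing_q_max: float = 0.05
    alpha: float = 0.01
    max_cond_size: int | None = 3
    edge_q_max: float = 0.05
    effect_min: float | None = None
    require_positive_r: bool = True
    hub_fraction: float = 0.2
    seed: int = 1

    def validate(self) -> None:
        if self.min_total < 0:
            raise ValueError("min_total must be >= 0")
        if self.transform not in expr_mod.TRANSFORM_MODES:
            raise ValueError(
                f"transform must be one of {expr_mod.TRANSFORM_MODES}"
            )
        if self.min_shared < 1:
            raise ValueError("min_shared must be >= 1")
        for name in ("sharing_q_max", "edge_q_max"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.max_cond_size is not None and self.max_cond_size < 0:
            raise ValueError("max_cond_size must be >= 0 or none")
        if not (0 < self.hub_fraction <= 1):
            raise ValueError("hub_fraction must be in (0, 1]")


_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}

_PARSERS = {
    "expression": str,
    "annotation": str,
    "evidence": lambda v: tuple(p.strip() for p in v.split(",") if p.strip()),
    "min_total": float,
    "transform": str,
    "min_shared": int,
    "sharing_q_max": float,
    "alpha": float,
    "max_cond_size": lambda v: None if v.lower() == "none" else int(v),
    "edge_q_max": float,
    "effect_min": lambda v: None if v.lower() == "none" else float(v),
    "require_positive_r": lambda v: _BOOL[v.lower()],
    "hub_fraction": float,
    "seed": int,
}


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse a flat ``key = value`` config file; unknown keys are rejected."""
    cfg = PipelineConfig()
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in _PARSERS:
                raise ValueError(
                    f"{path}:{lineno}: unknown key {key!r}; "
                    f"accepted: {sorted(_PARSERS)}"
                )
            try:
                setattr(cfg, key, _PARSERS[key](value))
            except (ValueError, KeyError) as exc:
                raise ValueError(
                    f"{path}:{lineno}: bad value for {key!r}: {value!r}"
                ) from exc
    cfg.validate()
    return cfg


@dataclass
class RunResult:
    """In-memory view of one pipeline run (tables are also written to disk)."""

    candidates: list
    effects: list
    network: net_mod.SpongeNetwork
    hubs: net_mod.HubSet | None
    manifest: dict
    outputs: dict[str, Path] = field(default_factory=dict)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _config_echo(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["evidence"] = list(cfg.evidence)
    return d


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> RunResult:
    """Execute all stages, writing candidate/effect/edge/hub tables + manifest.

    ``min_total = 0`` disables the low-expression filter entirely (on
    Gaussian-scale simulated data a literal row-sum cut would be
    meaningless).  Partial outputs are removed if a stage fails.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = {
        "candidates": outdir / "candidates.tsv",
        "effects": outdir / "effects.tsv",
        "edges": outdir / "edges.tsv",
        "hubs": outdir / "hubs.tsv",
        "manifest": outdir / "manifest.json",
    }
    written: list[Path] = []
    counts: dict[str, int] = {}
    stage = "load"
    try:
        x = expr_mod.read_expression(cfg.expression)
        ann = expr_mod.read_annotation(cfg.annotation)
        counts["genes_input"] = x.n_genes
        counts["samples"] = x.n_samples

        stage = "filter"
        if cfg.min_total > 0:
            x = expr_mod.filter_low_expression(x, cfg.min_total)
        counts["genes_after_filter"] = x.n_genes
        x = expr_mod.transform(x, cfg.transform)

        stage = "evidence"
        sets = [int_mod.load_interactions(p) for p in cfg.evidence]
        evidence = int_mod.merge(*sets)
        counts["evidence_records"] = len(evidence)
        counts["mirna_universe"] = len(evidence.mirna_universe)

        stage = "candidates"
        expressed = set(x.gene_ids)
        lnc_ids, mrna_ids, n_excluded = set(), set(), 0
        for g in x.gene_ids:
            if g not in ann:
                raise ValueError(f"expressed gene {g!r} lacks annotation")
            biotype = ann[g]
            if not evidence.has_target(g) or evidence.target_class_of(g) != biotype:
                n_excluded += 1
                continue
            (lnc_ids if biotype == "lncRNA" else mrna_ids).add(g)
        logger.info("candidates: excluded %d genes without usable evidence", n_excluded)
        counts["genes_without_evidence"] = n_excluded
        pairs = sharing_mod.enumerate_candidates(
            evidence, lnc_ids, mrna_ids, cfg.min_shared
        )
        pairs = sharing_mod.adjust_candidates(pairs)
        candidates = sharing_mod.filter_candidates(pairs, cfg.sharing_q_max)
        counts["pairs_enumerated"] = len(pairs)
        counts["candidates"] = len(candidates)
        sharing_mod.write_candidates(candidates, outputs["candidates"])
        written.append(outputs["candidates"])

        stage = "causal"
        ci_cfg = causal_mod.CiTestConfig(alpha=cfg.alpha, max_cond_size=cfg.max_cond_size)
        effects = (
            causal_mod.estimate_pair_effects(x, candidates, ci_cfg)
            if candidates else []
        )
        causal_mod.write_effects(effects, outputs["effects"])
        written.append(outputs["effects"])

        stage = "network"
        net = net_mod.call_edges(
            x, candidates, effects,
            q_max=cfg.edge_q_max,
            effect_min=cfg.effect_min,
            require_positive_r=cfg.require_positive_r,
        )
        counts["edges"] = net.n_edges
        counts["lnc_nodes"] = len(net.lnc_degree)
        counts["mrna_nodes"] = len(net.mrna_degree)
        net_mod.write_edges(net, outputs["edges"])
        written.append(outputs["edges"])

        stage = "hubs"
        hubs = net_mod.select_hubs(net, cfg.hub_fraction) if net.n_edges else None
        if hubs is not None:
            net_mod.write_hubs(hubs, net, outputs["hubs"])
        else:
            outputs["hubs"].write_text("#lnc_id\tdegree\n", encoding="utf-8")
        written.append(outputs["hubs"])
        counts["hubs"] = len(hubs.hubs) if hubs else 0

        stage = "manifest"
        manifest = {
            "version": __version__,
            "config": _config_echo(cfg),
            "inputs": {
                "expression": _sha256(cfg.expression),
                "annotation": _sha256(cfg.annotation),
                "evidence": [_sha256(p) for p in cfg.evidence],
            },
            "counts": counts,
        }
        outputs["manifest"].write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        written.append(outputs["manifest"])
    except PipelineError:
        raise
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc
    return RunResult(
        candidates=candidates,
        effects=effects,
        network=net,
        hubs=hubs,
        manifest=manifest,
        outputs=outputs,
    )
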