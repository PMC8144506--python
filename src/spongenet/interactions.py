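"""miRNA–target interaction evidence.

Validated miRNA–mRNA and miRNA–lncRNA interactions (as integrated from
databases such as miRTarBase, TarBase, NPInter and LncBase) are the evidence
from which candidate sponge pairs are enumerated.  This module reads,
validates, deduplicates and indexes such evidence and exposes the per-gene
miRNA sets and the pooled miRNA universe used by the shared-miRNA
enrichment test.

Identifier matching is exact string equality after trimming leading and
trailing whitespace; no case folding and no miRBase-version harmonization
is attempted (database integration is assumed to have happened upstream).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

TARGET_CLASSES = ("mRNA", "lncRNA")


@dataclass(frozen=True)
class InteractionRecord:
    """One piece of miRNA→target evidence.

    ``target_class`` is ``"mRNA"`` or ``"lncRNA"``; ``source`` is a free-text
    provenance label (database name) that plays no role in identity.
    """

    mirna_id: str
    target_id: str
    target_class: str
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "mirna_id", self.mirna_id.strip())
        object.__setattr__(self, "target_id", self.target_id.strip())
        if not self.mirna_id:
            raise ValueError("mirna_id is empty after trimming")
        if not self.target_id:
            raise ValueError("target_id is empty after trimming")
        if self.target_class not in TARGET_CLASSES:
            raise ValueError(
                f"target_class must be one of {TARGET_CLASSES}, "
                f"got {self.target_class!r}"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.mirna_id, self.target_id, self.target_class)


class InteractionSet:
    """Deduplicated miRNA→target evidence with per-gene indexes.

    Duplicate ``(mirna_id, target_id, target_class)`` triples collapse to the
    first occurrence (its ``source`` is kept).  The same ``(mirna, target)``
    pair annotated with two different target classes is an annotation
    inconsistency and is rejected, because the target class drives candidate
    pair enumeration and must be unambiguous.
    """

    def __init__(self, records: Iterable[InteractionRecord]):
        self._records: list[InteractionRecord] = []
        self._by_key: dict[tuple[str, str, str], InteractionRecord] = {}
        self._mirnas_of: dict[str, set[str]] = {}
        self._targets_of: dict[str, set[str]] = {}
        self._class_of: dict[str, str] = {}
        for rec in records:
            self._add(rec)

    def _add(self, rec: InteractionRecord) -> None:
        if rec.key in self._by_key:
            return
        pair_classes = {
            tc for tc in TARGET_CLASSES
            if (rec.mirna_id, rec.target_id, tc) in self._by_key
        }
        if pair_classes:
            raise ValueError(
                f"conflicting target_class for ({rec.mirna_id}, {rec.target_id}): "
                f"{sorted(pair_classes | {rec.target_class})}"
            )
        known = self._class_of.get(rec.target_id)
        if known is not None and known != rec.target_class:
            raise ValueError(
                f"target {rec.target_id!r} annotated as both {known} "
                f"and {rec.target_class}"
            )
        self._by_key[rec.key] = rec
        self._records.append(rec)
        self._class_of[rec.target_id] = rec.target_class
        self._mirnas_of.setdefault(rec.target_id, set()).add(rec.mirna_id)
        self._targets_of.setdefault(rec.mirna_id, set()).add(rec.target_id)

    @property
    def records(self) -> list[InteractionRecord]:
        return list(self._records)

    def __len__(self) -> int:
        return len(self._records)

    @property
    def mirna_universe(self) -> set[str]:
        """All distinct miRNA ids, pooled over both target classes."""
        return set(self._targets_of)

    def targets_of(self, mirna: str) -> set[str]:
        return set(self._targets_of.get(mirna, set()))

    def mirnas_of(self, target: str) -> set[str]:
        if target not in self._mirnas_of:
            raise KeyError(f"gene {target!r} has no interaction evidence")
        return set(self._mirnas_of[target])

    def has_target(self, target: str) -> bool:
        return target in self._mirnas_of

    def target_class_of(self, target: str) -> str:
        if target not in self._class_of:
            raise KeyError(f"gene {target!r} has no interaction evidence")
        return self._class_of[target]

    def targets_by_class(self, target_class: str) -> set[str]:
        if target_class not in TARGET_CLASSES:
            raise ValueError(f"unknown target_class {target_class!r}")
        return {t for t, c in self._class_of.items() if c == target_class}

    def summary(self) -> dict[str, int]:
        return {
            "n_records": len(self._records),
            "n_mirnas": len(self._targets_of),
            "n_targets": len(self._mirnas_of),
        }


def load_interactions(path: str | Path, target_class: str | None = None) -> InteractionSet:
    """Read a tab-separated interaction file into an :class:`InteractionSet`.

    Dialect: UTF-8, optional ``#``-prefixed header lines, columns
    ``mirna_id, target_id[, target_class[, source]]``.  ``target_class``
    supplies the class for two-column rows and must agree with an explicit
    third column when both are present.  Rows with fewer than two columns
    are skipped with a logged count; a file with no usable rows is an error.
    """
    path = Path(path)
    if target_class is not None and target_class not in TARGET_CLASSES:
        raise ValueError(f"target_class must be one of {TARGET_CLASSES}")
    records: list[InteractionRecord] = []
    n_malformed = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                logger.warning("%s:%d: malformed row skipped", path, lineno)
                n_malformed += 1
                continue
            row_class = fields[2].strip() if len(fields) >= 3 and fields[2].strip() else None
            if row_class is None:
                if target_class is None:
                    logger.warning(
                        "%s:%d: row lacks target_class and no default given; skipped",
                        path, lineno,
                    )
                    n_malformed += 1
                    continue
                row_class = target_class
            elif target_class is not None and row_class != target_class:
                raise ValueError(
                    f"{path}:{lineno}: row target_class {row_class!r} "
                    f"contradicts requested {target_class!r}"
                )
            source = fields[3].strip() if len(fields) >= 4 else ""
            records.append(
                InteractionRecord(fields[0], fields[1], row_class, source)
            )
    if n_malformed:
        logger.info("%s: skipped %d malformed rows", path, n_malformed)
    if not records:
        raise ValueError(f"{path}: no usable interaction evidence")
    return InteractionSet(records)


def merge(*sets: InteractionSet) -> InteractionSet:
    """Union of one or more interaction sets with global deduplication."""
    if not sets:
        raise ValueError("merge requires at least one InteractionSet")
    merged: list[InteractionRecord] = []
    for s in sets:
        merged.extend(s.records)
    return InteractionSet(merged)


def shared_mirnas(s: InteractionSet, lnc: str, mrna: str) -> set[str]:
    """miRNAs with evidence for both a lncRNA and an mRNA (sponge overlap)."""
    missing = [g for g in (lnc, mrna) if not s.has_target(g)]
    if missing:
        side = {lnc: "lncRNA side", mrna: "mRNA side"}
        detail = ", ".join(f"{g!r} ({side[g]})" for g in missing)
        raise KeyError(f"gene(s) without interaction evidence: {detail}")
    return s.mirnas_of(lnc) & s.mirnas_of(mrna)


def write_interactions(s: InteractionSet, path: str | Path) -> None:
    """Write the interaction dialect, deterministically sorted."""
    path = Path(path)
    recs = sorted(s.records, key=lambda r: (r.mirna_id, r.target_id))
    with path.open("w", encoding="utf-8") as fh:
        fh.write("#mirna_id\ttarget_id\ttarget_class\tsource\n")
        for r in recs:
            fh.write(f"{r.mirna_id}\t{r.target_id}\t{r.target_class}\t{r.source}\n")
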