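"""Gene × sample expression matrices and biotype annotation.

Holds the RNA-seq abundance matrix the correlation and causal stages
consume, the low-expression filter (genes whose total across samples falls
below a threshold are removed), the optional log2(v+1) transform, and the
biotype split into lncRNA and mRNA sub-matrices.

Values may be counts, normalized abundances, or already-transformed
(e.g. simulated Gaussian-scale) measurements; non-negativity is only
required when applying the log transform.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

TRANSFORM_MODES = ("log2p1", "none")
BIOTYPES = ("mRNA", "lncRNA")


class ExpressionMatrix:
    """A gene × sample matrix backed by a pandas DataFrame.

    Rows are genes, columns samples; ids must be unique and values finite.
    """

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if values.columns.has_duplicates:
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = values.to_numpy(dtype=float)
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        self.values = values.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        gene_ids = list(gene_ids)
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[gene_ids])

    def row(self, gene_id: str) -> np.ndarray:
        return self.values.loc[gene_id].to_numpy()


class GeneAnnotation:
    """Single-valued gene → biotype map (``mRNA`` or ``lncRNA``)."""

    def __init__(self, biotype_of: dict[str, str]):
        bad = {g: b for g, b in biotype_of.items() if b not in BIOTYPES}
        if bad:
            raise ValueError(f"unknown biotypes: {dict(list(bad.items())[:5])}")
        self.biotype_of = dict(biotype_of)

    def __getitem__(self, gene_id: str) -> str:
        return self.biotype_of[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.biotype_of

    def genes_of(self, biotype: str) -> set[str]:
        if biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {biotype!r}")
        return {g for g, b in self.biotype_of.items() if b == biotype}


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a tab-separated matrix: first column gene id, header of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    return ExpressionMatrix(df)


def write_expression(x: ExpressionMatrix, path: str | Path) -> None:
    df = x.values
    # integer-valued matrices round-trip bit-identically as integers
    if df.size and np.array_equal(df.to_numpy(), np.round(df.to_numpy())):
        df = df.astype(int)
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_annotation(path: str | Path) -> GeneAnnotation:
    """Read a two-column (gene id, biotype) tab-separated annotation."""
    biotype_of: dict[str, str] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            gene, biotype = fields[0], fields[1]
            if gene in biotype_of and biotype_of[gene] != biotype:
                raise ValueError(f"{path}:{lineno}: conflicting biotype for {gene!r}")
            biotype_of[gene] = biotype
    return GeneAnnotation(biotype_of)


def write_annotation(a: GeneAnnotation, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("#gene_id\tbiotype\n")
        for gene in sorted(a.biotype_of):
            fh.write(f"{gene}\t{a.biotype_of[gene]}\n")


def filter_low_expression(x: ExpressionMatrix, min_total: float) -> ExpressionMatrix:
    """Drop genes whose total over all samples is strictly below ``min_total``.

    The boundary is strict: a gene summing exactly to the threshold is kept
    (rows "lower than" the threshold are removed). Gene order is preserved.
    """
    if min_total < 0:
        raise ValueError("min_total must be non-negative")
    totals = x.values.sum(axis=1)
    kept = x.values.loc[totals >= min_total]
    if kept.shape[0] == 0:
        raise ValueError(
            f"min_total={min_total} removes all {x.n_genes} genes"
        )
    return ExpressionMatrix(kept)


def transform(x: ExpressionMatrix, mode: str = "log2p1") -> ExpressionMatrix:
    """Elementwise transform: ``log2p1`` maps v → log2(v+1); ``none`` is identity."""
    if mode not in TRANSFORM_MODES:
        raise ValueError(f"mode must be one of {TRANSFORM_MODES}, got {mode!r}")
    if mode == "none":
        return ExpressionMatrix(x.values.copy())
    arr = x.values.to_numpy()
    if arr.size and arr.min() < 0:
        raise ValueError("log2p1 transform requires non-negative values")
    return ExpressionMatrix(
        pd.DataFrame(np.log2(arr + 1.0), index=x.values.index, columns=x.values.columns)
    )


def split_by_biotype(
    x: ExpressionMatrix, a: GeneAnnotation
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Partition into (lncRNA matrix, mRNA matrix); every gene must be annotated."""
    missing = [g for g in x.gene_ids if g not in a]
    if missing:
        raise ValueError(f"unannotated genes: {missing[:10]}")
    lnc_rows = [g for g in x.gene_ids if a[g] == "lncRNA"]
    mrna_rows = [g for g in x.gene_ids if a[g] == "mRNA"]
    return (
        ExpressionMatrix(x.values.loc[lnc_rows]),
        ExpressionMatrix(x.values.loc[mrna_rows]),
    )
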