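from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spongenet.expression import ExpressionMatrix
from spongenet.interactions import InteractionRecord, InteractionSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_matrix(array, gene_ids=None, sample_ids=None) -> ExpressionMatrix:
    arr = np.asarray(array, dtype=float)
    gene_ids = gene_ids or [f"G{i}" for i in range(arr.shape[0])]
    sample_ids = sample_ids or [f"S{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=gene_ids, columns=sample_ids))


def evidence_from_sets(lnc_mirnas: dict, mrna_mirnas: dict) -> InteractionSet:
    """Build an InteractionSet from per-gene miRNA sets."""
    records = []
    for target_class, table in (("lncRNA", lnc_mirnas), ("mRNA", mrna_mirnas)):
        for gene, mirnas in table.items():
            for m in sorted(mirnas):
                records.append(InteractionRecord(m, gene, target_class, "test"))
    return InteractionSet(records)
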