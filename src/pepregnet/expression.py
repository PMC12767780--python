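"""Group-level expression summaries: TPM, expressing-cell counts, and their correlation.

Expression per tissue (or per finer annotation) is summarized two ways:
TPM on the pooled pseudobulk of the group (counts summed over the
group's cells, scaled to one million; UMI data needs no gene-length
normalization) and TCC, the number of cells in the group expressing the
gene at or above a detection threshold. The relationship between the two
is quantified with the Pearson product-moment correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import UndefinedStatisticError, ValidationError

__all__ = ["TissueExpression", "CorrelationResult", "tissue_expression", "correlate"]


@dataclass
class TissueExpression:
    """Per-group TPM and expressing-cell counts (groups x genes frames)."""

    tpm: pd.DataFrame
    tcc: pd.DataFrame
    n_cells: pd.Series  # cells per group
    group_by: str
    min_count: int


def tissue_expression(m, group_by: str = "tissue", min_count: int = 1,
                      groups=None) -> TissueExpression:
    """Pooled-pseudobulk TPM and TCC per cell group.

    ``group_by`` selects the metadata column defining groups. TPM is
    pooled count x 1e6 / pooled total count per group (rows sum to 1e6
    over all genes of the matrix); TCC is the number of the group's
    cells with count >= ``min_count``. If an explicit ``groups`` list is
    given, a group without cells raises an error naming it.
    """
    if group_by not in m.cell_meta.columns:
        raise ValidationError(f"no metadata column {group_by!r}")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    labels = m.cell_meta[group_by].to_numpy()
    present = pd.unique(labels)
    if groups is None:
        groups = list(present)
    else:
        missing = [g for g in groups if g not in set(present)]
        if missing:
            raise ValidationError(f"empty group(s): {missing}")
    tpm_rows, tcc_rows, sizes = [], [], []
    for g in groups:
        mask = labels == g
        pooled = m.counts[mask].sum(axis=0).astype(float)
        total = pooled.sum()
        if total == 0:
            raise UndefinedStatisticError(f"group {g!r} has zero total counts")
        tpm_rows.append(pooled * 1e6 / total)
        tcc_rows.append((m.counts[mask] >= min_count).sum(axis=0))
        sizes.append(int(mask.sum()))
    tpm = pd.DataFrame(tpm_rows, index=groups, columns=m.gene_ids)
    tcc = pd.DataFrame(tcc_rows, index=groups, columns=m.gene_ids)
    return TissueExpression(tpm=tpm, tcc=tcc,
                            n_cells=pd.Series(sizes, index=groups),
                            group_by=group_by, min_count=min_count)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int

    def summary(self) -> str:
        return f"Pearson R = {self.r:.4f} (n = {self.n})"


def correlate(te: TissueExpression, genes=None, aggregate: bool = False) -> CorrelationResult:
    """Pearson correlation of (TPM, TCC) points.

    By default every (group, gene) pair over the gene subset contributes
    one point; with ``aggregate=True`` the subset is summed per group
    first (one point per group, the per-tissue-totals view).
    """
    tpm, tcc = te.tpm, te.tcc
    if genes is not None:
        genes = list(genes)
        tpm, tcc = tpm[genes], tcc[genes]
    if aggregate:
        x = tpm.sum(axis=1).to_numpy()
        y = tcc.sum(axis=1).to_numpy()
    else:
        x = tpm.to_numpy().ravel()
        y = tcc.to_numpy().ravel()
    if x.size < 3:
        raise UndefinedStatisticError("need >= 3 points for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("correlation undefined: zero variance")
    r = float(sps.pearsonr(x, y).statistic)
    return CorrelationResult(r=r, n=int(x.size))
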