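"""End-to-end network-comparison pipeline over a (synthetic or loaded) dataset.

Chains the stages the receptor-bias analysis needs: class-stratified
TF→target importance inference (co-expression is inferred within the
cell population annotated as expressing the class, mirroring
tissue-stratified regulon pipelines), motif pruning into regulons,
regulon activity scoring, exclusive-cell selection, per-class network
construction and the NP-vs-NPR complexity comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import networks
from .io import load_panel
from .regulons import RegulonActivity, build_regulons, genie3_importance, score_regulons
from .synthetic import SyntheticDataset

__all__ = ["NetworkComparisonResult", "class_importance", "run_network_comparison"]


def class_importance(
    matrix,
    tfs,
    panel,
    n_trees: int = 200,
    seed: int = 0,
    program_column: str = "program",
) -> pd.DataFrame:
    """TF→target importance, inferred within each class's cell population.

    NP-gene targets are regressed on TF expression over the cells
    annotated as NP-cells and receptor targets over the NPR-cells, so
    the co-expression signal is not diluted by cells in which the target
    is silent. Falls back to all cells when the annotation column is
    absent.
    """
    meta = matrix.cell_meta
    parts = []
    for cls_genes, program in ((panel.np_genes, "np_cells"),
                               (panel.npr_genes, "npr_cells")):
        targets = [g for g in cls_genes if g in set(matrix.gene_ids)]
        if not targets:
            continue
        if program_column in meta.columns:
            cells = matrix.cell_ids[(meta[program_column] == program).to_numpy()]
            sub = matrix.subset_cells(cells)
        else:
            sub = matrix
        parts.append(genie3_importance(sub, tfs, targets, n_trees=n_trees, seed=seed))
    return pd.concat(parts, ignore_index=True)


@dataclass
class NetworkComparisonResult:
    importance: pd.DataFrame
    regulons: list
    activity: RegulonActivity
    np_cells: np.ndarray
    npr_cells: np.ndarray
    net_np: networks.TFGeneNetwork
    net_npr: networks.TFGeneNetwork
    comparison: networks.GroupComparison | None
    summary: pd.DataFrame

    @property
    def npr_bias(self) -> bool:
        """Does the receptor network involve more TFs than the NP network?"""
        return self.net_npr.stats().n_tfs > self.net_np.stats().n_tfs


def run_network_comparison(
    ds: SyntheticDataset,
    panel=None,
    n_trees: int = 200,
    top_k_per_tf: int = 50,
    top_fraction: float = 0.05,
    n_null: int = 100,
    min_count: int = 1,
    seed: int = 0,
) -> NetworkComparisonResult:
    """Simulated dataset → regulons → exclusive cells → class networks → comparison."""
    if panel is None:
        panel = ds.config.panel if ds.config.panel is not None else load_panel()
    m = ds.matrix
    imp = class_importance(m, ds.tf_genes, panel, n_trees=n_trees, seed=seed)
    regs = build_regulons(imp, ds.motif_support, top_k_per_tf=top_k_per_tf)
    activity = score_regulons(m, regs, top_fraction=top_fraction,
                              n_null=n_null, seed=seed)
    np_cells, npr_cells = networks.select_exclusive_cells(
        m, panel.np_genes, panel.npr_genes, min_count=min_count
    )
    net_np = networks.build_class_network(
        regs, activity, np_cells, panel.np_genes, class_label="NP"
    )
    net_npr = networks.build_class_network(
        regs, activity, npr_cells, panel.npr_genes, class_label="NPR"
    )
    results, summary = networks.compare_tissue_networks(
        {("all", "NP"): net_np, ("all", "NPR"): net_npr}, seed=seed
    )
    return NetworkComparisonResult(
        importance=imp, regulons=regs, activity=activity,
        np_cells=np_cells, npr_cells=npr_cells,
        net_np=net_np, net_npr=net_npr,
        comparison=results.get("all"), summary=summary,
    )
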