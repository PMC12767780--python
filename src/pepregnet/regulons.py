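"""Desk-scale regulon machinery.

This module implements the SCENIC-style chain on small matrices:

1. ``genie3_importance`` — tree-ensemble regression of each target gene on
   transcription-factor expression; the per-TF share of impurity reduction
   is the regulatory importance of the TF→target pair.
2. ``build_regulons`` — keep each TF's top-k targets by importance and
   prune targets without motif support, yielding one regulon per
   (TF, motif) with supported targets.
3. ``aucell_score`` — per-cell rank-AUC activity of a regulon's target set
   within the top-ranked fraction of genes.
4. ``binarize_activity`` — call a regulon active in a cell when its AUC
   exceeds a quantile of size-matched random gene-set AUCs.

All randomness is driven by explicit seeds; rank ties are broken by the
stable gene order of the matrix so results are bit-reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "Regulon",
    "RegulonActivity",
    "genie3_importance",
    "build_regulons",
    "aucell_score",
    "binarize_activity",
    "score_regulons",
]


@dataclass(frozen=True)
class Regulon:
    """A transcription factor with its motif-supported target set."""

    tf: str
    targets: frozenset
    motif_id: str
    context: str = "all"

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", frozenset(self.targets))
        if not self.targets:
            raise ValueError(f"regulon for {self.tf} has no targets")
        if self.tf in self.targets:
            raise ValueError(f"regulon for {self.tf} contains its own TF as target")

    @property
    def name(self) -> str:
        return f"{self.tf}({self.motif_id})"


def _expression_design(m, transform: str) -> np.ndarray:
    counts = m.counts.astype(float)
    if transform == "log1p":
        return np.log1p(counts)
    if transform == "depth_log1p":
        depth = counts.sum(axis=1, keepdims=True)
        depth[depth == 0] = 1.0
        return np.log1p(counts / depth * 1e4)
    raise ValueError(f"unknown transform {transform!r}")


def genie3_importance(
    m,
    tfs,
    targets,
    n_trees: int = 200,
    seed: int = 0,
    transform: str = "log1p",
    age_days=None,
    cell_type=None,
) -> pd.DataFrame:
    """Tree-ensemble TF→target importance table.

    For every target gene a random-forest regression of its (log1p)
    expression on all TF expressions is fitted; the importance of a
    TF→target pair is the TF's share of total impurity reduction,
    normalized to sum to one over TFs per target. A TF that is itself
    the target is excluded from that target's candidate set. Targets
    with constant expression yield all-zero importances (with a warning).

    Returns a tidy table (tf, target, importance) plus optional constant
    ``age_days`` / ``cell_type`` labels.
    """
    tfs = list(tfs)
    targets = list(targets)
    if m.n_cells < 20:
        raise ValueError(f"need >= 20 cells, got {m.n_cells}")
    if len(tfs) < 2:
        raise ValueError("need at least 2 candidate TFs")
    X = _expression_design(m, transform)
    tf_idx = m.gene_index(tfs)
    records = []
    rng = np.random.default_rng(seed)
    for target in targets:
        cand = [(t, i) for t, i in zip(tfs, tf_idx) if t != target]
        if len(cand) < 2:
            raise ValueError(f"fewer than 2 candidate TFs for target {target!r}")
        cand_tfs = [t for t, _ in cand]
        cand_cols = np.array([i for _, i in cand])
        y = X[:, m.gene_index([target])[0]]
        if np.all(y == y[0]):
            warnings.warn(f"target {target!r} has constant expression; "
                          f"importances set to zero", UserWarning, stacklevel=2)
            imp = np.zeros(len(cand))
        else:
            rf = RandomForestRegressor(
                n_estimators=n_trees,
                max_features=1.0,  # all TFs considered at every split
                random_state=int(rng.integers(0, 2**31 - 1)),
                n_jobs=1,
            )
            rf.fit(X[:, cand_cols], y)
            imp = rf.feature_importances_  # sums to 1 when any split occurred
        for tf, v in zip(cand_tfs, imp):
            records.append((tf, target, float(v)))
    out = pd.DataFrame(records, columns=["tf", "target", "importance"])
    if age_days is not None:
        out["age_days"] = age_days
    if cell_type is not None:
        out["cell_type"] = cell_type
    return out


def build_regulons(
    imp: pd.DataFrame,
    motifs: pd.DataFrame,
    top_k_per_tf: int = 50,
    context: str = "all",
) -> list[Regulon]:
    """Prune an importance table into motif-supported regulons.

    Per TF the top ``top_k_per_tf`` targets by importance are kept (ties
    broken toward the lexicographically smaller gene), then targets
    lacking (tf, gene) motif support are dropped. TFs missing from the
    motif table, and regulons left empty, are silently removed.
    """
    if imp.empty:
        raise ValueError("importance table is empty")
    support: dict[tuple[str, str], str] = {}
    for tf, motif_id, gene in motifs[["tf", "motif_id", "gene"]].itertuples(index=False):
        support[(tf, gene)] = motif_id
    regulons: list[Regulon] = []
    for tf, grp in imp.groupby("tf", sort=True):
        ranked = grp.sort_values(["importance", "target"],
                                 ascending=[False, True], kind="stable")
        top = ranked.head(top_k_per_tf)
        by_motif: dict[str, set] = {}
        for target in top["target"]:
            motif = support.get((tf, target))
            if motif is not None:
                by_motif.setdefault(motif, set()).add(target)
        for motif_id, targets in sorted(by_motif.items()):
            regulons.append(Regulon(tf=tf, targets=frozenset(targets),
                                    motif_id=motif_id, context=context))
    return regulons


# ---------------------------------------------------------------------------
# AUCell-style activity


def _rank_matrix(m) -> np.ndarray:
    """Per-cell 1-based gene ranks by decreasing count, ties by gene order."""
    # argsort on (-counts) is stable, so equal counts keep matrix gene order
    order = np.argsort(-m.counts, axis=1, kind="stable")
    ranks = np.empty_like(order)
    n_genes = m.n_genes
    cols = np.arange(1, n_genes + 1)
    rows = np.arange(m.n_cells)[:, None]
    ranks[rows, order] = cols
    return ranks


def _auc_from_ranks(ranks: np.ndarray, target_cols: np.ndarray,
                    top_fraction: float) -> np.ndarray:
    n_genes = ranks.shape[1]
    T = math.ceil(top_fraction * n_genes)
    mm = target_cols.size
    r = ranks[:, target_cols]  # cells x m target ranks
    inside = r <= T
    # sum over i=1..T of y(i), where y(i) = #targets with rank <= i
    num = np.where(inside, T - r + 1, 0).sum(axis=1)
    denom = sum(min(i, mm) for i in range(1, T + 1))
    return num / denom


def aucell_score(m, regulon: Regulon, top_fraction: float = 0.05) -> np.ndarray:
    """Per-cell rank-AUC of the regulon's targets within the top fraction.

    Genes are ranked per cell by decreasing count (ties by stable gene
    order). With T = ceil(top_fraction * n_genes) and recovery curve
    y(i) = number of targets at rank <= i, the score is
    sum_{i=1..T} y(i) / sum_{i=1..T} min(i, m), which is 1 when all m
    targets occupy the top m ranks and 0 when none enter the top T.
    """
    if not (0 < top_fraction <= 1):
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    present = sorted(set(regulon.targets) & set(m.gene_ids))
    if not present:
        raise ValueError(f"no targets of regulon {regulon.name} in the matrix")
    ranks = _rank_matrix(m)
    return _auc_from_ranks(ranks, m.gene_index(present), top_fraction)


def binarize_activity(
    auc: np.ndarray,
    m,
    regulon: Regulon,
    n_null: int = 200,
    quantile: float = 0.99,
    seed: int = 0,
    top_fraction: float = 0.05,
) -> tuple[np.ndarray, float]:
    """Threshold AUC scores against a size-matched random-gene-set null.

    ``n_null`` random gene sets of the regulon's (matrix-restricted) size
    are scored on the same cells; the threshold is the ``quantile`` of
    the pooled null AUC values and a cell is active iff auc > threshold.
    """
    if n_null < 20:
        raise ValueError(f"n_null must be >= 20, got {n_null}")
    present = sorted(set(regulon.targets) & set(m.gene_ids))
    size = len(present)
    if size == 0 or size > m.n_genes:
        raise ValueError("regulon size incompatible with the gene universe")
    rng = np.random.default_rng(seed)
    ranks = _rank_matrix(m)
    null = np.empty((n_null, m.n_cells))
    for i in range(n_null):
        cols = rng.choice(m.n_genes, size=size, replace=False)
        null[i] = _auc_from_ranks(ranks, cols, top_fraction)
    threshold = float(np.quantile(null.ravel(), quantile))
    return auc > threshold, threshold


@dataclass
class RegulonActivity:
    """AUC and binarized activity of a set of regulons over a matrix."""

    regulons: list[Regulon]
    cell_ids: np.ndarray
    auc: np.ndarray  # cells x regulons
    active: np.ndarray  # cells x regulons bool
    thresholds: np.ndarray  # per regulon
    top_fraction: float

    def auc_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.auc, index=self.cell_ids,
                            columns=[r.name for r in self.regulons])

    def active_in(self, cell_ids) -> np.ndarray:
        """Number of the given cells in which each regulon is active."""
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        try:
            idx = np.array([lookup[c] for c in cell_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"cell {e.args[0]!r} not covered by activity") from None
        if idx.size == 0:
            return np.zeros(len(self.regulons), dtype=int)
        return self.active[idx].sum(axis=0)


def score_regulons(
    m,
    regulons: list[Regulon],
    top_fraction: float = 0.05,
    n_null: int = 200,
    quantile: float = 0.99,
    seed: int = 0,
) -> RegulonActivity:
    """AUCell-score and binarize a list of regulons on one matrix.

    The per-cell rank matrix is computed once and shared by all regulons
    and all null sets, so scoring many regulons stays cheap.
    """
    ranks = _rank_matrix(m)
    n_r = len(regulons)
    auc = np.empty((m.n_cells, n_r))
    active = np.empty((m.n_cells, n_r), dtype=bool)
    thresholds = np.empty(n_r)
    rng = np.random.default_rng(seed)
    null_cache: dict[int, float] = {}
    for j, reg in enumerate(regulons):
        present = sorted(set(reg.targets) & set(m.gene_ids))
        if not present:
            raise ValueError(f"no targets of regulon {reg.name} in the matrix")
        cols = m.gene_index(present)
        auc[:, j] = _auc_from_ranks(ranks, cols, top_fraction)
        size = len(present)
        if size not in null_cache:
            null = np.empty((n_null, m.n_cells))
            for i in range(n_null):
                rnd = rng.choice(m.n_genes, size=size, replace=False)
                null[i] = _auc_from_ranks(ranks, rnd, top_fraction)
            null_cache[size] = float(np.quantile(null.ravel(), quantile))
        thresholds[j] = null_cache[size]
        active[:, j] = auc[:, j] > thresholds[j]
    return RegulonActivity(regulons=regulons, cell_ids=m.cell_ids, auc=auc,
                           active=active, thresholds=thresholds,
                           top_fraction=top_fraction)
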