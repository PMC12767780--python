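"""TF-NP and TF-NPR network construction and complexity comparison.

Cells are first split into class-exclusive populations (cells expressing
neuropeptides but no receptor of the panel, and vice versa — co-expressing
cells are excluded to sharpen the contrast). A bipartite TF→gene network
is then built per class from the regulons active in those cells, shared
TFs can be removed, TF→TF cascades are counted, and network complexity
(per-gene TF in-degree) is compared between classes per tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regulons import Regulon, RegulonActivity
from .stats import EstimationResult, TestResult, estimation_stats, route_and_test

__all__ = [
    "TFGeneNetwork",
    "NetworkStats",
    "select_exclusive_cells",
    "build_class_network",
    "remove_shared_tfs",
    "cascade_counts",
    "compare_tissue_networks",
    "GroupComparison",
]


@dataclass
class TFGeneNetwork:
    """Bipartite TF→gene network for one gene class and cell group."""

    class_label: str  # "NP" | "NPR"
    group: str  # tissue / annotation label or "all"
    edges: set  # {(tf, gene)}
    tf_set: set = field(default_factory=set)
    gene_set: set = field(default_factory=set)
    regulons: list = field(default_factory=list)  # regulons contributing edges
    panel_genes: set = field(default_factory=set)  # full class panel (for 0-degrees)

    def __post_init__(self) -> None:
        if not self.tf_set and self.edges:
            self.tf_set = {tf for tf, _ in self.edges}
        if not self.gene_set and self.edges:
            self.gene_set = {g for _, g in self.edges}

    def in_degrees(self) -> pd.Series:
        """Number of regulating TFs per panel gene (0 for unregulated genes)."""
        deg = {g: 0 for g in self.panel_genes | self.gene_set}
        for _, g in self.edges:
            deg[g] += 1
        return pd.Series(deg, dtype=int).sort_index()

    def stats(self) -> "NetworkStats":
        n_cascade = sum(
            1
            for t in self.tf_set
            if any(t in r.targets and r.tf in self.tf_set and r.tf != t
                   for r in self.regulons)
        )
        return NetworkStats(
            n_tfs=len(self.tf_set),
            n_nodes=len(self.tf_set | self.gene_set),
            n_edges=len(self.edges),
            n_cascade_tfs=n_cascade,
        )


@dataclass(frozen=True)
class NetworkStats:
    n_tfs: int
    n_nodes: int
    n_edges: int
    n_cascade_tfs: int


def select_exclusive_cells(m, np_genes, npr_genes, min_count: int = 1):
    """Split cells into NP-exclusive and NPR-exclusive populations.

    A cell is NP-exclusive when at least one panel neuropeptide reaches
    ``min_count`` and every panel receptor stays below it; NPR-exclusive
    symmetrically. Cells expressing both classes (or neither) fall in
    neither set, so the two populations are disjoint by construction.
    """
    np_genes = [g for g in np_genes if g in set(m.gene_ids)]
    npr_genes = [g for g in npr_genes if g in set(m.gene_ids)]
    if not np_genes or not npr_genes:
        raise ValueError("both gene panels must be non-empty and present in the matrix")
    np_expr = (m.counts[:, m.gene_index(np_genes)] >= min_count).any(axis=1)
    npr_expr = (m.counts[:, m.gene_index(npr_genes)] >= min_count).any(axis=1)
    np_cells = m.cell_ids[np_expr & ~npr_expr]
    npr_cells = m.cell_ids[npr_expr & ~np_expr]
    return np_cells, npr_cells


def build_class_network(
    regulons: list[Regulon],
    activity: RegulonActivity,
    cells,
    class_genes,
    group: str = "all",
    class_label: str = "NP",
    min_active_cells: int = 1,
) -> TFGeneNetwork:
    """Build the TF→gene network of a gene class from active regulons.

    The edge (tf, g) is included iff g is a panel gene of the class, g is
    in tf's regulon, and the regulon is active in at least
    ``min_active_cells`` of the given cells.
    """
    class_genes = set(class_genes)
    n_active = activity.active_in(cells)  # raises on unknown cells
    act_by_name = {r.name: n for r, n in zip(activity.regulons, n_active)}
    edges = set()
    contributing = []
    for r in regulons:
        n = act_by_name.get(r.name)
        if n is None:
            raise ValueError(f"regulon {r.name} not covered by the activity object")
        if n < min_active_cells:
            continue
        hit = r.targets & class_genes
        if hit:
            contributing.append(r)
            edges |= {(r.tf, g) for g in hit}
    return TFGeneNetwork(class_label=class_label, group=group, edges=edges,
                         regulons=contributing, panel_genes=class_genes)


def remove_shared_tfs(a: TFGeneNetwork, b: TFGeneNetwork):
    """Drop TFs present in both networks (and their edges) from each.

    Returns the two pruned networks and the shared TF set. Idempotent:
    applying it twice changes nothing.
    """
    if a.group != b.group:
        raise ValueError(f"group mismatch: {a.group!r} vs {b.group!r}")
    shared = a.tf_set & b.tf_set

    def prune(net: TFGeneNetwork) -> TFGeneNetwork:
        edges = {(tf, g) for tf, g in net.edges if tf not in shared}
        regs = [r for r in net.regulons if r.tf not in shared]
        return TFGeneNetwork(class_label=net.class_label, group=net.group,
                             edges=edges, regulons=regs,
                             panel_genes=net.panel_genes)

    return prune(a), prune(b), shared


def cascade_counts(regulons: list[Regulon], tf_set, group_by: str = "motif") -> dict:
    """Count TFs that are themselves targets of other TFs' regulons.

    A TF t is counted (once per covering regulon) when some regulon r
    with r.tf in ``tf_set`` other than t contains t among its targets;
    counts are keyed by the regulon's motif or tissue context.
    """
    if group_by not in ("motif", "tissue"):
        raise ValueError("group_by must be 'motif' or 'tissue'")
    tf_set = set(tf_set)
    counts: dict[str, int] = {}
    for r in regulons:
        if r.tf not in tf_set:
            continue
        regulated_tfs = {t for t in r.targets if t in tf_set and t != r.tf}
        if regulated_tfs:
            key = r.motif_id if group_by == "motif" else r.context
            counts[key] = counts.get(key, 0) + len(regulated_tfs)
    return counts


@dataclass
class GroupComparison:
    """Per-group NP-vs-NPR comparison of per-gene TF in-degree."""

    group: str
    np_in_degrees: np.ndarray
    npr_in_degrees: np.ndarray
    test: TestResult
    estimation: EstimationResult | None

    @property
    def dbm(self) -> float:
        return float(np.mean(self.npr_in_degrees) - np.mean(self.np_in_degrees))


def compare_tissue_networks(networks: dict, seed: int = 0):
    """Compare NP vs NPR network complexity per group.

    ``networks`` maps (group, class_label) to a TFGeneNetwork. The unit
    of replication is the per-gene TF in-degree. Groups with fewer than
    2 observations in either class are skipped with a warning. Returns
    (per-group GroupComparison dict, cross-group summary DataFrame).
    """
    groups = sorted({g for g, _ in networks})
    results: dict[str, GroupComparison] = {}
    rows = []
    for group in groups:
        a = networks.get((group, "NP"))
        b = networks.get((group, "NPR"))
        if a is None or b is None:
            warnings.warn(f"group {group!r}: missing one class; skipped",
                          UserWarning, stacklevel=2)
            continue
        deg_np = a.in_degrees().to_numpy()
        deg_npr = b.in_degrees().to_numpy()
        if len(deg_np) < 2 or len(deg_npr) < 2:
            warnings.warn(
                f"group {group!r}: fewer than 2 genes per class; skipped",
                UserWarning, stacklevel=2,
            )
            continue
        if len(deg_np) < 3 or len(deg_npr) < 3:
            warnings.warn(
                f"group {group!r}: fewer than 3 genes per class; "
                f"test unavailable, reporting stats only", UserWarning, stacklevel=2,
            )
            continue
        test = route_and_test(deg_np, deg_npr)
        est = None if test.degenerate else estimation_stats(deg_np, deg_npr, seed=seed)
        gc = GroupComparison(group=group, np_in_degrees=deg_np,
                             npr_in_degrees=deg_npr, test=test, estimation=est)
        results[group] = gc
        rows.append({
            "group": group,
            "np_n_tfs": a.stats().n_tfs,
            "npr_n_tfs": b.stats().n_tfs,
            "np_mean_in_degree": float(np.mean(deg_np)),
            "npr_mean_in_degree": float(np.mean(deg_npr)),
            "dbm": gc.dbm,
            "p": test.p,
            "method": test.method,
            "significance": test.significance_label,
        })
    summary = pd.DataFrame(rows)
    return results, summary
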