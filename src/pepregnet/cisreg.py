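"""Per-gene cis-regulatory feature summaries and NP-vs-NPR class comparison.

The regulatory annotation is a table of genomic intervals per gene, of
three kinds: TFBS hotspot areas (high-occupancy ChIP regions), curated
cis-regulatory modules, and generic ChIP peaks. For each (gene, kind) we
summarize the element count, the total span in kilobases and the mean
element length; the two gene classes are then compared feature-wise in
paired (one observation per NP-NPR pairing) or unpaired (one observation
per unique gene) mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ANNOTATION_KINDS, GenePanel
from .stats import EstimationResult, TestResult, estimation_stats, route_and_test

__all__ = ["summarize_features", "compare_classes", "ComparisonResult"]

FEATURES = ("count", "total_kb", "mean_kb")


def _merge_intervals(group: pd.DataFrame) -> float:
    """Total bp covered after merging overlaps."""
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(zip(group["start"], group["end"])):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def summarize_features(
    ann: pd.DataFrame,
    genes=None,
    merge_overlaps: bool = False,
) -> pd.DataFrame:
    """Count / total-kb / mean-kb per (gene, kind).

    Overlapping elements are summed as listed by default (each annotated
    element contributes its own length); ``merge_overlaps=True`` collapses
    overlaps before measuring the total. When a gene universe ``genes``
    is given, absent (gene, kind) combinations are reported with count 0,
    total 0 and missing mean.
    """
    if (ann["end"] <= ann["start"]).any():
        raise ValidationError("intervals must satisfy end > start")
    bad = set(ann["kind"]) - set(ANNOTATION_KINDS)
    if bad:
        raise ValidationError(f"unknown annotation kind(s): {sorted(bad)}")
    rows = []
    for (gene, kind), grp in ann.groupby(["gene", "kind"], sort=True):
        count = len(grp)
        if merge_overlaps:
            total_bp = _merge_intervals(grp)
        else:
            total_bp = float((grp["end"] - grp["start"]).sum())
        total_kb = total_bp / 1000.0
        rows.append((gene, kind, count, total_kb,
                     total_kb / count if count else np.nan))
    summary = pd.DataFrame(rows, columns=["gene", "kind", "count", "total_kb",
                                          "mean_kb"])
    if genes is not None:
        full = pd.MultiIndex.from_product([list(genes), list(ANNOTATION_KINDS)],
                                          names=["gene", "kind"])
        summary = (summary.set_index(["gene", "kind"])
                   .reindex(full)
                   .reset_index())
        summary["count"] = summary["count"].fillna(0).astype(int)
        summary["total_kb"] = summary["total_kb"].fillna(0.0)
    return summary


@dataclass
class ComparisonResult:
    """NP-vs-NPR comparison of one regulatory feature."""

    kind: str
    feature: str
    mode: str
    np_values: np.ndarray
    npr_values: np.ndarray
    dbm: float  # mean(NPR) - mean(NP)
    test: TestResult
    estimation: EstimationResult | None

    @property
    def degenerate(self) -> bool:
        return self.test.degenerate

    def summary(self) -> str:
        return (
            f"{self.kind}/{self.feature} ({self.mode}): "
            f"NP n={len(self.np_values)} mean={np.mean(self.np_values):.3g}, "
            f"NPR n={len(self.npr_values)} mean={np.mean(self.npr_values):.3g}, "
            f"DBM={self.dbm:.3g}; {self.test.summary()}"
        )


def _feature_lookup(summary: pd.DataFrame, kind: str) -> dict:
    sub = summary[summary["kind"] == kind]
    return {g: row for g, row in zip(sub["gene"], sub.itertuples(index=False))}


def _value(row, gene: str, feature: str) -> float:
    if row is None:  # gene absent from the annotation: count 0
        return 0.0 if feature in ("count", "total_kb") else np.nan
    return float(getattr(row, feature))


def compare_classes(
    summary: pd.DataFrame,
    panel: GenePanel,
    kind: str,
    feature: str = "count",
    mode: str = "unpaired",
    collapse_unique: bool = False,
    seed: int = 0,
) -> ComparisonResult:
    """Compare a regulatory feature between NP and NPR genes.

    Paired mode pairs genes by pair-table row, so genes appearing in
    several pairings contribute once per row (``collapse_unique=True``
    collapses to unique panel genes instead). Genes with undefined mean
    length (no elements) are dropped from mean_kb comparisons and kept
    as zero for count / total_kb.
    """
    if feature not in FEATURES:
        raise ValueError(f"feature must be one of {FEATURES}")
    if mode not in ("paired", "unpaired"):
        raise ValueError(f"mode must be 'paired' or 'unpaired', got {mode!r}")
    lookup = _feature_lookup(summary, kind)

    if mode == "paired" and not collapse_unique:
        np_vals, npr_vals = [], []
        for i, row in enumerate(panel.pairs.itertuples(index=False), start=1):
            for sym in (row.np_symbol, row.npr_symbol):
                if sym not in set(summary["gene"]):
                    raise ValidationError(
                        f"paired mode: pair-table row {i} member {sym!r} "
                        f"is not summarized"
                    )
            np_vals.append(_value(lookup.get(row.np_symbol), row.np_symbol, feature))
            npr_vals.append(_value(lookup.get(row.npr_symbol), row.npr_symbol, feature))
        np_vals, npr_vals = np.array(np_vals), np.array(npr_vals)
        if feature == "mean_kb":
            keep = ~(np.isnan(np_vals) | np.isnan(npr_vals))
            np_vals, npr_vals = np_vals[keep], npr_vals[keep]
        paired = True
    else:
        np_genes = sorted(set(panel.pairs["np_symbol"]))
        npr_genes = sorted(set(panel.pairs["npr_symbol"]))
        if mode == "paired":  # collapsed paired mode degenerates to unique genes
            paired = False
        else:
            paired = False
        np_vals = np.array([_value(lookup.get(g), g, feature) for g in np_genes])
        npr_vals = np.array([_value(lookup.get(g), g, feature) for g in npr_genes])
        if feature == "mean_kb":
            np_vals = np_vals[~np.isnan(np_vals)]
            npr_vals = npr_vals[~np.isnan(npr_vals)]

    test = route_and_test(np_vals, npr_vals, paired=paired)
    dbm = float(np.mean(npr_vals) - np.mean(np_vals))
    est = None
    if not test.degenerate:
        est = estimation_stats(np_vals, npr_vals, paired=paired, seed=seed)
    return ComparisonResult(kind=kind, feature=feature, mode=mode,
                            np_values=np_vals, npr_values=npr_vals,
                            dbm=dbm, test=test, estimation=est)
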