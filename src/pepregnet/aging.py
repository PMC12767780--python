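"""Age-stratified comparison of TF-gene pair importance.

Two protocols from the aging analysis:

* per-class top-k (default k = 50): per age (and optionally per cell
  type), TF-NP and TF-NPR pairs are each ranked by importance and the
  two top-k importance vectors are compared;
* pooled top-k (default k = 100): one joint ranking over both classes,
  reporting each class's membership count within the top k alongside the
  class mean importances.

Rankings are total orders: ties are broken lexicographically on
(tf, target), so results are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import TestResult, route_and_test

__all__ = [
    "TopKComparison",
    "PooledTopK",
    "topk_importance_compare",
    "pooled_topk",
    "regulon_age_profile",
]


@dataclass
class TopKComparison:
    age_days: float
    cell_type: str
    k: int
    mean_np: float
    mean_npr: float
    n_np: int
    n_npr: int
    test: TestResult | None

    @property
    def npr_minus_np(self) -> float:
        return self.mean_npr - self.mean_np


@dataclass
class PooledTopK:
    age_days: float
    cell_type: str
    k: int
    n_np: int  # NP-class pairs within the pooled top k
    n_npr: int
    mean_np: float  # mean importance of the class members within top k
    mean_npr: float
    test: TestResult | None


def _classify(imp: pd.DataFrame, panel) -> pd.DataFrame:
    np_set, npr_set = set(panel.np_genes), set(panel.npr_genes)
    cls = imp["target"].map(
        lambda g: "NP" if g in np_set else ("NPR" if g in npr_set else None)
    )
    out = imp.assign(gene_class=cls)
    return out[out["gene_class"].notna()]


def _ranked(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["importance", "tf", "target"],
                          ascending=[False, True, True], kind="stable")


def _topk_class(df: pd.DataFrame, k: int, label: str) -> pd.DataFrame:
    if len(df) < k:
        warnings.warn(f"{label}: only {len(df)} pairs available for k={k}; "
                      f"using all", UserWarning, stacklevel=3)
        k = len(df)
    return _ranked(df).head(k)


def topk_importance_compare(
    imp: pd.DataFrame,
    panel,
    k: int = 50,
    stratify: str | None = None,
) -> list[TopKComparison]:
    """Per-age comparison of top-k TF-NP vs TF-NPR pair importances.

    ``stratify`` restricts the table to one cell type first. Pairs whose
    target is not a panel gene are ignored. Returns one comparison per
    age, in increasing age order.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if "age_days" not in imp.columns:
        raise ValueError("importance table lacks an age_days column")
    if stratify is not None:
        imp = imp[imp["cell_type"] == stratify]
        if imp.empty:
            raise ValueError(f"no records for cell type {stratify!r}")
    imp = _classify(imp, panel)
    out = []
    for age in sorted(imp["age_days"].unique()):
        sub = imp[imp["age_days"] == age]
        top_np = _topk_class(sub[sub["gene_class"] == "NP"], k, f"age {age} NP")
        top_npr = _topk_class(sub[sub["gene_class"] == "NPR"], k, f"age {age} NPR")
        a = top_np["importance"].to_numpy()
        b = top_npr["importance"].to_numpy()
        test = route_and_test(a, b) if min(a.size, b.size) >= 3 else None
        out.append(TopKComparison(
            age_days=age, cell_type=stratify or "all", k=k,
            mean_np=float(a.mean()), mean_npr=float(b.mean()),
            n_np=a.size, n_npr=b.size, test=test,
        ))
    return out


def pooled_topk(
    imp: pd.DataFrame,
    panel,
    k: int = 100,
    stratify: str | None = None,
) -> list[PooledTopK]:
    """Per-age pooled ranking over both classes with top-k membership counts."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if "age_days" not in imp.columns:
        raise ValueError("importance table lacks an age_days column")
    if stratify is not None:
        imp = imp[imp["cell_type"] == stratify]
        if imp.empty:
            raise ValueError(f"no records for cell type {stratify!r}")
    imp = _classify(imp, panel)
    out = []
    for age in sorted(imp["age_days"].unique()):
        sub = imp[imp["age_days"] == age]
        top = _topk_class(sub, k, f"age {age} pooled")
        np_part = top[top["gene_class"] == "NP"]["importance"].to_numpy()
        npr_part = top[top["gene_class"] == "NPR"]["importance"].to_numpy()
        test = (route_and_test(np_part, npr_part)
                if min(np_part.size, npr_part.size) >= 3 else None)
        out.append(PooledTopK(
            age_days=age, cell_type=stratify or "all", k=k,
            n_np=np_part.size, n_npr=npr_part.size,
            mean_np=float(np_part.mean()) if np_part.size else float("nan"),
            mean_npr=float(npr_part.mean()) if npr_part.size else float("nan"),
            test=test,
        ))
    return out


def regulon_age_profile(auc: pd.DataFrame, cell_ages, ages) -> pd.DataFrame:
    """Mean regulon activity per age: regulons x ages matrix.

    ``auc`` is a cells x regulons frame, ``cell_ages`` the per-cell age
    labels aligned with its rows. Every requested age must be present,
    otherwise an error names the missing one. Row (regulon) order is the
    column order of ``auc``.
    """
    cell_ages = np.asarray(cell_ages)
    if cell_ages.size != len(auc):
        raise ValueError("cell_ages must align with auc rows")
    cols = {}
    for age in ages:
        mask = cell_ages == age
        if not mask.any():
            raise ValueError(f"no cells with age {age!r}")
        cols[age] = auc.loc[mask].mean(axis=0)
    return pd.DataFrame(cols)
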