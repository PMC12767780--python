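"""Relative qPCR quantification by the 2^-ddCt method.

Threshold-cycle (Ct) replicates are normalized against a reference
housekeeping gene (dCt = Ct_target - Ct_reference, replicates matched by
id), then against the control condition of the same (sex, age,
tissue-part) stratum (ddCt = dCt - mean control dCt). The fold change of
each replicate is 2^-ddCt, assuming perfect doubling per cycle; results
are reported as mean +- SEM over replicates. ``contrast_panel`` runs the
quantification over a gene panel and summarizes, per gene class, how
often expression responds significantly to the condition shifts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .stats import route_and_test

__all__ = ["RelExpression", "relative_expression", "contrast_panel",
           "ContrastPanelResult"]

STRATA = ["sex", "age_days", "tissue_part"]


@dataclass
class RelExpression:
    """Per-condition fold changes of one target gene."""

    gene: str
    reference_gene: str
    control_temperature: float
    table: pd.DataFrame  # sex, age_days, tissue_part, temperature_c,
    #                      fold, sem, n_reps
    replicate_folds: pd.DataFrame  # one row per replicate with its fold

    def fold(self, sex, age_days, tissue_part, temperature_c) -> float:
        t = self.table
        row = t[(t["sex"] == sex) & (t["age_days"] == age_days)
                & (t["tissue_part"] == tissue_part)
                & (t["temperature_c"] == temperature_c)]
        if row.empty:
            raise KeyError("condition not present")
        return float(row["fold"].iloc[0])


def _delta_ct(ct: pd.DataFrame, target_gene: str, reference_gene: str) -> pd.DataFrame:
    """Per-replicate dCt, matching target and reference by replicate id."""
    tgt = ct[ct["gene"] == target_gene]
    ref = ct[ct["gene"] == reference_gene]
    if ref.empty:
        raise ValidationError(f"reference gene {reference_gene!r} absent from table")
    if tgt.empty:
        raise ValidationError(f"target gene {target_gene!r} absent from table")
    keys = STRATA + ["temperature_c", "replicate_id"]
    merged = tgt.merge(ref, on=keys, suffixes=("_t", "_r"), how="outer",
                       indicator=True)
    bad = merged[merged["_merge"] != "both"]
    if len(bad):
        first = bad.iloc[0]
        raise ValidationError(
            "unmatched replicate: "
            f"(sex={first['sex']}, age={first['age_days']}, "
            f"part={first['tissue_part']}, T={first['temperature_c']}, "
            f"rep={first['replicate_id']}) present for only one of "
            f"{target_gene!r}/{reference_gene!r}"
        )
    merged["dct"] = merged["ct_t"] - merged["ct_r"]
    return merged[keys + ["dct"]]


def relative_expression(
    ct: pd.DataFrame,
    target_gene: str,
    reference_gene: str = "GAPDH",
    control_temperature: float = 25,
) -> RelExpression:
    """2^-ddCt fold change of a target gene relative to the control condition.

    The control is the ``control_temperature`` condition within the same
    (sex, age, tissue-part) stratum. Folds are computed per replicate
    (ddCt_rep = dCt_rep - mean control dCt of the stratum) and reported
    as mean +- SEM; the control condition itself is reported the same
    way, so its mean fold is ~1 (exactly 1 only at zero noise).
    """
    dct = _delta_ct(ct, target_gene, reference_gene)
    rep_rows = []
    for strat, grp in dct.groupby(STRATA, sort=True):
        ctrl = grp[grp["temperature_c"] == control_temperature]["dct"]
        if ctrl.empty:
            raise ValidationError(
                f"stratum {dict(zip(STRATA, strat))}: control condition "
                f"({control_temperature}) missing"
            )
        ctrl_mean = ctrl.mean()
        g = grp.assign(ddct=grp["dct"] - ctrl_mean)
        g = g.assign(fold=2.0 ** (-g["ddct"]))
        rep_rows.append(g)
    reps = pd.concat(rep_rows, ignore_index=True)
    agg = (reps.groupby(STRATA + ["temperature_c"], sort=True)["fold"]
           .agg(fold="mean", sem=lambda x: x.sem(ddof=1), n_reps="count")
           .reset_index())
    return RelExpression(gene=target_gene, reference_gene=reference_gene,
                         control_temperature=control_temperature,
                         table=agg, replicate_folds=reps)


@dataclass
class ContrastPanelResult:
    """Panel-wide condition contrasts and per-class responsiveness."""

    table: pd.DataFrame  # gene, gene_class, stratum, temperature, fold, sem,
    #                      n_reps, p, method, significant
    class_summary: pd.DataFrame  # gene_class, n_conditions, n_significant, fraction

    def summary(self) -> str:
        lines = ["responsive condition fraction by class:"]
        for row in self.class_summary.itertuples(index=False):
            lines.append(f"  {row.gene_class}: {row.n_significant}/{row.n_conditions}"
                         f" = {row.fraction:.2f}")
        return "\n".join(lines)


def contrast_panel(
    ct: pd.DataFrame,
    panel,
    reference_gene: str = "GAPDH",
    control_temperature: float = 25,
    alpha: float = 0.05,
) -> ContrastPanelResult:
    """Quantify every panel gene across conditions and contrast vs control.

    For each panel gene present in the Ct table and each non-control
    condition, the per-replicate folds are tested against the control
    replicates' folds of the same stratum (normality-gated routing).
    Conditions with fewer than 2 replicates are skipped with a warning;
    with 2 replicates the fold is reported but no test is run. The class
    summary gives the fraction of tested conditions with p < ``alpha``
    per gene class.
    """
    genes = [g for g in panel.network_genes if g in set(ct["gene"])]
    if not genes:
        raise ValidationError("no panel genes present in the Ct table")
    rows = []
    for gene in genes:
        rel = relative_expression(ct, gene, reference_gene, control_temperature)
        reps = rel.replicate_folds
        for strat, grp in reps.groupby(STRATA, sort=True):
            ctrl_folds = grp[grp["temperature_c"] == control_temperature]["fold"].to_numpy()
            for temp, sub in grp.groupby("temperature_c", sort=True):
                if temp == control_temperature:
                    continue
                folds = sub["fold"].to_numpy()
                if folds.size < 2:
                    warnings.warn(
                        f"{gene} {dict(zip(STRATA, strat))} T={temp}: fewer than "
                        f"2 replicates; skipped", UserWarning, stacklevel=2,
                    )
                    continue
                if folds.size >= 3 and ctrl_folds.size >= 3:
                    test = route_and_test(ctrl_folds, folds)
                    p, method = test.p, test.method
                else:
                    p, method = np.nan, "none"
                rows.append({
                    "gene": gene,
                    "gene_class": panel.gene_class(gene),
                    **dict(zip(STRATA, strat)),
                    "temperature_c": temp,
                    "fold": float(folds.mean()),
                    "sem": float(pd.Series(folds).sem(ddof=1)),
                    "n_reps": int(folds.size),
                    "p": p,
                    "method": method,
                })
    columns = ["gene", "gene_class", *STRATA, "temperature_c", "fold", "sem",
               "n_reps", "p", "method"]
    table = pd.DataFrame(rows, columns=columns)
    table["significant"] = table["p"] < alpha
    tested = table[table["p"].notna()]
    summary = (tested.groupby("gene_class")
               .agg(n_conditions=("significant", "size"),
                    n_significant=("significant", "sum"))
               .reset_index())
    summary["fraction"] = summary["n_significant"] / summary["n_conditions"]
    return ContrastPanelResult(table=table, class_summary=summary)
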