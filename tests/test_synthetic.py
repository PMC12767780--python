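"""Tests of the synthetic-data generators: reproducibility, validation, and
recoverability of planted parameters by direct moment estimators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pepregnet.errors import InvalidConfigError
from pepregnet.synthetic import (
    CtDesign,
    SimConfig,
    gen_cisreg_annotation,
    gen_ct_table,
    gen_expression,
    gen_importance_series,
)

SMALL = dict(n_cells=200, n_genes=60, n_tfs=8)


class TestGenExpression:
    def test_seeded_reproducibility(self):
        d1 = gen_expression(SimConfig(**SMALL, seed=7))
        d2 = gen_expression(SimConfig(**SMALL, seed=7))
        assert np.array_equal(d1.matrix.counts, d2.matrix.counts)
        assert d1.truth_edges == d2.truth_edges
        assert d1.matrix.cell_meta.equals(d2.matrix.cell_meta)

    def test_different_seeds_differ(self):
        d1 = gen_expression(SimConfig(**SMALL, seed=1))
        d2 = gen_expression(SimConfig(**SMALL, seed=2))
        assert not np.array_equal(d1.matrix.counts, d2.matrix.counts)

    def test_counts_are_nonnegative_integers(self):
        ds = gen_expression(SimConfig(**SMALL, seed=0))
        assert ds.matrix.counts.dtype.kind == "i"
        assert ds.matrix.counts.min() >= 0

    def test_truth_edges_reference_matrix_genes(self):
        ds = gen_expression(SimConfig(**SMALL, seed=0))
        genes = set(ds.matrix.gene_ids)
        for tf, target in ds.truth_edges:
            assert tf in genes and target in genes

    def test_every_panel_gene_has_a_regulator(self):
        ds = gen_expression(SimConfig(**SMALL, seed=3))
        targets = {t for _, t in ds.truth_edges}
        from pepregnet.io import load_panel

        assert targets == set(load_panel().network_genes)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(n_tfs=60, n_genes=60),  # TFs not < genes
            dict(n_genes=20),  # panel not coverable
            dict(effect_size=0.5),
            dict(tf_active_prob=0.0),
            dict(fanin_np=-1),
            dict(program_probs=(0.5, 0.5, 0.5)),
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(InvalidConfigError):
            gen_expression(SimConfig(**{**SMALL, **bad}))

    def test_neutral_effect_makes_targets_background_like(self):
        # effect_size 1 with all means equal: panel genes indistinguishable
        # from background genes by a per-gene two-sample test
        total, rejected = 0, 0
        for seed in range(20):
            cfg = SimConfig(n_cells=200, n_genes=60, n_tfs=8, effect_size=1.0,
                            panel_mean=0.5, offprogram_mean=0.5,
                            baseline_mean=0.5, tf_mean=0.5, seed=seed)
            ds = gen_expression(cfg)
            bg_cols = [i for i, g in enumerate(ds.matrix.gene_ids)
                       if g.startswith("bg")]
            bg = ds.matrix.counts[:, bg_cols].ravel()
            for gene in {t for _, t in ds.truth_edges}:
                col = ds.matrix.gene_index([gene])[0]
                p = sps.ttest_ind(ds.matrix.counts[:, col], bg).pvalue
                total += 1
                rejected += p < 0.01
        assert rejected / total <= 0.05

    def test_planted_fanin_asymmetry_recovered(self):
        # fan-in 8 vs 3: mean truth in-degree difference within +-1 of 5
        diffs = []
        for seed in range(20):
            cfg = SimConfig(n_cells=20, n_genes=60, n_tfs=15,
                            fanin_np=3, fanin_npr=8, seed=seed)
            ds = gen_expression(cfg)
            deg = {}
            for _, t in ds.truth_edges:
                deg[t] = deg.get(t, 0) + 1
            from pepregnet.io import load_panel

            panel = load_panel()
            np_deg = [deg.get(g, 0) for g in panel.np_genes]
            npr_deg = [deg.get(g, 0) for g in panel.npr_genes]
            diffs.append(np.mean(npr_deg) - np.mean(np_deg))
        assert abs(np.mean(diffs) - 5) <= 1


class TestGenCisregAnnotation:
    def test_seeded_reproducibility(self, panel):
        bias = {"NP": (5, 800), "NPR": (12, 800)}
        a1 = gen_cisreg_annotation(panel, bias, seed=9)
        a2 = gen_cisreg_annotation(panel, bias, seed=9)
        assert a1.equals(a2)

    def test_intervals_have_positive_length(self, panel):
        ann = gen_cisreg_annotation(panel, {"NP": (5, 800), "NPR": (12, 800)}, seed=0)
        assert (ann["end"] > ann["start"]).all()

    def test_identical_class_means_give_null_difference(self, panel):
        # equal planted means: |mean difference| below 3 SE over 50 seeds
        diffs = []
        np_syms, npr_syms = set(panel.all_np_symbols), set(panel.all_npr_symbols)
        for seed in range(50):
            ann = gen_cisreg_annotation(panel, {"NP": (6, 800), "NPR": (6, 800)},
                                        seed=seed)
            counts = ann.groupby("gene").size()
            a = [counts.get(g, 0) for g in np_syms]
            b = [counts.get(g, 0) for g in npr_syms]
            diffs.append(np.mean(b) - np.mean(a))
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * se

    def test_planted_class_means_recovered(self, panel):
        means_np, means_npr = [], []
        for seed in range(50):
            ann = gen_cisreg_annotation(panel, {"NP": (5, 800), "NPR": (12, 800)},
                                        seed=seed)
            counts = ann.groupby("gene").size()
            means_np.append(np.mean([counts.get(g, 0) for g in panel.all_np_symbols]))
            means_npr.append(np.mean([counts.get(g, 0) for g in panel.all_npr_symbols]))
        for vals, target in ((means_np, 5), (means_npr, 12)):
            se = np.std(vals, ddof=1) / np.sqrt(len(vals))
            assert abs(np.mean(vals) - target) < 3 * se

    def test_planted_mean_length_recovered(self, panel):
        lengths = []
        for seed in range(30):
            ann = gen_cisreg_annotation(panel, {"NP": (8, 500), "NPR": (8, 500)},
                                        seed=seed)
            lengths.append((ann["end"] - ann["start"]).mean())
        se = np.std(lengths, ddof=1) / np.sqrt(len(lengths))
        assert abs(np.mean(lengths) - 500) < 4 * se

    def test_unknown_class_mean_missing(self, panel):
        with pytest.raises(InvalidConfigError):
            gen_cisreg_annotation(panel, {"NP": (5, 800)}, seed=0)


class TestGenCtTable:
    def test_zero_noise_null_fold_exact(self):
        from pepregnet.qpcr import relative_expression

        design = CtDesign(genes=("GAPDH", "SIFa"))
        ct = gen_ct_table(design, noise_sd=0.0, seed=0)
        rel = relative_expression(ct, "SIFa")
        assert (rel.table["fold"] == 1.0).all()

    def test_zero_noise_planted_fold_exact(self):
        from pepregnet.qpcr import relative_expression

        design = CtDesign(genes=("GAPDH", "SIFaR"))
        ct = gen_ct_table(design, {("SIFaR", 37): 2.0}, noise_sd=0.0, seed=0)
        rel = relative_expression(ct, "SIFaR")
        assert rel.fold("male", 1, "head", 37) == pytest.approx(4.0)
        assert rel.fold("male", 1, "head", 29) == pytest.approx(1.0)

    def test_missing_reference_rejected(self):
        with pytest.raises(InvalidConfigError, match="reference"):
            gen_ct_table(CtDesign(genes=("SIFa",)), seed=0)

    def test_replicate_floor(self):
        with pytest.raises(InvalidConfigError):
            gen_ct_table(CtDesign(genes=("GAPDH", "SIFa")), n_reps=1, seed=0)

    def test_seeded_reproducibility(self):
        d = CtDesign(genes=("GAPDH", "SIFa"))
        assert gen_ct_table(d, seed=4).equals(gen_ct_table(d, seed=4))


class TestGenImportanceSeries:
    def test_zero_lift_class_means_equal(self, panel):
        diffs = []
        for seed in range(40):
            imp = gen_importance_series([5, 30], k_planted=80, npr_lift=0.0,
                                        seed=seed)
            for age in (5, 30):
                sub = imp[imp["age_days"] == age]
                np_mean = sub[sub["target"].isin(panel.np_genes)]["importance"].mean()
                npr_mean = sub[sub["target"].isin(panel.npr_genes)]["importance"].mean()
                diffs.append(npr_mean - np_mean)
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * se

    def test_positive_lift_raises_npr_mean_at_every_age(self, panel):
        imp = gen_importance_series([5, 30, 50, 70], k_planted=80, npr_lift=0.1,
                                    seed=0)
        for age in (5, 30, 50, 70):
            sub = imp[imp["age_days"] == age]
            np_mean = sub[sub["target"].isin(panel.np_genes)]["importance"].mean()
            npr_mean = sub[sub["target"].isin(panel.npr_genes)]["importance"].mean()
            assert npr_mean > np_mean

    def test_importances_nonnegative_and_reproducible(self):
        i1 = gen_importance_series([5], seed=3)
        i2 = gen_importance_series([5], seed=3)
        assert i1.equals(i2)
        assert (i1["importance"] >= 0).all()

    def test_empty_ages_rejected(self):
        with pytest.raises(InvalidConfigError):
            gen_importance_series([], seed=0)
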