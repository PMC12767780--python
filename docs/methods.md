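# Methods

`pepregnet` re-implements, as an offline and fully testable pipeline, a
comparative analysis of transcriptional regulation of neuropeptide (NP)
and neuropeptide-receptor (NPR) genes in *Drosophila melanogaster*. The
guiding biological question is whether receptor genes sit under broader
transcriptional control than their ligands — more cis-regulatory
elements, more regulating transcription factors (TFs), and more dynamic
expression under environmental shifts — and whether that asymmetry is
recoverable from single-cell expression data, TF-target importance
rankings, and qPCR measurements. Because the real inputs are large
public atlases, every stage here runs instead on synthetic data with
planted ground truth, so each claim the pipeline makes can be checked
against a known answer.

## The curated gene panel

The packaged pair table lists 48 NP-NPR pairings (symbol + FlyBase ID
per gene); the focused network panel maps 10 NPs to 13 receptors. Both
are transcribed verbatim from the curation they derive from, including
two printed anomalies (one FlyBase ID shared by two receptor symbols,
and NPs that appear in several rows because they have several
receptors). These are *flagged* in `GenePanel.validation_report`, never
silently resolved: the tables are data, and data cleaning belongs to the
caller. Symbol casing differs between the two tables for four genes
(e.g. `Crz` vs `CRZ`, `FMRFa` vs `FMRFamide`); membership checks
normalize case and one alias and note the normalization in the report.

## Synthetic expression data

`synthetic.gen_expression` draws a cells × genes UMI matrix from a
negative binomial with variance mu + phi·mu² (dispersion phi = 0.5
by default, the common single-cell choice). Three gene roles have
separate baselines:

| parameter | default | meaning |
|---|---|---|
| `baseline_mean` | 0.5 | background genes, everywhere |
| `tf_mean` | 5.0 | TF transcripts (well expressed, as regulon pipelines assume) |
| `panel_mean` | 2.0 | panel genes *within their program's cells* |
| `offprogram_mean` | 0.05 | panel genes elsewhere (dropout level) |

Two latent layers generate structure:

* **Cell programs.** Each cell is an NP-cell, an NPR-cell or "other"
  (probabilities 0.35/0.35/0.30), exposed in the cell annotation. Panel
  genes are expressed only in their class's cells. This emulates the
  cell-type specificity of NP/NPR expression in the fly atlases and is
  what makes the pipeline's NP-/NPR-exclusive cell selection meaningful;
  with a uniform baseline every cell would co-express both classes and
  the exclusive populations would be empty.
* **TF activity.** Each TF is independently active per cell with
  probability `tf_active_prob` (0.3). An active TF's own transcript mean
  is multiplied by `effect_size` (4), and each in-program target's mean
  is multiplied by `effect_size` once *per active regulator* — the
  multiplicative compounding makes every regulator's marginal
  contribution identifiable by regression, which an "any regulator
  active" switch would not.

The planted regulatory truth is the receptor bias itself: every panel
gene draws its regulator set with a truncated-at-one Poisson fan-in,
mean `fanin_npr` = 8 for receptors vs `fanin_np` = 3 for NPs. Motif
support is planted for every true TF→target edge plus three decoy
background genes per TF, so motif pruning is exercised without being
decorative. The latent TF activity matrix is kept on the dataset for
activity-recovery tests.

What the generator does **not** emulate: doublets, ambient RNA, batch
effects, gene-length effects (UMI counts need none), spatial structure,
or realistic gene-gene correlation beyond the planted TF programs.
Passing tests therefore demonstrate that the *methods* recover planted
structure of the assumed form at desk scale — not that the biological
conclusions hold on atlas data.

## GRN inference (tree-ensemble importance)

`regulons.genie3_importance` regresses each target's log1p expression on
all TF expressions with a 200-tree random forest (all TFs candidate at
every split), and reports each TF's share of impurity reduction,
normalized to sum to one per target. Seeds are mandatory; ties and RNG
are fully deterministic.

Two deliberate choices:

* **Transform.** The regression uses `log1p` of raw counts by default.
  Library-size (CPM-style) normalization is available
  (`transform="depth_log1p"`) but not the default: in data where a few
  strongly induced targets dominate a cell's library, depth scaling
  induces compositional anti-correlations between the TFs and every
  other gene, and measured edge recovery on the default simulation drops
  from AUROC ≈ 0.96 to ≈ 0.65.
* **Stratification.** `pipeline.class_importance` infers TF→NP edges
  within NP-annotated cells and TF→NPR edges within NPR-annotated cells,
  the way atlas regulon pipelines run per tissue or cell type. Pooling
  all cells leaves the cell-program mixture as dominant, unexplainable
  target variance and caps recovery around AUROC 0.78.

`build_regulons` keeps each TF's top-k targets (k = 50) by importance —
ties broken toward the lexicographically smaller gene — then drops
targets without (TF, gene) motif support, grouping the survivors by
motif into regulons.

## Regulon activity (rank-AUC) and binarization

`aucell_score` ranks genes per cell by decreasing count (ties by the
stable gene order of the matrix — deterministic, rather than the
randomized tie handling some implementations use). With
T = ceil(f·G) top-ranked genes (f = 0.05 by default) and recovery curve
y(i) = number of regulon targets at rank ≤ i, the score is

    AUC = sum_{i=1..T} y(i) / sum_{i=1..T} min(i, m),

normalized so that a regulon whose m targets occupy the top m ranks
scores exactly 1 and one with no target in the top T scores 0. The
implementation is checked against a brute-force rank-by-rank enumeration
to 1e-12.

Binarization uses an empirical null: the threshold is the 0.99 quantile
of AUCs of size-matched random gene sets (200 by default) scored on the
same cells, and a cell is "active" above it. This is simpler than
mixture-model thresholding and has a provable calibration: a regulon of
background genes is active in ≈ 1% of cells. Activity recovery of the
planted TF states is tested in an identifiable regime (near-disjoint
single-regulator regulons whose targets are expressed only when the
regulator is active); with overlapping regulons or constitutively
expressed targets, per-cell activity is partially confounded by design
and no method could attribute it to a single TF.

## Class networks and their comparison

Cells co-expressing both classes are excluded
(`select_exclusive_cells`): a cell counts as NP-exclusive when at least
one panel NP reaches the detection threshold (1 UMI by default) and no
panel receptor does. Per class, the bipartite TF→gene network contains
the edge (TF, g) when g is a class panel gene in the TF's regulon and
the regulon is active in at least one of the class's cells. Reported
complexity metrics: number of TFs, number of nodes (TFs ∪ genes),
number of edges, and the number of cascade TFs (TFs that are themselves
targets of another network TF's regulon). `remove_shared_tfs` drops TFs
common to both class networks (idempotent); `cascade_counts` tallies
TF→TF regulation by motif or tissue context.

The NP-vs-NPR comparison takes the per-gene TF in-degree as its unit of
replication, *including* panel genes with zero recovered regulators, so
the sample is the full class panel. Under equal planted fan-in the
comparison rejects at the nominal 5% level (measured over 200 simulated
panels); with fan-in 8 vs 3 the receptor excess propagates through the
full pipeline.

A note on TF counts: whether the receptor network can engage *more* TFs
than the NP network is bounded by the TF pool. With a 10-TF pool and
fan-ins of 8 and 3 over 10-13 genes, both class unions saturate the
pool, so end-to-end bias-recovery runs use a 20-TF pool (500 cells, 60
genes), where the NP union stays unsaturated.

## Aging: top-k importance comparisons

Per age (and optionally per cell type), TF-NP and TF-NPR pairs are each
ranked by importance (ties lexicographic on (tf, target), so rankings
are total orders) and the two top-k importance vectors (k = 50) are
compared; a pooled variant ranks both classes together (k = 100) and
reports each class's membership count within the top k. The default age
grid is {5, 30, 50, 70} days; the early-adult grid {1, 3, 5} is equally
supported.

A calibration caveat that the protocol itself carries: when k is smaller
than the candidate pool, the compared values are order statistics
selected on the very quantity being tested, and the nominal test level
is not maintained (measured type-I error ≈ 0.17 at k = 50 from a
100-pair pool). Null-calibration checks therefore plant exactly k pairs
per class; results of top-k comparisons on larger pools should be read
as descriptive rankings, not calibrated hypothesis tests.

## qPCR quantification

`qpcr.relative_expression` implements 2^-ddCt with an assumed exact
doubling per cycle: per replicate (matched by replicate id),
dCt = Ct_target − Ct_reference (reference gene GAPDH); ddCt subtracts
the mean control dCt of the same (sex, age, tissue-part) stratum
(control = 25 °C); the per-replicate fold is 2^-ddCt and conditions are
reported as mean ± SEM over replicate folds. Computing folds per
replicate (rather than propagating errors on mean Cts) gives a direct
SEM of the fold. Consequences worth knowing: the control condition's
mean fold is exactly 1 only at zero noise (Jensen's inequality otherwise
lifts it slightly), the mean of per-replicate *log2* folds is exactly
unbiased, and all folds are invariant to adding a constant to every Ct.

`contrast_panel` tests each gene × non-control condition against the
control replicates of the same stratum and summarizes, per gene class,
the fraction of tested conditions with p < 0.05 — the pipeline's
operational form of "NPR levels respond to temperature while NP levels
are stable". Conditions with fewer than 2 replicates are skipped with a
warning; with 2 the fold is reported untested.

The Ct generator plants log2 folds per (gene, temperature) with the
reference gene fixed at fold 1, baseline Cts of 16 (reference) and 24
(targets), and Gaussian Ct noise (sd 0.2, triplicates by default). The
replicate axis is a single flat axis; the technical-vs-biological
replicate hierarchy of real designs is not modeled.

## Statistical toolkit

`stats.route_and_test` screens both samples with a Kolmogorov-Smirnov
test of the standardized sample against the standard normal (this
estimates the parameters from the data without the Lilliefors
critical-value correction — the screen is therefore conservative toward
normality; both this and the interpretation are documented rather than
hidden). Both pass at p > 0.05 → two-sided Student's t-test (pooled
variance unpaired, or paired); otherwise a two-sided Mann-Whitney U
test, with a paired request falling back to the unpaired U with a
warning. Significance labels use the conventional star thresholds
0.05/0.01/0.001/0.0001. Two constant samples are flagged degenerate:
p = 1 when the constants are equal, p = 0 when they differ (there is no
within-group spread to test against, but two different constants are
not "indistinguishable").

`stats.estimation_stats` reports the difference between means
(DBM = mean(b) − mean(a)) with a bootstrap 95% CI. The default interval
is Hesterberg's *expanded* percentile: plain percentile intervals of a
mean are systematically narrow at small n (the bootstrap SD shrinks by
sqrt((n−1)/n) and the interval has z- rather than t-width), covering
only ≈ 92% at n = 10 per group; widening the percentile levels to
Phi(±t_{df,0.975}/shrink) restores ≈ 94-95% coverage. Plain
`"percentile"` and `"bca"` (via scipy) remain available.

## Problem sizes and numerical choices

Simulation-based checks run at desk scale: the default simulation is
1000 cells × 100 genes × 10 TFs; end-to-end network runs use 500 cells
× 60 genes × 20 TFs with 100-tree forests; null calibrations regenerate
200 truth panels; bootstrap coverage uses 1000 replicates of n = 10 per
group with 2000 resamples. All RNG flows from explicit integer seeds
(numpy `default_rng`); re-running any stage with the same seed is
bit-identical. Interval coordinates are 0-based half-open; lengths are
reported in kilobases; overlapping regulatory elements are summed as
listed by default with merging available as an option (the two
conventions are both defensible and both exposed).

## Known limitations

* The synthetic generator's independence assumptions (TF activities
  independent across TFs and cells; programs independent of TF
  activity) are stronger than real data; recovery results are upper
  bounds in that sense.
* The KS normality gate at small n has low power, so the router mostly
  chooses t-tests for small samples.
* Per-cell regulon activity is identifiable only to the extent regulons
  do not share targets; shared-target confounding is inherent to
  rank-AUC scoring, not specific to this implementation.
* The top-k comparison's selection bias (above) means its p-values on
  pools larger than k are descriptive.
* No multiple-testing correction is applied anywhere, matching the
  analysis this package re-implements.
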