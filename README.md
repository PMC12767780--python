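# pepregnet

Analysis toolkit for the transcriptional regulation of neuropeptide (NP)
and neuropeptide-receptor (NPR) genes in *Drosophila melanogaster*.

Neuropeptides signal through receptors that are mostly GPCRs, and a
recurring observation in fly genomics is that the *receptor* side of
each NP-NPR pair carries the regulatory burden: NPR loci harbor more
cis-regulatory elements, more transcription factors (TFs) regulate NPR
expression, and NPR mRNA levels respond to environmental shifts
(e.g. temperature) while NP levels stay comparatively stable. This
package implements the full analysis chain needed to quantify that
receptor bias — and, because the real inputs are large single-cell
atlases, it ships a synthetic-data generator with planted ground truth
so that every stage runs and is verified completely offline.

It is intended for computational biologists who want a small, tested,
deterministic implementation of these building blocks:

* **Curated panels** (`pepregnet.io`): the 48-row NP-NPR pair table and
  the 10-NP / 13-NPR network panel, packaged as TSV, with a validation
  report that flags (rather than resolves) curation anomalies.
* **Cis-regulatory comparison** (`pepregnet.cisreg`): per-gene counts,
  total and mean lengths (kb) of TFBS hotspot areas, cis-regulatory
  modules and ChIP peaks; NP-vs-NPR comparison in paired (per pairing)
  and unpaired (per gene) modes.
* **Expression summaries** (`pepregnet.expression`): pooled-pseudobulk
  TPM and expressing-cell counts (TCC) per tissue or annotation, and
  their Pearson correlation.
* **Regulon machinery** (`pepregnet.regulons`): GENIE3-style
  random-forest TF→target importance, motif-pruned regulons, AUCell-style
  per-cell rank-AUC activity

      AUC = Σ_{i=1..T} y(i) / Σ_{i=1..T} min(i, m),   T = ⌈f·G⌉,

  and activity binarization against a size-matched random-set null.
* **Network comparison** (`pepregnet.networks`): NP-/NPR-exclusive cell
  selection, bipartite TF→gene networks from active regulons,
  shared-TF removal, TF→TF cascade counts, and per-tissue complexity
  comparison on per-gene TF in-degree.
* **Aging analysis** (`pepregnet.aging`): per-age top-k TF-NP vs TF-NPR
  importance comparison (k = 50), pooled top-k membership counts
  (k = 100), regulon × age activity profiles.
* **qPCR quantification** (`pepregnet.qpcr`): 2^−ΔΔCt relative
  expression against a reference gene (GAPDH) and a 25 °C control,
  with per-replicate folds, SEM, and per-class responsiveness summaries.
* **Statistics** (`pepregnet.stats`): KS-gated routing between
  Student's t and Mann-Whitney U, significance stars, and estimation
  statistics (difference between means with a bootstrap 95% CI).
* **Synthetic data** (`pepregnet.synthetic`): negative-binomial UMI
  counts with latent cell programs and TF activities, planted
  receptor-biased fan-in, interval annotations, Ct tables and
  importance series — all bit-reproducible from a seed.

See `docs/methods.md` for the models, defaults, and their rationale.

## Worked example

Simulate a dataset in which each receptor gene draws on average 8
regulating TFs and each neuropeptide 3 (of a 20-TF pool), then run the
pipeline: class-stratified importance inference → motif-pruned regulons
→ activity scoring → exclusive-cell selection → class networks →
comparison.

```python
from pepregnet.synthetic import SimConfig, gen_expression
from pepregnet.pipeline import run_network_comparison

cfg = SimConfig(n_cells=500, n_genes=60, n_tfs=20,
                fanin_np=3, fanin_npr=8, seed=7)
ds = gen_expression(cfg)
res = run_network_comparison(ds, n_trees=100, seed=7)
print("NP-exclusive cells:", len(res.np_cells),
      "| NPR-exclusive cells:", len(res.npr_cells))
print("NP network:", res.net_np.stats())
print("NPR network:", res.net_npr.stats())
print(res.comparison.test.summary())
print(res.comparison.estimation.summary())
```

prints

```
NP-exclusive cells: 122 | NPR-exclusive cells: 157
NP network: NetworkStats(n_tfs=4, n_nodes=11, n_edges=12, n_cascade_tfs=0)
NPR network: NetworkStats(n_tfs=20, n_nodes=33, n_edges=95, n_cascade_tfs=0)
t_unpaired: stat=-5.784, p=9.673e-06 (****), n=10/13
DBM=6.108 [95% CI 4.131, 8.143]
```

Reading the output: after excluding co-expressing cells, the recovered
NPR network engages all 20 TFs versus 4 for the NP network, and the
per-gene TF in-degree of receptors exceeds that of neuropeptides by
6.1 TFs on average (bootstrap 95% CI 4.1-8.1; unpaired t-test
p ≈ 1e-5) — the planted receptor bias, recovered end to end.

The same stages are available as CLI subcommands operating on a TOML
config:

```sh
pepregnet simulate  --config cfg.toml --seed 1 --out out/sim
pepregnet netcompare --config cfg.toml --seed 1 --out out/net
pepregnet cisreg    --seed 1 --out out/cis
pepregnet aging     --seed 1 --out out/age
pepregnet qpcr      --seed 1 --out out/qpcr
```

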