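"""Synthetic single-cell, cis-regulatory, importance and qPCR data with planted truth.

Every generator is a pure function of its configuration and seed, so each
downstream stage of the pipeline can be tested offline against known
ground truth. The expression simulator emulates the statistical structure
the analysis assumes in real fly single-nucleus data:

* UMI counts are negative-binomial (variance = mu + disp * mu^2) with
  gene-role-specific baseline means (background genes, TF genes, panel
  genes).
* Panel expression is cell-type specific: each cell carries a latent
  program (NP-cells / NPR-cells / other, drawn with ``program_probs``)
  exposed in the cell annotation; panel genes of the matching class are
  expressed at ``panel_mean`` in their program's cells and at the
  dropout-level ``offprogram_mean`` elsewhere — the reason NP- and
  NPR-exclusive cell populations exist, as they do in the fly atlases.
* A latent per-cell Bernoulli activity drives each transcription factor:
  an active TF's own transcript mean and the means of its (in-program)
  target genes are lifted by ``effect_size`` (targets multiplicatively
  per active regulator, so every regulator's contribution is
  identifiable).
* Neuropeptide-receptor genes draw more regulators than neuropeptide
  genes (truncated Poisson fan-in ``fanin_npr`` vs ``fanin_np``) — the
  planted form of receptor-biased transcriptional control.
* Cells carry tissue / annotation / age / sex labels; motif support is
  planted for every true TF→target edge plus decoy genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .regulons import Regulon

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "CtDesign",
    "gen_expression",
    "gen_cisreg_annotation",
    "gen_ct_table",
    "gen_importance_series",
]

DEFAULT_TISSUES = ("head", "body")
DEFAULT_AGES = (5, 30, 50, 70)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the expression simulator.

    Defaults are the desk-scale conditions used throughout the test
    suite: 1000 cells, 100 genes, 10 TFs, four-fold expression lift on
    targets of active TFs, and the receptor-biased fan-in asymmetry
    (8 TFs per receptor vs 3 per neuropeptide on average).
    """

    n_cells: int = 1000
    n_genes: int = 100
    n_tfs: int = 10
    panel: object = None  # GenePanel; packaged panel when None
    fanin_np: float = 3.0
    fanin_npr: float = 8.0
    tf_active_prob: float = 0.3
    effect_size: float = 4.0
    baseline_mean: float = 0.5  # background genes
    tf_mean: float = 5.0  # TF transcripts (well-expressed, as SCENIC assumes)
    panel_mean: float = 2.0  # panel genes within their program's cells
    offprogram_mean: float = 0.05  # panel genes outside their program (dropout level)
    program_probs: tuple = (0.35, 0.35, 0.30)  # NP-cells, NPR-cells, other
    nb_dispersion: float = 0.5
    tissues: tuple = DEFAULT_TISSUES
    ages: tuple = DEFAULT_AGES
    seed: int = 0

    def validate(self, n_panel_genes: int) -> None:
        if min(self.n_cells, self.n_genes, self.n_tfs) < 1:
            raise InvalidConfigError("all counts must be >= 1")
        if self.n_tfs >= self.n_genes:
            raise InvalidConfigError(
                f"n_tfs ({self.n_tfs}) must be < n_genes ({self.n_genes})"
            )
        if self.n_tfs + n_panel_genes > self.n_genes:
            raise InvalidConfigError(
                f"panel ({n_panel_genes} genes) plus {self.n_tfs} TFs not "
                f"coverable by n_genes={self.n_genes}"
            )
        if self.fanin_np < 0 or self.fanin_npr < 0:
            raise InvalidConfigError("fan-in means must be >= 0")
        if self.effect_size < 1:
            raise InvalidConfigError("effect_size must be >= 1")
        if not (0 < self.tf_active_prob < 1):
            raise InvalidConfigError("tf_active_prob must be in (0, 1)")
        if min(self.baseline_mean, self.tf_mean, self.panel_mean,
               self.offprogram_mean) <= 0 or self.nb_dispersion < 0:
            raise InvalidConfigError("expression means must be > 0 and "
                                     "nb_dispersion >= 0")
        if len(self.program_probs) != 3 or abs(sum(self.program_probs) - 1) > 1e-9 \
                or min(self.program_probs) < 0:
            raise InvalidConfigError("program_probs must be 3 probabilities summing to 1")


@dataclass
class SyntheticDataset:
    """Expression matrix plus the planted regulatory ground truth."""

    matrix: object  # ExpressionMatrix
    truth_regulons: list[Regulon]
    truth_edges: set
    motif_support: pd.DataFrame  # tf, motif_id, gene (true edges + decoys)
    config: SimConfig
    tf_activity: pd.DataFrame | None = None  # cells x TFs latent Bernoulli states

    @property
    def tf_genes(self) -> list[str]:
        return [r.tf for r in self.truth_regulons]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draw with var = mu + dispersion * mu^2 (Poisson when dispersion=0)."""
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def gen_expression(config: SimConfig) -> SyntheticDataset:
    """Simulate a cells x genes UMI matrix with planted TF→target edges."""
    from .io import load_panel, ExpressionMatrix  # local import to avoid cycle

    panel = config.panel if config.panel is not None else load_panel()
    np_genes = panel.np_genes
    npr_genes = panel.npr_genes
    panel_genes = np_genes + npr_genes
    config.validate(len(panel_genes))
    rng = np.random.default_rng(config.seed)

    n_tfs = config.n_tfs
    tf_names = [f"tf{i + 1:02d}" for i in range(n_tfs)]
    n_bg = config.n_genes - n_tfs - len(panel_genes)
    bg_names = [f"bg{i + 1:04d}" for i in range(n_bg)]
    gene_ids = np.array(tf_names + panel_genes + bg_names)

    # planted regulators: truncated-at-1 Poisson fan-in per panel gene
    edges_mask = np.zeros((n_tfs, len(panel_genes)), dtype=bool)
    for j, gene in enumerate(panel_genes):
        fanin = config.fanin_npr if gene in npr_genes else config.fanin_np
        k = min(max(1, int(rng.poisson(fanin))), n_tfs)
        regs = rng.choice(n_tfs, size=k, replace=False)
        edges_mask[regs, j] = True
    truth_edges = {
        (tf_names[i], panel_genes[j])
        for i, j in zip(*np.nonzero(edges_mask))
    }

    # latent cell programs (NP-cells / NPR-cells / other) and TF activity
    programs = rng.choice(np.array(["np_cells", "npr_cells", "other"]),
                          size=config.n_cells, p=config.program_probs)
    active = rng.random((config.n_cells, n_tfs)) < config.tf_active_prob

    mean = np.full((config.n_cells, config.n_genes), config.baseline_mean)
    mean[:, :n_tfs] = np.where(active, config.tf_mean * config.effect_size,
                               config.tf_mean)
    n_active_regs = active.astype(float) @ edges_mask  # cells x panel genes
    in_program = np.zeros((config.n_cells, len(panel_genes)), dtype=bool)
    in_program[:, :len(np_genes)] = (programs == "np_cells")[:, None]
    in_program[:, len(np_genes):] = (programs == "npr_cells")[:, None]
    mean[:, n_tfs:n_tfs + len(panel_genes)] = np.where(
        in_program,
        config.panel_mean * config.effect_size ** n_active_regs,
        config.offprogram_mean,
    )
    counts = _nb_draw(rng, mean, config.nb_dispersion).astype(np.int64)

    # cell metadata; the program is exposed as the cell-type annotation
    tissues = rng.choice(config.tissues, size=config.n_cells)
    annotations = np.array([f"{t}_{p}" for t, p in zip(tissues, programs)])
    ages = rng.choice(config.ages, size=config.n_cells)
    sexes = rng.choice(["male", "female"], size=config.n_cells)
    cell_ids = np.array([f"cell{i + 1:05d}" for i in range(config.n_cells)])
    cell_meta = pd.DataFrame(
        {"tissue": tissues, "annotation": annotations, "program": programs,
         "age_days": ages, "sex": sexes},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    matrix = ExpressionMatrix(cell_ids=cell_ids, gene_ids=gene_ids,
                              counts=counts, cell_meta=cell_meta)

    # planted regulons and motif support (true edges + decoy background genes)
    truth_regulons = []
    support_rows = []
    n_decoys = min(3, n_bg)
    for i, tf in enumerate(tf_names):
        targets = frozenset(panel_genes[j] for j in np.nonzero(edges_mask[i])[0])
        motif = f"motif_{tf}"
        if targets:
            truth_regulons.append(Regulon(tf=tf, targets=targets, motif_id=motif))
        for g in sorted(targets):
            support_rows.append((tf, motif, g))
        if n_decoys:
            for g in rng.choice(bg_names, size=n_decoys, replace=False):
                support_rows.append((tf, motif, g))
    motif_support = pd.DataFrame(support_rows, columns=["tf", "motif_id", "gene"])

    tf_activity = pd.DataFrame(active, index=pd.Index(cell_ids, name="cell_id"),
                               columns=tf_names)
    return SyntheticDataset(matrix=matrix, truth_regulons=truth_regulons,
                            truth_edges=truth_edges, motif_support=motif_support,
                            config=config, tf_activity=tf_activity)


# ---------------------------------------------------------------------------
# cis-regulatory annotation generator

#: log-normal shape parameter for interval lengths (fixed; the class mean
#: is matched by adjusting the log-scale location).
_LENGTH_SIGMA = 0.5


def gen_cisreg_annotation(
    panel,
    bias: dict,
    seed: int = 0,
    kind: str = "TFBS_HSA",
    span_bp: int = 100_000,
) -> pd.DataFrame:
    """Generate per-gene interval annotations with class-specific means.

    ``bias`` maps gene class ("NP" / "NPR") to a (mean_count,
    mean_length_bp) tuple. Per gene of the full pair table the feature
    count is Poisson with the class mean and lengths are log-normal with
    the class mean length. Intervals are 0-based half-open, start < end.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gene in panel.all_np_symbols + panel.all_npr_symbols:
        cls = panel.gene_class(gene)
        if cls not in bias:
            raise InvalidConfigError(f"no bias entry for gene class {cls!r}")
        mean_count, mean_len = bias[cls]
        if mean_count <= 0 or mean_len <= 0:
            raise InvalidConfigError("class means must be > 0")
        count = rng.poisson(mean_count)
        mu = np.log(mean_len) - _LENGTH_SIGMA**2 / 2
        lengths = np.maximum(1, np.round(rng.lognormal(mu, _LENGTH_SIGMA, count))).astype(int)
        starts = rng.integers(0, span_bp, size=count)
        for s, ln in zip(starts, lengths):
            rows.append((gene, kind, int(s), int(s + ln)))
    return pd.DataFrame(rows, columns=["gene", "kind", "start", "end"])


# ---------------------------------------------------------------------------
# qPCR Ct generator


@dataclass(frozen=True)
class CtDesign:
    """Factorial design of the temperature-shift qPCR experiment."""

    genes: tuple
    reference_gene: str = "GAPDH"
    temperatures: tuple = (25, 29, 37)
    ages: tuple = (1, 3, 5)
    sexes: tuple = ("male", "female")
    tissue_parts: tuple = ("head", "body")
    control_temperature: int = 25

    def validate(self) -> None:
        if self.reference_gene not in self.genes:
            raise InvalidConfigError(
                f"reference gene {self.reference_gene!r} missing from design"
            )
        if self.control_temperature not in self.temperatures:
            raise InvalidConfigError("control temperature missing from design")


#: Baseline threshold cycles (arbitrary but realistic: the reference
#: housekeeping gene amplifies ~8 cycles earlier than the targets).
_CT_BASE_REFERENCE = 16.0
_CT_BASE_TARGET = 24.0


def gen_ct_table(
    design: CtDesign,
    response: dict | None = None,
    noise_sd: float = 0.2,
    n_reps: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a replicated Ct table with planted log2 fold changes.

    ``response`` maps (gene, temperature_c) to the planted log2 fold
    relative to the control temperature (missing entries mean fold 1);
    the reference gene is always fold 1. By construction the true
    2^-ddCt of each condition equals the planted fold exactly at
    ``noise_sd = 0``.
    """
    design.validate()
    if n_reps < 2:
        raise InvalidConfigError("n_reps must be >= 2")
    if noise_sd < 0:
        raise InvalidConfigError("noise_sd must be >= 0")
    response = dict(response or {})
    rng = np.random.default_rng(seed)
    rows = []
    for gene in design.genes:
        base = _CT_BASE_REFERENCE if gene == design.reference_gene else _CT_BASE_TARGET
        for sex in design.sexes:
            for age in design.ages:
                for part in design.tissue_parts:
                    for temp in design.temperatures:
                        if gene == design.reference_gene or temp == design.control_temperature:
                            log2_fold = 0.0
                        else:
                            log2_fold = float(response.get((gene, temp), 0.0))
                        for rep in range(1, n_reps + 1):
                            ct = base - log2_fold + rng.normal(0, noise_sd)
                            rows.append((gene, sex, age, temp, part, rep, ct))
    return pd.DataFrame(rows, columns=["gene", "sex", "age_days", "temperature_c",
                                       "tissue_part", "replicate_id", "ct"])


# ---------------------------------------------------------------------------
# TF-gene importance series generator

#: Gamma(shape, scale) baseline for pair importances.
_IMP_SHAPE = 2.0
_IMP_SCALE = 0.05


def gen_importance_series(
    ages,
    k_planted: int = 100,
    npr_lift: float = 0.05,
    drift: float = 0.0,
    seed: int = 0,
    panel=None,
    n_tfs: int = 20,
    cell_types=("all",),
) -> pd.DataFrame:
    """Generate (tf, target, importance, age_days, cell_type) records.

    Per age and cell type, ``k_planted`` TF-NP and ``k_planted`` TF-NPR
    pairs are drawn. Importances follow Gamma(2, 0.05) scaled by
    ``(1 + drift * age_index)``; TF-NPR pairs additionally receive the
    additive ``npr_lift``. The lift is the plantable form of
    receptor-biased regulatory importance.
    """
    ages = list(ages)
    if not ages:
        raise InvalidConfigError("ages must be non-empty")
    if npr_lift < 0:
        raise InvalidConfigError("npr_lift must be >= 0 (importances are non-negative)")
    if panel is None:
        from .io import load_panel

        panel = load_panel()
    rng = np.random.default_rng(seed)
    tf_names = [f"tf{i + 1:02d}" for i in range(n_tfs)]
    rows = []
    for ct in cell_types:
        for age_idx, age in enumerate(ages):
            scale_mult = 1.0 + drift * age_idx
            if scale_mult <= 0:
                raise InvalidConfigError("drift makes importances negative")
            for cls_genes, lift in ((panel.np_genes, 0.0), (panel.npr_genes, npr_lift)):
                pairs = [(tf, g) for tf in tf_names for g in cls_genes]
                idx = rng.choice(len(pairs), size=min(k_planted, len(pairs)),
                                 replace=False)
                base = rng.gamma(_IMP_SHAPE, _IMP_SCALE, size=idx.size) * scale_mult
                for i, b in zip(idx, base):
                    tf, g = pairs[i]
                    rows.append((tf, g, float(b + lift), age, ct))
    return pd.DataFrame(rows, columns=["tf", "target", "importance",
                                       "age_days", "cell_type"])
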