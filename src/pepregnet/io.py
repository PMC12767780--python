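"""Readers and writers for the pipeline's on-disk formats.

Formats are deliberately plain text: Matrix Market triplets plus TSV
sidecars for the expression matrix, TSV for interval annotations and
importance tables, CSV for qPCR Ct tables, JSON for result payloads and
a GMT-like one-regulon-per-line file. Interval coordinates are 0-based
half-open throughout.

The curated neuropeptide / neuropeptide-receptor pair tables for
*Drosophila melanogaster* are packaged under ``pepregnet/data`` and
loaded with :func:`load_panel`.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import FormatError, ValidationError
from .regulons import Regulon

__all__ = [
    "GenePanel",
    "ExpressionMatrix",
    "load_panel",
    "load_expression",
    "write_expression",
    "read_annotation",
    "write_annotation",
    "read_ct_table",
    "write_ct_table",
    "read_regulons",
    "write_regulons",
    "read_importance",
    "write_importance",
    "write_dataset",
    "load_dataset",
]

_FBGN_RE = re.compile(r"^FBgn\d{7}$")

#: Known symbol aliases between the pair table and the network panel
#: (the two tables were curated independently and differ in casing).
_SYMBOL_ALIASES = {"fmrfa": "fmrfamide"}

ANNOTATION_KINDS = ("TFBS_HSA", "CRM", "PEAK")

CT_COLUMNS = ["gene", "sex", "age_days", "temperature_c", "tissue_part",
              "replicate_id", "ct"]


def _norm_symbol(sym: str) -> str:
    s = sym.strip().lower()
    return _SYMBOL_ALIASES.get(s, s)


@dataclass
class GenePanel:
    """Curated NP-NPR gene panel.

    ``pairs`` holds the full pair table (one row per NP-NPR pairing,
    order preserved; genes appearing in several pairings appear in
    several rows). ``panel2`` maps each neuropeptide of the focused
    network panel to its receptor list.
    """

    pairs: pd.DataFrame  # columns: np_symbol, np_flybase_id, npr_symbol, npr_flybase_id
    panel2: dict[str, list[str]]
    validation_report: list[str] = field(default_factory=list)

    @property
    def np_genes(self) -> list[str]:
        """Unique neuropeptides of the network panel, in table order."""
        return list(self.panel2)

    @property
    def npr_genes(self) -> list[str]:
        """Unique receptors of the network panel, in table order."""
        seen: dict[str, None] = {}
        for rs in self.panel2.values():
            for r in rs:
                seen.setdefault(r, None)
        return list(seen)

    @property
    def network_genes(self) -> list[str]:
        return self.np_genes + self.npr_genes

    @property
    def all_np_symbols(self) -> list[str]:
        """Unique neuropeptide symbols of the full pair table, in order."""
        return list(dict.fromkeys(self.pairs["np_symbol"]))

    @property
    def all_npr_symbols(self) -> list[str]:
        """Unique receptor symbols of the full pair table, in order."""
        return list(dict.fromkeys(self.pairs["npr_symbol"]))

    def gene_class(self, gene: str) -> str | None:
        """Return "NP"/"NPR" for a panel gene (network panel or pair table)."""
        if gene in self.panel2:
            return "NP"
        if any(gene in rs for rs in self.panel2.values()):
            return "NPR"
        if gene in set(self.pairs["np_symbol"]):
            return "NP"
        if gene in set(self.pairs["npr_symbol"]):
            return "NPR"
        return None


def _validate_panel(pairs: pd.DataFrame, panel2: dict[str, list[str]]) -> list[str]:
    report: list[str] = []
    for col in ("np_flybase_id", "npr_flybase_id"):
        bad = pairs.loc[~pairs[col].map(lambda x: bool(_FBGN_RE.match(str(x)))), col]
        if len(bad):
            raise ValidationError(
                f"malformed FlyBase ID(s) in column {col}: {sorted(set(bad))}"
            )
    # flag (symbol, ID) inconsistencies instead of resolving them
    for side in ("np", "npr"):
        sym_col, id_col = f"{side}_symbol", f"{side}_flybase_id"
        by_id = pairs.groupby(id_col)[sym_col].agg(lambda s: sorted(set(s)))
        for fbgn, syms in by_id.items():
            if len(syms) > 1:
                report.append(f"{fbgn} maps to multiple symbols: {syms}")
    dup_np = pairs["np_symbol"][pairs["np_symbol"].duplicated()].unique()
    if len(dup_np):
        report.append(f"NPs appearing in multiple rows: {sorted(dup_np)}")

    # network-panel symbols must occur in the pair table (modulo casing/aliases)
    known = {_norm_symbol(s) for s in pairs["np_symbol"]} | {
        _norm_symbol(s) for s in pairs["npr_symbol"]
    }
    for np_sym, npr_syms in panel2.items():
        for sym in [np_sym, *npr_syms]:
            if _norm_symbol(sym) not in known:
                raise ValidationError(
                    f"network-panel gene {sym!r} is absent from the pair table"
                )
            if sym not in set(pairs["np_symbol"]) | set(pairs["npr_symbol"]):
                report.append(
                    f"network-panel symbol {sym!r} matches the pair table only "
                    f"after case/alias normalization"
                )
    return report


def load_panel(pairs_path: str | Path | None = None,
               panel2_path: str | Path | None = None) -> GenePanel:
    """Load a gene panel; with no arguments, the packaged curated tables."""
    if pairs_path is None:
        pairs_path = resources.files("pepregnet.data") / "np_npr_pairs.tsv"
    if panel2_path is None:
        panel2_path = resources.files("pepregnet.data") / "network_panel.tsv"
    pairs = pd.read_csv(pairs_path, sep="\t", dtype=str)
    expected = ["np_symbol", "np_flybase_id", "npr_symbol", "npr_flybase_id"]
    if list(pairs.columns) != expected:
        raise FormatError(f"pair table must have columns {expected}, got {list(pairs.columns)}")
    net = pd.read_csv(panel2_path, sep="\t", dtype=str)
    panel2: dict[str, list[str]] = {}
    for np_sym, npr_sym in net.itertuples(index=False):
        panel2.setdefault(np_sym, []).append(npr_sym)
    report = _validate_panel(pairs, panel2)
    return GenePanel(pairs=pairs, panel2=panel2, validation_report=report)


# ---------------------------------------------------------------------------
# expression matrices

META_COLUMNS = ["tissue", "annotation", "age_days", "sex"]


@dataclass
class ExpressionMatrix:
    """Cells x genes UMI count matrix with per-cell metadata."""

    cell_ids: np.ndarray  # (n_cells,) str
    gene_ids: np.ndarray  # (n_genes,) str
    counts: np.ndarray  # (n_cells, n_genes) non-negative int
    cell_meta: pd.DataFrame  # indexed by cell_id; tissue, annotation, age_days, sex

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=str)
        self.gene_ids = np.asarray(self.gene_ids, dtype=str)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.cell_ids.size, self.gene_ids.size):
            raise ValidationError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{self.cell_ids.size} cells x {self.gene_ids.size} genes"
            )
        if np.any(self.counts < 0):
            raise ValidationError("negative counts are not allowed")
        if len(set(self.cell_ids)) != self.cell_ids.size:
            raise ValidationError("cell_ids are not unique")
        if len(set(self.gene_ids)) != self.gene_ids.size:
            raise ValidationError("gene_ids are not unique")
        missing = [c for c in META_COLUMNS if c not in self.cell_meta.columns]
        if missing:
            raise ValidationError(f"cell_meta lacks columns {missing}")
        if not np.array_equal(np.asarray(self.cell_meta.index, dtype=str), self.cell_ids):
            raise ValidationError("cell_meta index must equal cell_ids, in order")

    @property
    def n_cells(self) -> int:
        return self.cell_ids.size

    @property
    def n_genes(self) -> int:
        return self.gene_ids.size

    def gene_index(self, genes) -> np.ndarray:
        """Column indices of ``genes`` (error on unknown genes)."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as e:
            raise KeyError(f"gene {e.args[0]!r} not in matrix") from None

    def subset_cells(self, cell_ids) -> "ExpressionMatrix":
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        idx = np.array([lookup[c] for c in cell_ids], dtype=int)
        return ExpressionMatrix(
            cell_ids=self.cell_ids[idx],
            gene_ids=self.gene_ids,
            counts=self.counts[idx],
            cell_meta=self.cell_meta.iloc[idx],
        )


def write_expression(m: ExpressionMatrix, outdir: str | Path, fmt: str = "mtx") -> None:
    """Write a matrix as MTX triplet (+ cells.tsv/genes.tsv) or dense TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if fmt == "mtx":
        sparse = scipy.sparse.coo_matrix(m.counts)
        scipy.io.mmwrite(outdir / "matrix.mtx", sparse, field="integer")
        pd.Series(m.gene_ids, name="gene_id").to_csv(
            outdir / "genes.tsv", sep="\t", index=False
        )
        meta = m.cell_meta.copy()
        meta.insert(0, "cell_id", m.cell_ids)
        meta.to_csv(outdir / "cells.tsv", sep="\t", index=False)
    elif fmt == "dense_tsv":
        df = pd.DataFrame(m.counts, index=pd.Index(m.cell_ids, name="cell_id"),
                          columns=m.gene_ids)
        df.to_csv(outdir / "matrix.tsv", sep="\t")
        meta = m.cell_meta.copy()
        meta.insert(0, "cell_id", m.cell_ids)
        meta.to_csv(outdir / "cells.tsv", sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_expression(path: str | Path, fmt: str = "mtx") -> ExpressionMatrix:
    """Load an expression matrix written by :func:`write_expression`."""
    path = Path(path)
    meta = pd.read_csv(path / "cells.tsv", sep="\t", dtype={"cell_id": str})
    meta = meta.set_index("cell_id")
    if fmt == "mtx":
        try:
            counts = scipy.io.mmread(path / "matrix.mtx")
        except ValueError as e:
            raise FormatError(f"malformed MTX file: {e}") from e
        counts = np.asarray(counts.todense())
        genes = pd.read_csv(path / "genes.tsv", sep="\t", dtype=str)["gene_id"].to_numpy()
        if counts.shape != (len(meta), len(genes)):
            raise FormatError(
                f"MTX dimensions {counts.shape} do not match index files "
                f"({len(meta)} cells, {len(genes)} genes)"
            )
    elif fmt == "dense_tsv":
        df = pd.read_csv(path / "matrix.tsv", sep="\t", index_col="cell_id")
        counts = df.to_numpy()
        genes = df.columns.to_numpy(dtype=str)
        if not np.array_equal(np.asarray(df.index, dtype=str),
                              np.asarray(meta.index, dtype=str)):
            raise FormatError("dense TSV cell order does not match cells.tsv")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if np.any(counts < 0):
        raise ValidationError("negative count encountered")
    return ExpressionMatrix(
        cell_ids=np.asarray(meta.index, dtype=str),
        gene_ids=genes,
        counts=counts.astype(np.int64),
        cell_meta=meta,
    )


# ---------------------------------------------------------------------------
# interval annotations (BED-like TSV; 0-based half-open)


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann[["gene", "kind", "start", "end"]].to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    missing = [c for c in ("gene", "kind", "start", "end") if c not in ann.columns]
    if missing:
        raise FormatError(f"annotation lacks columns {missing}")
    bad_kind = set(ann["kind"]) - set(ANNOTATION_KINDS)
    if bad_kind:
        raise ValidationError(f"unknown annotation kind(s): {sorted(bad_kind)}")
    if (ann["end"] <= ann["start"]).any():
        raise ValidationError("annotation intervals must satisfy end > start")
    return ann


# ---------------------------------------------------------------------------
# qPCR Ct tables (CSV)


def write_ct_table(ct: pd.DataFrame, path: str | Path) -> None:
    ct[CT_COLUMNS].to_csv(path, index=False)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    ct = pd.read_csv(path)
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise FormatError(f"Ct table lacks columns {missing}")
    if (ct["ct"] <= 0).any():
        raise ValidationError("Ct values must be positive")
    return ct


# ---------------------------------------------------------------------------
# regulons (GMT-like: tf <tab> motif <tab> context <tab> target ...)


def write_regulons(regulons: list[Regulon], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regulons:
            targets = "\t".join(sorted(r.targets))
            fh.write(f"{r.tf}\t{r.motif_id}\t{r.context}\t{targets}\n")


def read_regulons(path: str | Path) -> list[Regulon]:
    regulons = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise FormatError(f"line {lineno}: regulon line needs >= 4 fields")
            tf, motif_id, context, *targets = parts
            regulons.append(Regulon(tf=tf, targets=frozenset(targets),
                                    motif_id=motif_id, context=context))
    return regulons


# ---------------------------------------------------------------------------
# importance tables (TSV)

IMPORTANCE_COLUMNS = ["tf", "target", "importance"]


def write_importance(imp: pd.DataFrame, path: str | Path) -> None:
    imp.to_csv(path, sep="\t", index=False)


def read_importance(path: str | Path) -> pd.DataFrame:
    imp = pd.read_csv(path, sep="\t")
    missing = [c for c in IMPORTANCE_COLUMNS if c not in imp.columns]
    if missing:
        raise FormatError(f"importance table lacks columns {missing}")
    if (imp["importance"] < 0).any():
        raise ValidationError("importances must be non-negative")
    return imp


# ---------------------------------------------------------------------------
# synthetic dataset bundles


def write_dataset(ds, outdir: str | Path) -> None:
    """Write a SyntheticDataset: MTX bundle, motif support, planted truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression(ds.matrix, outdir, fmt="mtx")
    ds.motif_support.to_csv(outdir / "motif_support.tsv", sep="\t", index=False)
    truth = {
        "edges": sorted([tf, tgt] for tf, tgt in ds.truth_edges),
        "regulons": [
            {"tf": r.tf, "motif_id": r.motif_id, "context": r.context,
             "targets": sorted(r.targets)}
            for r in ds.truth_regulons
        ],
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


def load_dataset(path: str | Path):
    """Load the parts of a dataset bundle needed downstream."""
    path = Path(path)
    matrix = load_expression(path, fmt="mtx")
    motif_support = pd.read_csv(path / "motif_support.tsv", sep="\t")
    truth = json.loads((path / "truth.json").read_text())
    truth_edges = {(tf, tgt) for tf, tgt in truth["edges"]}
    truth_regulons = [
        Regulon(tf=r["tf"], targets=frozenset(r["targets"]),
                motif_id=r["motif_id"], context=r["context"])
        for r in truth["regulons"]
    ]
    return matrix, motif_support, truth_edges, truth_regulons
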