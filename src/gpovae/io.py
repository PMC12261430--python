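"""Reading, writing and preprocessing of Perturb-Seq style count data.

A dataset is a cells x genes integer UMI count matrix with a per-cell
treatment label (the symbol of the CRISPR-targeted gene, or ``"control"``),
a binary QC/artifact flag ``A`` and per-cell library sizes ``L``.  Two
container dialects are supported: AnnData ``.h5ad`` and a MatrixMarket trio
(``matrix.mtx`` + ``genes.tsv`` + ``cells.tsv``).

Preprocessing follows the standard interventional-benchmark recipe: annotate
cells with six configurable QC criteria, drop treatments whose on-target
knockdown is too weak to be a credible intervention, and build the gene
vocabulary: the perturbed set G° (genes with interventional cells) plus the
extended set G+ (unperturbed genes passing a differential-expression cutoff),
over which the causal-probability matrix is defined.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

CONTROL_LABEL = "control"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class QCConfig:
    """Six per-cell quality-control criteria (all configurable).

    A cell passes QC iff it satisfies every criterion; ``A = 1`` marks
    failure (artifact present).  Defaults follow common droplet-RNA-seq
    filtering guidelines; they target real datasets with thousands of genes
    and should be relaxed for small simulated gene panels.
    """

    min_counts: float = 500.0           # (1) min total UMI counts per cell
    max_counts: float = 50_000.0        # (2) max total UMI counts per cell
    min_genes: float = 200.0            # (3) min detected genes per cell
    max_genes: float = 8_000.0          # (4) max detected genes per cell
    max_mito_fraction: float = 0.2      # (5) max mitochondrial count fraction
    max_top50_fraction: float = 0.5     # (6) max count fraction in top-50 genes
    mito_prefix: str = "MT-"
    top_n_genes: int = 50

    def __post_init__(self):
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and not np.isfinite(v):
                raise ValueError(f"QC threshold {f.name} must be finite")


@dataclass
class GeneVocabulary:
    """The perturbed (G°) and extended (G+) gene sets and their column order.

    The causal matrix lives on G°∪G+ with perturbed genes first, each block
    lexicographic, so its block structure is reproducible.
    """

    all_genes: list[str]
    perturbed: list[str]
    extended: list[str]

    def __post_init__(self):
        if set(self.perturbed) & set(self.extended):
            raise ValueError("perturbed and extended gene sets must be disjoint")
        missing = (set(self.perturbed) | set(self.extended)) - set(self.all_genes)
        if missing:
            raise ValueError(f"vocabulary genes absent from dataset: {sorted(missing)}")
        self.perturbed = sorted(self.perturbed)
        self.extended = sorted(self.extended)
        self.index: dict[str, int] = {
            g: i for i, g in enumerate(self.perturbed + self.extended)
        }

    @property
    def genes(self) -> list[str]:
        """G°∪G+ in column order."""
        return self.perturbed + self.extended

    @property
    def size(self) -> int:
        return len(self.index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "set": ["perturbed"] * len(self.perturbed)
                + ["extended"] * len(self.extended),
            }
        )

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class PerturbDataset:
    """Counts X, treatment one-hots P, artifact flags A and library sizes L."""

    X: np.ndarray
    gene_names: list[str]
    treatment_labels: np.ndarray
    A: np.ndarray | None = None
    P: np.ndarray | None = None
    vocab: GeneVocabulary | None = None
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X)
        if sparse.issparse(self.X):  # pragma: no cover - defensive
            self.X = self.X.toarray()
        if not np.issubdtype(self.X.dtype, np.integer):
            if not np.allclose(self.X, np.round(self.X)):
                raise ValueError("count matrix must hold integer UMI counts")
            self.X = self.X.astype(np.int64)
        if (self.X < 0).any():
            raise ValueError("counts must be non-negative")
        self.treatment_labels = np.asarray(self.treatment_labels, dtype=object)
        if self.treatment_labels.shape[0] != self.X.shape[0]:
            raise ValueError("one treatment label per cell required")
        if self.A is None:
            self.A = np.zeros(self.X.shape[0], dtype=np.int8)
        self.A = np.asarray(self.A).astype(np.int8).ravel()
        if not set(np.unique(self.A)) <= {0, 1}:
            raise ValueError("A must be binary")
        if not self.cell_ids:
            self.cell_ids = [f"cell{i}" for i in range(self.X.shape[0])]
        self.gene_names = list(self.gene_names)

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    @property
    def L(self) -> np.ndarray:
        """Library sizes, always recomputed as row sums of X."""
        return self.X.sum(axis=1)

    @property
    def is_control(self) -> np.ndarray:
        return self.treatment_labels == CONTROL_LABEL

    def treatments(self) -> list[str]:
        """Distinct non-control target genes, sorted."""
        return sorted(set(self.treatment_labels) - {CONTROL_LABEL})

    def subset(self, idx) -> "PerturbDataset":
        idx = np.asarray(idx)
        return PerturbDataset(
            X=self.X[idx],
            gene_names=self.gene_names,
            treatment_labels=self.treatment_labels[idx],
            A=self.A[idx],
            P=None if self.P is None else self.P[idx],
            vocab=self.vocab,
            cell_ids=[self.cell_ids[i] for i in idx],
        )


def lognorm(X: np.ndarray, target_sum: float = 1e4) -> np.ndarray:
    """log1p of counts-per-``target_sum`` library-size normalization."""
    X = np.asarray(X, dtype=np.float64)
    lib = X.sum(axis=1, keepdims=True)
    lib = np.where(lib > 0, lib, 1.0)
    return np.log1p(X / lib * target_sum)


# ---------------------------------------------------------------------------
# container I/O
# ---------------------------------------------------------------------------

_TARGET_COL = "target_gene"
_QC_COL = "qc_fail"


def load_dataset(path: str, format: str | None = None) -> PerturbDataset:
    """Load a Perturb-Seq container (``h5ad`` or an ``mtx_dir`` trio).

    The cell metadata must name the perturbation target in a ``target_gene``
    column (literal ``"control"`` for control cells).  Library sizes are
    recomputed from the counts regardless of any stored annotation.
    """
    if format is None:
        format = "mtx_dir" if os.path.isdir(path) else "h5ad"
    if format == "h5ad":
        import anndata

        adata = anndata.read_h5ad(path)
        if _TARGET_COL not in adata.obs.columns:
            raise ValueError(
                f"cell metadata must contain a '{_TARGET_COL}' column naming the "
                "perturbation target ('control' for controls)"
            )
        X = adata.X.toarray() if sparse.issparse(adata.X) else np.asarray(adata.X)
        A = (
            adata.obs[_QC_COL].to_numpy().astype(np.int8)
            if _QC_COL in adata.obs.columns
            else None
        )
        return PerturbDataset(
            X=X,
            gene_names=list(adata.var_names),
            treatment_labels=adata.obs[_TARGET_COL].to_numpy(),
            A=A,
            cell_ids=list(adata.obs_names),
        )
    if format == "mtx_dir":
        X = spio.mmread(os.path.join(path, "matrix.mtx"))
        X = X.toarray() if sparse.issparse(X) else np.asarray(X)
        genes = pd.read_csv(os.path.join(path, "genes.tsv"), sep="\t")
        cells = pd.read_csv(os.path.join(path, "cells.tsv"), sep="\t")
        if _TARGET_COL not in cells.columns:
            raise ValueError(f"cells.tsv must contain a '{_TARGET_COL}' column")
        A = cells[_QC_COL].to_numpy().astype(np.int8) if _QC_COL in cells.columns else None
        return PerturbDataset(
            X=X,
            gene_names=list(genes["gene"]),
            treatment_labels=cells[_TARGET_COL].to_numpy(),
            A=A,
            cell_ids=list(cells["cell_id"].astype(str)),
        )
    raise ValueError(f"unknown format {format!r}")


def write_dataset(dataset: PerturbDataset, path: str, format: str = "mtx_dir") -> None:
    """Write a dataset as ``.h5ad`` or a MatrixMarket trio (cells x genes)."""
    if format == "h5ad":
        import anndata

        adata = anndata.AnnData(
            X=dataset.X.astype(np.int64),
            obs=pd.DataFrame(
                {
                    _TARGET_COL: dataset.treatment_labels.astype(str),
                    _QC_COL: dataset.A.astype(int),
                },
                index=dataset.cell_ids,
            ),
            var=pd.DataFrame(index=dataset.gene_names),
        )
        adata.write_h5ad(path)
        return
    if format == "mtx_dir":
        os.makedirs(path, exist_ok=True)
        spio.mmwrite(os.path.join(path, "matrix.mtx"), sparse.coo_matrix(dataset.X))
        pd.DataFrame({"gene": dataset.gene_names}).to_csv(
            os.path.join(path, "genes.tsv"), sep="\t", index=False
        )
        pd.DataFrame(
            {
                "cell_id": dataset.cell_ids,
                _TARGET_COL: dataset.treatment_labels.astype(str),
                _QC_COL: dataset.A.astype(int),
            }
        ).to_csv(os.path.join(path, "cells.tsv"), sep="\t", index=False)
        return
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# QC annotation
# ---------------------------------------------------------------------------

def qc_criteria_table(dataset: PerturbDataset, qc: QCConfig | None = None) -> pd.DataFrame:
    """Per-cell boolean table, one column per criterion (True = fail)."""
    qc = qc or QCConfig()
    X = dataset.X.astype(np.float64)
    total = X.sum(axis=1)
    detected = (X > 0).sum(axis=1)
    is_mito = np.array(
        [g.upper().startswith(qc.mito_prefix.upper()) for g in dataset.gene_names]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, X[:, is_mito].sum(axis=1) / np.maximum(total, 1), 0.0)
        k = min(qc.top_n_genes, X.shape[1])
        top_counts = np.sort(X, axis=1)[:, -k:].sum(axis=1)
        top_frac = np.where(total > 0, top_counts / np.maximum(total, 1), 1.0)
    return pd.DataFrame(
        {
            "fail_min_counts": total < qc.min_counts,
            "fail_max_counts": total > qc.max_counts,
            "fail_min_genes": detected < qc.min_genes,
            "fail_max_genes": detected > qc.max_genes,
            "fail_mito_fraction": mito_frac > qc.max_mito_fraction,
            "fail_top50_fraction": top_frac > qc.max_top50_fraction,
        },
        index=dataset.cell_ids,
    )


def annotate_qc(dataset: PerturbDataset, qc: QCConfig | None = None) -> PerturbDataset:
    """Set ``A[n] = 0`` iff cell *n* passes all six criteria, else 1."""
    table = qc_criteria_table(dataset, qc)
    out = dataset.subset(np.arange(dataset.n_cells))
    out.A = table.to_numpy().any(axis=1).astype(np.int8)
    return out


# ---------------------------------------------------------------------------
# weak-perturbation exclusion
# ---------------------------------------------------------------------------

def knockdown_fractions(dataset: PerturbDataset) -> pd.DataFrame:
    """On-target knockdown per treatment: 1 - mean_treated/mean_control, in [0,1]."""
    ctrl = dataset.is_control
    if not ctrl.any():
        raise ValueError("dataset has no control cells")
    norm = lognorm(dataset.X)
    # knockdown measured on library-normalized (linear) expression
    lin = np.expm1(norm)
    rows = []
    gene_pos = {g: i for i, g in enumerate(dataset.gene_names)}
    for t in dataset.treatments():
        if t not in gene_pos:
            raise ValueError(f"treatment target {t!r} is not a measured gene")
        j = gene_pos[t]
        mask = dataset.treatment_labels == t
        mean_t = lin[mask, j].mean()
        mean_c = lin[ctrl, j].mean()
        kd = 1.0 if mean_c <= 0 else np.clip(1.0 - mean_t / mean_c, 0.0, 1.0)
        rows.append({"treatment": t, "knockdown": kd, "n_cells": int(mask.sum())})
    return pd.DataFrame(rows)


def filter_weak_perturbations(
    dataset: PerturbDataset, min_knockdown_fraction: float = 0.3
) -> tuple[PerturbDataset, pd.DataFrame]:
    """Drop all cells of treatments with on-target knockdown below threshold.

    Control cells are never removed.  Returns the filtered dataset and a
    report with per-treatment knockdown and removal status.
    """
    report = knockdown_fractions(dataset)
    report["removed"] = report["knockdown"] < min_knockdown_fraction
    weak = set(report.loc[report["removed"], "treatment"])
    keep = np.array(
        [lab == CONTROL_LABEL or lab not in weak for lab in dataset.treatment_labels]
    )
    return dataset.subset(np.where(keep)[0]), report


# ---------------------------------------------------------------------------
# vocabulary
# ---------------------------------------------------------------------------

def build_gene_vocabulary(
    dataset: PerturbDataset,
    logfc_cutoff: float = 1.0,
    adj_p_cutoff: float = 0.05,
) -> GeneVocabulary:
    """Construct G° (treatment targets) and G+ (pooled-DE passing genes).

    Extended genes are those not perturbed whose pooled treated-vs-control
    Wilcoxon rank-sum test on log1p-normalized counts passes
    ``|log2FC| >= logfc_cutoff`` and BH-adjusted ``p < adj_p_cutoff``.
    """
    ctrl = dataset.is_control
    if not ctrl.any():
        raise ValueError("dataset has no control cells")
    if ctrl.all():
        raise ValueError("dataset has no treated cells")
    perturbed = dataset.treatments()
    norm = lognorm(dataset.X)
    treated = ~ctrl
    lin_t = np.expm1(norm[treated]).mean(axis=0)
    lin_c = np.expm1(norm[ctrl]).mean(axis=0)
    logfc = np.log2((lin_t + 1.0) / (lin_c + 1.0))
    pvals = np.ones(dataset.n_genes)
    for j in range(dataset.n_genes):
        a, b = norm[treated, j], norm[ctrl, j]
        if np.ptp(np.concatenate([a, b])) == 0:
            continue
        pvals[j] = stats.ranksums(a, b).pvalue
    adj = multipletests(pvals, method="fdr_bh")[1]
    perturbed_set = set(perturbed)
    extended = [
        g
        for j, g in enumerate(dataset.gene_names)
        if g not in perturbed_set
        and abs(logfc[j]) >= logfc_cutoff
        and adj[j] < adj_p_cutoff
    ]
    return GeneVocabulary(
        all_genes=list(dataset.gene_names), perturbed=perturbed, extended=extended
    )


def encode_treatments(dataset: PerturbDataset, vocab: GeneVocabulary) -> PerturbDataset:
    """Attach the N x |G°∪G+| one-hot treatment matrix P (control rows zero)."""
    P = np.zeros((dataset.n_cells, vocab.size), dtype=np.float64)
    for n, lab in enumerate(dataset.treatment_labels):
        if lab == CONTROL_LABEL:
            continue
        if lab not in vocab.index or lab not in vocab.perturbed:
            raise ValueError(f"treatment target {lab!r} not in perturbed vocabulary")
        P[n, vocab.index[lab]] = 1.0
    out = dataset.subset(np.arange(dataset.n_cells))
    out.P = P
    out.vocab = vocab
    return out
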