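"""Prediction metrics and statistical GRN evaluation.

Prediction quality compares predicted vs observed average treatment effects:
Pearson correlation (ATE-ρ), coefficient of determination (ATE-R², which is
unbounded below), and Jaccard similarity of the top-k |ATE| gene sets.

The GRN read out of the causal matrix (strict probability > threshold, so a
fresh 0.5-initialized matrix has zero edges) is scored without ground truth,
against the interventional data itself: μWD is the mean over inferred edges
A→B of the 1-D Wasserstein-1 distance between the expression of B in
control cells and in A-perturbed cells, and FOR is the fraction of inferred
non-edges whose perturbation effect is nonetheless statistically significant
(Mann-Whitney U with Benjamini-Hochberg correction over all candidate
pairs).  Expression enters both on the log1p CP10K scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gpo import CausalParamMatrix
from .io import PerturbDataset, lognorm


# ---------------------------------------------------------------------------
# prediction metrics
# ---------------------------------------------------------------------------

def _values(x) -> np.ndarray:
    return np.asarray(getattr(x, "values", x), dtype=np.float64)


def ate_pearson(pred, obs) -> float | None:
    """Pearson r between predicted and observed ATE profiles (None if undefined)."""
    p, o = _values(pred), _values(obs)
    if p.shape != o.shape:
        raise ValueError("profiles must share the gene universe and ordering")
    if p.std() == 0 or o.std() == 0:
        return None
    return float(stats.pearsonr(p, o)[0])


def ate_r2(pred, obs) -> float | None:
    """Coefficient of determination of obs against pred; unbounded below."""
    p, o = _values(pred), _values(obs)
    if p.shape != o.shape:
        raise ValueError("profiles must share the gene universe and ordering")
    ss_tot = float(((o - o.mean()) ** 2).sum())
    if ss_tot == 0:
        return None
    ss_res = float(((o - p) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def _top_k(values: np.ndarray, k: int) -> set[int]:
    order = np.lexsort((np.arange(values.size), -np.abs(values)))
    return set(order[:k].tolist())


def jaccard_top_k(pred, obs, k: int = 50) -> float:
    """|top-k(pred) ∩ top-k(obs)| / |union|, ranking by |ATE| (ties by gene order)."""
    p, o = _values(pred), _values(obs)
    if k > p.size:
        raise ValueError(f"k={k} exceeds the number of genes ({p.size})")
    a, b = _top_k(p, k), _top_k(o, k)
    return len(a & b) / len(a | b)


# ---------------------------------------------------------------------------
# GRN extraction and statistical evaluation
# ---------------------------------------------------------------------------

@dataclass
class GRN:
    """Thresholded directed graph over the vocabulary genes."""

    edges: pd.DataFrame          # columns: source, target, weight
    genes: list[str]
    threshold: float
    restrict: str = "all"

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["source"], self.edges["target"]))

    def write_tsv(self, path: str) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str, genes: list[str] | None = None,
                 threshold: float = 0.5) -> "GRN":
        edges = pd.read_csv(path, sep="\t")
        genes = genes or sorted(set(edges["source"]) | set(edges["target"]))
        return cls(edges=edges, genes=genes, threshold=threshold)


@dataclass
class GRNEvalReport:
    """Statistical GRN evaluation: μWD, FOR (−1 sentinel) and edge count."""

    mu_wd: float
    for_rate: float
    n_edges: int
    per_edge: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        return {"mu_wd": self.mu_wd, "for_rate": self.for_rate, "n_edges": self.n_edges}


def extract_grn(
    params, threshold: float = 0.5, restrict: str = "all",
    genes: list[str] | None = None,
) -> GRN:
    """Edges are entries with probability strictly above the threshold.

    ``restrict="perturbed_only"`` drops edges touching an extended gene (the
    benchmark-comparability mode); it requires ``params`` to be a
    :class:`CausalParamMatrix` built from a vocabulary or an explicit gene
    list plus a perturbed-gene prefix convention via ``genes``.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if isinstance(params, CausalParamMatrix):
        probs = params.probabilities
        genes = genes or params.genes
    else:
        probs = np.asarray(params, dtype=np.float64)
        genes = genes or [f"g{i}" for i in range(probs.shape[0])]
    src, tgt = np.nonzero(probs > threshold)
    edges = pd.DataFrame(
        {
            "source": [genes[i] for i in src],
            "target": [genes[j] for j in tgt],
            "weight": probs[src, tgt],
        }
    )
    return GRN(edges=edges, genes=list(genes), threshold=threshold, restrict=restrict)


def restrict_to_perturbed(grn: GRN, perturbed: list[str]) -> GRN:
    """Drop every edge touching a gene outside the perturbed set G°."""
    keep = set(perturbed)
    edges = grn.edges[
        grn.edges["source"].isin(keep) & grn.edges["target"].isin(keep)
    ].reset_index(drop=True)
    return GRN(edges=edges, genes=[g for g in grn.genes if g in keep],
               threshold=grn.threshold, restrict="perturbed_only")


def _expression_groups(dataset: PerturbDataset):
    norm = lognorm(dataset.X)
    gene_pos = {g: i for i, g in enumerate(dataset.gene_names)}
    ctrl = norm[dataset.is_control]
    groups = {t: norm[dataset.treatment_labels == t] for t in dataset.treatments()}
    return norm, gene_pos, ctrl, groups


def mean_wasserstein(grn: GRN, dataset: PerturbDataset) -> tuple[float, pd.DataFrame]:
    """μWD over evaluable edges (source has interventional cells); 0.0 if none."""
    if not dataset.is_control.any():
        raise ValueError("dataset has no control cells")
    _, gene_pos, ctrl, groups = _expression_groups(dataset)
    rows = []
    for src, tgt in zip(grn.edges["source"], grn.edges["target"]):
        if src not in groups or tgt not in gene_pos:
            rows.append({"source": src, "target": tgt, "wd": np.nan,
                         "evaluable": False})
            continue
        j = gene_pos[tgt]
        wd = stats.wasserstein_distance(ctrl[:, j], groups[src][:, j])
        rows.append({"source": src, "target": tgt, "wd": wd, "evaluable": True})
    table = pd.DataFrame(rows, columns=["source", "target", "wd", "evaluable"])
    evaluable = table[table["evaluable"] == True]  # noqa: E712
    mu = float(evaluable["wd"].mean()) if len(evaluable) else 0.0
    return mu, table


def false_omission_rate(
    grn: GRN, dataset: PerturbDataset, fdr: float = 0.05
) -> float:
    """FOR = significant non-edges / all non-edges over interventional pairs.

    Candidates are ordered pairs (i, j), i ≠ j, with i perturbed in the
    data and both genes in the GRN's universe.  Returns −1 when the GRN
    leaves no negative pairs.
    """
    if not dataset.is_control.any():
        raise ValueError("dataset has no control cells")
    _, gene_pos, ctrl, groups = _expression_groups(dataset)
    universe = [g for g in grn.genes if g in gene_pos]
    sources = [g for g in universe if g in groups]
    candidates = [(i, j) for i in sources for j in universe if i != j]
    if not candidates:
        return -1.0
    pvals = np.ones(len(candidates))
    for k, (i, j) in enumerate(candidates):
        a, b = groups[i][:, gene_pos[j]], ctrl[:, gene_pos[j]]
        if np.ptp(np.concatenate([a, b])) == 0:
            continue
        pvals[k] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    significant = multipletests(pvals, alpha=fdr, method="fdr_bh")[0]
    edge_set = grn.edge_set()
    negatives = np.array([(i, j) not in edge_set for i, j in candidates])
    n_neg = int(negatives.sum())
    if n_neg == 0:
        return -1.0
    fn = int((negatives & significant).sum())
    return fn / n_neg


def evaluate_grn(grn: GRN, dataset: PerturbDataset, fdr: float = 0.05) -> GRNEvalReport:
    mu, table = mean_wasserstein(grn, dataset)
    rate = false_omission_rate(grn, dataset, fdr=fdr)
    return GRNEvalReport(mu_wd=mu, for_rate=rate, n_edges=grn.n_edges, per_edge=table)


def hub_genes(params, degree_threshold: float = 0.3, top_n: int = 3,
              genes: list[str] | None = None) -> list[str]:
    """Top genes by combined in+out degree after binarizing at the threshold.

    Genes with zero degree are never ranked; ties break by gene order.
    """
    if isinstance(params, CausalParamMatrix):
        probs = params.probabilities
        genes = genes or params.genes
    elif isinstance(params, GRN):
        genes = genes or params.genes
        pos = {g: i for i, g in enumerate(genes)}
        probs = np.zeros((len(genes), len(genes)))
        for s, t, w in zip(params.edges["source"], params.edges["target"],
                           params.edges["weight"]):
            probs[pos[s], pos[t]] = w
    else:
        probs = np.asarray(params, dtype=np.float64)
        genes = genes or [f"g{i}" for i in range(probs.shape[0])]
    binary = probs > degree_threshold
    degree = binary.sum(axis=0) + binary.sum(axis=1)
    order = np.lexsort((np.arange(len(genes)), -degree))
    ranked = [genes[i] for i in order if degree[i] > 0]
    return ranked[:top_n]
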