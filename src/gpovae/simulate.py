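"""Synthetic Perturb-Seq generator with a known ground-truth causal network.

The generator emulates the features of interventional single-cell screens
that the model and its evaluation depend on: a sparse directed gene network
(self-loops allowed, no acyclicity constraint), strong on-target knockdown,
perturbation effects that propagate along multi-hop directed paths with a
1/|G°∪G+| damping per extra hop, Gamma-Poisson (negative-binomial) UMI
counts with log-normal library sizes, and a configurable fraction of
artifact-bearing cells whose counts are globally scaled (a library-size
distortion, the simplest QC-detectable artifact).

Edge signs are drawn with a per-target consensus: each target gene has a
preferred response direction which incoming edges follow with probability
``sign_consistency``.  This mirrors the correlated response programs of real
perturbation screens; with fully independent per-edge signs the response of
a held-out perturbation would be unidentifiable in principle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CONTROL_LABEL, GeneVocabulary, PerturbDataset


@dataclass
class SimulationConfig:
    """Study conditions for one simulated screen."""

    n_perturbed: int = 20
    n_extended: int = 10
    n_other_genes: int = 20
    cells_per_treatment: int = 200
    n_control: int = 200
    edge_density: float = 0.1
    max_hops: int = 5
    baseline_mean_range: tuple[float, float] = (5.0, 200.0)
    dispersion: float = 10.0            # Gamma-Poisson theta
    artifact_rate: float = 0.05
    artifact_effect: float = 2.0        # global count scaling of artifact cells
    on_target_knockdown: float = 0.8
    effect_range: tuple[float, float] = (0.5, 2.0)
    sign_consistency: float = 0.8
    n_hubs: int = 3                     # "shared response program" genes
    hub_probability: float = 0.85       # edge prob into and out of hub genes
    library_mean: float = 5_000.0
    library_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_perturbed", "cells_per_treatment", "n_control"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_extended < 0 or self.n_other_genes < 0:
            raise ValueError("gene counts must be non-negative")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must be in [0, 1]")

    @property
    def vocab_size(self) -> int:
        return self.n_perturbed + self.n_extended

    @property
    def n_genes(self) -> int:
        return self.vocab_size + self.n_other_genes

    def gene_names(self) -> tuple[list[str], list[str], list[str]]:
        width = max(2, len(str(self.n_genes)))
        pert = [f"PG{i:0{width}d}" for i in range(self.n_perturbed)]
        ext = [f"EG{i:0{width}d}" for i in range(self.n_extended)]
        other = [f"NG{i:0{width}d}" for i in range(self.n_other_genes)]
        return pert, ext, other

    def vocabulary(self) -> GeneVocabulary:
        pert, ext, other = self.gene_names()
        return GeneVocabulary(all_genes=pert + ext + other, perturbed=pert, extended=ext)


@dataclass
class GroundTruthGRN:
    """Planted directed network over G°∪G+ with signed effect sizes.

    ``effect_sizes[i, j]`` is the log-expression change of target *j* per
    unit knockdown of source *i*; its support is the adjacency support.
    """

    adjacency: np.ndarray
    effect_sizes: np.ndarray
    genes: list[str]

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency).astype(np.int8)
        self.effect_sizes = np.asarray(self.effect_sizes, dtype=np.float64)
        if self.adjacency.shape != self.effect_sizes.shape:
            raise ValueError("adjacency and effect_sizes shapes differ")
        if ((self.adjacency == 0) & (self.effect_sizes != 0)).any():
            raise ValueError("effect_sizes support exceeds adjacency support")

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def to_edge_frame(self) -> pd.DataFrame:
        src, tgt = np.nonzero(self.adjacency)
        return pd.DataFrame(
            {
                "source": [self.genes[i] for i in src],
                "target": [self.genes[j] for j in tgt],
                "effect": self.effect_sizes[src, tgt],
            }
        )

    def write_tsv(self, path: str) -> None:
        self.to_edge_frame().to_csv(path, sep="\t", index=False)


def sample_ground_truth_grn(config: SimulationConfig) -> GroundTruthGRN:
    """Draw a random directed network with expected density ``edge_density``."""
    V = config.vocab_size
    if config.edge_density > 0 and config.edge_density * V * V < 1:
        raise ValueError("edge_density too low: expected edge count below 1")
    rng = np.random.default_rng(config.seed)
    # degree heterogeneity: a few perturbed "hub" genes sit downstream of most
    # treatments (the shared response programs of real screens); the remaining
    # columns are thinned so the expected overall density stays edge_density
    p_edge = np.full((V, V), config.edge_density)
    n_hubs = min(config.n_hubs, config.n_perturbed)
    hubs = np.array([], dtype=np.int64)
    if n_hubs > 0 and config.hub_probability > config.edge_density:
        hubs = rng.choice(config.n_perturbed, size=n_hubs, replace=False)
        # hubs sit both downstream (dense column) and upstream (dense row) of
        # the network; edge_density keeps governing all non-hub entries
        p_edge[:, hubs] = config.hub_probability
        p_edge[hubs, :] = config.hub_probability
    adj = (rng.random((V, V)) < p_edge).astype(np.int8)
    lo, hi = config.effect_range
    magnitude = rng.uniform(lo, hi, size=(V, V))
    # per-target consensus direction, followed with prob sign_consistency
    target_sign = np.where(rng.random(V) < 0.5, 1.0, -1.0)
    follow = rng.random((V, V)) < config.sign_consistency
    sign = np.where(follow, target_sign[None, :], -target_sign[None, :])
    effects = adj * magnitude * sign
    return GroundTruthGRN(
        adjacency=adj, effect_sizes=effects, genes=config.vocabulary().genes
    )


def propagated_shifts(grn: GroundTruthGRN, max_hops: int) -> np.ndarray:
    """Summed path products over directed paths of length <= max_hops.

    ``S[i, j]`` is the log-expression shift of gene *j* per unit knockdown of
    gene *i*; a path of length k is damped by ``V^-(k-1)`` with
    V = |G°∪G+|, matching the K-hop accumulation used by the model.
    """
    if max_hops < 1:
        raise ValueError("max_hops must be >= 1")
    F = grn.effect_sizes
    V = F.shape[0]
    S = np.zeros_like(F)
    term = np.eye(V)
    for _ in range(max_hops):
        term = term @ F
        S = S + term
        term = term / V
    return S


def simulate_perturbseq(
    grn: GroundTruthGRN, config: SimulationConfig
) -> tuple[PerturbDataset, GroundTruthGRN]:
    """Sample a full screen: controls, one block per treatment, artifacts."""
    vocab = config.vocabulary()
    if grn.adjacency.shape[0] != vocab.size:
        raise ValueError("GRN shape does not match config gene counts")
    rng = np.random.default_rng(config.seed + 1)
    S = propagated_shifts(grn, config.max_hops)
    kd = config.on_target_knockdown

    lo, hi = config.baseline_mean_range
    baseline = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_genes))

    labels: list[str] = [CONTROL_LABEL] * config.n_control
    shift_rows = [np.zeros(config.n_genes)] * config.n_control
    for i, gene in enumerate(vocab.perturbed):
        shift = np.zeros(config.n_genes)
        shift[: vocab.size] = kd * S[i]
        with np.errstate(divide="ignore"):  # kd=1 -> -inf -> expression 0
            shift[vocab.index[gene]] += np.log1p(-kd)
        labels.extend([gene] * config.cells_per_treatment)
        shift_rows.extend([shift] * config.cells_per_treatment)

    N = len(labels)
    shifts = np.vstack(shift_rows)
    props = baseline[None, :] * np.exp(shifts)
    props = props / props.sum(axis=1, keepdims=True)

    lib = rng.lognormal(np.log(config.library_mean), config.library_sigma, size=N)
    artifact = (rng.random(N) < config.artifact_rate).astype(np.int8)
    lib = lib * np.where(artifact == 1, config.artifact_effect, 1.0)

    mean = props * lib[:, None]
    theta = config.dispersion
    rate = rng.gamma(shape=theta, scale=mean / theta)
    X = rng.poisson(rate).astype(np.int64)

    P = np.zeros((N, vocab.size))
    for n, lab in enumerate(labels):
        if lab != CONTROL_LABEL:
            P[n, vocab.index[lab]] = 1.0

    dataset = PerturbDataset(
        X=X,
        gene_names=vocab.all_genes,
        treatment_labels=np.array(labels, dtype=object),
        A=artifact,
        P=P,
        vocab=vocab,
    )
    return dataset, grn


def true_ate_profiles(
    grn: GroundTruthGRN, config: SimulationConfig
) -> dict[str, np.ndarray]:
    """Analytic log-scale expected shift per treatment over all genes.

    Useful as the noiseless reference for treatment-effect recovery checks.
    """
    vocab = config.vocabulary()
    S = propagated_shifts(grn, config.max_hops)
    out = {}
    for i, gene in enumerate(vocab.perturbed):
        shift = np.zeros(config.n_genes)
        shift[: vocab.size] = config.on_target_knockdown * S[i]
        shift[vocab.index[gene]] += np.log1p(-config.on_target_knockdown)
        out[gene] = shift
    return out


def ot_pairing_fixture(
    n_treated: int, n_control: int, seed: int, dim: int = 3
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two small point clouds plus the brute-force optimal assignment.

    Enumerates all injective assignments of treated points to distinct
    controls (requires ``n_treated <= n_control``) and returns the one
    minimizing total squared-Euclidean cost.  Only feasible for tiny sizes.
    """
    if n_treated > 8 or n_control > 8:
        raise ValueError("fixture is brute-force only; sizes must be <= 8")
    if n_treated > n_control:
        raise ValueError("need n_treated <= n_control for injective assignment")
    rng = np.random.default_rng(seed)
    treated = rng.normal(size=(n_treated, dim))
    control = rng.normal(size=(n_control, dim))
    cost = ((treated[:, None, :] - control[None, :, :]) ** 2).sum(axis=2)
    best, best_cost = None, np.inf
    for perm in itertools.permutations(range(n_control), n_treated):
        c = cost[np.arange(n_treated), list(perm)].sum()
        if c < best_cost - 1e-12:
            best, best_cost = np.array(perm), c
    return treated, control, best
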