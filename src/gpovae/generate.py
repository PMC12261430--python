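"""Post-training generation and average-treatment-effect prediction.

Generation samples the basal state from its standard-normal prior, forms the
perturbation shift Zp from the trained causal matrix (fresh Bernoulli masks
and effect draws per generated cell) and decodes through the Gamma-Poisson
observation model.  Artifact-free generation sets Za to zero exactly — the
artifact posterior parameters are never touched, so the output is bitwise
independent of them.  Library sizes are resampled from the training
empirical distribution.

The ATE of a treatment is the per-gene difference of mean log1p CP10K
expression between generated treated and generated control populations; the
identical normalization applied to observed cells makes predicted and
observed profiles directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CONTROL_LABEL, PerturbDataset, lognorm
from .model import GPOVAE


@dataclass
class ATEProfile:
    """Per-gene average treatment effect on the log1p CP10K scale."""

    values: np.ndarray
    genes: list[str]
    treatment: str
    n_samples: int
    unseen: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "ate": self.values})

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _resolve_library(model: GPOVAE, library_sizes) -> np.ndarray:
    if library_sizes is None:
        library_sizes = getattr(model, "train_library_sizes", None)
    if library_sizes is None:
        raise ValueError(
            "no library sizes available: pass library_sizes or train the model first"
        )
    return np.asarray(library_sizes, dtype=np.float64)


def generate(
    model: GPOVAE,
    treatment: str,
    n_samples: int,
    artifact_free: bool = True,
    seed: int | np.random.Generator = 0,
    library_sizes: np.ndarray | None = None,
) -> np.ndarray:
    """Sample a count matrix of predicted cells under one treatment."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vocab = model.vocab
    d = model.config.latent_dim
    V = vocab.size
    if treatment != CONTROL_LABEL and treatment not in vocab.index:
        raise ValueError(f"unknown treatment {treatment!r} (not in G°∪G+ vocabulary)")

    lib_pool = _resolve_library(model, library_sizes)
    Zb = rng.standard_normal((n_samples, d))

    if treatment == CONTROL_LABEL:
        Zp = np.zeros((n_samples, V))
    else:
        j = vocab.index[treatment]
        probs = model.W.probabilities[j]
        mean_E, logvar = model.effect_posterior()
        mean_row = np.asarray(
            mean_E.data if hasattr(mean_E, "data") else mean_E)[j]
        sigma = float(np.exp(0.5 * np.asarray(
            logvar.data if hasattr(logvar, "data") else logvar).ravel()[0]))
        mask = (rng.random((n_samples, V)) < probs[None, :]).astype(np.float64)
        effects = mean_row[None, :] + sigma * rng.standard_normal((n_samples, V))
        Zp = mask * effects

    if artifact_free:
        Za = np.zeros((n_samples, d))
    else:
        u = model.mu_u.data + np.exp(
            0.5 * np.clip(model.logvar_u.data, -6, 6)) * rng.standard_normal(d)
        Za = np.ones((n_samples, 1)) * u[None, :]

    L = rng.choice(lib_pool, size=n_samples, replace=True)
    out = model.decode(Zb, Zp, Za, L, rng=rng)
    return out.counts


def average_treatment_effect(
    model: GPOVAE,
    treatment: str,
    n_samples: int = 2000,
    seed: int = 0,
    library_sizes: np.ndarray | None = None,
) -> ATEProfile:
    """Predicted ATE: generated-treated minus generated-control mean expression."""
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    X_t = generate(model, treatment, n_samples, artifact_free=True, seed=rng,
                   library_sizes=library_sizes)
    X_c = generate(model, CONTROL_LABEL, n_samples, artifact_free=True, seed=rng,
                   library_sizes=library_sizes)
    values = lognorm(X_t).mean(axis=0) - lognorm(X_c).mean(axis=0)
    return ATEProfile(values=values, genes=model.gene_names, treatment=treatment,
                      n_samples=n_samples)


def predict_unseen(
    model: GPOVAE,
    holdout_gene: str,
    n_samples: int = 2000,
    seed: int = 0,
    library_sizes: np.ndarray | None = None,
) -> ATEProfile:
    """ATE prediction for a treatment never seen in training.

    Identical generative path to :func:`average_treatment_effect`; the Ŵ row
    of the held-out gene exists (it is part of G°∪G+) even though no
    interventional cell informed it directly.
    """
    if holdout_gene not in model.vocab.index:
        raise ValueError(f"{holdout_gene!r} is outside the G°∪G+ vocabulary")
    profile = average_treatment_effect(
        model, holdout_gene, n_samples=n_samples, seed=seed,
        library_sizes=library_sizes)
    profile.unseen = True
    return profile


def observed_average_treatment_effect(
    dataset: PerturbDataset, treatment: str
) -> ATEProfile:
    """Empirical ATE of a treatment from observed cells (same normalization)."""
    mask = dataset.treatment_labels == treatment
    ctrl = dataset.is_control
    if not mask.any():
        raise ValueError(f"no cells with treatment {treatment!r}")
    if not ctrl.any():
        raise ValueError("dataset has no control cells")
    norm = lognorm(dataset.X)
    values = norm[mask].mean(axis=0) - norm[ctrl].mean(axis=0)
    return ATEProfile(values=values, genes=dataset.gene_names, treatment=treatment,
                      n_samples=int(mask.sum()))
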