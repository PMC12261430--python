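"""Stochastic variational training of the full objective J = -ELBO + αJade + βJgpo.

The causal matrix Ŵ receives gradients along two routes: through the
relaxed mask samples inside the ELBO, and through the GPO loss.  The DGE
reference ΔX is computed once from the training cells before the loop and
frozen.  Ablation switches restrict the GPO loss to its sparsity-only,
DGE-only or K-hop-only components to expose their individual optimization
dynamics.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _autodiff as ad
from .gpo import DEFAULT_K, DGEReference, _gpo_terms, build_dge_reference
from .io import CONTROL_LABEL, GeneVocabulary, PerturbDataset, encode_treatments
from .model import GPOVAE, ModelConfig


@dataclass
class TrainConfig:
    epochs: int = 40
    batch_size: int = 256
    lr: float = 1e-3
    w_lr: float = 3e-2          # separate Adam step size for the Ŵ logits
    w_betas: tuple[float, float] = (0.9, 0.9)  # short-memory moments for Ŵ
    optimizer: str = "adam"
    ablation: str = "full"
    temperature_start: float = 1.0
    temperature_end: float = 0.5
    seed: int = 0
    checkpoint_every: int = 0
    checkpoint_dir: str | None = None
    patience: int | None = None

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class TrainHistory:
    """Per-epoch loss components and GRN edge counts."""

    records: list[dict] = field(default_factory=list)
    diverged: bool = False

    def append(self, **kwargs) -> None:
        self.records.append(kwargs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def __len__(self) -> int:
        return len(self.records)


def split_dataset(
    dataset: PerturbDataset,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    stratify_by_treatment: bool = True,
    holdout_treatments: list[str] | None = None,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Train/val/test index sets, optionally holding treatments out entirely.

    Every cell of a held-out treatment goes to the test split; the remaining
    cells (controls included) are split per group when stratifying.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    holdout = list(holdout_treatments or [])
    present = set(dataset.treatments())
    missing = [g for g in holdout if g not in present]
    if missing:
        raise ValueError(f"holdout treatments absent from dataset: {missing}")
    rng = np.random.default_rng(seed)
    splits = {"train": [], "val": [], "test": []}
    labels = dataset.treatment_labels
    groups = [CONTROL_LABEL] + dataset.treatments() if stratify_by_treatment else [None]
    for g in groups:
        idx = np.where(labels == g)[0] if g is not None else np.arange(dataset.n_cells)
        if g in holdout:
            splits["test"].extend(idx)
            continue
        idx = rng.permutation(idx)
        n = idx.size
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        n_val = min(n_val, n - n_train)
        splits["train"].extend(idx[:n_train])
        splits["val"].extend(idx[n_train:n_train + n_val])
        splits["test"].extend(idx[n_train + n_val:])
    return {k: np.sort(np.array(v, dtype=np.int64)) for k, v in splits.items()}


def train(
    dataset: PerturbDataset,
    vocab: GeneVocabulary | None = None,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    dge_reference: DGEReference | None = None,
) -> tuple[GPOVAE, TrainHistory]:
    """Fit the model by minibatch Adam; deterministic given the seed."""
    tc = train_config or TrainConfig()
    mc = model_config or ModelConfig()
    vocab = vocab or dataset.vocab
    if vocab is None:
        raise ValueError("a gene vocabulary is required")
    if dataset.P is None:
        dataset = encode_treatments(dataset, vocab)
    if tc.optimizer != "adam":
        raise ValueError("only the adam optimizer is supported")

    use_gpo = mc.beta > 0
    if use_gpo and tc.ablation != "sp_only" and dge_reference is None:
        dge_reference = build_dge_reference(dataset, vocab)
    delta = dge_reference.delta if dge_reference is not None else None

    mc.seed = tc.seed
    model = GPOVAE(dataset.gene_names, vocab, mc)
    model.train_library_sizes = dataset.L.astype(np.float64)
    rng = np.random.default_rng(tc.seed + 1)
    opt = ad.Adam(model.parameters(), lr=tc.lr,
                  lr_overrides={"w_logits": tc.w_lr},
                  betas_overrides={"w_logits": tuple(tc.w_betas)})

    N = dataset.n_cells
    X, P, A = dataset.X, dataset.P, dataset.A
    history = TrainHistory()
    last_good = model.state_dict()
    best_loss, stall = np.inf, 0

    for epoch in range(tc.epochs):
        t0 = time.time()
        frac = epoch / max(tc.epochs - 1, 1)
        temp = tc.temperature_start + (tc.temperature_end - tc.temperature_start) * frac
        order = rng.permutation(N)
        sums = {"total": 0.0, "recon": 0.0, "kl_zb": 0.0, "kl_m": 0.0,
                "jade": 0.0, "j_dge_k": 0.0, "j_sp": 0.0}
        n_batches = 0
        for start in range(0, N, tc.batch_size):
            idx = order[start:start + tc.batch_size]
            Xb, Pb, Ab = X[idx], P[idx], A[idx]
            opt.zero_grad()
            elbo, parts = model.elbo(
                Xb, Pb, Ab, n_mc_samples=1, temperature=temp, n_total=N, rng=rng)
            loss = ad.mul(elbo, -1.0)
            jade_val = 0.0
            if mc.alpha > 0 and (Ab == 1).any():
                jade = model.artifact_disentanglement_loss(Xb, Pb, Ab, rng=rng)
                loss = ad.add(loss, ad.mul(jade, mc.alpha))
                jade_val = float(ad._data(jade))
            j_dge_val = j_sp_val = 0.0
            if use_gpo:
                db = delta[idx] if delta is not None else np.zeros((idx.size, vocab.size))
                j_dge, j_sp = _gpo_terms(
                    model.W.probabilities_graph(), Pb, db, mc.K, tc.ablation,
                    vocab.size, mc.sp_weight)
                loss = ad.add(loss, ad.mul(ad.add(j_dge, j_sp), mc.beta))
                j_dge_val = float(ad._data(j_dge))
                j_sp_val = float(ad._data(j_sp))
            total = float(ad._data(loss))
            if not np.isfinite(total):
                model.load_state_dict(last_good)
                history.diverged = True
                return model, history
            loss.backward()
            opt.step()
            sums["total"] += total
            sums["recon"] += parts["recon"]
            sums["kl_zb"] += parts["kl_zb"]
            sums["kl_m"] += parts["kl_m"]
            sums["jade"] += jade_val
            sums["j_dge_k"] += j_dge_val
            sums["j_sp"] += j_sp_val
            n_batches += 1
        probs = model.W.probabilities
        history.append(
            epoch=epoch,
            temperature=temp,
            n_edges=int((probs > 0.5).sum()),
            mean_probability=float(probs.mean()),
            wall_clock=time.time() - t0,
            **{k: v / n_batches for k, v in sums.items()},
        )
        last_good = model.state_dict()
        if tc.checkpoint_every and tc.checkpoint_dir:
            if (epoch + 1) % tc.checkpoint_every == 0:
                model.save(f"{tc.checkpoint_dir}/checkpoint_epoch{epoch + 1:04d}.npz")
        epoch_loss = sums["total"] / n_batches
        if tc.patience is not None:
            if epoch_loss < best_loss - 1e-6:
                best_loss, stall = epoch_loss, 0
            else:
                stall += 1
                if stall > tc.patience:
                    break
    return model, history
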