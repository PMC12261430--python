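"""Disentangled count VAE with a causal-matrix perturbation prior.

Three encoders factor a cell's state: a latent perturbation encoder whose
sparsity mask is drawn from Bernoulli(Ŵ) over the causal-probability matrix
(Zp = P (E ⊙ M)), a latent artifact encoder that maps the binary QC flag to
a shared artifact embedding (Za = A·u), and a latent basal-state encoder
over the expression profile.  The decoder emits per-gene proportions on the
simplex (softmax) scaled by the cell's library size, observed through a
Gamma-Poisson (negative binomial) count model.

The effect posterior mean is a structured parameterization
E_mean[i, j] = b_target[j] + w_self·δ_ij + R[i, j]: a per-target response
bias shared across sources, a shared on-target (self-edge) gain, and a
per-entry residual.  It is deliberately independent of the sampled mask —
conditioning on M happens through the product E ⊙ M — so the only gradient
paths into extended-source rows of Ŵ are the GPO loss and the mask KL
(which vanishes at the 0.5 initialization).  The shared components are what
allow a never-trained (held-out) perturbation row to produce a calibrated
response prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _autodiff as ad
from .gpo import CausalParamMatrix, SparseMask, sample_mask
from .io import GeneVocabulary, lognorm

_LOGVAR_BOUND = 6.0


@dataclass
class ModelConfig:
    """Architecture and loss-weight configuration."""

    latent_dim: int = 16
    hidden: tuple[int, ...] = (64, 64)
    K: int = 5
    alpha: float = 1.0          # weight of the artifact-disentanglement loss
    beta: float = 1.0           # weight of the GPO loss
    temperature: float = 1.0
    effect_logvar_init: float = -4.0
    theta_init: float = 10.0
    sp_weight: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        self.hidden = tuple(self.hidden)


@dataclass
class DecoderOutput:
    """Poisson rates, mean parameters, dispersions and sampled counts."""

    rates: np.ndarray
    mean: np.ndarray
    theta: np.ndarray
    counts: np.ndarray


def _kl_normal(mu, logvar):
    """KL(N(mu, exp(logvar)) || N(0, I)), summed over all entries."""
    return ad.mul(
        ad.sum_(ad.sub(ad.add(ad.square(mu), ad.exp(logvar)), ad.add(logvar, 1.0))),
        0.5,
    )


def _kl_bernoulli_half(p):
    """KL(Ber(p) || Ber(0.5)) summed over entries (zero iff p = 0.5)."""
    eps = 1e-9
    p = ad.mul(p, 1.0 - 2 * eps)
    p = ad.add(p, eps)
    one_m = ad.sub(1.0, p)
    return ad.sum_(
        ad.add(
            ad.mul(p, ad.log(ad.mul(p, 2.0))),
            ad.mul(one_m, ad.log(ad.mul(one_m, 2.0))),
        )
    )


def _bounded_logvar(raw):
    return ad.mul(ad.tanh(ad.mul(raw, 1.0 / _LOGVAR_BOUND)), _LOGVAR_BOUND)


class GPOVAE:
    """The full model: parameters, encoders, decoder and loss terms."""

    def __init__(self, gene_names: list[str], vocab: GeneVocabulary,
                 config: ModelConfig | None = None):
        self.gene_names = list(gene_names)
        self.vocab = vocab
        self.config = config or ModelConfig()
        rng = np.random.default_rng(self.config.seed)
        G, V, d = len(self.gene_names), vocab.size, self.config.latent_dim

        self.W = CausalParamMatrix(vocab.genes)

        def param(shape, scale=None, name=""):
            if scale is None:
                fan_in = shape[0] if len(shape) > 1 else 1
                scale = 1.0 / np.sqrt(max(fan_in, 1))
            data = rng.normal(0.0, scale, size=shape) if scale > 0 else np.zeros(shape)
            return ad.Tensor(data, requires_grad=True, name=name)

        # effect posterior: target bias + shared self gain + residual
        self.b_target = param((V,), scale=0.0, name="b_target")
        self.w_self = param((1,), scale=0.0, name="w_self")
        self.R = param((V, V), scale=0.0, name="effect_residual")
        self.effect_logvar = ad.Tensor(
            np.full((1,), self.config.effect_logvar_init), requires_grad=True,
            name="effect_logvar")

        # artifact embedding posterior
        self.mu_u = param((d,), scale=0.0, name="mu_u")
        self.logvar_u = param((d,), scale=0.0, name="logvar_u")

        # basal encoder MLP: [lognorm X, Zp, Za] -> posterior moments
        sizes = (G + V + d,) + self.config.hidden
        self.enc_w = [param((sizes[i], sizes[i + 1]), name=f"enc_w{i}")
                      for i in range(len(sizes) - 1)]
        self.enc_b = [param((sizes[i + 1],), scale=0.0, name=f"enc_b{i}")
                      for i in range(len(sizes) - 1)]
        self.enc_mu = param((sizes[-1], d), name="enc_mu")
        self.enc_mu_b = param((d,), scale=0.0, name="enc_mu_b")
        self.enc_lv = param((sizes[-1], d), name="enc_lv")
        self.enc_lv_b = param((d,), scale=0.0, name="enc_lv_b")

        # decoder: gene bias + MLP(Zb) + injected Zp + linear Za
        h = self.config.hidden[0] if self.config.hidden else 32
        self.dec_w1 = param((d, h), name="dec_w1")
        self.dec_b1 = param((h,), scale=0.0, name="dec_b1")
        self.dec_w2 = param((h, G), scale=1.0 / np.sqrt(h), name="dec_w2")
        self.dec_bias = param((G,), scale=0.0, name="dec_bias")
        self.dec_za = param((d, G), scale=0.0, name="dec_za")
        self.zp_gain = ad.Tensor(np.ones(1), requires_grad=True, name="zp_gain")
        self.log_theta = ad.Tensor(
            np.full((G,), np.log(self.config.theta_init)), requires_grad=True,
            name="log_theta")

        # fixed scatter of the V vocabulary columns into the G gene columns
        inject = np.zeros((V, G))
        gene_pos = {g: i for i, g in enumerate(self.gene_names)}
        for g, j in vocab.index.items():
            inject[j, gene_pos[g]] = 1.0
        self._inject = inject

    # -- parameter plumbing ---------------------------------------------
    def parameters(self) -> list[ad.Tensor]:
        params = [self.W.logits, self.b_target, self.w_self, self.R,
                  self.effect_logvar, self.mu_u, self.logvar_u,
                  self.enc_mu, self.enc_mu_b, self.enc_lv, self.enc_lv_b,
                  self.dec_w1, self.dec_b1, self.dec_w2, self.dec_bias,
                  self.dec_za, self.zp_gain, self.log_theta]
        params.extend(self.enc_w)
        params.extend(self.enc_b)
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, p in enumerate(self.parameters()):
            out[f"{i:03d}_{p.name}"] = p.data.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = np.array(state[f"{i:03d}_{p.name}"], dtype=np.float64)

    def save(self, path: str) -> None:
        extra = {}
        lib = getattr(self, "train_library_sizes", None)
        if lib is not None:
            extra["_library"] = np.asarray(lib)
        np.savez(path, **self.state_dict(), **extra,
                 _config=json.dumps(asdict(self.config)),
                 _genes=json.dumps(self.gene_names),
                 _perturbed=json.dumps(self.vocab.perturbed),
                 _extended=json.dumps(self.vocab.extended))

    @classmethod
    def load(cls, path: str) -> "GPOVAE":
        data = np.load(path, allow_pickle=False)
        cfg = ModelConfig(**json.loads(str(data["_config"])))
        genes = json.loads(str(data["_genes"]))
        vocab = GeneVocabulary(
            all_genes=genes,
            perturbed=json.loads(str(data["_perturbed"])),
            extended=json.loads(str(data["_extended"])),
        )
        model = cls(genes, vocab, cfg)
        model.load_state_dict({k: data[k] for k in data.files if not k.startswith("_")})
        if "_library" in data.files:
            model.train_library_sizes = np.asarray(data["_library"], dtype=np.float64)
        return model

    # -- encoders --------------------------------------------------------
    def effect_posterior(self):
        """Mean and (bounded) log-variance of the effect matrix posterior."""
        V = self.vocab.size
        eye = np.eye(V)
        mean = ad.add(
            ad.add(ad.reshape(self.b_target, (1, V)), ad.mul(eye, self.w_self)),
            self.R,
        )
        logvar = _bounded_logvar(self.effect_logvar)
        return mean, logvar

    def encode_perturbation(self, P: np.ndarray, mode: str = "relaxed",
                            temperature: float | None = None,
                            rng: np.random.Generator | None = None):
        """Sample (M, E) and form Zp = P (E ⊙ M); control rows are zero.

        ``mode``: "relaxed" (concrete mask, reparameterized E), "hard"
        (Bernoulli mask, reparameterized E) or "mean" (hard mask, E at its
        posterior mean).
        """
        rng = rng or np.random.default_rng(0)
        temperature = self.config.temperature if temperature is None else temperature
        V = self.vocab.size
        if mode == "relaxed":
            mask = sample_mask(self.W, temperature=temperature, mode="relaxed", seed=rng)
            m = mask.tensor
        else:
            mask = sample_mask(self.W, mode="hard", seed=rng)
            m = mask.values
        mean, logvar = self.effect_posterior()
        if mode == "mean":
            E = mean
        else:
            eps = rng.standard_normal((V, V))
            E = ad.add(mean, ad.mul(ad.exp(ad.mul(logvar, 0.5)), eps))
        Zp = ad.matmul(np.asarray(P, dtype=np.float64), ad.mul(E, m))
        return mask, E, Zp

    def encode_artifact(self, A: np.ndarray, sample: bool = True,
                        rng: np.random.Generator | None = None):
        """u ~ N(mu, sigma) shared across the batch; Za = A · u (outer product)."""
        rng = rng or np.random.default_rng(0)
        d = self.config.latent_dim
        logvar = _bounded_logvar(self.logvar_u)
        if sample:
            eps = rng.standard_normal(d)
            u = ad.add(self.mu_u, ad.mul(ad.exp(ad.mul(logvar, 0.5)), eps))
        else:
            u = self.mu_u
        A_col = np.asarray(A, dtype=np.float64).reshape(-1, 1)
        Za = ad.matmul(A_col, ad.reshape(u, (1, d)))
        return u, Za

    def encode_basal(self, X: np.ndarray, Zp, Za, sample: bool = True,
                     rng: np.random.Generator | None = None):
        """Posterior moments of Zb from [lognorm X, Zp, Za]; reparameterized draw."""
        rng = rng or np.random.default_rng(0)
        hid = ad.concat([lognorm(X), Zp, Za], axis=1)
        for w, b in zip(self.enc_w, self.enc_b):
            hid = ad.tanh(ad.add(ad.matmul(hid, w), b))
        mu = ad.add(ad.matmul(hid, self.enc_mu), self.enc_mu_b)
        logvar = _bounded_logvar(ad.add(ad.matmul(hid, self.enc_lv), self.enc_lv_b))
        if not np.all(np.isfinite(ad._data(mu))):
            raise FloatingPointError("non-finite basal-encoder activations")
        if sample:
            eps = rng.standard_normal(ad._data(mu).shape)
            Zb = ad.add(mu, ad.mul(ad.exp(ad.mul(logvar, 0.5)), eps))
        else:
            Zb = mu
        return Zb, mu, logvar

    # -- decoder ---------------------------------------------------------
    def decoder_log_proportions(self, Zb, Zp, Za):
        """Log of softmax-normalized per-gene expression proportions."""
        hid = ad.tanh(ad.add(ad.matmul(Zb, self.dec_w1), self.dec_b1))
        logits = ad.add(ad.matmul(hid, self.dec_w2), self.dec_bias)
        logits = ad.add(logits, ad.mul(ad.matmul(Zp, self._inject), self.zp_gain))
        logits = ad.add(logits, ad.matmul(Za, self.dec_za))
        return ad.log_softmax(logits, axis=1)

    def decode(self, Zb, Zp, Za, L: np.ndarray,
               rng: np.random.Generator | None = None) -> DecoderOutput:
        """Sample counts through the Gamma-Poisson observation model."""
        rng = rng or np.random.default_rng(0)
        L = np.asarray(L, dtype=np.float64).ravel()
        if (L <= 0).any():
            raise ValueError("library sizes must be positive")
        log_props = ad._data(self.decoder_log_proportions(Zb, Zp, Za))
        mean = np.exp(log_props) * L[:, None]
        theta = np.exp(self.log_theta.data)[None, :] * np.ones_like(mean)
        rates = rng.gamma(shape=theta, scale=mean / theta)
        counts = rng.poisson(rates).astype(np.int64)
        return DecoderOutput(rates=rates, mean=mean, theta=theta, counts=counts)

    def nb_log_likelihood(self, X: np.ndarray, log_props, L: np.ndarray):
        """Gamma-Poisson (negative binomial) log-likelihood, summed over genes."""
        X = np.asarray(X, dtype=np.float64)
        L = np.maximum(np.asarray(L, dtype=np.float64).reshape(-1, 1), 1.0)
        theta = ad.reshape(ad.exp(self.log_theta), (1, -1))
        log_mu = ad.add(log_props, np.log(L))
        mu = ad.exp(log_mu)
        log_theta_mu = ad.log(ad.add(theta, mu))
        ll = ad.add(
            ad.sub(ad.lgamma(ad.add(X, theta)), ad.lgamma(theta)),
            ad.add(
                ad.mul(theta, ad.sub(ad.log(theta), log_theta_mu)),
                ad.mul(X, ad.sub(log_mu, log_theta_mu)),
            ),
        )
        const = -_sp_gammaln(X + 1.0)
        return ad.sum_(ad.add(ll, const), axis=1)

    # -- losses ----------------------------------------------------------
    def kl_terms(self):
        """Global-latent KL terms (E, M, u) against their priors.

        The effect prior is hierarchical: p(E) = N(b_target + w_self·I, 1)
        with the structured components as prior location, so the KL
        regularizes only the per-entry residual R.  Penalizing the full
        posterior mean would erode the shared response components that
        untrained (held-out) source rows rely on.
        """
        _, logvar = self.effect_posterior()
        kl_e = _kl_normal(self.R, logvar)
        kl_m = _kl_bernoulli_half(self.W.probabilities_graph())
        kl_u = _kl_normal(self.mu_u, _bounded_logvar(self.logvar_u))
        return kl_e, kl_m, kl_u

    def elbo(self, X: np.ndarray, P: np.ndarray, A: np.ndarray,
             n_mc_samples: int = 1, temperature: float | None = None,
             n_total: int | None = None,
             rng: np.random.Generator | None = None):
        """Monte-Carlo ELBO per cell (to maximize) with a per-term breakdown.

        Global-latent KL terms are scaled by batch/total so that minibatch
        gradients are unbiased for the full-data ELBO.
        """
        if n_mc_samples < 1:
            raise ValueError("n_mc_samples must be >= 1")
        rng = rng or np.random.default_rng(0)
        B = X.shape[0]
        n_total = n_total or B
        recon_acc, klzb_acc = None, None
        for _ in range(n_mc_samples):
            mask, E, Zp = self.encode_perturbation(
                P, mode="relaxed", temperature=temperature, rng=rng)
            u, Za = self.encode_artifact(A, rng=rng)
            Zb, mu_b, lv_b = self.encode_basal(X, Zp, Za, rng=rng)
            log_props = self.decoder_log_proportions(Zb, Zp, Za)
            recon = ad.sum_(self.nb_log_likelihood(X, log_props, X.sum(axis=1)))
            kl_zb = _kl_normal(mu_b, lv_b)
            recon_acc = recon if recon_acc is None else ad.add(recon_acc, recon)
            klzb_acc = kl_zb if klzb_acc is None else ad.add(klzb_acc, kl_zb)
        recon = ad.mul(recon_acc, 1.0 / n_mc_samples)
        kl_zb = ad.mul(klzb_acc, 1.0 / n_mc_samples)
        kl_e, kl_m, kl_u = self.kl_terms()
        kl_global = ad.add(ad.add(kl_e, kl_m), kl_u)
        elbo = ad.sub(
            ad.mul(ad.sub(recon, kl_zb), 1.0 / B),
            ad.mul(kl_global, 1.0 / n_total),
        )
        parts = {
            "recon": float(ad._data(recon)) / B,
            "kl_zb": float(ad._data(kl_zb)) / B,
            "kl_e": float(ad._data(kl_e)),
            "kl_m": float(ad._data(kl_m)),
            "kl_u": float(ad._data(kl_u)),
        }
        return elbo, parts

    def artifact_disentanglement_loss(self, X: np.ndarray, P: np.ndarray,
                                      A: np.ndarray,
                                      rng: np.random.Generator | None = None):
        """Counterfactual surrogate for artifact disentanglement.

        For QC-fail cells the factual reconstruction (Za = u) must explain
        the observed counts, while the counterfactual reconstruction
        (Za = 0) is pushed, by first-moment matching of library-normalized
        expression, toward the QC-pass population.  Returns 0 when the batch
        has no flagged cells.
        """
        rng = rng or np.random.default_rng(0)
        A = np.asarray(A).ravel()
        flagged = np.where(A == 1)[0]
        if flagged.size == 0:
            return ad.Tensor(np.zeros(()))
        Xf, Pf = X[flagged], P[flagged]
        mask, E, Zp = self.encode_perturbation(Pf, mode="relaxed", rng=rng)
        u, Za_fact = self.encode_artifact(np.ones(flagged.size), rng=rng)
        Zb, mu_b, lv_b = self.encode_basal(Xf, Zp, Za_fact, rng=rng)
        log_props_fact = self.decoder_log_proportions(Zb, Zp, Za_fact)
        nll_fact = ad.mul(
            ad.sum_(self.nb_log_likelihood(Xf, log_props_fact, Xf.sum(axis=1))),
            -1.0 / (flagged.size * len(self.gene_names)),
        )
        Za_zero = np.zeros((flagged.size, self.config.latent_dim))
        log_props_cf = self.decoder_log_proportions(Zb, Zp, Za_zero)
        clean = np.where(A == 0)[0]
        if clean.size == 0:
            return nll_fact
        target = (X[clean] / np.maximum(X[clean].sum(axis=1, keepdims=True), 1)).mean(axis=0)
        cf_mean = ad.mean(ad.exp(log_props_cf), axis=0)
        moment = ad.sum_(ad.square(ad.sub(cf_mean, target)))
        return ad.add(nll_fact, ad.mul(moment, float(len(self.gene_names))))


def _sp_gammaln(x):
    from scipy.special import gammaln

    return gammaln(x)
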