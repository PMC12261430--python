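# Methods

## The model

`gpovae` predicts single-cell transcriptional responses to single-gene
CRISPR perturbations with a disentangled variational autoencoder whose
perturbation mechanism is gated by an explicit gene regulatory network
(GRN) prior.

A dataset is a tuple (X, P, A): UMI counts X ∈ ℕ^(N×|G|), one-hot
treatments P ∈ {0,1}^(N×V) over the vocabulary V = |G°∪G+| (perturbed
genes G° first, then extended genes G+, each lexicographic), and binary
QC/artifact flags A.  Library sizes L are row sums of X by construction.

Three latent subspaces factor a cell:

* **Perturbation.**  A global mask M ~ Bernoulli(Ŵ) is drawn from the
  causal-probability matrix Ŵ ∈ [0,1]^(V×V) (stored as logits, initialized
  at probability exactly 0.5; self-loops allowed, no acyclicity
  constraint).  A global effect matrix E is drawn from a Normal posterior
  and the per-cell shift is Zp = P (E ⊙ M): the row of masked effects of
  the targeted gene.
* **Artifact.**  A single embedding u ~ N(μ̂, σ̂) shared by the batch, with
  Za = A·u, so QC-pass cells are exactly artifact-free in the generative
  path.
* **Basal.**  Zb ~ N(f_enc(log1p-CP10K X, Zp, Za)) with a standard-normal
  prior.

The decoder maps (Zb, Zp, Za) to gene proportions by softmax — Zp is
injected additively into the gene logits at its vocabulary columns, so an
effect entry reads directly as a log-proportion shift — scaled by L, and
counts are observed through a Gamma-Poisson model: Λ ~ Γ(mean = props·L,
concentration Θ), X̃ ~ Poisson(Λ), i.e. a negative binomial with per-gene
dispersion.  Training maximizes a Monte-Carlo ELBO with the reconstruction
term integrated analytically over Λ (the NB marginal), KL terms for Zb, E,
M (Bernoulli(0.5) prior, exact KL) and u, and the global-latent KLs scaled
by 1/N for unbiased minibatch gradients.

### Effect posterior parameterization

E's posterior mean is structured: E_mean[i,j] = b_target[j] + w_self·δ_ij
+ R[i,j] — a per-target response bias shared across sources, a shared
on-target gain, and a per-entry residual; the posterior variance is a
shared scalar.  The prior on E is hierarchical, N(b_target + w_self·I, 1),
so the KL regularizes only R.  Two deliberate consequences:

* The parameterization is independent of the sampled mask, so the only
  gradient paths into rows of Ŵ whose source gene never appears as a
  treatment are the GRN-alignment loss and the mask KL (which vanishes at
  the 0.5 initialization).  Under the DGE-only ablation those rows remain
  at exactly 0.5 — an assertable invariant.
* The shared components are what a never-trained (held-out) source row can
  still express; penalizing the full mean would erode them.

## GRN-aligned parameter optimization

Each treated cell is paired with a control cell by exact discrete optimal
transport (squared-Euclidean cost on log1p-CP10K expression over the
vocabulary columns, uniform weights, solved per treatment group).  Equal
group sizes use the Hungarian algorithm; sizes in integer ratio replicate
controls (the uniform-marginal optimum is integral there); otherwise the
exact EMD linear program (HiGHS) is solved and each treated cell takes the
control with the largest transport mass.  An entropic Sinkhorn
approximation is available behind a flag for very large groups.

The reference matrix ΔX holds, per treated cell, |log1p-CP10K difference|
to its paired control over the vocabulary columns, row-max-normalized into
[0,1] so references live on the probability scale of Ŵ (an unnormalized
mode is available; see Limitations).  Control rows are zero.  References
are computed once from training cells and frozen.

The GRN-alignment objective is

    Jgpo(Ŵ) = JdgeK + Jsp
    JdgeK   = mean_n || (P T^K)_n − Δx_n ||₁
    T^K     = Ŵ + Σ_{k=2..K} Ŵ^k / V          (K = 5)
    Jsp     = sp_weight · mean_ij |Ŵ_ij|

with ablation switches `sp_only` / `dge_only` (K effectively 1) /
`dgek_only` / `full`.  K-hop accumulation lets multi-hop paths — including
extended genes as intermediates — receive gradient; the L1 penalty (the
sparsity idea of NOTEARS, without its acyclicity constraint) prunes
connections that the observed effects do not support.

**Choice of sp_weight.**  The two terms use different reductions (per-cell
row L1 vs per-entry mean), so their relative gradient scale is a free
calibration.  The per-entry subgradient of the DGE term for a treatment
with n_t cells among N is ≈ n_t/N, while an entry-mean penalty contributes
1/V².  We set sp_weight = V by default, making the penalty a row-mean L1 —
the same per-row scale as the DGE residual — which places the sparsity
force within a factor N/(V·n_t) of the data force.  At the package's
default synthetic conditions this is the regime in which the penalty
actually prunes; with sp_weight = 1 it would shift the fitted quantile of
the per-cell reference distribution by well under 1% and be inert.

## Training

Stochastic variational inference with Adam (lr 1e-3).  The Ŵ logits get
their own step size (3e-2) and short-memory moment estimates (β = 0.9,
0.9): at the 0.5 initialization T^K is dominated by its highest power
(entries ≈ 0.5^K·V^(K−2)), and the resulting large early gradients would
otherwise saturate the second-moment estimate and freeze Ŵ for thousands
of steps after the transient decays.  The mask relaxation temperature
anneals 1.0 → 0.5 linearly; evaluation and generation use hard Bernoulli
masks.  Total objective: J = −ELBO + α·Jade + β·Jgpo with α = β = 1.

Jade, the artifact-disentanglement surrogate, decodes flagged cells twice —
factual (Za = u) and counterfactual (Za = 0) — penalizing factual
reconstruction error and the first-moment mismatch between counterfactual
library-normalized expression and the QC-pass population.

## Generation and prediction

Generation samples Zb from N(0, I), per-cell masks and effects from the
trained posteriors, sets Za = 0 exactly (artifact-free outputs are bitwise
independent of μ̂, σ̂), resamples library sizes from the training empirical
distribution, and decodes through the Gamma-Poisson model.  The predicted
average treatment effect (ATE) of a treatment is the per-gene difference
of mean log1p-CP10K expression between generated treated and generated
control populations; observed ATEs use the identical normalization.

Prediction metrics: Pearson ATE-ρ, ATE-R² (1 − SS_res/SS_tot, unbounded
below), and Jaccard similarity of top-50 |ATE| gene sets (deterministic
gene-order tie break).  GRN metrics follow the interventional-benchmark
convention: edges are entries with probability strictly above 0.5 (an
untrained matrix therefore has zero edges); μWD is the mean 1-D
Wasserstein-1 distance between control and source-perturbed expression of
each edge's target (0.0 for an empty or non-evaluable edge set); FOR is
the fraction of non-edges among interventional pairs whose
perturbation effect is significant (Mann-Whitney U, BH at FDR 0.05), with
sentinel −1 when the graph leaves no negative pairs.  Hub genes binarize
at 0.3 and rank by combined in+out degree.

## Synthetic data

The generator emulates the features the method depends on:

* a planted directed network over G°∪G+ with expected density
  `edge_density` (default 0.1) on non-hub entries, plus `n_hubs` (default
  3) perturbed "shared response program" genes whose in- and out-edges
  appear with probability 0.85 — the degree heterogeneity of real screens,
  where ribosome/growth-program genes sit downstream of most
  perturbations;
* signed effects with |effect| ∈ [0.5, 2] (log-expression change per unit
  knockdown) and per-target sign consistency 0.8 — responses of a gene
  across different upstream perturbations are usually directionally
  coherent, and without this property the response to a held-out
  perturbation would be unidentifiable in principle;
* on-target knockdown 0.8; multi-hop propagation as summed path products
  damped by 1/V per extra hop (matching the model's accumulation), paths
  truncated at 5 hops;
* Gamma-Poisson counts (dispersion 10) with log-normal library sizes
  (mean 5000, σ 0.3), 200 cells per treatment and 200 controls (equal
  sizes make OT pairing an exact assignment), 20 perturbed + 10 extended
  + 20 background genes;
* a 5% artifact fraction whose counts are globally scaled 2× (library
  distortion), flagged A = 1.

Not emulated: gene-length or capture bias, batch structure, cell cycle,
guide-level variability, multi-gene perturbations.  Passing tests on this
generator demonstrate the mechanics of the method — identifiability of
interventionally observed rows of Ŵ, calibration of the count model,
direction of the ablation effects — not performance on real screens.

## Numerical choices

* Pure-numpy reverse-mode autodiff; float64 throughout; gradients verified
  against central finite differences.
* Encoders/decoder are small tanh MLPs (hidden 64×64, latent d = 16) —
  appropriate to the synthetic problem sizes; all sizes configurable.
* Posterior log-variances are smoothly bounded to ±6 (tanh) for stability.
* Matrix powers by iterated multiplication (K ≤ 5), on the probability
  view, no thresholding before accumulation.
* Ties in top-k rankings and hub ranking break by gene order; OT argmax
  ties resolve to the lowest control index.
* Zero-count cells never divide by zero in QC (they fail min-counts); the
  NB likelihood floors library sizes at 1.
* Degenerate inputs raise: empty control sets, K = 0, non-integer counts,
  out-of-vocabulary treatments, fractions not summing to 1.

## Known limitations

* A held-out (never-trained) row of Ŵ receives gradient only through
  K-hop paths.  At desk scale (tens of treatments) that aggregate push is
  roughly an order of magnitude weaker than the sparsity force needed for
  meaningful pruning, so held-out rows — including the on-target
  self-loop, the dominant component of a knockdown's ATE — are driven
  toward zero and unseen-perturbation predictions retain little signal.
  The mechanism strengthens with the number of treatments sharing response
  programs; with hundreds of treatments it can win.  The unseen-treatment
  experiment is implemented and measured honestly rather than tuned.
* With row-max-normalized references every target is fittable by a direct
  entry of Ŵ, so K-hop accumulation inflates extended-gene edges only
  mildly before the sparsity penalty prunes them; the dense-versus-sparse
  contrast between the K-hop-only and full objectives is therefore
  directionally present but quantitatively modest.  The `normalize="none"`
  reference mode preserves raw fold-change magnitudes (which can exceed
  the probability range and force mass into multi-hop paths) at the cost
  of leaving the regression target off the probability scale.
* The six QC criteria and the artifact-disentanglement loss are this
  package's own concrete surrogates for conventions that vary between
  pipelines; both are isolated behind single operations and configurable.
* Multi-gene perturbations are out of scope; P has at most one active
  column per cell.
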