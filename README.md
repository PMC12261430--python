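# gpovae

An explainable variational autoencoder for predicting single-cell
transcriptional responses to genetic perturbations (Perturb-Seq style
CRISPR screens), whose latent perturbation mechanism doubles as an
inferred gene regulatory network (GRN).

## Who this is for

Computational biologists working with interventional single-cell data who
want (i) generative prediction of post-perturbation expression profiles
and (ii) a directed, probabilistic gene-gene network that explains those
predictions — without a separate network-inference pipeline.

## The model

A dataset D = (X, P, A) holds UMI counts X ∈ ℕ^(N×|G|), one-hot treatments
P over the vocabulary G°∪G+ (perturbed genes with interventional cells,
plus extended genes passing a differential-expression cutoff) and binary
QC flags A.  Three disentangled latents feed a Gamma-Poisson decoder:

    M  ~ Bernoulli(Ŵ)            sparsity mask over the causal matrix
    E  ~ N(f_enc,p)               gene-wise perturbation effects
    Zp = P (E ⊙ M)                sparse mechanism shift of the treatment
    Za = A · u,  u ~ N(μ̂, σ̂)     shared technical-artifact embedding
    Zb ~ N(f_enc,b(X, Zp, Za))    basal cell state
    Λ  ~ Γ(f_dec(Zb, Zp, Za)·L, Θ),   X̃ ~ Poisson(Λ)

Ŵ ∈ [0,1]^(V×V) is the matrix of causal probabilities source → target
(V = |G°∪G+|; self-loops allowed).  Besides the ELBO, Ŵ is shaped by a
GRN-alignment objective

    Jgpo(Ŵ) = mean_n ‖(P T̂ᴷ)_n − Δx_n‖₁ + ‖Ŵ‖₁,
    T̂ᴷ = Ŵ + Σ_{k=2..K} Ŵᵏ / V    (K = 5),

where Δx_n is a per-cell differential-expression reference built by
pairing each treated cell with a control cell via exact optimal transport.
K-hop accumulation propagates gradient to multi-hop paths (through
extended genes); the L1 penalty prunes unsupported connections.
Thresholding Ŵ at 0.5 yields the inferred GRN, evaluated statistically by
mean Wasserstein distance (μWD) and false omission rate (FOR).  The total
objective is J = −ELBO(Jrec) + α·Jade + β·Jgpo.

Everything runs on a small numpy reverse-mode autodiff engine — no GPU or
deep-learning framework required.

## Worked example

```python
from gpovae import (SimulationConfig, sample_ground_truth_grn,
                    simulate_perturbseq, train, ModelConfig, TrainConfig,
                    extract_grn, mean_wasserstein, average_treatment_effect,
                    observed_average_treatment_effect, ate_pearson)

cfg = SimulationConfig(seed=11, n_hubs=0)       # 50 genes, 20 perturbed,
grn = sample_ground_truth_grn(cfg)              # planted 10%-density net
data, _ = simulate_perturbseq(grn, cfg)         # 4200 cells

model, history = train(data, model_config=ModelConfig(),
                       train_config=TrainConfig(epochs=40, seed=11))

net = extract_grn(model.W)                      # edges with prob > 0.5
mu, _ = mean_wasserstein(net, data)
print(f"edges={net.n_edges}  muWD={mu:.3f}")

gene = data.vocab.perturbed[3]
pred = average_treatment_effect(model, gene, n_samples=2000, seed=11)
obs = observed_average_treatment_effect(data, gene)
print(f"ATE-rho({gene}) = {ate_pearson(pred, obs):.3f}")
```

Output:

```
edges=54  muWD=1.426
ATE-rho(PG03) = 0.978
```

54 inferred edges is the sparse regime the L1 penalty targets (the planted
network has 100 true edges, many below the 0.5 reference-scale threshold);
μWD ≈ 1.4 says the average retained edge links a perturbation to a target
whose expression distribution moves strongly; and ATE-ρ ≈ 0.98 means the
generated response profile for this knockdown correlates tightly with the
empirical profile across all 50 genes.

The same pipeline is available from the shell:

```bash
gpovae simulate --outdir screen/ --seed 11
gpovae preprocess screen/ --outdir prep/
gpovae train prep/dataset --outdir run/ --epochs 40 --seed 11
gpovae eval-grn run/causal_matrix.tsv --data screen/ --out grn.json
gpovae ablate prep/dataset --outdir ablation/ --epochs 100 --seed 11
```

## Layout

| module | contents |
| --- | --- |
| `gpovae.io` | `.h5ad` / MatrixMarket readers and writers, QC criteria, weak-perturbation filter, gene vocabulary, one-hot encoding |
| `gpovae.simulate` | synthetic screens with planted causal networks, Gamma-Poisson counts, artifacts; brute-force OT fixtures |
| `gpovae.gpo` | causal matrix Ŵ, mask sampling, K-hop accumulation, OT pairing, DGE references, the GPO loss |
| `gpovae.model` | encoders, Gamma-Poisson decoder, ELBO, artifact-disentanglement surrogate |
| `gpovae.train` | SVI loop, ablation switches, splits and holdouts |
| `gpovae.generate` | post-training generation and ATE prediction (incl. unseen treatments) |
| `gpovae.metrics` | ATE-ρ / ATE-R² / Jaccard, GRN extraction, μWD, FOR, hub genes |
| `gpovae.cli` | `gpovae` command-line entry point |

See `docs/methods.md` for the model's assumptions, parameter choices and
known limitations.
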