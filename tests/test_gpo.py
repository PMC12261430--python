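"""Causal matrix, mask sampling, K-hop accumulation, OT pairing and GPO loss."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpovae import (
    CausalParamMatrix,
    build_dge_reference,
    dge_loss,
    gpo_loss,
    khop_accumulate,
    ot_pairing_fixture,
    pair_optimal_transport,
    sample_mask,
    sparsity_penalty,
)
from gpovae.gpo import _emd_plan
from gpovae.io import CONTROL_LABEL, PerturbDataset, GeneVocabulary

BIG = 500.0  # logit magnitude mapping to probability 1/0 at float precision


def _params(logits):
    logits = np.asarray(logits, dtype=float)
    return CausalParamMatrix([f"g{i}" for i in range(logits.shape[0])], logits=logits)


# ---------------------------------------------------------------------------
# parameter matrix + masks
# ---------------------------------------------------------------------------

def test_fresh_initialization_is_exactly_half():
    p = CausalParamMatrix(["a", "b"])
    assert (p.probabilities == 0.5).all()


def test_checkpoint_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    p = _params(rng.normal(size=(4, 4)))
    path = str(tmp_path / "w.tsv")
    p.write_tsv(path)
    back = CausalParamMatrix.read_tsv(path)
    assert back.genes == p.genes
    assert np.allclose(back.probabilities, p.probabilities, atol=1e-6)


def test_hard_mask_extremes_and_marginal():
    logits = np.full((3, 3), -BIG)
    logits[0, 1] = BIG
    p = _params(logits)
    for seed in range(5):
        m = sample_mask(p, mode="hard", seed=seed).values
        assert m[0, 1] == 1.0 and m.sum() == 1.0
    draws = [sample_mask(CausalParamMatrix([f"g{i}" for i in range(10)]),
                         mode="hard", seed=s).values for s in range(100)]
    mean = np.mean(draws)  # 10^4 Bernoulli(0.5) draws
    assert abs(mean - 0.5) < 3 * np.sqrt(0.25 / 10_000)


def test_relaxed_mask_carries_gradient_to_logits():
    p = CausalParamMatrix(["a", "b"])
    mask = sample_mask(p, temperature=0.7, mode="relaxed", seed=1)
    assert ((mask.values > 0) & (mask.values < 1)).all()
    mask.tensor.backward(np.ones_like(mask.values))
    assert p.logits.grad is not None and np.any(p.logits.grad != 0)
    with pytest.raises(ValueError):
        sample_mask(p, temperature=0.0, mode="relaxed", seed=1)


# ---------------------------------------------------------------------------
# K-hop accumulation
# ---------------------------------------------------------------------------

def test_khop_identity_at_one_hop():
    rng = np.random.default_rng(3)
    p = _params(rng.normal(size=(5, 5)))
    assert np.array_equal(khop_accumulate(p, K=1).values, p.probabilities)
    with pytest.raises(ValueError):
        khop_accumulate(p, K=0)


def test_khop_two_edge_chain_gives_one_over_n_genes():
    logits = np.full((4, 4), -BIG)
    logits[0, 2] = BIG  # i -> m with probability 1
    logits[2, 1] = BIG  # m -> j with probability 1
    T = khop_accumulate(_params(logits), K=2)
    assert abs(T.values[0, 1] - 0.25) < 1e-12


def test_khop_zero_matrix_stays_zero():
    T = khop_accumulate(_params(np.full((3, 3), -BIG)), K=5)
    assert np.allclose(T.values, 0.0, atol=1e-12)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_khop_monotone_in_k(seed):
    rng = np.random.default_rng(seed)
    p = _params(rng.normal(size=(6, 6)))
    prev = khop_accumulate(p, K=1).values
    for K in range(2, 6):
        cur = khop_accumulate(p, K=K).values
        assert (cur >= prev - 1e-15).all()
        prev = cur


# ---------------------------------------------------------------------------
# OT pairing
# ---------------------------------------------------------------------------

def test_identical_sets_pair_identically(rng):
    pts = rng.normal(size=(6, 4))
    assert np.array_equal(pair_optimal_transport(pts, pts), np.arange(6))


def test_single_control_absorbs_everything(rng):
    treated = rng.normal(size=(4, 3))
    assert np.array_equal(
        pair_optimal_transport(treated, treated[:1]), np.zeros(4, dtype=int))
    with pytest.raises(ValueError, match="empty"):
        pair_optimal_transport(treated, treated[:0])


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_equal_size_pairing_matches_enumeration(seed):
    treated, control, best = ot_pairing_fixture(5, 5, seed=seed)
    got = pair_optimal_transport(treated, control)
    cost = ((treated[:, None] - control[None]) ** 2).sum(-1)
    assert cost[np.arange(5), got].sum() == pytest.approx(
        cost[np.arange(5), best].sum())


def test_emd_plan_satisfies_marginals_and_beats_independence(rng):
    treated, control = rng.normal(size=(3, 2)), rng.normal(size=(5, 2))
    cost = ((treated[:, None] - control[None]) ** 2).sum(-1)
    plan = _emd_plan(cost)
    assert np.allclose(plan.sum(axis=1), 1 / 3)
    assert np.allclose(plan.sum(axis=0), 1 / 5)
    independence = np.full((3, 5), 1 / 15)
    assert (plan * cost).sum() <= (independence * cost).sum() + 1e-12


def test_divisible_group_sizes_equal_lp_route(rng):
    treated = rng.normal(size=(6, 3))
    control = rng.normal(size=(3, 3))
    lp = pair_optimal_transport(treated, control, method="emd")
    cost_lp = ((treated - control[lp]) ** 2).sum()
    # tiling route is exercised through build_dge_reference's auto path; here
    # just confirm the LP pairing is no worse than any greedy alternative
    greedy = np.argmin(((treated[:, None] - control[None]) ** 2).sum(-1), axis=1)
    assert cost_lp <= ((treated - control[greedy]) ** 2).sum() + 1e-9


def test_sinkhorn_approximates_exact_pairing():
    rng = np.random.default_rng(12)
    # two well-separated clusters: pairing must stay within cluster
    treated = np.vstack([rng.normal(0, 0.1, (3, 2)), rng.normal(10, 0.1, (3, 2))])
    control = np.vstack([rng.normal(0, 0.1, (3, 2)), rng.normal(10, 0.1, (3, 2))])
    pairing = pair_optimal_transport(treated, control, method="sinkhorn")
    assert (pairing[:3] < 3).all() and (pairing[3:] >= 3).all()


# ---------------------------------------------------------------------------
# DGE reference
# ---------------------------------------------------------------------------

def test_dge_reference_tsv_round_trip(small_sim, small_dge, tmp_path):
    path = str(tmp_path / "delta.tsv")
    small_dge.write_tsv(path)
    from gpovae import DGEReference

    back = DGEReference.read_tsv(path)
    assert np.allclose(back.delta, small_dge.delta)
    assert np.array_equal(back.paired_control_index,
                          small_dge.paired_control_index)
    assert back.genes == small_dge.genes


def test_dge_reference_contracts(small_sim, small_dge):
    _, _, ds = small_sim
    ref = small_dge
    ctrl = ds.is_control
    assert np.all(ref.delta[ctrl] == 0.0)
    assert ref.delta.min() >= 0.0 and ref.delta.max() <= 1.0
    treated_rows = ref.delta[~ctrl]
    assert np.allclose(treated_rows.max(axis=1), 1.0)  # row-max normalization
    assert (ref.paired_control_index[~ctrl] >= 0).all()
    assert np.all(ctrl[ref.paired_control_index[~ctrl]])  # pairs are controls


def test_treated_cell_identical_to_control_gives_zero_row():
    genes = ["a", "b", "c"]
    X = np.array([[5, 10, 2], [9, 1, 4], [5, 10, 2]])
    labels = np.array([CONTROL_LABEL, CONTROL_LABEL, "a"], dtype=object)
    ds = PerturbDataset(X=X, gene_names=genes, treatment_labels=labels)
    vocab = GeneVocabulary(all_genes=genes, perturbed=["a"], extended=["b", "c"])
    ref = build_dge_reference(ds, vocab)
    assert np.allclose(ref.delta[2], 0.0)
    assert ref.paired_control_index[2] == 0


def test_single_gene_difference_normalizes_to_one():
    genes = ["a", "b"]
    X = np.array([[10, 10], [10, 30]])
    labels = np.array([CONTROL_LABEL, "a"], dtype=object)
    ds = PerturbDataset(X=X, gene_names=genes, treatment_labels=labels)
    vocab = GeneVocabulary(all_genes=genes, perturbed=["a"], extended=["b"])
    ref = build_dge_reference(ds, vocab)
    row = ref.delta[1]
    assert row.max() == pytest.approx(1.0)
    assert (row > 0).sum() == 2  # both genes shift under CP10K renormalization
    raw = build_dge_reference(ds, vocab, normalize="none")
    assert raw.delta[1].max() > 0 and not raw.normalized


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def test_dge_loss_hand_example():
    matrix = np.array([[0.2, 0.5, 0.1]])
    P = np.array([[1.0]])
    delta = np.array([[0.0, 1.0, 0.1]])
    assert dge_loss(matrix, P, delta) == pytest.approx(0.7)


def test_dge_loss_zero_cases(small_dge, small_sim):
    _, _, ds = small_sim
    V = small_dge.delta.shape[1]
    # P @ matrix == delta -> 0
    assert dge_loss(np.eye(V), np.eye(V), np.eye(V)) == pytest.approx(0.0)
    ctrl = ds.is_control
    loss = dge_loss(np.ones((V, V)), ds.P[ctrl], small_dge.delta[ctrl])
    assert loss == pytest.approx(0.0)  # all-control batch


def test_dge_loss_cell_permutation_invariant_and_gene_equivariant(rng):
    V, N = 4, 7
    M = rng.random((V, V))
    P = np.zeros((N, V))
    P[np.arange(N), rng.integers(0, V, N)] = 1.0
    delta = rng.random((N, V))
    base = dge_loss(M, P, delta)
    perm = rng.permutation(N)
    assert dge_loss(M, P[perm], delta[perm]) == pytest.approx(base)
    gperm = rng.permutation(V)
    assert dge_loss(M[np.ix_(gperm, gperm)], P[:, gperm],
                    delta[:, gperm]) == pytest.approx(base)


def test_sparsity_penalty_values():
    assert sparsity_penalty(np.zeros((4, 4))) == 0.0
    assert sparsity_penalty(np.ones((4, 4))) == 1.0
    assert sparsity_penalty(CausalParamMatrix(list("abcd"))) == pytest.approx(0.5)


def test_gpo_loss_decomposition_and_ablations(small_sim, small_dge):
    _, _, ds = small_sim
    rng = np.random.default_rng(4)
    V = ds.vocab.size
    params = CausalParamMatrix(ds.vocab.genes, logits=rng.normal(size=(V, V)))
    full = gpo_loss(params, ds.P, small_dge, K=5, ablation="full")
    dgek = gpo_loss(params, ds.P, small_dge, K=5, ablation="dgek_only")
    sp = gpo_loss(params, ds.P, small_dge, K=5, ablation="sp_only")
    dge = gpo_loss(params, ds.P, small_dge, K=5, ablation="dge_only")
    assert full.j_gpo == pytest.approx(full.j_dge_k + full.j_sp)
    assert full.j_dge_k == pytest.approx(dgek.j_dge_k)
    assert full.j_sp == pytest.approx(sp.j_sp)
    assert dgek.j_sp == 0.0 and sp.j_dge_k == 0.0
    assert dge.j_dge_k != pytest.approx(dgek.j_dge_k)  # K-hop mass differs
    with pytest.raises(ValueError):
        gpo_loss(params, ds.P, small_dge, ablation="nope")


def test_sp_only_on_zero_matrix_is_identically_zero():
    params = _params(np.full((3, 3), -BIG))
    out = gpo_loss(params, np.zeros((2, 3)), np.zeros((2, 3)), ablation="sp_only")
    assert out.j_dge_k == 0.0 and out.j_sp == pytest.approx(0.0) \
        and out.j_gpo == pytest.approx(0.0)


def test_dge_only_vs_full_diverge_once_two_hop_paths_exist(small_sim, small_dge):
    _, _, ds = small_sim
    V = ds.vocab.size
    logits = np.full((V, V), -BIG)
    logits[0, 2] = BIG
    logits[2, 1] = BIG
    params = CausalParamMatrix(ds.vocab.genes, logits=logits)
    dge = gpo_loss(params, ds.P, small_dge, K=5, ablation="dge_only")
    dgek = gpo_loss(params, ds.P, small_dge, K=5, ablation="dgek_only")
    assert dge.j_dge_k != pytest.approx(dgek.j_dge_k)
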