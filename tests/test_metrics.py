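"""Prediction metrics and statistical GRN evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import wasserstein_distance

from gpovae import (
    CausalParamMatrix,
    GroundTruthGRN,
    PerturbDataset,
    SimulationConfig,
    ate_pearson,
    ate_r2,
    evaluate_grn,
    extract_grn,
    false_omission_rate,
    hub_genes,
    jaccard_top_k,
    mean_wasserstein,
    restrict_to_perturbed,
    simulate_perturbseq,
)
from gpovae.io import CONTROL_LABEL
from gpovae.metrics import GRN


# ---------------------------------------------------------------------------
# ATE metrics
# ---------------------------------------------------------------------------

def test_pearson_hand_values():
    assert ate_pearson([1, 2, 3], [2, 4, 7]) == pytest.approx(0.9934, abs=5e-5)
    assert ate_pearson([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
    assert ate_pearson([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)
    assert ate_pearson([1, 1, 1], [1, 2, 3]) is None  # undefined, not NaN


def test_r2_hand_values():
    assert ate_r2([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
    assert ate_r2([2, 2, 2], [1, 2, 3]) == pytest.approx(0.0)  # predict the mean
    assert ate_r2([3, 2, 1], [1, 2, 3]) == pytest.approx(-3.0)  # unbounded below
    assert ate_r2([1, 2, 3], [5, 5, 5]) is None


def test_jaccard_hand_values_and_properties(rng):
    a = rng.normal(size=100)
    assert jaccard_top_k(a, a, k=50) == pytest.approx(1.0)
    b = np.zeros(100)
    b[:50] = 1.0
    c = np.zeros(100)
    c[50:] = 1.0
    assert jaccard_top_k(b, c, k=50) == 0.0
    # 30 shared of top-50 each -> 30 / 70
    x = np.zeros(100)
    x[:50] = 10.0
    y = np.zeros(100)
    y[20:70] = 10.0
    assert jaccard_top_k(x, y, k=50) == pytest.approx(30 / 70)
    d = rng.normal(size=100)
    assert jaccard_top_k(a, d, k=20) == jaccard_top_k(d, a, k=20)  # symmetric
    assert 0.0 <= jaccard_top_k(a, d, k=20) <= 1.0
    with pytest.raises(ValueError):
        jaccard_top_k(a, d, k=101)


# ---------------------------------------------------------------------------
# GRN extraction
# ---------------------------------------------------------------------------

@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1), st.integers(1, 40))
def test_jaccard_bounded_and_symmetric(seed, k):
    rng = np.random.default_rng(seed)
    a, b = rng.normal(size=40), rng.normal(size=40)
    j = jaccard_top_k(a, b, k=k)
    assert 0.0 <= j <= 1.0
    assert j == jaccard_top_k(b, a, k=k)
    assert jaccard_top_k(a, a, k=k) == 1.0


def test_fresh_initialization_yields_zero_edges():
    params = CausalParamMatrix(list("abc"))
    assert extract_grn(params, threshold=0.5).n_edges == 0  # strict inequality


def test_saturated_matrix_yields_complete_graph_with_self_loops():
    grn = extract_grn(np.ones((3, 3)) * 0.999, threshold=0.5)
    assert grn.n_edges == 9
    assert ("g0", "g0") in grn.edge_set()


def test_mixed_matrix_keeps_exactly_supra_threshold_entries():
    probs = np.full((4, 4), 0.2)
    probs[0, 1], probs[2, 3], probs[3, 3] = 0.9, 0.6, 0.51
    grn = extract_grn(probs, threshold=0.5)
    assert grn.edge_set() == {("g0", "g1"), ("g2", "g3"), ("g3", "g3")}


def test_threshold_nesting(rng):
    probs = rng.random((6, 6))
    prev = extract_grn(probs, threshold=0.1).edge_set()
    for t in (0.3, 0.5, 0.7, 0.9):
        cur = extract_grn(probs, threshold=t).edge_set()
        assert cur <= prev
        prev = cur
    with pytest.raises(ValueError):
        extract_grn(probs, threshold=0.0)


def test_restrict_to_perturbed_drops_extended_touching_edges():
    probs = np.array([[0.9, 0.9], [0.9, 0.1]])
    grn = extract_grn(probs, genes=["p1", "e1"])
    kept = restrict_to_perturbed(grn, ["p1"])
    assert kept.edge_set() == {("p1", "p1")}


def test_grn_tsv_round_trip(tmp_path):
    probs = np.array([[0.9, 0.6], [0.2, 0.8]])
    grn = extract_grn(probs, genes=["a", "b"])
    path = str(tmp_path / "grn.tsv")
    grn.write_tsv(path)
    back = GRN.read_tsv(path)
    assert back.edge_set() == grn.edge_set()


# ---------------------------------------------------------------------------
# Wasserstein evaluation
# ---------------------------------------------------------------------------

def _two_group_dataset(ctrl_vals, pert_vals):
    """Controls and 'a'-perturbed cells with target gene 'b' values fixed."""
    n_c, n_p = len(ctrl_vals), len(pert_vals)
    X = np.zeros((n_c + n_p, 3), dtype=np.int64)
    X[:, 0] = 10_000  # dominant filler gene fixes the library size
    X[:n_c, 1] = ctrl_vals
    X[n_c:, 1] = pert_vals
    labels = np.array([CONTROL_LABEL] * n_c + ["a"] * n_p, dtype=object)
    return PerturbDataset(X=X, gene_names=["filler", "b", "a"],
                          treatment_labels=labels)


def test_w1_hand_value_on_equal_samples():
    ds = _two_group_dataset([0, 0, 1, 1], [1, 1, 2, 2])
    grn = GRN(edges=pd.DataFrame({"source": ["a"], "target": ["b"],
                                  "weight": [0.9]}),
              genes=["a", "b"], threshold=0.5)
    mu, table = mean_wasserstein(grn, ds)
    # log1p CP10K is monotone; with equal libraries W1 = mean sorted gap
    from gpovae.io import lognorm

    norm = lognorm(ds.X)
    expect = np.abs(np.sort(norm[:4, 1]) - np.sort(norm[4:, 1])).mean()
    assert mu == pytest.approx(expect, abs=1e-12)
    assert mu == pytest.approx(
        wasserstein_distance(norm[:4, 1], norm[4:, 1]), abs=1e-12)


def test_identical_distributions_have_zero_wd():
    ds = _two_group_dataset([3, 5, 7, 9], [3, 5, 7, 9])
    grn = GRN(edges=pd.DataFrame({"source": ["a"], "target": ["b"],
                                  "weight": [0.9]}),
              genes=["a", "b"], threshold=0.5)
    mu, _ = mean_wasserstein(grn, ds)
    assert mu == pytest.approx(0.0, abs=1e-12)


def test_empty_grn_muwd_is_zero(small_sim):
    _, _, ds = small_sim
    grn = GRN(edges=pd.DataFrame(columns=["source", "target", "weight"]),
              genes=ds.vocab.genes, threshold=0.5)
    mu, table = mean_wasserstein(grn, ds)
    assert mu == 0.0 and len(table) == 0
    report = evaluate_grn(grn, ds)
    assert report.mu_wd == 0.0 and report.n_edges == 0


def test_non_interventional_sources_are_skipped_not_scored(small_sim):
    _, _, ds = small_sim
    ext = ds.vocab.extended[0]
    tgt = ds.vocab.perturbed[0]
    grn = GRN(edges=pd.DataFrame({"source": [ext], "target": [tgt],
                                  "weight": [0.9]}),
              genes=ds.vocab.genes, threshold=0.5)
    mu, table = mean_wasserstein(grn, ds)
    assert mu == 0.0
    assert not table["evaluable"].any()


# ---------------------------------------------------------------------------
# false omission rate
# ---------------------------------------------------------------------------

def _null_sim(seed=0):
    cfg = SimulationConfig(n_perturbed=10, n_extended=0, n_other_genes=10,
                           cells_per_treatment=60, n_control=60,
                           edge_density=0.05, n_hubs=0, artifact_rate=0.0,
                           on_target_knockdown=0.0, seed=seed)
    grn = sample = None
    from gpovae import sample_ground_truth_grn

    grn = sample_ground_truth_grn(cfg)
    grn.effect_sizes[:] = 0.0  # no true effects at all
    ds, _ = simulate_perturbseq(grn, cfg)
    return cfg, ds


def test_dense_grn_hits_negative_free_sentinel(small_sim):
    _, _, ds = small_sim
    genes = ds.vocab.genes
    pairs = [(i, j) for i in genes for j in genes if i != j]
    grn = GRN(edges=pd.DataFrame(
        {"source": [p[0] for p in pairs], "target": [p[1] for p in pairs],
         "weight": 0.9}), genes=genes, threshold=0.5)
    assert false_omission_rate(grn, ds) == -1.0


def test_null_simulation_for_is_calibrated():
    _, ds = _null_sim()
    grn = GRN(edges=pd.DataFrame(columns=["source", "target", "weight"]),
              genes=[g for g in ds.gene_names], threshold=0.5)
    rate = false_omission_rate(grn, ds, fdr=0.05)
    assert 0.0 <= rate <= 0.10  # below twice the nominal FDR under the null


def test_planted_truth_grn_has_near_zero_for():
    # plenty of background genes keep the compositional closure shift (the
    # relative rise of every other gene when the target drops) below the
    # detection threshold, as in genome-scale screens
    cfg = SimulationConfig(n_perturbed=8, n_extended=0, n_other_genes=92,
                           cells_per_treatment=80, n_control=80,
                           edge_density=0.15, n_hubs=0, artifact_rate=0.0,
                           max_hops=1, effect_range=(1.5, 2.0), seed=3)
    from gpovae import sample_ground_truth_grn

    grn_true = sample_ground_truth_grn(cfg)
    ds, _ = simulate_perturbseq(grn_true, cfg)
    src, tgt = np.nonzero(grn_true.adjacency)
    genes = cfg.vocabulary().genes
    edges = pd.DataFrame({"source": [genes[i] for i in src],
                          "target": [genes[j] for j in tgt], "weight": 0.9})
    grn = GRN(edges=edges, genes=genes, threshold=0.5)
    assert false_omission_rate(grn, ds) < 0.15


def test_adding_edges_never_increases_for(small_sim):
    _, _, ds = small_sim
    genes = ds.vocab.genes
    rng = np.random.default_rng(1)
    pairs = [(i, j) for i in ds.treatments() for j in genes if i != j]
    order = rng.permutation(len(pairs))
    prev = None
    for n_edges in (0, 10, 25, len(pairs)):
        chosen = [pairs[k] for k in order[:n_edges]]
        grn = GRN(edges=pd.DataFrame(
            {"source": [p[0] for p in chosen],
             "target": [p[1] for p in chosen], "weight": 0.9}),
            genes=genes, threshold=0.5)
        rate = false_omission_rate(grn, ds)
        if prev is not None and prev >= 0 and rate >= 0:
            assert rate <= prev + 1e-12
        prev = rate


# ---------------------------------------------------------------------------
# hub genes
# ---------------------------------------------------------------------------

def test_hub_ranking():
    assert hub_genes(np.zeros((4, 4))) == []  # no degree, no ranking
    star = np.zeros((5, 5))
    star[2, :] = 0.9  # out-edges from the center
    star[:, 2] = 0.9  # in-edges to the center
    assert hub_genes(star, top_n=1) == ["g2"]
    # hand-set combined degrees (4, 3, 3, 1, 0) -> deterministic tie order
    probs = np.zeros((5, 5))
    probs[0, [1, 2, 3, 4]] = 0.9          # g0: out 4
    probs[1, [2, 3, 4]] = 0.9             # g1: out 3
    probs[2, [3, 4]] = 0.9                # g2: out 2 (+2 in = 4 total)
    degrees = (probs > 0.3).sum(0) + (probs > 0.3).sum(1)
    top = hub_genes(probs, degree_threshold=0.3, top_n=3)
    expect = [f"g{i}" for i in np.lexsort((np.arange(5), -degrees))[:3]]
    assert top == expect


def test_hub_threshold_binarizes():
    probs = np.full((3, 3), 0.29)
    assert hub_genes(probs, degree_threshold=0.3) == []
    assert hub_genes(probs, degree_threshold=0.2) != []
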