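import numpy as np
import pytest
import scipy.sparse as sp

from spatialsig.core_io import NormalizedMatrix
from spatialsig.preprocessing import normalize_log
from spatialsig.scoring import (
    builtin_gene_list_names,
    cell_cycle_score,
    expression_bins,
    load_builtin_gene_list,
    module_score,
    phase_distribution,
    rescore,
    score_contrast,
)
from spatialsig.synthetic_data import SyntheticSpec, generate_dataset

from conftest import make_dataset


def constant_norm(n_genes, n_spots, c=1.0):
    return NormalizedMatrix(
        values=sp.csr_matrix(np.full((n_genes, n_spots), c)), scale_factor=1e4
    )


def gene_ids(n):
    return np.array([f"g{i:03d}" for i in range(n)], dtype=object)


def test_constant_matrix_scores_zero():
    norm = constant_norm(60, 10)
    res = module_score(norm, gene_ids(60), [f"g{i:03d}" for i in range(5)], n_bins=3, n_ctrl=5, seed=0)
    assert np.allclose(res.score, 0.0, atol=1e-12)


def test_score_matches_brute_force_formula(default_bundle):
    """Oracle: direct dense recomputation from the drawn controls."""
    ds, norm, truth = (
        default_bundle["dataset"],
        default_bundle["norm"],
        default_bundle["truth"],
    )
    genes = list(truth["genes"].query("set_name == 'blastema_program'")["gene"])[:20]
    res = module_score(norm, ds.gene_ids, genes, seed=42)
    dense = norm.values.toarray()
    idx = {g: i for i, g in enumerate(ds.gene_ids)}
    sig_rows = np.array([idx[g] for g in res.gene_set])
    pooled = np.concatenate([res.controls[g] for g in sorted(res.gene_set)])
    expected = dense[sig_rows].mean(axis=0) - dense[pooled].mean(axis=0)
    assert np.allclose(res.score, expected, atol=1e-12)
    # planted contrast positive
    bl = ds.spots_in_regions(["blastema"])
    rest = ds.spots_in_regions(["digit", "bone", "boundary"])
    assert res.score[bl].mean() > res.score[rest].mean()


def test_seeded_determinism(default_bundle):
    ds, norm = default_bundle["dataset"], default_bundle["norm"]
    genes = [str(g) for g in ds.gene_ids[:15]]
    a = module_score(norm, ds.gene_ids, genes, seed=9)
    b = module_score(norm, ds.gene_ids, genes, seed=9)
    c = module_score(norm, ds.gene_ids, genes, seed=10)
    assert np.array_equal(a.score, b.score)
    assert all(np.array_equal(a.controls[g], b.controls[g]) for g in genes)
    assert not np.array_equal(a.score, c.score)


def test_shift_equivariance_exact(default_bundle):
    """+1 on signature genes in a spot subset raises scores by exactly 1."""
    ds, norm = default_bundle["dataset"], default_bundle["norm"]
    genes = [str(g) for g in ds.gene_ids[200:220]]
    res = module_score(norm, ds.gene_ids, genes, seed=3)
    shifted = norm.values.toarray()
    rows = [list(ds.gene_ids).index(g) for g in genes]
    subset = ds.spots_in_regions(["blastema"])
    shifted[np.ix_(rows, subset)] += 1.0
    shifted_norm = NormalizedMatrix(sp.csr_matrix(shifted), norm.scale_factor)
    new_score = rescore(shifted_norm, ds.gene_ids, res)
    delta = new_score - res.score
    assert np.allclose(delta[subset], 1.0, atol=1e-12)
    others = np.setdiff1d(np.arange(ds.n_spots), subset)
    assert np.allclose(delta[others], 0.0, atol=1e-12)


def test_empty_intersection_is_hard_error(default_bundle):
    ds, norm = default_bundle["dataset"], default_bundle["norm"]
    with pytest.raises(ValueError, match="missing"):
        module_score(norm, ds.gene_ids, ["NotAGene1", "NotAGene2"])


def test_full_universe_rejected():
    norm = constant_norm(10, 4)
    with pytest.raises(ValueError, match="whole gene universe"):
        module_score(norm, gene_ids(10), [f"g{i:03d}" for i in range(10)], n_bins=2, n_ctrl=2)


def test_small_bin_falls_back_to_replacement():
    rng = np.random.default_rng(0)
    norm = NormalizedMatrix(sp.csr_matrix(rng.random((12, 6))), 1e4)
    res = module_score(norm, gene_ids(12), ["g000"], n_bins=6, n_ctrl=5, seed=0)
    assert res.sampled_with_replacement == ["g000"]


def test_expression_bins_equal_frequency(default_bundle):
    ds, norm = default_bundle["dataset"], default_bundle["norm"]
    bins = expression_bins(norm, ds.gene_ids, 24)
    counts = np.bincount(bins, minlength=24)
    assert counts.min() >= len(ds.gene_ids) // 24
    assert counts.max() <= len(ds.gene_ids) // 24 + 1


def test_cell_cycle_phase_rules(default_bundle):
    ds, norm, truth = (
        default_bundle["dataset"],
        default_bundle["norm"],
        default_bundle["truth"],
    )
    s_genes = list(truth["genes"].query("role == 'cycle_s'")["gene"])
    g2m_genes = list(truth["genes"].query("role == 'cycle_g2m'")["gene"])
    cc = cell_cycle_score(norm, ds.gene_ids, s_genes, g2m_genes, seed=5)
    top = np.maximum(cc.s_score, cc.g2m_score)
    assert np.all((cc.phase == "G1") == (top <= 0))
    pos = top > 0
    assert np.all(
        cc.phase[pos]
        == np.where(cc.s_score[pos] >= cc.g2m_score[pos], "S", "G2M")
    )


def test_cell_cycle_phase_recovery(default_bundle):
    ds, norm, truth = (
        default_bundle["dataset"],
        default_bundle["norm"],
        default_bundle["truth"],
    )
    s_genes = list(truth["genes"].query("role == 'cycle_s'")["gene"])
    g2m_genes = list(truth["genes"].query("role == 'cycle_g2m'")["gene"])
    cc = cell_cycle_score(norm, ds.gene_ids, s_genes, g2m_genes, seed=5)
    true_phase = truth["spots"]["phase"].to_numpy()
    assert (cc.phase == true_phase).mean() >= 0.95


def test_score_contrast_identical_scores(toy_dataset):
    scores = np.ones(4)
    diff, p, _ = score_contrast(scores, toy_dataset, "blastema", "digit")
    assert diff == 0.0 and p == 1.0


def test_score_contrast_exact_enumeration():
    regions = ["a"] * 3 + ["b"] * 3
    ds = make_dataset(np.ones((1, 6), dtype=int), regions=regions)
    scores = np.array([10.0, 11, 12, 0, 1, 2])
    diff, p, _ = score_contrast(scores, ds, "a", "b")
    assert diff == 10.0 and p == 2 / 20  # C(6,3) = 20 assignments, 2 extreme


def test_phase_distribution_hand_case(toy_dataset):
    from spatialsig.scoring import CellCycleResult

    cc = CellCycleResult(
        s_score=np.zeros(4),
        g2m_score=np.zeros(4),
        phase=np.array(["S", "S", "G1", "G2M"], dtype=object),
    )
    ds = toy_dataset.subset_spots(np.arange(4))
    ds.regions[:] = "blastema"
    dist = phase_distribution(cc, ds).set_index("region")
    assert dist.loc["blastema", ["S", "G2M", "G1"]].tolist() == [0.5, 0.25, 0.25]
    assert np.isclose(dist[["S", "G2M", "G1"]].sum(axis=1), 1).all()


def test_builtin_gene_lists_load():
    names = builtin_gene_list_names()
    assert {"s_phase", "g2m_phase", "glycolysis", "oxphos", "wnt"} <= set(names)
    s = load_builtin_gene_list("s_phase")
    assert "Pcna" in s and len(s) > 20
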