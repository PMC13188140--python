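"""Rank-sum testing, FDR adjustment and the marker-finding filters."""

import numpy as np
import pytest
from scipy import stats

from skinspace.de import (
    _exact_rank_sum_p,
    bh_adjust,
    find_markers,
    log2_fold_change,
    rank_sum_test,
)
from skinspace.qc import normalize


def test_exact_enumeration_extreme_case():
    """(1,2,3) vs (4,5,6): the most extreme of C(6,3)=20 rank splits,
    one-sided mass 1/20, two-sided p = 0.1."""
    _, p = rank_sum_test([1, 2, 3], [4, 5, 6])
    assert p == pytest.approx(0.1)


def test_identical_groups_give_p_one():
    _, p = rank_sum_test([1, 2, 3], [1, 2, 3])
    assert p == pytest.approx(1.0)


def test_p_value_symmetric_under_group_swap():
    x, y = [0.3, 1.7, 2.2, 5.0], [0.9, 1.1]
    assert rank_sum_test(x, y)[1] == pytest.approx(rank_sum_test(y, x)[1])


def test_empty_group_rejected():
    with pytest.raises(ValueError):
        rank_sum_test([], [1.0])


def test_exact_enumeration_matches_scipy_exact():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n1 = int(rng.integers(2, 6))
        n2 = int(rng.integers(2, 11 - n1))
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        ours = _exact_rank_sum_p(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert ours == pytest.approx(float(ref), abs=1e-12)


def test_normal_approximation_close_to_enumeration():
    """Tie-free n=5 vs n=5: asymptotic p within 0.03 of the exact p."""
    rng = np.random.default_rng(1)
    worst = 0.0
    for _ in range(200):
        x = rng.normal(size=5)
        y = rng.normal(0.5, size=5)
        exact = _exact_rank_sum_p(x, y)
        approx = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        ).pvalue
        worst = max(worst, abs(exact - float(approx)))
    assert worst <= 0.03


def test_bh_step_up_hand_example():
    adjusted = bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert adjusted == pytest.approx([0.04, 0.04, 0.04, 0.04])


def test_bh_single_value_and_cap():
    assert bh_adjust([0.2]) == pytest.approx([0.2])
    assert (bh_adjust([0.8, 0.9, 1.0]) <= 1.0).all()


def test_bh_preserves_rank_order():
    rng = np.random.default_rng(2)
    p = rng.uniform(size=30)
    adj = bh_adjust(p)
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()
    assert (adj >= p - 1e-12).all()


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])
    with pytest.raises(ValueError, match="unknown adjustment"):
        bh_adjust([0.5], method="holm")


def de_fixture(make_counts, n=200):
    """Two groups of n bins: G_DE shifted between groups, G_RARE detected
    once in group 1, G_NULL balanced, T keeps totals positive."""
    rng = np.random.default_rng(3)
    mat = np.zeros((4, 2 * n), dtype=int)
    mat[0, :n] = rng.poisson(2.0, n)          # G_DE high in group 1
    mat[0, n:] = rng.poisson(0.2, n)
    mat[1, 0] = 1                              # G_RARE: single positive bin
    mat[2, :] = rng.poisson(1.0, 2 * n)        # G_NULL
    mat[3, :] = 5                              # T filler
    counts = make_counts(mat, gene_names=["G_DE", "G_RARE", "G_NULL", "T"])
    labels = np.array(["g1"] * n + ["g2"] * n)
    return normalize(counts), labels


def test_find_markers_min_pct_filter(make_counts):
    norm, labels = de_fixture(make_counts)
    table = find_markers(norm, labels, "g1", "g2", min_pct=0.01)
    genes = set(table["gene"])
    # pct for G_RARE is 1/200 = 0.005 in group 1 and 0 in group 2 -> excluded
    assert "G_RARE" not in genes
    assert {"G_DE", "G_NULL", "T"} <= genes


def test_find_markers_absent_gene_not_tested(make_counts):
    mat = np.array([[0, 0, 0, 0], [1, 1, 1, 1]])
    norm = normalize(make_counts(mat, gene_names=["G_OFF", "T"]))
    labels = np.array(["a", "a", "b", "b"])
    table = find_markers(norm, labels, "a", "b")
    assert "G_OFF" not in set(table["gene"])


def test_find_markers_excludes_mt_genes(make_counts):
    mat = np.ones((2, 6), dtype=int)
    norm = normalize(make_counts(mat, gene_names=["MT-CO1", "ACTB"]))
    labels = np.array(["a"] * 3 + ["b"] * 3)
    table = find_markers(norm, labels, "a", "b")
    assert set(table["gene"]) == {"ACTB"}


def test_find_markers_only_pos_keeps_positive_lfc(make_counts):
    norm, labels = de_fixture(make_counts)
    table = find_markers(norm, labels, "g2", "g1", only_pos=True)
    assert (table["log2_fc"] > 0).all()
    assert "G_DE" not in set(table["gene"])  # G_DE is higher in g1


def test_find_markers_overlapping_groups_rejected(make_counts):
    norm, labels = de_fixture(make_counts)
    with pytest.raises(ValueError, match="unknown or empty"):
        find_markers(norm, labels, "g1", "nope")


def test_find_markers_invariant_to_bin_order(make_counts):
    norm, labels = de_fixture(make_counts)
    table = find_markers(norm, labels, "g1", "g2")
    rng = np.random.default_rng(4)
    perm = rng.permutation(norm.n_bins)
    table_perm = find_markers(norm.subset_bins(perm), labels[perm], "g1", "g2")
    assert list(table["gene"]) == list(table_perm["gene"])
    for col in ("p_value", "log2_fc", "pct_1", "pct_2"):
        assert list(table[col]) == pytest.approx(list(table_perm[col]))


def test_adjusted_p_not_below_raw(make_counts):
    norm, labels = de_fixture(make_counts)
    table = find_markers(norm, labels, "g1", "g2")
    assert (table["p_adjusted"] >= table["p_value"] - 1e-12).all()


def test_log2_fc_sign_convention():
    x = np.log1p(np.array([3.0, 3.0]))
    y = np.log1p(np.array([1.0, 1.0]))
    assert log2_fold_change(x, y) == pytest.approx(np.log2(3.0), rel=1e-6)


def test_cdkn1a_induced_in_uv_control(processed):
    """On the default synthetic experiment the senescence gene CDKN1A is
    tested and up in ctrl relative to neg_ctrl."""
    _, _, bins_qc, norm = processed(1)
    table = find_markers(norm, bins_qc["condition"].to_numpy(), "ctrl", "neg_ctrl")
    row = table.set_index("gene").loc["CDKN1A"]
    assert row["log2_fc"] > 0
    assert row["p_adjusted"] < 0.01
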