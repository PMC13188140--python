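"""Positive-bin counts, tissue areas, densities, pooling and consistency."""

import numpy as np
import pandas as pd
import pytest

from skinspace.metrics import (
    directional_consistency,
    density,
    pool_by_condition,
    positive_bins,
    section_metrics,
    tissue_area,
)
from skinspace.qc import normalize


def test_positive_bins_counting(make_counts):
    counts = make_counts([[0, 1, 0, 3, 2], [1, 1, 1, 1, 1]], gene_names=["A", "T"])
    norm = normalize(counts)
    assert positive_bins(norm, "A") == 3
    assert positive_bins(norm, "A", mask=np.array([True, True, False, False, False])) == 1


def test_all_zero_gene_has_no_positive_bins(make_counts):
    counts = make_counts([[0, 0, 0], [1, 2, 1]], gene_names=["A", "T"])
    assert positive_bins(normalize(counts), "A") == 0


def test_unknown_gene_raises(make_counts):
    counts = make_counts([[1, 1]], gene_names=["A"])
    with pytest.raises(KeyError, match="NOPE"):
        positive_bins(normalize(counts), "NOPE")


def test_positive_bins_match_raw_nonzero_oracle(make_counts):
    rng = np.random.default_rng(42)
    for _ in range(20):
        mat = rng.poisson(0.4, size=(6, 40))
        mat[-1, :] += 1  # keep bin totals positive
        counts = make_counts(mat)
        norm = normalize(counts, scale_factor=rng.choice([1e3, 1e4]))
        for gi, gene in enumerate(counts.gene_names):
            assert positive_bins(norm, gene) == int((mat[gi] > 0).sum())


@pytest.mark.parametrize(
    "n_bins, edge, expected",
    [(1, 16.0, 0.000256), (0, 16.0, 0.0), (4069, 16.0, 1.041664), (1, 8.0, 6.4e-5)],
)
def test_tissue_area(n_bins, edge, expected):
    assert tissue_area(n_bins, edge) == pytest.approx(expected, rel=1e-12)


def test_tissue_area_rejects_negative():
    with pytest.raises(ValueError):
        tissue_area(-1)


@pytest.mark.parametrize(
    "n_pos, area, expected",
    [(256, tissue_area(1000), 1000.0), (0, 0.256, 0.0), (1000, tissue_area(1000), 3906.25)],
)
def test_density(n_pos, area, expected):
    assert density(n_pos, area) == pytest.approx(expected)


def test_density_zero_area_raises():
    with pytest.raises(ValueError):
        density(5, 0.0)


def per_section_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "section_id", "condition", "n_positive_bins",
            "n_tissue_bins", "tissue_area_mm2", "density_per_mm2",
        ],
    )


def test_pooling_sums_before_dividing():
    """Pooled density is sum(pos)/sum(area), not the mean of densities."""
    same = per_section_frame(
        [
            ("G", "s1", "ctrl", 10, 100, 0.1, 100.0),
            ("G", "s2", "ctrl", 30, 300, 0.3, 100.0),
        ]
    )
    assert pool_by_condition(same)["density_per_mm2"].iloc[0] == pytest.approx(100.0)

    uneven = per_section_frame(
        [
            ("G", "s1", "ctrl", 10, 100, 0.1, 100.0),
            ("G", "s2", "ctrl", 10, 300, 0.3, 10 / 0.3),
        ]
    )
    pooled = pool_by_condition(uneven)["density_per_mm2"].iloc[0]
    assert pooled == pytest.approx(50.0)
    assert pooled != pytest.approx((100.0 + 10 / 0.3) / 2)  # mean is ~66.7


def test_single_section_pooling_is_identity():
    one = per_section_frame([("G", "s1", "icon", 7, 50, 0.0128, 7 / 0.0128)])
    pooled = pool_by_condition(one)
    assert pooled["n_positive_bins"].iloc[0] == 7
    assert pooled["density_per_mm2"].iloc[0] == pytest.approx(7 / 0.0128)


def test_pooled_positives_additive_random():
    rng = np.random.default_rng(7)
    rows = []
    for s in range(4):
        pos = int(rng.integers(0, 50))
        nb = int(rng.integers(50, 100))
        rows.append(("G", f"s{s}", "ctrl", pos, nb, tissue_area(nb), 0.0))
    frame = per_section_frame(rows)
    pooled = pool_by_condition(frame)
    assert pooled["n_positive_bins"].iloc[0] == frame["n_positive_bins"].sum()
    assert pooled["tissue_area_mm2"].iloc[0] == pytest.approx(
        frame["tissue_area_mm2"].sum()
    )


def test_split_section_leaves_pooled_metrics_unchanged():
    whole = per_section_frame([("G", "s1", "ctrl", 40, 400, tissue_area(400), 0.0)])
    halves = per_section_frame(
        [
            ("G", "s1a", "ctrl", 15, 150, tissue_area(150), 0.0),
            ("G", "s1b", "ctrl", 25, 250, tissue_area(250), 0.0),
        ]
    )
    a = pool_by_condition(whole)
    b = pool_by_condition(halves)
    for col in ("n_positive_bins", "n_tissue_bins", "tissue_area_mm2", "density_per_mm2"):
        assert a[col].iloc[0] == pytest.approx(b[col].iloc[0])


def consistency_frame(da, db, cond_a="ctrl", cond_b="icon"):
    rows = []
    for i, d in enumerate(da):
        rows.append(("G", f"a{i}", cond_a, 0, 100, 0.0256, d))
    for i, d in enumerate(db):
        rows.append(("G", f"b{i}", cond_b, 0, 100, 0.0256, d))
    frame = per_section_frame(rows)
    # keep pooled density consistent with the per-section densities
    frame["n_positive_bins"] = (frame["density_per_mm2"] * frame["tissue_area_mm2"]).round().astype(int)
    return frame


def test_consistency_unanimous_sections():
    frame = consistency_frame([100.0, 110.0], [50.0, 60.0])
    assert directional_consistency(frame, "ctrl", "icon")["G"] == 1.0


def test_consistency_three_of_four_pairs():
    # pooled ctrl > pooled icon, but one cross pair disagrees
    frame = consistency_frame([200.0, 55.0], [60.0, 20.0])
    assert directional_consistency(frame, "ctrl", "icon")["G"] == pytest.approx(0.75)


def test_consistency_zero_pooled_difference():
    frame = consistency_frame([100.0, 50.0], [60.0, 90.0])
    # pooled difference 0 but every pair differs -> sign(0) matches nothing
    assert directional_consistency(frame, "ctrl", "icon")["G"] == 0.0


def test_consistency_missing_condition_raises():
    frame = consistency_frame([1.0], [2.0])
    with pytest.raises(ValueError, match="neg_ctrl"):
        directional_consistency(frame, "ctrl", "neg_ctrl")


def test_density_invariant_to_renormalization(processed):
    """The positivity metric depends only on the raw zero pattern, so two
    different scale factors give identical densities."""
    _, counts_qc, bins_qc, _ = processed(1)
    sub = bins_qc[bins_qc["section_id"] == bins_qc["section_id"].iloc[0]]
    tables = []
    for sf in (1e4, 1e3):
        norm = normalize(counts_qc, scale_factor=sf)
        tables.append(section_metrics(norm, sub))
    pd.testing.assert_frame_equal(tables[0], tables[1])


def test_section_metrics_missing_panel_gene(processed):
    _, counts_qc, bins_qc, norm = processed(1)
    with pytest.raises(KeyError, match="NOTAGENE"):
        section_metrics(norm, bins_qc, genes=("CDKN1A", "NOTAGENE"))
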