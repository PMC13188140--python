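"""Gene-positive bin counts and densities per mm² of tissue.

For each gene of a senescence/DNA-damage panel and each condition, two
metrics are computed over QC-passing in-tissue bins: (i) the number of
bins with detectable (non-zero) normalized expression, and (ii) that
count divided by the tissue area in mm², where each square bin of edge
e μm contributes (e/1000)² mm². Condition-level values pool bins across
the condition's sections — sums of positives and of area, then one
division — rather than averaging per-section densities.

Directional consistency between two conditions is the constructed
statistic: over all cross pairs (section of a, section of b), the
fraction of pairs whose density difference has the same sign as the
pooled difference, with sign(0) agreeing only with 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .io import NormalizedMatrix

DEFAULT_SENESCENCE_PANEL = (
    "CDKN1A", "CRYAB", "DST", "EZR", "FTL",
    "HMOX1", "KRT6A", "S100A2", "S100A16", "ZFP36",
)


@dataclass
class DensityResult:
    gene: str
    condition: str
    n_positive_bins: int
    n_tissue_bins: int
    tissue_area_mm2: float
    density_per_mm2: float
    consistency: float | None = None


def positive_bins(
    norm: NormalizedMatrix, gene: str, mask: np.ndarray | None = None
) -> int:
    """Number of bins with expression > 0 for one gene.

    Under the zero-preserving transform this equals the raw non-zero
    count, so the metric is invariant to the normalization scale factor.
    """
    vec = norm.gene_vector(gene)
    if mask is not None:
        vec = vec[np.asarray(mask)]
    return int((vec > 0).sum())


def tissue_area(n_tissue_bins: int, bin_edge_um: float = 16.0) -> float:
    """Tissue area in mm² of n square bins with the given edge length."""
    if n_tissue_bins < 0:
        raise ValueError("negative bin count")
    if bin_edge_um <= 0:
        raise ValueError("bin_edge_um must be > 0")
    return n_tissue_bins * (bin_edge_um / 1000.0) ** 2


def density(n_positive: int, area_mm2: float) -> float:
    """Positive bins per mm² of tissue."""
    if area_mm2 <= 0:
        raise ValueError("tissue area must be > 0")
    return n_positive / area_mm2


def section_metrics(
    norm: NormalizedMatrix,
    bins: pd.DataFrame,
    genes: Sequence[str] = DEFAULT_SENESCENCE_PANEL,
    bin_edge_um: float | None = None,
) -> pd.DataFrame:
    """Tidy per-gene metrics for the bins of one section.

    ``bins`` should already be restricted to the counting population
    (QC-passing in-tissue bins by default in the pipeline).
    """
    missing = [g for g in genes if g not in set(norm.gene_names)]
    if missing:
        raise KeyError(f"panel genes missing from matrix: {missing}")
    if bin_edge_um is None:
        bin_edge_um = float(bins["bin_edge_um"].iloc[0]) if len(bins) else 16.0
    n_bins = len(bins)
    area = tissue_area(n_bins, bin_edge_um)
    keep = np.isin(norm.barcodes, bins["barcode"].to_numpy())
    rows = []
    for gene in genes:
        n_pos = positive_bins(norm, gene, mask=keep)
        rows.append(
            {
                "gene": gene,
                "section_id": bins["section_id"].iloc[0] if n_bins else "",
                "condition": bins["condition"].iloc[0] if n_bins else "",
                "n_positive_bins": n_pos,
                "n_tissue_bins": n_bins,
                "tissue_area_mm2": area,
                "density_per_mm2": density(n_pos, area) if area > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def pool_by_condition(per_section: pd.DataFrame) -> pd.DataFrame:
    """Condition-level metrics by pooling bins across sections.

    Counts and areas are summed within (gene, condition) before the
    single division; this is the bins-pooled estimator, not the mean of
    per-section densities.
    """
    if per_section.empty:
        raise ValueError("no per-section metrics to pool")
    pooled = (
        per_section.groupby(["gene", "condition"], sort=False)
        .agg(
            n_positive_bins=("n_positive_bins", "sum"),
            n_tissue_bins=("n_tissue_bins", "sum"),
            tissue_area_mm2=("tissue_area_mm2", "sum"),
            n_sections=("section_id", "nunique"),
        )
        .reset_index()
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled["density_per_mm2"] = np.where(
            pooled["tissue_area_mm2"] > 0,
            pooled["n_positive_bins"] / pooled["tissue_area_mm2"],
            0.0,
        )
    return pooled


def mean_section_density(per_section: pd.DataFrame) -> pd.DataFrame:
    """Alternative summary: unweighted mean of per-section densities."""
    return (
        per_section.groupby(["gene", "condition"], sort=False)["density_per_mm2"]
        .mean()
        .reset_index()
        .rename(columns={"density_per_mm2": "mean_density_per_mm2"})
    )


def _sign(x: float) -> int:
    return int(np.sign(x))


def directional_consistency(
    per_section: pd.DataFrame, condition_a: str, condition_b: str
) -> pd.Series:
    """Per-gene sign-agreement fraction over cross-section pairs.

    A pair (section i of a, section j of b) agrees when the sign of its
    density difference matches the sign of the pooled density difference
    between a and b; a zero pooled difference agrees only with zero pair
    differences.
    """
    for cond in (condition_a, condition_b):
        if cond not in set(per_section["condition"]):
            raise ValueError(f"no sections for condition {cond!r}")
    pooled = pool_by_condition(per_section).set_index(["gene", "condition"])
    out = {}
    for gene, sub in per_section.groupby("gene", sort=False):
        da = sub.loc[sub["condition"] == condition_a, "density_per_mm2"].to_numpy()
        db = sub.loc[sub["condition"] == condition_b, "density_per_mm2"].to_numpy()
        pooled_diff = (
            pooled.loc[(gene, condition_a), "density_per_mm2"]
            - pooled.loc[(gene, condition_b), "density_per_mm2"]
        )
        target = _sign(pooled_diff)
        pairs = [(x, y) for x, y in product(da, db)]
        agree = sum(_sign(x - y) == target for x, y in pairs)
        out[gene] = agree / len(pairs)
    return pd.Series(out, name="consistency")


def density_results(
    pooled: pd.DataFrame, consistency: pd.Series | None = None
) -> list[DensityResult]:
    """Materialize pooled rows (optionally with a consistency score)."""
    results = []
    for _, row in pooled.iterrows():
        cons = None
        if consistency is not None and row["gene"] in consistency.index:
            cons = float(consistency[row["gene"]])
        results.append(
            DensityResult(
                gene=row["gene"],
                condition=row["condition"],
                n_positive_bins=int(row["n_positive_bins"]),
                n_tissue_bins=int(row["n_tissue_bins"]),
                tissue_area_mm2=float(row["tissue_area_mm2"]),
                density_per_mm2=float(row["density_per_mm2"]),
                consistency=cons,
            )
        )
    return results
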