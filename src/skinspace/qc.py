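"""Per-bin quality control and positivity-preserving normalization.

Retention follows the binned-spatial convention: a bin is kept when it
overlaps tissue (``in_tissue = 1``), has at least one count and one
detected gene, and its mitochondrial content is strictly below 15% of
total counts. Mitochondrial genes are identified by the exact,
case-sensitive ``MT-`` name prefix.

Normalization is log1p of depth-scaled counts,
``ln(1 + scale_factor * count / bin_total)`` with a default scale factor
of 10,000. The transform is monotone and zero-preserving, so every
downstream positive-bin count depends only on the raw zero/non-zero
pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, NormalizedMatrix

MT_PREFIX = "MT-"


@dataclass
class QCThresholds:
    require_in_tissue: bool = True
    min_count_exclusive: float = 0.0
    min_feature_exclusive: float = 0.0
    max_percent_mt_exclusive: float = 15.0

    def __post_init__(self) -> None:
        if not (0.0 < self.max_percent_mt_exclusive <= 100.0):
            raise ValueError("max_percent_mt_exclusive must be in (0, 100]")


def compute_percent_mt(counts: CountMatrix, prefix: str = MT_PREFIX) -> np.ndarray:
    """100 x (MT- counts) / (total counts) per bin; zero-total bins give 0."""
    totals = np.asarray(counts.matrix.sum(axis=0)).ravel()
    is_mt = np.array([str(g).startswith(prefix) for g in counts.gene_names])
    if not is_mt.any():
        return np.zeros(counts.n_bins)
    mt_totals = np.asarray(counts.matrix[is_mt, :].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(totals > 0, 100.0 * mt_totals / np.maximum(totals, 1e-300), 0.0)
    return pct


def compute_qc_stats(counts: CountMatrix, bins: pd.DataFrame) -> pd.DataFrame:
    """Populate n_count, n_feature and percent_mt from the raw matrix."""
    bins = bins.copy()
    bins["n_count"] = np.asarray(counts.matrix.sum(axis=0)).ravel()
    bins["n_feature"] = np.asarray((counts.matrix > 0).sum(axis=0)).ravel()
    bins["percent_mt"] = compute_percent_mt(counts)
    return bins


def qc_mask(bins: pd.DataFrame, thresholds: QCThresholds) -> np.ndarray:
    mask = np.ones(len(bins), dtype=bool)
    if thresholds.require_in_tissue:
        mask &= bins["in_tissue"].to_numpy() == 1
    mask &= bins["n_count"].to_numpy() > thresholds.min_count_exclusive
    mask &= bins["n_feature"].to_numpy() > thresholds.min_feature_exclusive
    mask &= bins["percent_mt"].to_numpy() < thresholds.max_percent_mt_exclusive
    return mask


def apply_qc(
    counts: CountMatrix,
    bins: pd.DataFrame,
    thresholds: QCThresholds | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Retain bins passing all criteria; idempotent.

    After the threshold pass, any bin whose normalized column would be
    all-zero (a zero-total bin) is removed in a second pass; under the
    zero-preserving transform this coincides with the n_count rule, so
    the pass is a no-op safeguard rather than a second filter.
    """
    thresholds = thresholds or QCThresholds()
    if bins["percent_mt"].isna().any():
        raise ValueError("percent_mt not populated; run compute_qc_stats first")
    mask = qc_mask(bins, thresholds)
    kept = counts.subset_bins(mask)
    kept_bins = bins.loc[mask].reset_index(drop=True)
    nonzero = np.asarray(kept.matrix.sum(axis=0)).ravel() > 0
    if not nonzero.all():
        kept = kept.subset_bins(nonzero)
        kept_bins = kept_bins.loc[nonzero].reset_index(drop=True)
    return kept, kept_bins


def qc_report(bins: pd.DataFrame, thresholds: QCThresholds | None = None) -> pd.DataFrame:
    """Per-bin pass/fail on each criterion with a failure reason."""
    thresholds = thresholds or QCThresholds()
    report = bins.loc[:, ["barcode", "in_tissue", "n_count", "n_feature", "percent_mt"]].copy()
    if thresholds.require_in_tissue:
        report["pass_in_tissue"] = bins["in_tissue"].to_numpy() == 1
    else:
        report["pass_in_tissue"] = True
    report["pass_n_count"] = bins["n_count"].to_numpy() > thresholds.min_count_exclusive
    report["pass_n_feature"] = (
        bins["n_feature"].to_numpy() > thresholds.min_feature_exclusive
    )
    report["pass_percent_mt"] = (
        bins["percent_mt"].to_numpy() < thresholds.max_percent_mt_exclusive
    )
    crit = ["pass_in_tissue", "pass_n_count", "pass_n_feature", "pass_percent_mt"]
    report["retained"] = report[crit].all(axis=1)

    def reason(row):
        failed = [c.removeprefix("pass_") for c in crit if not row[c]]
        return ";".join(failed)

    report["fail_reason"] = report.apply(reason, axis=1)
    return report


def normalize(counts: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """ln(1 + scale_factor * count / bin_total), per bin."""
    if scale_factor <= 0:
        raise ValueError("scale_factor must be > 0")
    totals = np.asarray(counts.matrix.sum(axis=0)).ravel()
    if counts.n_bins and (totals <= 0).any():
        raise ValueError(
            "bins with zero total counts cannot be normalized; apply QC first"
        )
    mat = sp.csc_matrix(counts.matrix, dtype=float)
    col_of = np.repeat(np.arange(counts.n_bins), np.diff(mat.indptr))
    mat.data = np.log1p(scale_factor * mat.data / totals[col_of])
    return NormalizedMatrix(
        matrix=sp.csr_matrix(mat),
        gene_ids=counts.gene_ids,
        gene_names=counts.gene_names,
        barcodes=counts.barcodes,
        scale_factor=scale_factor,
    )
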