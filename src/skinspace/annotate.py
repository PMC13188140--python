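"""Marker-based epidermal/dermal layer annotation of spatial bins.

Each bin is scored per layer as the mean z-scaled normalized expression
of the layer's marker genes (z-scaling per gene across the bins of the
same section), and labelled with the arg-max layer when that maximum is
strictly positive and unique; otherwise the bin is ``unassigned``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import NormalizedMatrix

DEFAULT_MARKER_PANEL: dict[str, tuple[str, ...]] = {
    "BC": ("TP63",),
    "SC": ("KRT10", "KRTDAP"),
    "GC": ("FLG",),
    "FB": ("COL1A1", "TIMP1"),
}

UNASSIGNED = "unassigned"


def validate_panel(panel: dict[str, tuple[str, ...]]) -> None:
    if not panel:
        raise ValueError("marker panel is empty")
    seen: dict[str, str] = {}
    for label, genes in panel.items():
        if not genes:
            raise ValueError(f"marker set for label {label!r} is empty")
        for g in genes:
            if g in seen:
                raise ValueError(
                    f"gene {g!r} appears in both {seen[g]!r} and {label!r}"
                )
            seen[g] = label


def marker_scores(
    norm: NormalizedMatrix,
    panel: dict[str, tuple[str, ...]] | None = None,
    sections: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-bin per-label score matrix (bins x labels).

    Zero-variance marker genes contribute 0 to their label's score, so a
    section where a marker is never detected degrades gracefully instead
    of dividing by zero.
    """
    panel = panel or DEFAULT_MARKER_PANEL
    validate_panel(panel)
    all_genes = [g for genes in panel.values() for g in genes]
    missing = [g for g in all_genes if g not in set(norm.gene_names)]
    if missing:
        raise KeyError(f"marker genes missing from matrix: {missing}")

    if sections is None:
        section_ids = np.zeros(norm.n_bins, dtype=int)
    else:
        section_ids = np.asarray(sections)
        if len(section_ids) != norm.n_bins:
            raise ValueError("sections length does not match number of bins")

    expr = np.vstack([norm.gene_vector(g) for g in all_genes])  # genes x bins
    z = np.zeros_like(expr)
    for sec in np.unique(section_ids):
        cols = section_ids == sec
        if cols.sum() < 2:
            raise ValueError(
                f"section {sec!r} has fewer than 2 bins; z-scaling undefined"
            )
        block = expr[:, cols]
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=0, keepdims=True)
        safe = np.where(sd > 0, sd, 1.0)
        z[:, cols] = np.where(sd > 0, (block - mu) / safe, 0.0)

    gene_pos = {g: i for i, g in enumerate(all_genes)}
    scores = {
        label: z[[gene_pos[g] for g in genes], :].mean(axis=0)
        for label, genes in panel.items()
    }
    return pd.DataFrame(scores, index=pd.Index(norm.barcodes, name="barcode"))


def assign_labels(scores: pd.DataFrame) -> pd.Series:
    """Arg-max label when strictly positive and unique, else unassigned."""
    values = scores.to_numpy()
    labels = np.array(scores.columns, dtype=object)
    best = values.max(axis=1)
    n_at_max = (values == best[:, None]).sum(axis=1)
    winner = labels[values.argmax(axis=1)]
    out = np.where((best > 0) & (n_at_max == 1), winner, UNASSIGNED)
    return pd.Series(out, index=scores.index, name="layer_label")


def annotate_bins(
    norm: NormalizedMatrix,
    bins: pd.DataFrame,
    panel: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Attach a layer_label column, z-scaling per section when available."""
    sections = bins["section_id"].to_numpy() if "section_id" in bins else None
    scores = marker_scores(norm, panel, sections)
    labels = assign_labels(scores)
    out = bins.copy()
    out["layer_label"] = labels.to_numpy()
    return out


def composition(
    bins: pd.DataFrame,
    by: str = "condition",
    panel: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Per-condition label proportions over {layers, unassigned}; rows sum to 1."""
    if "layer_label" not in bins:
        raise ValueError("labels not assigned; run annotate_bins first")
    labels = list((panel or DEFAULT_MARKER_PANEL).keys()) + [UNASSIGNED]
    table = (
        bins.groupby(by)["layer_label"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=labels, fill_value=0.0)
    )
    table.columns.name = None
    return table


def label_depth_profile(bins: pd.DataFrame) -> pd.DataFrame:
    """Post-hoc spatial concordance report: array-row depth per label."""
    return (
        bins.groupby("layer_label")["array_row"]
        .agg(["mean", "std", "count"])
        .rename(columns={"mean": "mean_row", "std": "sd_row", "count": "n_bins"})
    )
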