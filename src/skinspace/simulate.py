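"""Seeded synthetic Visium-HD-style skin datasets with known ground truth.

The generator emulates a vertically stratified skin section captured on a
square bin grid: a non-tissue background band at the top, then granular
(GC), spinous (SC) and basal (BC) epidermis, and a fibroblast-rich dermis
(FB) below. Three conditions are simulated — an unirradiated negative
control (``neg_ctrl``), a UV-damaged control (``ctrl``) and a UV-damaged,
treated arm (``icon``) — with a configurable number of sections each,
treated as technical replicates.

Counts are negative-binomial with a per-bin log-normal library-size
factor and a per-section depth offset. Canonical layer markers (TP63;
KRT10, KRTDAP; FLG; COL1A1, TIMP1) are strongly enriched in their layer;
a ten-gene senescence/DNA-damage panel is fold-induced by UV and
partially attenuated by treatment; MT- prefixed genes carry a baseline
mitochondrial fraction with a spiked subpopulation that exercises the
percent.mt QC filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, write_dataset

CONDITIONS = ("neg_ctrl", "ctrl", "icon")
LAYERS = ("background", "GC", "SC", "BC", "FB")

MARKER_GENES = {
    "BC": ("TP63",),
    "SC": ("KRT10", "KRTDAP"),
    "GC": ("FLG",),
    "FB": ("COL1A1", "TIMP1"),
}

SENESCENCE_GENES = (
    "CDKN1A", "CRYAB", "DST", "EZR", "FTL",
    "HMOX1", "KRT6A", "S100A2", "S100A16", "ZFP36",
)

MT_GENES = ("MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-CYB")


@dataclass
class SimulationConfig:
    """Study design and noise model for one simulated experiment.

    ``layer_geometry`` gives the top-to-bottom band fractions of the grid
    for (background, GC, SC, BC, FB); they must sum to 1. ``uv_fold`` and
    ``icon_fold`` are the fold inductions of the senescence panel under
    the UV-damaged control and the treated arm (1 <= icon_fold <= uv_fold).
    ``dispersion`` is the negative-binomial size parameter theta;
    ``libsize_sigma`` the log-sd of the per-bin depth factor.
    """

    grid_rows: int = 64
    grid_cols: int = 64
    bin_edge_um: float = 16.0
    conditions: tuple[str, ...] = CONDITIONS
    sections_per_condition: int = 2
    layer_geometry: tuple[float, ...] = (0.20, 0.08, 0.16, 0.16, 0.40)
    baseline_mean: float = 0.2
    marker_in_mean: float = 5.0
    marker_off_mean: float = 0.02
    dispersion: float = 10.0
    libsize_sigma: float = 0.25
    section_depth_factors: tuple[float, ...] = (1.0, 1.15)
    uv_fold: float = 4.0
    icon_fold: float = 1.5
    mt_fraction: float = 0.05
    mt_spike_fraction: float = 0.05
    mt_spike_factor: float = 10.0
    background_ambient: float = 0.05
    n_filler_genes: int = 180
    filler_mean_range: tuple[float, float] = (0.05, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1.0 <= self.icon_fold <= self.uv_fold):
            raise ValueError(
                f"need 1 <= icon_fold <= uv_fold, got icon_fold={self.icon_fold}, "
                f"uv_fold={self.uv_fold}"
            )
        if len(self.layer_geometry) != len(LAYERS):
            raise ValueError("layer_geometry needs one fraction per layer")
        if abs(sum(self.layer_geometry) - 1.0) > 1e-9:
            raise ValueError("layer_geometry band fractions must sum to 1")
        if any(f < 0 for f in self.layer_geometry):
            raise ValueError("layer_geometry fractions must be non-negative")
        if self.dispersion <= 0:
            raise ValueError("dispersion (NB size) must be > 0")
        if self.baseline_mean < 0 or self.libsize_sigma < 0:
            raise ValueError("baseline_mean and libsize_sigma must be >= 0")
        if len(self.section_depth_factors) < self.sections_per_condition:
            raise ValueError("need a depth factor per section")
        if any(d <= 0 for d in self.section_depth_factors):
            raise ValueError("section depth factors must be > 0")

    def condition_fold(self, condition: str) -> float:
        return {"neg_ctrl": 1.0, "ctrl": self.uv_fold, "icon": self.icon_fold}[
            condition
        ]


@dataclass
class GroundTruth:
    """Generator-side truth for parameter-recovery tests.

    ``layer_labels`` covers every in-tissue bin exactly once;
    ``expected_mean`` is the tissue-average expected count per bin for
    each gene (library-size factor has mean one, so it is also the
    marginal expectation at unit section depth).
    """

    layer_labels: pd.Series
    expected_mean: pd.Series
    senescence_genes: tuple[str, ...]
    condition_folds: dict[str, float]
    mt_spiked: pd.Series


@dataclass
class SectionDataset:
    counts: CountMatrix
    bins: pd.DataFrame
    truth: GroundTruth
    condition: str
    section_id: str
    bin_edge_um: float


def gene_panel(config: SimulationConfig) -> pd.DataFrame:
    """Panel of markers, senescence genes, MT- genes and filler genes
    with their baseline (neg_ctrl, off-layer) NB means."""
    marker_names = list(sum(MARKER_GENES.values(), ()))
    names = marker_names + list(SENESCENCE_GENES) + list(MT_GENES)
    means = [config.marker_off_mean] * len(marker_names) + [config.baseline_mean] * (
        len(SENESCENCE_GENES) + len(MT_GENES)
    )

    lo, hi = config.filler_mean_range
    filler_means = np.geomspace(lo, hi, config.n_filler_genes)
    for i, m in enumerate(filler_means):
        names.append(f"FILLER{i + 1:03d}")
        means.append(float(m))

    # MT baseline set so the expected mitochondrial share of a typical
    # tissue bin is mt_fraction; marker contribution averaged over layers.
    tissue_fracs = np.asarray(config.layer_geometry[1:], dtype=float)
    tissue_fracs = tissue_fracs / tissue_fracs.sum() if tissue_fracs.sum() else tissue_fracs
    marker_extra = 0.0
    for layer, genes in MARKER_GENES.items():
        frac = tissue_fracs[LAYERS.index(layer) - 1]
        marker_extra += frac * len(genes) * (config.marker_in_mean - config.marker_off_mean)
    non_mt_total = (
        sum(means) - len(MT_GENES) * config.baseline_mean + marker_extra
    )
    mt_total = config.mt_fraction / (1.0 - config.mt_fraction) * non_mt_total
    panel = pd.DataFrame({"gene_name": names, "baseline_mean": means})
    panel.loc[panel["gene_name"].isin(MT_GENES), "baseline_mean"] = (
        mt_total / len(MT_GENES)
    )
    panel["gene_id"] = [f"SYN{i + 1:05d}" for i in range(len(panel))]
    return panel


def layer_of_rows(config: SimulationConfig) -> np.ndarray:
    """Per-grid-row layer label from the cumulative band fractions."""
    bounds = np.round(np.cumsum(config.layer_geometry) * config.grid_rows).astype(int)
    bounds[-1] = config.grid_rows
    labels = np.empty(config.grid_rows, dtype=object)
    start = 0
    for layer, stop in zip(LAYERS, bounds):
        labels[start:stop] = layer
        start = stop
    return labels


def generate_section(
    config: SimulationConfig, condition: str, section_index: int
) -> SectionDataset:
    """Draw one tissue section; fully determined by (seed, condition, section)."""
    cond_idx = config.conditions.index(condition)
    rng = np.random.default_rng([config.seed, cond_idx, section_index])

    rows = config.grid_rows
    cols = config.grid_cols
    n_bins = rows * cols
    row_layers = layer_of_rows(config)
    array_row = np.repeat(np.arange(rows), cols)
    array_col = np.tile(np.arange(cols), rows)
    bin_layer = row_layers[array_row]
    in_tissue = (bin_layer != "background").astype(int)

    panel = gene_panel(config)
    genes = panel["gene_name"].to_numpy(dtype=object)
    mean = np.tile(panel["baseline_mean"].to_numpy()[:, None], (1, n_bins))

    for layer, layer_genes in MARKER_GENES.items():
        gsel = np.isin(genes, layer_genes)
        bsel = bin_layer == layer
        mean[np.ix_(gsel, bsel)] *= config.marker_in_mean / config.marker_off_mean

    fold = config.condition_fold(condition)
    sen_sel = np.isin(genes, SENESCENCE_GENES)
    mean[np.ix_(sen_sel, in_tissue == 1)] *= fold

    mt_sel = np.char.startswith(genes.astype(str), "MT-")
    tissue_idx = np.flatnonzero(in_tissue == 1)
    n_spike = int(round(config.mt_spike_fraction * tissue_idx.size))
    spike_idx = rng.choice(tissue_idx, size=n_spike, replace=False) if n_spike else np.array([], int)
    mean[np.ix_(mt_sel, spike_idx)] *= config.mt_spike_factor

    mean[:, in_tissue == 0] *= config.background_ambient

    depth = config.section_depth_factors[section_index] * rng.lognormal(
        mean=-config.libsize_sigma**2 / 2.0, sigma=config.libsize_sigma, size=n_bins
    )
    mu = mean * depth[None, :]

    theta = config.dispersion
    p = theta / (theta + mu)
    counts = rng.negative_binomial(theta, p)

    barcodes = np.array(
        [f"BIN_{r:03d}_{c:03d}" for r, c in zip(array_row, array_col)], dtype=object
    )
    section_id = f"{condition}_s{section_index + 1}"
    counts_mat = CountMatrix(
        matrix=sp.csr_matrix(counts),
        gene_ids=panel["gene_id"].to_numpy(dtype=object),
        gene_names=genes,
        barcodes=barcodes,
    )
    bins = pd.DataFrame(
        {
            "barcode": barcodes,
            "in_tissue": in_tissue,
            "array_row": array_row,
            "array_col": array_col,
            "pxl_row": array_row * config.bin_edge_um,
            "pxl_col": array_col * config.bin_edge_um,
            "section_id": section_id,
            "condition": condition,
            "bin_edge_um": config.bin_edge_um,
            "n_count": np.nan,
            "n_feature": np.nan,
            "percent_mt": np.nan,
        }
    )

    tissue_bc = barcodes[in_tissue == 1]
    expected = mean[:, in_tissue == 1].mean(axis=1) if tissue_bc.size else np.zeros(len(genes))
    truth = GroundTruth(
        layer_labels=pd.Series(bin_layer[in_tissue == 1], index=tissue_bc),
        expected_mean=pd.Series(
            expected * config.section_depth_factors[section_index], index=genes
        ),
        senescence_genes=SENESCENCE_GENES,
        condition_folds={c: config.condition_fold(c) for c in config.conditions},
        mt_spiked=pd.Series(np.isin(barcodes, barcodes[spike_idx]), index=barcodes),
    )
    return SectionDataset(
        counts=counts_mat,
        bins=bins,
        truth=truth,
        condition=condition,
        section_id=section_id,
        bin_edge_um=config.bin_edge_um,
    )


def generate_dataset(config: SimulationConfig) -> list[SectionDataset]:
    """All condition x section datasets for one experiment."""
    return [
        generate_section(config, condition, s)
        for condition in config.conditions
        for s in range(config.sections_per_condition)
    ]


def write_experiment(sections: Sequence[SectionDataset], directory) -> list[Path]:
    """One dataset directory per section, named <condition>_s<k>."""
    directory = Path(directory)
    paths = []
    for ds in sections:
        paths.append(
            write_dataset(
                ds.counts,
                ds.bins,
                directory / ds.section_id,
                bin_edge_um=ds.bin_edge_um,
                section_id=ds.section_id,
                condition=ds.condition,
            )
        )
    return paths
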