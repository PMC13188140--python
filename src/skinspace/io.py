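"""Reading, writing and merging binned spatial expression datasets.

The on-disk layout follows the 10x binned-output convention: a Matrix
Market counts file (genes x bins, integer), header-less ``features.tsv``
and ``barcodes.tsv``, a ``tissue_positions.csv`` with header, and a
``scalefactors.json`` carrying the bin edge length in micrometres plus
optional section/condition labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

DATASET_FILES = (
    "matrix.mtx",
    "features.tsv",
    "barcodes.tsv",
    "tissue_positions.csv",
    "scalefactors.json",
)

POSITION_COLUMNS = (
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row",
    "pxl_col",
)


@dataclass
class CountMatrix:
    """Genes x bins sparse matrix of non-negative integer counts.

    ``gene_ids`` and ``gene_names`` run along the rows, ``barcodes``
    along the columns. Gene identity matching throughout the package is
    by ``gene_names`` string, case-sensitive.
    """

    matrix: sp.csr_matrix
    gene_ids: np.ndarray
    gene_names: np.ndarray
    barcodes: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        n_genes, n_bins = self.matrix.shape
        if len(self.gene_ids) != n_genes or len(self.gene_names) != n_genes:
            raise ValueError(
                f"gene table length {len(self.gene_names)} does not match "
                f"matrix rows {n_genes}"
            )
        if len(self.barcodes) != n_bins:
            raise ValueError(
                f"barcode table length {len(self.barcodes)} does not match "
                f"matrix columns {n_bins}"
            )
        if len(set(self.barcodes)) != n_bins:
            raise ValueError("duplicate barcodes")
        if len(set(self.gene_names)) != n_genes:
            raise ValueError("duplicate gene names")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("negative counts")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    def gene_index(self, gene: str) -> int:
        idx = np.flatnonzero(self.gene_names == gene)
        if idx.size == 0:
            raise KeyError(f"unknown gene name: {gene!r}")
        return int(idx[0])

    def gene_vector(self, gene: str) -> np.ndarray:
        """Dense per-bin vector for one gene."""
        return np.asarray(
            self.matrix.getrow(self.gene_index(gene)).todense()
        ).ravel()

    def subset_bins(self, mask_or_index) -> "CountMatrix":
        cols = np.asarray(mask_or_index)
        if cols.dtype == bool:
            cols = np.flatnonzero(cols)
        return replace(
            self,
            matrix=sp.csr_matrix(self.matrix[:, cols]),
            barcodes=self.barcodes[cols],
        )


@dataclass
class NormalizedMatrix:
    """Depth-scaled log expression with the same axis labels as its counts.

    The transform is positivity preserving: an entry is strictly positive
    exactly when the raw count is.
    """

    matrix: sp.csr_matrix
    gene_ids: np.ndarray
    gene_names: np.ndarray
    barcodes: np.ndarray
    scale_factor: float = 1e4

    __post_init__ = CountMatrix.__post_init__
    n_genes = CountMatrix.n_genes
    n_bins = CountMatrix.n_bins
    gene_index = CountMatrix.gene_index
    gene_vector = CountMatrix.gene_vector
    subset_bins = CountMatrix.subset_bins


def empty_bin_table(barcodes: Sequence[str]) -> pd.DataFrame:
    """Bin table skeleton with QC statistics left unpopulated."""
    return pd.DataFrame(
        {
            "barcode": list(barcodes),
            "n_count": np.nan,
            "n_feature": np.nan,
            "percent_mt": np.nan,
        }
    )


def write_dataset(counts: CountMatrix, bins: pd.DataFrame, directory,
                  bin_edge_um: float = 16.0,
                  section_id: str | None = None,
                  condition: str | None = None) -> Path:
    """Write the five-file dataset layout readable by :func:`read_dataset`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(counts.matrix).astype(np.int64)
    mmwrite(str(directory / "matrix.mtx"), mat, field="integer")
    pd.DataFrame({"gene_id": counts.gene_ids, "gene_name": counts.gene_names}).to_csv(
        directory / "features.tsv", sep="\t", header=False, index=False
    )
    pd.DataFrame({"barcode": counts.barcodes}).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )
    bins.loc[:, list(POSITION_COLUMNS)].to_csv(
        directory / "tissue_positions.csv", index=False
    )
    meta = {"bin_edge_um": float(bin_edge_um)}
    if section_id is not None:
        meta["section_id"] = section_id
    if condition is not None:
        meta["condition"] = condition
    (directory / "scalefactors.json").write_text(json.dumps(meta, indent=1))
    return directory


def read_dataset(directory) -> tuple[CountMatrix, pd.DataFrame]:
    """Load one section; QC statistics are left for qc.compute_qc_stats."""
    directory = Path(directory)
    missing = [f for f in DATASET_FILES if not (directory / f).exists()]
    if missing:
        raise FileNotFoundError(f"missing dataset files in {directory}: {missing}")

    mat = sp.csr_matrix(mmread(str(directory / "matrix.mtx")))
    if mat.nnz and mat.data.min() < 0:
        raise ValueError(f"negative counts in {directory / 'matrix.mtx'}")
    features = pd.read_csv(
        directory / "features.tsv", sep="\t", header=None,
        names=["gene_id", "gene_name"], dtype=str,
    )
    barcodes = pd.read_csv(
        directory / "barcodes.tsv", sep="\t", header=None, names=["barcode"],
        dtype=str,
    )["barcode"].to_numpy(dtype=object)
    positions = pd.read_csv(directory / "tissue_positions.csv")
    meta = json.loads((directory / "scalefactors.json").read_text())

    if mat.shape[0] != len(features):
        raise ValueError(
            f"matrix has {mat.shape[0]} genes but features.tsv lists {len(features)}"
        )
    if mat.shape[1] != len(barcodes):
        raise ValueError(
            f"matrix has {mat.shape[1]} bins but barcodes.tsv lists {len(barcodes)}"
        )
    if len(positions) != len(barcodes) or set(positions["barcode"]) != set(barcodes):
        raise ValueError("tissue_positions.csv barcodes do not match barcodes.tsv")

    counts = CountMatrix(
        matrix=mat,
        gene_ids=features["gene_id"].to_numpy(dtype=object),
        gene_names=features["gene_name"].to_numpy(dtype=object),
        barcodes=barcodes,
    )
    bins = positions.set_index("barcode").loc[list(barcodes)].reset_index()
    bins["bin_edge_um"] = float(meta.get("bin_edge_um", 16.0))
    if "section_id" in meta:
        bins["section_id"] = meta["section_id"]
    if "condition" in meta:
        bins["condition"] = meta["condition"]
    for col in ("n_count", "n_feature", "percent_mt"):
        if col not in bins:
            bins[col] = np.nan
    return counts, bins


def merge_sections(
    datasets: Sequence[tuple[CountMatrix, pd.DataFrame]],
) -> tuple[CountMatrix, pd.DataFrame]:
    """Column-wise concatenation of sections sharing one gene panel.

    With more than one dataset, barcodes are suffixed by section_id so
    pooled bins stay unique; a single dataset passes through unchanged.
    """
    if not datasets:
        raise ValueError("no datasets to merge")
    if len(datasets) == 1:
        return datasets[0]

    ref = datasets[0][0]
    for counts, _ in datasets[1:]:
        if not np.array_equal(counts.gene_names, ref.gene_names):
            raise ValueError("gene panel mismatch between sections")

    matrices, tables, all_barcodes = [], [], []
    for i, (counts, bins) in enumerate(datasets):
        section = str(bins["section_id"].iloc[0]) if "section_id" in bins else str(i)
        suffixed = np.array([f"{bc}-{section}" for bc in counts.barcodes],
                            dtype=object)
        matrices.append(counts.matrix)
        all_barcodes.append(suffixed)
        table = bins.copy()
        table["barcode"] = [f"{bc}-{section}" for bc in table["barcode"]]
        tables.append(table)

    merged_counts = CountMatrix(
        matrix=sp.csr_matrix(sp.hstack(matrices)),
        gene_ids=ref.gene_ids,
        gene_names=ref.gene_names,
        barcodes=np.concatenate(all_barcodes),
    )
    merged_bins = pd.concat(tables, ignore_index=True)
    return merged_counts, merged_bins
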