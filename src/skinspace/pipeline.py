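"""End-to-end pipeline: simulate -> QC -> annotate -> metrics -> DE.

All outputs are plain text (CSV tables plus a JSON manifest), every
table carries the seed and config hash in a comment header, and a rerun
from the manifest reproduces every output byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotate import DEFAULT_MARKER_PANEL, annotate_bins, composition
from .de import find_markers
from .io import merge_sections
from .metrics import (
    DEFAULT_SENESCENCE_PANEL,
    directional_consistency,
    pool_by_condition,
    section_metrics,
)
from .qc import QCThresholds, apply_qc, compute_qc_stats, normalize, qc_report
from .simulate import SimulationConfig, generate_dataset

DEFAULT_COMPARISONS = (("neg_ctrl", "ctrl"), ("icon", "ctrl"))


class PipelineError(RuntimeError):
    """A stage failure, prefixed with the stage name."""


@dataclass
class PipelineConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    marker_panel: dict = field(default_factory=lambda: dict(DEFAULT_MARKER_PANEL))
    senescence_panel: tuple = DEFAULT_SENESCENCE_PANEL
    scale_factor: float = 1e4
    min_pct: float = 0.01
    logfc_threshold: float = 0.0
    p_adjust: str = "BH"
    area_population: str = "qc_passed"  # or "in_tissue"
    comparisons: tuple = DEFAULT_COMPARISONS

    def to_dict(self) -> dict:
        d = asdict(self)
        d["marker_panel"] = {k: list(v) for k, v in self.marker_panel.items()}
        d["senescence_panel"] = list(self.senescence_panel)
        d["comparisons"] = [list(c) for c in self.comparisons]
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", d.pop("simulation", {}))
        qc = d.pop("qc", {})
        markers = d.pop("marker_panel", d.pop("markers", None))
        senescence = d.pop("senescence_panel", d.pop("senescence", None))
        de = d.pop("de", {})
        seed = d.pop("seed", None)
        comparisons = d.pop("comparisons", None)

        def _tuplify(obj):
            return tuple(tuple(v) if isinstance(v, list) else v for v in obj)

        for key in ("conditions", "layer_geometry", "section_depth_factors",
                    "filler_mean_range"):
            if key in sim and isinstance(sim[key], list):
                sim[key] = tuple(sim[key])
        cfg = cls(
            sim=SimulationConfig(**sim),
            qc=QCThresholds(**qc),
            **{k: v for k, v in d.items() if k in (
                "scale_factor", "min_pct", "logfc_threshold", "p_adjust",
                "area_population",
            )},
        )
        if markers:
            cfg.marker_panel = {k: tuple(v) for k, v in markers.items()}
        if senescence:
            cfg.senescence_panel = tuple(senescence)
        for k in ("min_pct", "logfc_threshold", "p_adjust"):
            if k in de:
                setattr(cfg, k, de[k])
        if comparisons:
            cfg.comparisons = _tuplify(comparisons)
        if seed is not None:
            cfg.sim = replace(cfg.sim, seed=int(seed))
        return cfg

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            data = tomllib.loads(path.read_text())
        else:
            import yaml

            data = yaml.safe_load(path.read_text())
        return cls.from_dict(data or {})


def _write_csv(df: pd.DataFrame, path: Path, header: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=index)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage and write the report bundle; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.sim.seed
    chash = config.config_hash()
    header = f"# skinspace seed={seed} config_sha256={chash}\n"
    stats: dict = {}
    stage = "simulate"
    try:
        sections = generate_dataset(config.sim)
        stats["n_sections"] = len(sections)

        stage = "merge"
        counts, bins = merge_sections([(s.counts, s.bins) for s in sections])
        stats["n_bins_total"] = int(counts.n_bins)
        stats["n_genes"] = int(counts.n_genes)

        stage = "qc"
        bins = compute_qc_stats(counts, bins)
        report = qc_report(bins, config.qc)
        _write_csv(report, outdir / "qc_report.csv", header)
        pre_qc_bins = bins
        counts_qc, bins_qc = apply_qc(counts, bins, config.qc)
        stats["n_bins_qc_passed"] = int(counts_qc.n_bins)

        stage = "normalize"
        norm = normalize(counts_qc, scale_factor=config.scale_factor)

        stage = "annotate"
        bins_qc = annotate_bins(norm, bins_qc, config.marker_panel)
        _write_csv(bins_qc, outdir / "bins_annotated.csv", header)
        comp = composition(bins_qc, panel=config.marker_panel)
        _write_csv(comp, outdir / "composition.csv", header, index=True)
        truth_acc = _annotation_accuracy(sections, bins_qc)
        if truth_acc is not None:
            stats["annotation_accuracy"] = truth_acc

        stage = "metrics"
        per_section = []
        for sec_id, sub in bins_qc.groupby("section_id", sort=False):
            if config.area_population == "in_tissue":
                pre = pre_qc_bins
                n_area = int(
                    ((pre["section_id"] == sec_id) & (pre["in_tissue"] == 1)).sum()
                )
            else:
                n_area = None
            tbl = section_metrics(
                norm, sub, config.senescence_panel,
                bin_edge_um=config.sim.bin_edge_um,
            )
            if n_area is not None:
                edge = config.sim.bin_edge_um
                tbl["n_tissue_bins"] = n_area
                tbl["tissue_area_mm2"] = n_area * (edge / 1000.0) ** 2
                tbl["density_per_mm2"] = (
                    tbl["n_positive_bins"] / tbl["tissue_area_mm2"]
                )
            per_section.append(tbl)
        per_section = pd.concat(per_section, ignore_index=True)
        _write_csv(per_section, outdir / "density_per_section.csv", header)
        pooled = pool_by_condition(per_section)
        _write_csv(pooled, outdir / "density_pooled.csv", header)

        cons_rows = []
        for cond_a, cond_b in config.comparisons:
            cons = directional_consistency(per_section, cond_a, cond_b)
            for gene, value in cons.items():
                cons_rows.append(
                    {"gene": gene, "comparison": f"{cond_a}_vs_{cond_b}",
                     "consistency": value}
                )
        _write_csv(pd.DataFrame(cons_rows), outdir / "consistency.csv", header)

        stage = "de"
        labels = bins_qc["condition"].to_numpy()
        for cond_a, cond_b in config.comparisons:
            table = find_markers(
                norm, labels, cond_a, cond_b,
                min_pct=config.min_pct,
                logfc_threshold=config.logfc_threshold,
                p_adjust=config.p_adjust,
            )
            _write_csv(table, outdir / f"de_{cond_a}_vs_{cond_b}.csv", header)
            stats[f"n_genes_tested_{cond_a}_vs_{cond_b}"] = int(len(table))

        stage = "manifest"
        manifest = {
            "seed": seed,
            "config": config.to_dict(),
            "config_sha256": chash,
            "skinspace_version": __version__,
            "stats": stats,
        }
        # no sort_keys: the marker-panel dict order is part of the config
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return manifest
    except Exception as err:
        (outdir / "FAILED").write_text(f"stage={stage}: {err}\n")
        raise PipelineError(f"stage {stage!r} failed: {err}") from err


def _annotation_accuracy(sections, bins_qc: pd.DataFrame) -> float | None:
    """Accuracy of layer labels against generator ground truth, over the
    QC-passing in-tissue bins (unassigned counts as an error)."""
    truth = {}
    for sec in sections:
        if sec.truth is None:
            return None
        for bc, layer in sec.truth.layer_labels.items():
            truth[f"{bc}-{sec.section_id}"] = layer
    labelled = bins_qc.dropna(subset=["layer_label"])
    hits = [
        truth.get(bc) == lab
        for bc, lab in zip(labelled["barcode"], labelled["layer_label"])
        if bc in truth
    ]
    return float(np.mean(hits)) if hits else None


def run_from_manifest(manifest_path, outdir) -> dict:
    """Re-run the pipeline from a manifest's embedded config."""
    manifest = json.loads(Path(manifest_path).read_text())
    cfg_dict = manifest["config"]
    sim = cfg_dict.pop("sim")
    qc = cfg_dict.pop("qc")
    config = PipelineConfig.from_dict({"sim": sim, "qc": qc, **cfg_dict})
    return run_pipeline(config, outdir)
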