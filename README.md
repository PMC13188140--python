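# skinspace

Quantification pipeline for binned (Visium-HD-style) spatial transcriptomics of
UV-stressed human skin, built around a question from photoaging research: does a
topical NAD⁺-repleting treatment attenuate the spatial footprint of cellular
senescence in the epidermis and dermis?

The package implements the full desk analysis — per-bin quality control,
positivity-preserving normalization, marker-based epidermal/dermal layer
annotation, gene-positive-bin counting and density per mm² with condition-level
pooling and cross-section directional consistency, and pairwise rank-sum
differential expression — together with a seeded synthetic data generator that
emulates the three-arm study design (negative control, UV-damaged control,
UV-damaged + treatment; two tissue sections per arm), so every stage is testable
without any external download. A set of standalone calculators covers the
accompanying bench-assay quantifications (comet assay, mitochondrial membrane
potential, vesicle loading efficiency, logistic replicative lifespan,
mitochondrial length classes).

## The core quantities

For a gene *g* and condition *c*, over QC-passing in-tissue bins:

- **Positive bins** `N⁺(g, c)` — bins with normalized expression > 0
  (equivalently raw count ≥ 1 under the zero-preserving transform).
- **Tissue area** `A(c) = n_bins × (e/1000)²` mm² for bin edge *e* μm;
  a 16 μm bin covers 0.000256 mm².
- **Density** `D(g, c) = N⁺(g, c) / A(c)` bins per mm², pooled across a
  condition's sections by summing numerators and areas before dividing.
- **Directional consistency** — over all cross pairs of sections from two
  conditions, the fraction whose density difference has the same sign as the
  pooled difference.

QC keeps bins with `in_tissue = 1`, `n_count > 0`, `n_feature > 0` and
`percent.mt < 15%` (strict), where `percent.mt` sums genes with the exact
`MT-` name prefix. Differential expression uses the two-sided Wilcoxon
rank-sum test with `min.pct = 0.01`, `logfc.threshold = 0`, both directions
kept, `MT-` genes excluded, and Benjamini–Hochberg adjustment.

## Worked example

```python
import skinspace as ss
import pandas as pd

cfg = ss.SimulationConfig(seed=1)            # 64x64 bins, 3 conditions x 2 sections
sections = ss.generate_dataset(cfg)
counts, bins = ss.merge_sections([(s.counts, s.bins) for s in sections])
bins = ss.compute_qc_stats(counts, bins)
counts_qc, bins_qc = ss.apply_qc(counts, bins)
norm = ss.normalize(counts_qc)               # ln(1 + 1e4 * count / bin_total)

per_section = pd.concat(
    [ss.section_metrics(norm, sub) for _, sub in bins_qc.groupby("section_id")],
    ignore_index=True,
)
pooled = ss.pool_by_condition(per_section).set_index(["gene", "condition"])
print(pooled.loc["CDKN1A", "density_per_mm2"])
```

prints

```
condition
ctrl        2110.106319
icon        1082.264742
neg_ctrl     747.052173
Name: density_per_mm2, dtype: float64
```

i.e. the senescence marker CDKN1A (p21) is positive in ~747 bins/mm² of
unirradiated tissue, jumps to ~2110 bins/mm² after UV, and the treated arm sits
at ~1082 bins/mm² — the UV induction is recovered and the treatment attenuation
is visible as a drop back toward baseline. The same ordering holds for the full
ten-gene senescence/DNA-damage panel (CDKN1A, CRYAB, DST, EZR, FTL, HMOX1,
KRT6A, S100A2, S100A16, ZFP36).

The whole pipeline, including annotation, DE tables and a reproducibility
manifest, is one call (or `skinspace run --seed 1 --out out/`):

```python
from skinspace.pipeline import PipelineConfig, run_pipeline
manifest = run_pipeline(PipelineConfig(), "out/")
```

A CLI mirrors each stage (`skinspace simulate|qc|annotate|metrics|de|run`) and
exposes the assay calculators (`comet`, `dpsi`, `loading`, `growth`,
`mito-class`).

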