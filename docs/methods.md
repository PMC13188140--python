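# Methods

## The analysis model

The pipeline quantifies where and how strongly a gene set is expressed across a
tissue section captured on a square bin grid. The unit of observation is the
spatial bin (default edge 16 μm); the raw datum is a genes × bins matrix of
non-negative integer counts plus a per-bin position table with an `in_tissue`
flag. The experiment it is built for is a three-arm skin study — unirradiated
negative control (`neg_ctrl`), UV-damaged control (`ctrl`), and UV-damaged with
an NAD⁺-repleting treatment (`icon`) — with two sections per arm treated as
technical replicates.

Stages, in order:

1. **QC.** Per-bin totals (`n_count`), detected genes (`n_feature`) and
   mitochondrial percentage (`percent_mt`, genes with the exact case-sensitive
   `MT-` prefix) are computed from the raw matrix. A bin is retained iff
   `in_tissue = 1`, `n_count > 0`, `n_feature > 0` and `percent_mt < 15`
   (strict). Zero-total bins are assigned `percent_mt = 0` and then removed by
   the count rule, avoiding 0/0. A second pass removes any bin whose normalized
   column would be all-zero; under the transform below this coincides with the
   count rule, so the pass is an idempotence safeguard. QC is idempotent.

2. **Normalization.** `x → ln(1 + s·count/bin_total)` with scale factor
   `s = 10,000`. This is a deliberate substitution for regularized-NB
   normalization and anchor-based slide integration: the downstream positivity
   metric depends only on the zero/non-zero pattern, which any monotone,
   zero-preserving transform leaves identical, and condition-level summaries
   are pooled on metrics rather than on embeddings. Consequently the positivity
   rule here is exactly `raw count ≥ 1`; it is not a reproduction of
   residual-based expression signs. Cross-slide latent-space integration is
   intentionally absent.

3. **Layer annotation.** Score(label, bin) = mean over the label's marker genes
   of the per-gene z-scaled normalized expression, z-scaling computed across the
   bins of the same section (population sd, ddof 0). Defaults: basal BC {TP63},
   spinous SC {KRT10, KRTDAP}, granular GC {FLG}, fibroblast/dermis FB {COL1A1,
   TIMP1}; a gene may serve only one label. A bin takes the arg-max label when
   the maximum is strictly positive and unique, else `unassigned` (the explicit
   fifth class). Zero-variance genes contribute 0. Bins are annotated directly
   from marker scores — no clustering step precedes annotation, since no
   clustering parameters are part of this design; spatial position enters only
   through an optional post-hoc depth-profile report, never as an assignment
   input.

4. **Density metrics.** For each panel gene and condition: positive bins
   `N⁺` (normalized value > 0) among QC-passing in-tissue bins; tissue area
   `A = n_bins · (edge/1000)²` mm² (0.000256 mm² per 16 μm bin); density
   `N⁺/A`. Condition pooling sums `N⁺` and `A` over the condition's sections
   before dividing (the bins-pooled estimator), so splitting a section in two
   leaves every pooled value unchanged. The area denominator defaults to the
   same population as the numerator (QC-passing bins); an `in_tissue`
   alternative (all pre-QC tissue bins) is exposed as `area_population`
   because the mask-based reading of "tissue area" is also defensible. The
   per-section-mean density is provided alongside as `mean_section_density`.

5. **Directional consistency** is a constructed statistic: over all cross
   pairs (section of condition a × section of condition b), the fraction of
   pairs whose density difference has the same sign as the pooled difference;
   sign(0) agrees only with 0. It formalizes the qualitative requirement that
   an effect be reproduced by every pair of independent sections; 1.0 means
   unanimous ordering.

6. **Differential expression.** Two-sided Wilcoxon rank-sum per gene on
   normalized values. Exact p by full enumeration of rank assignments when
   n₁+n₂ ≤ 10 and tie-free (at most C(10,5) = 252 splits — cheap, and an
   internal oracle for the approximation); otherwise the normal approximation
   with tie and continuity corrections. Genes are tested iff
   max(pct₁, pct₂) ≥ 0.01 and |log2FC| ≥ 0 (both directions kept); `MT-` genes
   are excluded; log2FC = log₂((mean expm1(x₁)+ε)/(mean expm1(x₂)+ε)),
   ε = 1e-9, the usual single-cell convention. Adjustment is
   Benjamini–Hochberg over the tested genes (Bonferroni available via
   `p_adjust`); BH is the default because the surrounding analysis framework
   is FDR-based. The two standard comparisons are `neg_ctrl vs ctrl` and
   `icon vs ctrl`.

## The synthetic generator

Real tissue for this design is not publicly deposited, so the generator is a
first-class module producing the study's conditions with known ground truth.
Geometry is a vertical stack of horizontal bands — background (non-tissue),
then GC/SC/BC epidermis, then FB dermis — with default grid 64×64 and band
fractions (0.20, 0.08, 0.16, 0.16, 0.40) of the grid, i.e. tissue fractions
(GC 0.1, SC 0.2, BC 0.2, FB 0.5). Counts are negative binomial with size
θ = 10 and mean = baseline × layer effect × condition fold × depth, where
depth = per-section factor (defaults 1.0, 1.15) × per-bin log-normal factor
(σ = 0.25, unit mean). Choices and rationale:

- **Baseline mean 0.2 counts/bin/gene, ~200 genes** → ~40–50 counts per 16 μm
  bin: shallow, realistic for fine-binned spatial data, and enough for stable
  rank-sum behavior at ~3,300 tissue bins per section.
- **Markers: in-layer mean 5.0, off-layer mean 0.02.** Canonical structural
  markers (FLG, KRT10, COL1A1, TP63) are among the most layer-restricted and
  abundant transcripts in skin; near-binary layer restriction (≈2% stray
  positivity from ambient/segmentation noise) is the realistic regime. It is
  also the regime the z-score annotator needs: at sparse depths the normalized
  values are nearly binary, so a common off-layer mean as high as the general
  baseline would let single stray counts produce large z-scores and steal
  labels.
- **Senescence panel fold induction**: ctrl ×4.0, icon ×1.5, neg_ctrl ×1,
  applied across all tissue layers (the biology does not pin the induction to
  one compartment, and the metrics are compartment-agnostic).
- **Mitochondrial content**: five `MT-` genes sized so a typical bin has ~5%
  mitochondrial counts; 5% of tissue bins get a ×10 MT spike, pushing them
  past the 15% QC threshold so the filter is exercised (and removing ≈5% of
  bins in every run).
- **Per-gene magnitudes are not calibrated to any real tissue** — no per-gene
  means or dispersions for this design are published. Filler genes span a
  geometric ladder of means (0.05–1.0) for realism.

Determinism: every section's stream is `default_rng([seed, condition_index,
section_index])`, so datasets are reproducible per section and independent
across sections, and the full pipeline rerun from its manifest is
byte-identical.

What the generator does **not** emulate: spatial autocorrelation within a
layer, cell-type mixtures within bins, slide-level batch structure beyond one
scalar depth factor, ambient RNA gradients, segmentation artifacts at layer
boundaries, or multi-resolution re-binning. Passing recovery tests on this
generator therefore demonstrates that the pipeline's logic is correct under a
faithful negative-binomial rendering of the study design — not that the
pipeline's numbers on real UV-stressed skin would be unbiased.

## Bench-assay calculators

Pure functions with validated domains: Tail DNA (%) = 100 × tail/cell
intensity; Olive Tail Moment = Tail DNA (%) / tail moment length — note this
is the division form this pipeline standardizes on, whereas the classical
definition multiplies tail DNA fraction by tail-centre distance; the
discrepancy is flagged in the docstring and deliberately not "corrected".
ΔΨm = F_treatment − F_FCCP. Loading efficiency (%) = 100 × (total − free in
filtrate)/total. Mitochondrial skeleton classes: fragmented < 3 μm ≤
intermediate < 8 μm ≤ elongated; the 3 μm boundary is the only free choice and
is assigned to intermediate (closed lower bound), 8 μm is forced into
elongated. Logistic growth N(t) = K/(1+e^{−r(t−t0)}) is fit by least squares
(initialization: K₀ = 1.05 × max, t0₀ at half-max, r₀ from the early-phase
log-linear slope; non-convergence raises rather than defaulting), and the
replicative-lifespan summary is the closed form t95 = t0 + ln(19)/r, from
0.95K ⇒ e^{−r(t−t0)} = 1/19.

## Numerical and design notes

- Gene identity is matched by name string, case-sensitive; the `MT-` rule is a
  string prefix by construction.
- Bin area derives from the `scalefactors.json` bin edge; 16 μm is only the
  default, never hard-coded downstream.
- Barcodes gain a `-<section_id>` suffix on merge (only when merging more than
  one section, so a single-section merge is the identity).
- Ties at the arg-max of annotation scores are resolved to `unassigned` by
  exact float equality; z-scaling uses population sd.
- BH adjustment delegates to the standard step-up implementation with
  monotonicity enforcement and a cap at 1.
- Test and acceptance problem sizes (64×64 grid, ~200 genes, seeds 1–5, ten
  seeds for null calibration) are the package's chosen desk scale: large enough
  for stable rank-based statistics, small enough to iterate on.

## Known limitations

- The normalization stand-in means absolute normalized magnitudes (and hence
  log fold changes) are not comparable to residual-based workflows; zero
  patterns and rank-based p-values are.
- Annotation accuracy degrades when marker layer-specificity weakens (see the
  generator note above); the score rule has no spatial smoothing.
- Directional consistency with two sections per arm takes values in
  {0, 0.25, 0.5, 0.75, 1}; it is a coarse reproducibility screen, not a test
  statistic.
- DE assumes exchangeable bins within a condition; bins from the same section
  are correlated in real tissue, so p-values on real data would be
  anti-conservative. Pseudobulk or mixed models are out of scope.
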