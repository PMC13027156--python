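# Methods

## Scope and design

`fmtquant` quantifies two microscopy readouts of fibroblast-to-myofibroblast
transition — nuclear translocation of a target protein (Nuclear Enrichment
Index, NEI) and in-situ proximity-ligation puncta per nucleus (PLA index) —
and provides the hierarchical statistics and RNA-seq count bookkeeping that
surround them. Because no public imaging or sequencing data accompany the
study design the package targets, correctness is established by construction:
a first-class synthetic-data module generates inputs whose truth is known
exactly, and every stage is validated by recovering that truth.

## Intensity domain

All intensities live on a float [0, 255] domain. The absolute background
floor of the PLA pipeline (pixels < 80 are zeroed) only has meaning on an
8-bit-like scale, so the simulators, readers and the floor default are all
expressed on it; `intensity_scale` is configurable for other bit depths, in
which case the floor must be rescaled by the caller. Whether real
acquisitions are 8-bit is an assumption, not a certainty — the floor and all
size thresholds are therefore plain parameters.

## Nuclear segmentation and the enrichment index

Pipeline order is fixed: Gaussian smoothing of the DNA-counterstain channel
(σ = 3 px) → global Li minimum-cross-entropy threshold (iterated fixed point
from the array mean; a constant channel raises a "degenerate histogram"
error) → binarization → connected-component labeling → removal of small
components. Conventions the underlying description leaves open, fixed here
and covered by tests:

* binarization keeps pixels **≥** threshold (boundary included);
* components use **8-connectivity**, the common choice for blob labeling;
* the area exclusion is **strict <** (a 700 px object survives; likewise
  25 px puncta and 3000 px PLA nuclei);
* intensity means for the index are taken from the **raw** channels — the
  smoothing exists to stabilize segmentation, not measurement;
* the index pools all nuclear pixels of an image (one value per image);
  per-nucleus ratios are available as an opt-in diagnostic only.

The index is scale-equivariant: rescaling both channels by a common positive
factor leaves it unchanged (tested to 1e-9); rescaling the target channel
alone scales it proportionally.

## PLA puncta detection

Floor (< 80 → 0) **then** blur (σ = 1.5) — in that order; the reverse order
changes results and is exposed as `order="blur_then_floor"` for sensitivity
analysis. Detection then applies the Li threshold, drops components < 25 px,
and splits merged puncta by watershed on the inverted smoothed intensity.
Watershed seeds are regional intensity maxima, plateau-aware (one seed per
connected maximal region), thinned so no two seeds within one component are
closer than 2σ (the brighter seed wins; ties break lexicographically by
position). Size exclusion runs **before** watershed and fragments are not
re-filtered, so the ≥ 25 px guarantee applies to pre-split components. The
split never changes the union of foreground pixels (asserted as a test
invariant). Nuclei in PLA fields use the same pipeline shape with σ = 1.5
and a 3000 px floor; Li thresholding is used there too for internal
consistency, as the thresholding method for that stage is otherwise
unspecified. A field with zero nuclei has an undefined index and is excluded
with a logged error — never reported as infinite.

## Synthetic fields

Nuclei are rendered as randomly oriented ellipses (semi-axes uniform in the
configured radius range) with edges softened by a σ = 2 px blur of the
binary stencil, so Li thresholding is exercised on realistic gradients
rather than a degenerate two-level histogram. Centers are rejection-sampled
(budget: 1000 attempts per object, deterministic given the seed; exhaustion
raises a "field too crowded" error) with pairwise separation large enough
that components remain distinct after the σ = 3 analysis blur. At the
default radius range (17–23 px) every nucleus clears the 700 px floor by
construction; the PLA preset (radii 33–37 px on 384² fields) clears 3000 px.

The translocation target channel is built as
`f · (A_t/A_m) · marker + (1−f) · cytoplasm`, where `f` is the nuclear
fraction of the target signal. With `f = 1` the target is pixel-wise
proportional to the clean marker, so the true enrichment ratio equals
`A_t/A_m` exactly and is invariant to the segmented mask — the property that
makes noise-free recovery exact to floating tolerance. The stored ground
truth is always computed numerically from the clean channels over the true
nuclear support (stencil ≥ 0.5). Noise is additive zero-mean Gaussian,
clipped to range (optional Poisson shot noise), so the measured index is
unbiased; background and amplitude defaults (8 and 100) keep clipping
negligible and the clean signal is required to fit the intensity scale
(overflow raises rather than silently biasing the truth).

PLA spots are 2-D Gaussian kernels (amplitude 160, σ = 2 px — comfortably
above the 80 floor) whose count is Poisson with mean `rate × n_nuclei`. The
default well-separated mode enforces pairwise spot distance > 4σ, which
makes the placed count exactly recoverable; it is the regime in which
recovery claims hold. What the simulator deliberately does **not** model:
point-spread-function optics, 3-D structure, cell morphology, spatially
varying illumination, autofluorescence, or puncta clustering inside cells.
Passing recovery tests therefore demonstrates the correctness of the
pipeline's logic and boundary rules, not robustness to every real-world
imaging artifact.

## Gamma GLMM layer

Indices are positive and right-skewed; the comparison model is a Gamma GLMM
with square-root link:

```
value ~ group + (1 | experiment) + (1 | experiment:specimen)
```

Images within a specimen share the specimen intercept and the Gamma residual
carries image-to-image variability. An image-level random intercept was
considered and rejected: with one index per image it is an observation-level
random effect, unidentifiable from the Gamma residual, so "intra-specimen
image variability" is represented by the residual and the specimen intercept
rather than a third variance component.

The optimizer is delegated to glmmTMB through a batch `Rscript` backend (one
invocation fits many datasets, amortizing interpreter startup); the module
itself owns model assembly, the nesting structure, estimated marginal means
and contrasts. EMMs are computed from the fixed-effect coefficients and
their covariance on the link scale and back-transformed (η²) to the response
scale; treatment-vs-control contrasts are Wald tests on the link scale with
response-scale ratios `(η_g/η_0)²` and delta-method intervals on the log
ratio. Inference is asymptotic (normal reference), the standard convention
for GLMM marginal means. p-values across the contrasts of one analysis are
BH-adjusted (the FDR family is one analysis, not a whole study). An R
`emmeans` run on the same fitted model serves as an independent cross-check
of this construction in the test-suite.

Two numerical subtleties of the square-root link:

* the likelihood is invariant under a global sign flip of the linear
  predictor, so the optimizer can land on the negative branch; fits are
  canonicalized (data-derived starting values; a restart from the fully
  mirrored parameter vector when all group means come back negative; a
  residual all-negative solution is flipped analytically, which is exact by
  symmetry). Mixed-sign solutions are rejected with an explicit error.
* with few specimen clusters the specimen variance tends to collapse to
  zero, making Wald tests anti-conservative. Random-effect standard
  deviations therefore carry a weak regularizing prior (gamma with shape 2.5
  and near-zero rate, i.e. density ∝ sd^1.5 — soft repulsion from zero, no
  upward pull), the same convention as the default covariance prior of
  Bayesian-regularized mixed-model fitters. Under the simulated study
  conditions (2 groups × 3 specimens × 4 images × 3 experiments, Gamma shape
  10, link-scale random SDs 0.05) this yields a 0.03 type-I error at
  α = 0.05 and 98% coverage of a true response ratio over 200 fits per
  scenario — both computed by the acceptance script, not quoted.

When the random-effect structure is inestimable (single experiment **and**
single specimen) the fit falls back to a fixed-effects Gamma GLM
(statsmodels) with a logged warning and an explicit `fallback` flag. For an
intercept-only Gamma GLM the score equation forces the fitted mean to equal
the arithmetic sample mean for any smooth link, which the tests exploit as
an exact oracle.

Zero-valued indices (a PLA field with zero puncta) violate the Gamma
support. Dropping them would bias group means upward, so they receive the
smallest half-resolution offset, `0.5 / nuclei_count`, derived from the
field's own resolution; the adjustment is logged, counted in the result, and
can be disabled (`zero_offset=False`, which then errors on zeros) or
replaced by an explicit offset.

### FDR adjustment

`adjust_fdr` is textbook Benjamini–Hochberg (step-up, `p·m/rank` with a
running minimum from the largest rank, capped at 1, input order preserved).
Note that BH is **not** idempotent: re-adjusting an adjusted vector can only
inflate it further, because the step-up envelope is not a fixed point
(e.g. BH([1, 0.25]) = [1, 0.5] but BH([1, 0.5]) = [1, 1]). The tested
guarantees are agreement with an independent hand-rolled reference,
monotonicity in both senses (adjusted ≥ raw; order preservation), and
permutation equivariance.

## Count preparation and DEG logic

Pipeline order is fixed and enforced: PAR_Y collapsing first (so merged rows
are filtered on their summed counts), then the pre-filters. Collapsing
strips the `_PAR_Y` suffix and, on collision, sums count rows element-wise;
the merged transcript length is the count-weighted mean of the two lengths
(preserving the semantics of the length filter; an all-zero pair falls back
to the unweighted mean). The low-expression rule drops genes with row total
strictly below 2 × (number of samples) — "number of samples" is read as all
samples of the analyzed matrix, not per group — and the length rule drops
genes with mean transcript length ≤ 20 bp (inclusive). DEG significance is
strict on both sides: |log2FC| > 1 **and** FDR < 0.01; which adjusted
p-value populates the `fdr` column (plain BH or covariate-weighted) is the
caller's choice, since the differential-testing engine is a delegated
interface — any results table with `gene_id`/`log2fc`/`fdr` columns is
accepted, and a DESeq2 adapter (pydeseq2) is provided for convenience and
used in the end-to-end tests. Set overlap between two conditions is
per-direction; genes significant in opposite directions are excluded from
both common sets and reported separately as discordant.

## Problem sizes and reproducibility

Simulation studies use 200 replicates per condition (fields for recovery,
fits for calibration), 192²–384² px fields with 3–6 nuclei, and 1200 × 16
count matrices — sizes at which the Monte-Carlo error of the reported means
is far below the tolerances being checked. All randomness flows from
`numpy.random.default_rng` seeds; identical configuration (including seed)
reproduces every array and output file byte for byte, which the test-suite
asserts by hashing.

## Known limitations

* The NEI is image-global; no per-cell nuclear/cytoplasmic ratio.
* PLA puncta are counted per field, not assigned to cells; no 3-D detection
  or chromatic-shift correction.
* The mixed-model backend requires an R installation with glmmTMB; there is
  no pure-Python Gamma GLMM path beyond the fixed-effects fallback.
* The synthetic fields idealize real microscopy (see above); recovery
  results bound logic errors, not acquisition artifacts.
* Read-level RNA-seq processing, DE-engine internals and GO enrichment are
  out of scope by design.
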