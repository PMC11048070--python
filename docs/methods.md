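# Methods

This note documents the models and procedures implemented in `spondyref`,
the defaults and the reasoning behind them, what the synthetic data do and
do not emulate, and the numerical choices that matter.

## Coordinate frame, units and metric definitions

Landmarks are 2D corner points (antero-superior, postero-superior,
antero-inferior, postero-inferior) of each vertebral body L1–S1 in the
sagittal plane, +x anterior and +y cephalad (an input flag flips y for
image-frame files). Lengths are arbitrary: lateral radiographs have unknown
magnification and typically no scaling device, so every reported quantity
is a ratio, a percentage of endplate width, or an angle. The normalizer W
for a level is always the superior-endplate width of the inferior vertebra.

**Method 1 (endplate-based).** ADH and PDH are signed perpendicular
distances from the antero-/postero-inferior corners of the superior
vertebra to the line through the inferior vertebra's superior endplate,
÷W×100. ASPO (PSPO) is the along-endplate offset of the matching corners,
positive when the anterior corner is anterior (the posterior corner
posterior). Measuring offsets along the endplate direction rather than raw
x makes them rotation invariant. DA is the signed angle between the two
facing endplate lines, negative when ADH < PDH.

**Method 2 (midplane-based).** The midplane of a vertebra joins the
midpoints of its anterior and posterior walls (the corner-point centroid
lies on this line). The bisectrix bisects the two midplanes; for midplane
angles below 1e-6 rad the construction switches to the parallel line midway
between them, because the intersection point recedes to infinity and the
bisector through it is numerically unstable. VDH/DDH sum the perpendicular
distances of the facing corners to the bisectrix; MPA is the signed
midplane angle; CSPO is the signed distance between the perpendicular feet
of the two corner-centroids on the bisectrix, ÷W×100, positive anterior.
A consequence worth knowing: rotating one vertebra about its own centroid
tilts the bisectrix by half the midplane angle, so CSPO changes by
|c_sup − c_inf|·sin(MPA/2) even though neither centroid moved. That is
inherent to the construction, not an artifact.

**Composites.** Average disc height (ADH+PDH)/2; disc area = |shoelace|
of the quadrilateral (sup-AI, sup-PI, inf-PS, inf-AS) ÷W², with
self-intersecting quadrilaterals flagged; EPWR = width of the superior
vertebra's inferior endplate ÷ W; height/width ratio = mean wall length ÷
mean endplate width of the superior vertebra.

Every metric is invariant under rigid motion and uniform scaling to 1e-9
(property-tested). Under mirror reflection with anterior/posterior
relabelling, corner-wise metrics swap (ASPO↔PSPO, ADH↔PDH, VDH↔DDH) and
the signed angles and CSPO negate.

## Exclusion, trimming and the reference table

Two passes define "normal":

1. drop every level with a definite osteophyte/sclerosis flag (the flag is
   an input, e.g. from a grading network); compute per-level mean and SD of
   the seven gating metrics — disc angle, ASPO, PSPO, average disc height,
   disc area, EPWR, height/width ratio — on the remainder;
2. keep only levels with all seven gating metrics inside the per-level
   mean ± 1.96·SD window. 1.96 (not 2) because a score of exactly 2 should
   fall just outside the interval.

Exactly two passes are standard; an `iterate` flag repeats pass 2 to a
fixed point for exploration only. The audit records every removal with the
rule(s) that triggered it, and removed + kept equals the input count per
level by construction.

The reference table reports, per (level, metric): n, mean, SD, median, CV,
moment skewness, non-excess kurtosis (normal ≈ 3), Hodges–Lehmann
location, Qn scale, and the mean ± 1.96·SD interval. Because a hard trim
window truncates the Gaussian core of the normal sub-population, the raw
post-trim SD is biased low (a ±1.96σ window shrinks it by ~13%, and the
truncated sample's kurtosis is bounded near 2.4–2.8 regardless of sample
size). Since the window applied to each stratum is known exactly, the table
also reports `mu_norm`/`sigma_norm`: the maximum-likelihood parameters of a
normal distribution restricted to that window (a consistency correction of
the same kind as the constants in MAD or Qn). These are the default
location/scale for z-scoring; without the correction, tail prevalences on
truly normal discs run systematically high. The MLE uses sufficient
statistics, so each fit is O(1) per objective evaluation (Nelder–Mead on
(μ, log σ)).

## Robust estimators

Hodges–Lehmann location = median of all Walsh averages (xi+xj)/2, i ≤ j.
Qn = 2.2219 · d(n) · (k-th smallest pairwise gap |xi − xj|, i < j), with
k = C(h,2), h = ⌊n/2⌋+1, and the published finite-sample factors d(n)
(0.844 at n = 5; n/(n+1.4) odd, n/(n+3.8) even for n > 9). Both are order
statistics of O(n²) pairwise sets; they are computed by full enumeration up
to n = 1024 and, above that, by bisection on the value axis using the
monotone pair-counting trick (counting pairs below a threshold costs
O(n log n) on sorted data) with an exact final snap to the smallest
pairwise value above the bracket — exact at every n, no subsampling.
The test suite verifies exact agreement with brute-force enumeration and,
for Qn, agreement with an independent implementation up to the ratio of
consistency constants.

## Scores, age model, SpondyIndex

z = (x − μ)/σ with the level-specific `mu_norm`/`sigma_norm`; the robust
score substitutes HL and Qn. Prevalences are reported for |z| > 2 and
|z| > 3, absolute by default with one-sided tails alongside (the absolute
version is the primary interpretation).

The age trend of standardized average disc height is modelled as
z = b0·e^(b1·age), fitted by nonlinear least squares initialized at
b0 = sign(mean z)·0.001, b1 = 0.05. With the conventional coefficients
b0 = −0.0037, b1 = 0.078 the curve passes −1.19 at age 74.

**SpondyIndex.** OLS of ASPO (or PSPO) on EPWR, ADH, PDH and one indicator
per level (no global intercept), trained on radiographically normal levels
from wide-angle flexion/extension exams; one pass removes
|studentized residual| > 3, the model is refitted, and per-level residual
SDs are stored. The index is (observed − predicted)/residual SD; AntSI > 2
flags anterolisthesis and PstSI > 2 retrolisthesis, each approximately a
one-sided 2.3% event on normal discs by construction. Two deliberate
predictor choices:

* *Disc angle is excluded*: the two disc heights carry the same
  information, and the heights are the better-conditioned predictors.
* *Disc area is excluded by default* (selectable via `predictors=`):
  the shoelace area is an exact function of the same four corners that
  define the offsets — 2e4·area = ADH·(100+PSPO) + PDH·(100+ASPO) — so
  once heights and EPWR are conditioned on, area algebraically encodes the
  offset being predicted, with conditioning quality growing with the disc
  angle. On synthetic wide-angle extension exams, (area, EPWR, heights)
  recover ~44% of the variance of the true anatomic offset; a model given
  area therefore "explains away" part of a real slip and loses detection
  power. This is a genuine circularity of same-landmark-derived predictors,
  not a quirk of the generator; a reported strong statistical association
  between disc area and ASPO is exactly what this mechanism produces.

The posture-transfer property — a neutral-position z-score misclassifies a
large fraction of normal flexed levels because SPO is coupled to disc
angle, while the SpondyIndex, which accounts for the heights, does not —
is exercised directly in the acceptance suite.

Per-spine summaries are the maxima of AntSI and PstSI and the minimum
z(avgDH) over available levels; their association with a binary back-pain
report is a univariable logistic regression reporting the odds ratio per
unit, Wald p, and McFadden pseudo-R² (convention fixed; labelled as such).

## Projection-error phantom study

A phantom extrudes the 2D mid-sagittal corners laterally by ±half_width
(default 0.7·W, reflecting vertebrae being wider laterally than deep),
poses the segment by rotations about the vertical (axial) and
anterior–posterior (coronal) axes through the segment centroid, and
projects all corners onto a detector plane along rays from a point source
(defaults SDD 1016, ODD 150 phantom units — a typical lateral lumbar
setup). A reader facing the doubled contour is emulated by collapsing each
left/right projected pair to its midpoint (a nearest-point alternative is
selectable). Errors are |measured − true| per metric, standardized by the
reference SD, evaluated with the same phantoms at every pose (paired
design).

Structural facts the study verifies: at zero out-of-plane pose the error is
zero to machine precision for any source/detector distances (all metrics
are ratios, and the lateral pair-averaging restores a uniform scale); the
median error grows with pose; badly out-of-plane poses push offset metrics
beyond half a reference SD. Sign-evenness of the axial pose holds exactly
only in the parallel-beam limit — a point source magnifies the near side
more, so ±θ differ at clinical distances.

## The synthetic population

The generator produces coherent landmark spines (S1 up to L1, each level's
construction reproducing its metric targets exactly) with the statistical
structure the analysis assumes. Defaults, with rationale:

* **Normal metrics**: average disc height N(30, 4) %EPW; disc angle means
  graded −2°, 1.5°, 5°, 8.5°, 12° from L1L2 to L5S1 (SD 3°), covering the
  slightly kyphotic upper levels through the strongly lordotic L5S1;
  height/width ratio N(0.6, 0.05); endplate widths ~N(35, 2.5) units with
  2% within-subject variation (the absolute scale cancels).
* **Offset structure**: ASPO = 50(g−1) + s − 0.20·Δc + ε, PSPO = 50(g−1) −
  s + 0.14·Δc + ε′, where g ~ N(1, 0.015) is the vertebra size ratio
  (moving both offsets together), s ~ N(0, 1.7) %EPW is the neutral-zone
  resting offset (moving them oppositely), Δc is the deviation of
  ADH−PDH from its level mean (the angle coupling), and ε, ε′ are small
  metric noises (0.6, 0.8). These choices reproduce the field's observed
  correlation pattern: offsets ~N(0, ≈2.2) %EPW, a strong negative
  ASPO–PSPO correlation, ASPO negatively and PSPO positively correlated
  with disc angle. Note one structural constraint: the same two corners
  define both offsets and the superior vertebra's inferior endplate width,
  so ASPO+PSPO ≈ 100(EPWR−1) identically — offset SDs, EPWR spread and the
  ASPO–PSPO correlation cannot be set independently, and the emergent EPWR
  spread (~0.015) follows from the offset structure.
* **Landmark digitization error**: iid Gaussian jitter of 0.6 %EPW per
  coordinate (~0.2 mm on a 35 mm endplate, a high-quality automated
  placement). Without it, measured metrics satisfy exact algebraic
  identities that no real measurement satisfies, and near-collinear
  regressions become degenerate. The analytic oracle for normal-disc
  (mean, SD) propagates this jitter through the exact metric Jacobian at
  the mean geometry (first-order delta method, finite differences).
* **Degeneration** (prevalence 0.3): heights shifted by N(−3, 1) normal
  SDs (severity varies), angle shifted N(−4°, 3°), resting-offset SD ×6
  (degenerative instability), mild endplate remodelling (size ratio
  +0.02, SD ×2), wall-height SD ×1.5. Flags have 80% sensitivity and 5%
  false positives. Degeneration is age-independent in the generator — a
  deliberate simplification; consequently age-trend fits are performed on
  the pipeline's trimmed normal subset.
* **Demographics**: sex-specific age and BMI mixtures with older ages
  over-represented (male fraction 0.618, ages N(50.9, 15.3) and
  N(63.3, 6.4), clipped to 25–90); the exponential age effect
  b0 = −0.0037, b1 = 0.078 shifts standardized disc height.
* **Flexion/extension exams**: disc angles uniform on −8°…+5° (flexion)
  and +5°…+18° (extension); anatomy (s, g, heights, degeneration,
  prevalence 0.05 for these younger volunteers) persists across a
  subject's two exams, noise does not.
* **Injected listhesis**: the slip *replaces* the neutral-zone resting
  offset with a fixed displacement (default 3 offset-model residual SDs,
  anterior or posterior) — a listhesis is a fixed anatomic displacement,
  not an increment on a random resting position.
* **Back pain**: Bernoulli with logit = logit(0.181) + log(1.14)·(max
  posterior offset deviation in residual-SD units) + log(0.80)·(min
  standardized disc height), covariates centred at their population means
  so the base rate is realized.

What the generator does **not** emulate: vertebral shape beyond four
corners (no endplate curvature, corner rounding, osteophyte geometry), no
age–degeneration correlation, no scoliosis or frontal-plane deformity, no
image-level artifacts, no missing levels or field-of-view truncation
(missing data paths are exercised by tests directly). Passing tests
therefore demonstrate correctness of the pipeline's statistics and
geometry under a faithful but idealized anatomy — not clinical validity of
thresholds on real radiographs.

## Numerical choices and degenerate inputs

Endplates with coincident corners raise a degeneracy error at ingest and
are skipped (with an audit row) in batch processing. Near-parallel
midplanes switch the bisectrix to the midway-parallel construction below
1e-6 rad. Self-intersecting disc quadrilaterals are flagged and their area
taken as the absolute shoelace value, so digitization order cannot flip
signs. Constant samples yield Qn = 0 and undefined (NaN) shape statistics.
CSV readers parse floats in correctly-rounded mode so write→read round
trips are bit-exact. All generators are pure functions of (config, seed).

## Known limitations

* The trimmed sample is a truncated distribution; its raw SD and kurtosis
  are biased (see above). `sigma_norm` corrects the scale for metrics with
  an explicit trim window; metrics that are only *indirectly* selected
  (through correlated gating metrics) retain a small conservative bias.
* The SpondyIndex residual absorbs a small amount of real anatomic offset
  through EPWR (the size-ratio identity), so its residual SD slightly
  understates the generative one; calibration is preserved because the
  same absorption applies at train and test time.
* The projection study reports standardized errors for this package's
  geometry defaults; absolute error magnitudes depend on source distance,
  phantom width and pose distribution, all config-exposed.
* Reference values produced from synthetic populations characterize the
  pipeline, not any human population.
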