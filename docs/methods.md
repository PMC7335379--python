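# Methods

## The assay, in brief

Tendon-derived cells compact a collagen-I gel around a 2×4 array of
micro-posts. At t = 0 the four outermost posts are released and the
tissue remodels for 48 h under hourly brightfield imaging (or a two-frame
0 h / 48 h acquisition on a second microscope). The measured quantities
are the silhouette area over time, the binary intact/released outcome,
and protein read-outs from ELISA, Western blot and gelatin zymography,
each regressed on patient age, gender and tendon type.

## Synthetic cohort

Ages are drawn from a truncated normal on [12, 55] y whose *truncated*
moments are least-squares-fitted to the census targets (mean 27.9, sd
12.9 y). A mathematical note: on that interval the truncated-normal sd
has a supremum of ≈ 11.6 y at mean 27.9 (the family approaches a tilted
uniform), so the target sd is not exactly attainable; the fitted
distribution achieves mean ≈ 28.3, sd ≈ 11.7 over seeds, within the
±1.5 y tolerance used by the census checks. Gender is Bernoulli
(p = 20/36 male); with probability 5/36 a patient contributes both a
semitendinosus and a gracilis tendon (sharing age and gender), otherwise
one tendon (semitendinosus with p = 25/31), reproducing ≈ 41 tendons per
36 patients with 30/41 semitendinosus.

## Read-out effect structure

The generator inverts the inference layer:

- **Relative area (%)**: `35 + 0.96·age + ε`, ε ~ N(0, 24²). The
  intercept is invented (the source value is unreported); the noise sd
  is back-calculated so the fitted slope's standard error and R² at the
  study scale match the published fit (SE ≈ 0.36, R² ≈ 0.2). The value
  is left unclipped: truncating the ~2% of draws that graze zero in the
  young, noisy tail would bias the slope-recovery calibration.
- **Intact/released**: Bernoulli with
  `logit P(intact) = −2.0 + 0.19·age + 1.6·male − 2.7·semitendinosus`.
  The slopes are the published point estimates; the intercept (never
  printed) is solved by Monte Carlo so the expected release rate equals
  the observed 10/41 ≈ 24%. `solve_release_intercept` re-derives it for
  any parameterization.
- **Pro-collagen I (ng/ml)**: a two-plateau logistic step
  `low + (high − low)·σ((25 − age)/2)` with high/low = 608/121.6 (5:1
  ratio) plus N(0, 130²) noise. The plateaus are calibrated so that a
  *linear* fit to the step recovers an age slope of ≈ −15 ng/ml/y — the
  published coefficient — under the covariate distribution the
  regression actually sees. That last qualifier matters: released
  micro-tissues (disproportionately young) yield no biochemistry, so the
  pro-collagen regression runs on an age-selected sample, and for a
  misspecified (step-vs-linear) model the projection coefficient depends
  on the covariate distribution. `induced_procollagen_slope` computes
  this intact-selected projection (≈ −15.0; the unselected projection for
  the same plateaus is ≈ −16.4) and is the generating value against
  which recovery and CI coverage are scored.
- **Tenomodulin and α-SMA ratios**: age-independent lognormals
  (medians 0.05 and 2.0; σ = 0.5 and 0.75 — the α-SMA spread reproduces
  the reported ~21-fold inter-patient range).
- **Active MMP2 (A.U.)**: `30 − 0.17·age + N(0, 17²)`; **active
  fraction**: N(0.45, 0.05²) clipped to [0, 1] (little inter-patient
  variation by design).

Released tendons get missing values for all biochemical read-outs,
mirroring the exclusion of released micro-tissues from further analyses.

## Image synthesis

Each frame holds a darker star-convex silhouette (elliptical radial
potential modulated by seeded low-order harmonics) spanning the four
anchored posts, the post array, an optional additive linear illumination
gradient, and Gaussian noise; intensities are 16-bit. The area follows
`A(t) = plateau + (initial − plateau)·e^(−rate·t)` (defaults 1.8 →
0.75 mm² at 0.12 h⁻¹ — a phenomenological decay, not a mechanical
model). The ground-truth mask selects exactly `round(A(t)/pixel area)`
pixels of the potential, so mask pixel count × pixel area equals the
closed form to within half a pixel area, and the reported ground-truth
area *is* the mask count times pixel area (exactly consistent by
construction). After a programmed release the blob detaches from every
post, collapses to 0.15 mm² and drifts laterally clear of the anchor
regions; anisotropy (aspect ratio 1 → 1.6) grows as compaction
progresses. Post geometry is configurable; the default 8-post, 2×4 array
with the 4 corner posts released at t = 0 is a declared choice — the
source describes releasing "the four outermost posts" but not the array.

Gels are rendered as anisotropic Gaussian bumps (σ_row = 3 px,
σ_col = 8 px) at the log-linear migration position
`row = a + b·log₁₀(kDa)` of each band, with integrated magnitude exactly
proportional to the programmed amount, over a background level +
horizontal gradient + noise. `dark-bands-on-light` is exactly one minus
the bright rendering, so polarity symmetry is testable to machine
precision.

## Segmentation choices

- Automatic threshold: between-class-variance maximization (Otsu);
  fixed-value override available. Affine-invariant, so pixel counts are
  unchanged under positive affine intensity maps.
- Components: 8-connectivity; hole identification: 4-connectivity; ties
  on component size break to the smallest row-major pixel index.
- Strategy-A validity heuristics (all flags, never silent failures):
  degenerate threshold; between-class variance fraction < 0.92 of total
  ("no-tissue" — a featureless frame still yields an Otsu threshold, so
  an explicit bimodality criterion is needed, and this one is
  affine-invariant); mask below 0.5% or above 45% of the frame
  ("implausible-area" — the upper bound sits well above the largest
  plausible silhouette, ~27% of the frame, but low enough to catch the
  merged tissue+background class produced by strong illumination
  gradients, which plateaus near 50–70% and would slip past a looser
  bound); no overlap with a central ROI of fractional half-width 0.25
  ("off-center").
- Strategy B: Gaussian pre-smoothing (σ = 1 px) before the Sobel
  magnitude; the binarized edge map is closed with a 3×3 structuring
  element to guarantee a closed contour; the subtraction clamps at zero;
  the final binarization uses a low fixed threshold (5% of the frame
  maximum) because the carved outline is exactly zero while Otsu on the
  carved image would re-split tissue from background — the very
  separation that just failed in strategy A. The filled outline
  straddles the true boundary by roughly the edge-operator support, so
  the mask is eroded by 2 px (configurable) before counting.
- Fallback: A runs first; any flag triggers B; if B also flags, a
  failure result carries both flag sets.

On the default scene batteries (20 scenes × 49 frames) the median area
error is ≈ 0.01% for A on clean frames and ≈ 0.45% for B on frames with
a 0.8-range illumination gradient.

## Release classification

A human observation in the original assay, operationalized here: a
tissue is released at the first frame whose mask overlaps fewer than two
anchored-post regions, sustained for ≥ 2 consecutive frames (one frame
suffices for the final frame of a two-frame endpoint series), because
partial detachment from a single post can precede full release.
Endpoint frames for the relative area are matched within ±1 h. Areas are
compared in mm², never raw pixels, since the two acquisition paths may
differ in pixel size. Pre-release events (detachment before t = 0) are
out of scope; negative release times are disallowed.

## Densitometry

Two-stage subtractive background correction (the source names the
normalizations but no formula): the global background (median of the
oriented image outside all lane windows, per pixel) is subtracted first;
the band is then the window sum minus the local background × window
pixel count, clamped at zero. The local background is the pooled median
of the 6 flanking rows on each side of the band window — unless the two
flank medians disagree by more than 4 standard errors of the median, in
which case the dimmer flank is used (a neighboring band, e.g. pro-MMP2
12 px from active MMP2, is leaking into one flank). Band windows map
kDa ± 3 (configurable) through the fitted migration map; the tubulin
50–55 kDa doublet is a single spanning window. A below-detection flag
(corrected intensity under 5 noise-σ·√window) marks empty windows such
as MMP9 at 92 kDa rather than letting zeros propagate into ratios.
Quantification accuracy is noise-limited for weak bands: the local
background's sampling error is amplified by the window pixel count, so
bands should sit well above the noise floor (peak ≳ 20× noise sd) for
percent-level accuracy.

The loading-control rule flags tubulin intensities outside
[Q1 − 1.5·IQR, Q3 + 1.5·IQR] (quartiles by linear interpolation of order
statistics). Flags annotate, never remove: the pro-collagen model is
fitted both with all samples and excluding flagged ones (the source does
not say which was done, so both variants are reported).

## Inference layer

OLS with intercept and classical t-tests for continuous read-outs;
maximum-likelihood logit (Newton, tolerance 1e-8, max 100 iterations)
with Wald tests for intact/released; McFadden pseudo-R² (the flavor is a
choice — it is likelihood-based and the most common default). Intact is
coded 1, so a positive age coefficient means older patients' tissues
stay attached. Non-convergence or diverging coefficients (perfect or
quasi-complete separation — which genuinely occurs at n ≈ 41 when, e.g.,
no gracilis tendon releases) is refused with a diagnostic; the pipeline
logs the refusal and omits the row rather than reporting a divergent
fit. Patients contributing two tendons contribute two independent rows;
no patient-level random effect is fitted (a limitation, kept for
comparability with the tendon-level analysis this reproduces). No
multiple-testing correction; α = 0.05 per test. Normality diagnostics:
ordered residuals against Φ⁻¹((i − ½)/n) with the probability-plot
correlation as a scalar summary.

## Problem sizes

Default batteries: 20 scenes × 49 frames per segmentation condition;
30–50 scenes for release classification; 100 replicates at n = 500
tendons (and 100 at the n ≈ 41 study scale) for recovery, coverage and
power; the demo pipeline runs the full 36-patient design with two-frame
endpoint imaging. These sizes were chosen so the complete analysis runs
in minutes on a laptop while keeping Monte-Carlo error well below the
tolerances checked.

## What the synthetic data does and does not show

The generator reproduces the study's *effect structure* (calibrated
slopes, release rate, plateau ratio, demographic census) and realistic
imaging nuisances (noise, illumination gradients, post occlusion, band
overlap, loading variation). It does not emulate condensation rings,
meniscus shadows, debris, out-of-focus frames, partial detachments, gel
smearing or saturated bands; passing batteries therefore demonstrate
correctness of the algorithms under the modeled nuisances, not
performance on arbitrary real microscopy. Real acquisitions should be
spot-checked against the quality flags, which are the designed first
line of defense.
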