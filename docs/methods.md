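# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot establish.

## Stimulus model

All image processing happens in linear-light RGB on `[0, 1]`; the display
power law (`v^2.2` and its inverse) is applied only when importing or
exporting image files. A scene is an image plus an annotated contour
point: CRF center (0-based row/col pixels), contour orientation (degrees
counterclockwise from horizontal, in `[0, 180)`), a unit normal toward the
occluding object, the CRF radius `r` (pixels), and two region masks
restricted to the disc of radius `r` — one per side of the contour. Masks
come from annotation; the synthetic scene generator emits exact masks from
its rendered geometry, leaving pixels within half a pixel of the contour
unassigned.

The factorial transforms:

- **Side.** 180° rotation about the CRF center. Integer-pixel centers are
  assumed, so the rotation is exact index arithmetic with no interpolation;
  display area uncovered by the rotated image is filled with the scene's
  background color, matching the interstimulus rule.
- **Polarity.** `T(x) = (x̄₁ + x̄₂) − x`, with the region means always taken
  on the original, unrotated scene. `T` is an involution and swaps the two
  region means, flipping the local edge-contrast polarity while fixing the
  local mean. Out-of-gamut results are clipped to `[0, 1]` and the clipped
  pixel count is carried in the variant's metadata rather than silently
  discarded.
- **Extent.** The patch blend is `α·image + (1 − α)·background` with `α = 1`
  for `d < r` and `erfc[k(d − r)]` beyond (`k = 1.8` per pixel). The
  published formula lists the `d < r` branch twice; the implementation uses
  the only continuous, monotone reading. Because the blend is applied after
  rotation, full and patch variants of the same side/polarity are
  pixel-identical inside radius `r` — by construction, not approximately.

The background for every variant of a scene is `BG = (x̄₁ + x̄₂)/2`.
Square-test displays place one square edge through the CRF center at the
preferred orientation, with the two square placements partitioning the edge
line (`d ≥ 0` vs `d < 0`) so that paired side/polarity displays are
pixel-identical within the `2w × w` band swept by the two placements.

## Synthetic neurons

Model neurons are inhomogeneous Poisson processes simulated in 1-ms
Bernoulli bins (`p = rate · 1 ms`). At the rates used (≤ ~100 Hz) the
discretization bias of mean counts is below 0.5%; exact exponential-gap
simulation was not worth the complexity. The rate is assembled from:

| component | default | role |
|---|---|---|
| baseline | 5 Hz | pre-onset rate |
| evoked | 40 Hz | post-onset rate (× 1.3 for the preferred polarity) |
| onset latency | 44 / 47 / 46 ms | scene-full / scene-patch / square classes |
| local BO component | 3.5 Hz, 40–85 ms | transient; present in full *and* patch |
| context BO component | 40 Hz peak (squares), ×0.5 in scenes; ramp 44→140 ms, decaying to 0.6 of peak at 300 ms | present in full and square only |
| scene dispersion σ | 0.6 | Normal(1, σ²) multiplier on both BO components per scene |

The border-ownership difference (preferred minus non-preferred side) is
applied symmetrically (±half to each side) and rates are truncated at zero.
Scene multipliers are Normal because the deconvolution step approximates
both distributions with Gaussians; the implied true consistency is the mass
above zero, Φ(1/σ), which gives recovery experiments a closed-form ground
truth (σ = 1/Φ⁻¹(c) injects consistency c).

Defaults describe a recording session of 43 scenes (the mean of the
emulated experiments' 10–177 range) with 4 replicates of each of the 8
scene conditions plus the 8-condition square test. The 40 Hz context
amplitude puts normalized square effects around 2–3 trial-SDs, the range
occupied by strongly selective real cells. Firing-rate levels are fixture
choices, not claims about V2.

**Timing calibration.** Onset latencies are direct parameters, but the
two-phase-regression latency of a ramping signal is an estimator property,
not a generator parameter. The context onset, local amplitude/offset and
decay fraction were therefore chosen by running the latency estimator on
the noise-free *expected* cumulative curves over a parameter grid
(`scripts/calibrate_preset.py`) so that the recovered pooled latencies are
44 ms (onset), ~60 ms (full-scene signal) and ~73 ms (context). The
calibrated preset is frozen in `preset_paper_calibrated`.

What the generator does *not* emulate: real scene statistics (curvature,
junctions, texture gradients and their correlation with perceived
border-ownership), non-Poisson spiking (bursting, refractoriness, serial
correlation), rate adaptation within the 300-ms presentation beyond the
built-in component shapes, and eye-movement or attentional variability.
Passing recovery tests therefore shows the *analysis chain* is correct and
calibrated — not that real V2 data would satisfy the generator's
assumptions.

## Spike-count models

Counts in the closed-open window [40, 300) ms are transformed with
`√(x + 3/8)`, which stabilizes Poisson variance near 1/4. Each cell is fit
separately with fixed-effects OLS including all interactions: 3-way for the
square test (side × polarity × size) and 4-way for scenes (side × polarity
× extent × scene), scene ID being an ordinary fixed factor with one level
per scene. "Repeated-measures" in the source description is resolved as
fixed-effects OLS per cell with Type-II tests — the behavior of the
standard Type-II ANOVA implementation applied to a single cell's trials —
with no random-effect terms.

Type-II sums of squares follow the marginality convention: each term is
tested against the model containing every term that does not include it,
with F against the full model's residual variance. On complete balanced
designs the term subspaces are mutually orthogonal under sum-to-zero
coding, so the implementation uses direct projections there (identical
results, ~15× faster for many-level scene factors) and nested model
comparisons otherwise; both routes are cross-checked against
`statsmodels.anova_lm(typ=2)` in the tests.

Effects are preferred-minus-nonpreferred marginal-mean differences on the
transformed scale (cell means averaged with equal weight over the other
factors); the source never writes an explicit effect formula, and this
choice equals the sum-to-zero coefficient contrast on balanced data. The
square effect averages the two size-specific contrasts (a pooled-model
variant is exposed as an option; the two coincide on balanced data). Each
cell's sign convention is anchored to its square-test effect; the context
effect is full − patch exactly. Normalization divides all of a cell's
effects by the square-model residual SD only — that model contains every
experimental variable, so its residual reflects pure repeat-presentation
variability. Significance of the full-image and patch border-ownership
effects uses extent-restricted 3-way models; the context effect uses the
side × extent interaction of the 4-way model; the threshold is p < 0.01
throughout. Orientation screening keeps cells with OMI =
(Rθ − Rθ⊥)/(Rθ + Rθ⊥) of at least 0.20 (inclusive).

## Population slope

With each cell's preferred-side sign arbitrary, any population summary must
be invariant to reflecting single cells' (square, scene) effect pairs
through the origin, which forces a through-origin fit. The slope is the
orthogonal (total) least-squares direction: the leading eigenvector of the
uncentered second-moment matrix. An isotropic moment matrix is reported as
slope 1 with a degeneracy flag; a vertical optimum as an infinite-slope
flag. A minimum-absolute-deviation variant (angle grid search) is provided
as a robustness check. Confidence intervals are percentile bootstrap over
cells (B = 1000 default); BCa was not used because the CI flavor is
unstated in the source description and percentile is the plainest choice.

## Consistency and deconvolution

Per-scene effects (one per scene and extent kind, square-anchored signs)
are sorted in decreasing order for display. The null ensemble re-simulates
the cell from its fitted 4-way model with every side-containing term's
coefficients zeroed plus Gaussian noise at the residual variance; because
per-scene effects are linear in the responses, surrogates are computed by a
single weight-matrix product. Envelopes are per-rank 2.5/97.5 percentiles,
either across surrogates or across scene-bootstrap resamples of the mean
sorted curve.

The corrected consistency uses the closed-form Gaussian route: fit
`N(m, s²)` to the observed effects and `N(0, s₀²)` to the pooled null;
the deconvolved law is `N(m, s² − s₀²)` and the corrected index is its
mass above zero. When `s² ≤ s₀²` the deconvolved variance is floored at
`(0.05·s₀)²` with a warning flag (the estimate then saturates toward 0 or
1). A Fourier deconvoluting-KDE backend exists for non-Gaussian effect
laws; with Gaussian (supersmooth) measurement error its bandwidth must be
floored at the noise SD to keep the inverse filter stable, which makes it
deliberately conservative (attenuated toward 0.5) relative to the Gaussian
route. Proportion tests against chance 0.5 are one-tailed binomial (exact,
or continuity-corrected normal), Bonferroni-multiplied and capped at 1.

## Latencies

Population cumulative spike counts are pooled raw across cells and
presentations at 1-ms resolution (a per-presentation normalization option
exists; pooling choice is unstated in the source and raw pooling is the
default). The curve value at t counts spikes before t, so a rate change at
τ produces a slope change exactly at τ. Windows: 0–80 ms for the total
response (both regression legs free); 30–150 ms for differential signals
(first leg forced to zero, since preferred and non-preferred conditions
cancel before the signal exists) — the context signal uses the same
window by parallel with the other differential signals, as no separate
window is stated. The two-phase fit grid-searches integer-ms breakpoints
(≥3 points per leg), fits each leg by OLS without imposing continuity at
the breakpoint, and defines the latency as the legs' intersection; if no
breakpoint improves on a single line by more than 1% of its SS, a
"no-onset" flag is raised. Bootstrap SDs resample presentations with
replacement within cell and condition, preserving presentation counts;
multinomial presentation weights turn each replicate into one weighted sum,
and the two-phase fit is vectorized across replicates with prefix sums.
PSTHs are smoothed with Lowess at span 0.12 ("tension" is interpreted as
the span fraction of the standard Lowess smoother, exposed in config).

## Pipeline and formats

Trial tables are CSV with semicolon-joined spike times at 0.1-ms precision
(inspectable, loss-free at 1-ms analysis resolution). Configuration is
YAML with defaults equal to the study constants (k = 1.8, window 40–300 ms,
α = 0.01, Lowess 0.12, OMI ≥ 0.20). The pipeline report includes slopes
with CIs, preference-consistency counts, the upright-vs-rotated Wilcoxon
check, per-cell consistency results, the latency table, and the Pearson
correlation between Fisher-transformed consistency (arctanh(2c − 1)) and
per-cell latency; identical config and seed give byte-identical reports.

## Problem sizes

The validation experiments use: 1000 surrogate neurons × 40 scenes for the
null positive-proportion check; 2000 zero-amplitude cells for the type-I
rate; 30 calibrated cells for pooled latencies; 50 replicate neurons × 44
scenes for consistency recovery; and 140 cells for slope recovery — sizes
chosen to match the emulated study's scales while keeping a full run in the
minutes range on one core.

## Known limitations

- The Gaussian deconvolution slightly underestimates high consistencies
  (variance subtraction plus estimation noise in `s²`); the validation
  suite quantifies this on the generator.
- Orthogonal regression assumes comparable noise on both axes; the shared
  normalization makes this approximately true, but cells with very
  different square- and scene-test presentation counts would violate it.
- The two-phase latency of a ramping signal is an estimator-defined
  quantity (≈ the half-maximal-strength time), not the signal's first
  departure from zero; comparisons across studies must use the same
  estimator.
- Scene ID as a fixed factor means effects are conditional on the tested
  scene set; no generalization to a scene population is modeled.
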