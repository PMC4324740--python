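# Methods

This note documents the models, numerical choices and limitations of
`tonguegloss`, in the order the pipeline runs.

## Camera calibration and CIELAB

The RGB→XYZ conversion is an affine map fitted by ordinary least
squares, one multiple regression per XYZ channel on the terms
(R, G, B, 1) — a 3×4 matrix. An optional second-order expansion
(`quadratic=True`, adding R², G², B², RG, RB, GB) is available but off
by default: the affine form is the minimal model consistent with a
linear sensor plus black-level offset, and with only 24 patches the
ten-term fit risks overfitting. The fit requires at least as many
patches as terms and a full-rank design (all-neutral charts are
rejected).

The reference white defaults to the reference XYZ of the chart's white
patch, i.e. "white is whatever the chart's white reflects under the
session's illumination"; a standard illuminant can be supplied instead
when absolute colorimetry is wanted. L\*a\*b\* uses the CIE1976
formulas with the exact rational constants ε = 216/24389 and
κ = 24389/27 for the two-branch companding function. Negative
tristimulus values — possible when noisy pixels are extrapolated
through the calibration — are clamped to 0 with a logged warning, since
L\* is undefined for negative Y.

All image arithmetic is floating point on the native 8-bit 0–255 scale;
nothing is renormalised to [0, 1].

ROI lightness averages the RGB over the region first and converts the
mean second (not the mean of per-pixel L\*): ΔL\* is defined on the
region's mean colour, matching how a filter paper integrates moisture
over its footprint. The two orders differ whenever the region is
heterogeneous, because the conversion is nonlinear.

## Gloss extraction

The gloss component is `clip(gloss − nongloss, 0)` per channel, reduced
to one channel by Rec. 709 luminance weights (0.2126, 0.7152, 0.0722).
Gloss is achromatic specular light, so luminance is the natural scalar;
negative differences are frame noise and slight motion between the two
exposures (~0.1 s apart) and carry no gloss information. No
registration is applied — the frames are assumed aligned.

**Otsu threshold.** Computed on a 256-bin integer histogram (floor
binning) of the difference values *inside the tongue mask only* —
including background pixels would corrupt the gloss/dark-noise
bimodality. Class counts and sums are integers, so candidate
between-class variances are compared as exact rationals
((s₀n₁ − s₁n₀)²/n₀n₁, maximised over splits): the argmax, with ties
broken toward the smallest level, is bit-reproducible and free of
floating-point tie ambiguity. Note that in a histogram with an empty
gap between modes every split through the gap ties, so the
smallest-level rule places the threshold at the *low* edge of the gap.

Two guards handle gloss-free input, where Otsu's method necessarily
bisects noise:

- a constant difference image raises a degenerate-histogram condition
  internally and reports zero glossy area;
- if the two class means are closer than `min_contrast` (default 20
  luminance levels — roughly 7× the differencing noise at the synthetic
  default σ = 2, and far below any plausible specular highlight), the
  pair is declared gloss-free.

**Despeckling.** Because the threshold sits at the low edge of the gap,
isolated extreme-noise pixels can leak into the glossy class. Specular
highlights are contiguous patches of liquid surface, whereas noise
leaks are spatially uncorrelated singletons, so connected components
smaller than `min_blob_px` (default 4, 8-connectivity) are removed.
This matters most for small glossy areas (~1% of the tongue), where a
handful of singletons would visibly distort the mask.

The glossy-area ratio is 100 × |glossy ∩ tongue| / |tongue|. The ΔL\*
gloss degree is not clamped: dry tongues legitimately read near (or
marginally below) zero.

## ROI placement

The measurement square mirrors the filter-paper protocol: side 10 mm,
centred on the tongue midline, its **near edge** 10 mm from the tip
(reading "10 mm from the tip" as edge distance; subtract half the side
from `offset_mm` for the centre-distance convention). Membership is
evaluated per pixel in midline coordinates with half-open intervals, so
axis-aligned squares have exactly (side/mm_per_px)² pixels and the mask
is translation-equivariant; sub-epsilon trigonometric residue at
axis-aligned angles is snapped to zero so the square lands on exact
pixel rows/columns. The pixel scale `mm_per_px` must be supplied — it
is a property of the camera geometry, not recoverable from a single
image. Tongue masks are supplied externally (e.g. manual annotation);
automatic tongue segmentation is out of scope.

## Moisture regression

`estimate_moisture` evaluates moisture_mg = slope·g + intercept; the
bundled default is slope 4.2×10⁻⁴ mg per gloss-degree unit, intercept
−0.017 mg (r = 0.80, n = 25). Negative predictions are reported as 0
with a `clamped` flag, the raw value preserved — the line's root is at
g ≈ 40.5, below which the formula has no physical reading. Which gloss
index feeds the model (ΔL\* by default, or the area percentage) is
carried as model metadata; with the bundled coefficients both plausible
index scales predict sub-0.03 mg amounts, so the model is best read as
a relative, not absolute, moisture scale. Fitting uses OLS
(`scipy.stats.linregress`) with normal and dry subjects pooled, and
optional per-state stratification; Pearson r is reported with its
two-sided t-test p-value.

## Time series

Trajectories apply gloss detection independently per frame pair, timed
from protrusion start. Series are summarised by their **initial** ratio
by default — recovery is about the state of the tongue at the moment it
is stuck out; the mean over the series is available as an alternative.
The recovery fraction is second-series ÷ first-series summary, and the
recovery curve flags the smallest rest interval whose fraction reaches
the criterion (default 0.95 — "recovered" operationalised as within 5%
of the original, configurable).

## Synthetic data

The generators emulate the acquisition geometry, not tongue appearance:

- **Charts** are rendered through a known 3×4 camera matrix by solving
  the inverse problem (RGB = A⁻¹(XYZ − b)) for 24 canonical patch XYZs,
  plus optional Gaussian sensor noise. RGBs are deliberately not
  clipped so a noiseless chart round-trips through calibration exactly.
- **Tongue pairs**: an ellipse (~13 000 px at defaults) of uniform
  reddish base colour on a dark background; the gloss frame adds
  `speckle_amplitude` (default +120 levels) on a contiguous blob of an
  *exact* pixel count, grown from random seeds by dilation with
  raster-order truncation; each frame gets independent per-pixel
  Gaussian noise (default σ = 2) and is quantised to 8 bits. Defaults
  put the gloss far above the noise floor, as a strongly directional
  source does.
- **Drying series**: the speckle count decays as
  round(initial·e^(−t/τ_dry)) with τ_dry = 20 s by default (halving in
  ~14 s, between observed fast- and slow-drying subjects); the blob
  shrinks through a fixed growth ordering, so masks are nested and
  ground-truth fractions are monotone. Between-series recovery follows
  1 − e^(−t/τ_rec), τ_rec = 60 s. Both exponentials are this package's
  models — empirical trajectories are reported without a functional
  form — chosen as the simplest relaxation dynamics.
- **Moisture datasets**: gloss uniform on (41, 100) — above the bundled
  line's root — with σ = 0.005 mg noise, n = 25, the lower-gloss half
  labelled `dry` (13) and the upper `normal` (12). Moisture is floored
  at 0 by default (a filter paper cannot lose weight). Because the
  line's values (0.0002–0.025 mg) are comparable to the noise, flooring
  censors low-gloss records and biases OLS recovery of the generative
  parameters by several standard errors; parameter-recovery studies
  (including `scripts/acceptance.py`) therefore pass
  `floor_at_zero=False`, which realises the intended censoring-free
  regime.

What passing the synthetic suites does **not** show: robustness to
papillae/coating texture, tongue motion between frames, non-uniform
illumination, saturated highlights beyond per-channel clipping, or
saliva-type differences. The generators produce the cleanest scene
consistent with the acquisition model; real photographs will be harder.

## Problem sizes and runtime choices

Synthetic scenes are 200×260 px (tongue ≈ 13 000 px), drying series use
6–21 frames, and Monte-Carlo studies use 100–200 replicates — large
enough for the envelopes to be meaningful, small enough that the whole
suite runs in seconds on one core.

## Known limitations

- The bundled regression's absolute scale is suspect (sub-0.03 mg
  predictions versus tens of mg of filter-paper absorbency); treat
  outputs as a relative index unless refitted on own data.
- Otsu with the smallest-level tie-break is conservative: thresholds
  sit at the low edge of the inter-mode gap, which the despeckling step
  compensates for.
- Frame pairs are assumed co-registered; there is no motion
  compensation hook beyond supplying pre-registered frames.
- `GlossMoistureRecord` does not hard-enforce non-negative moisture, to
  allow unclipped simulation studies; file-based inputs are expected to
  be physical (non-negative).
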