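# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `canopyhist`, in the spirit of a methods appendix: what
the package computes, why the defaults are what they are, and what passing
its tests does and does not demonstrate.

## Color indices and masking

All six indices are ratios or normalized differences of the 8-bit R, G, B
channels, computed in double precision after casting.  Pixels whose
denominator is zero (pure black for the sum-based indices, R = 0 for G/R,
B = 0 for G/B) carry no defined value; they are masked invalid and excluded
from every downstream statistic rather than clamped to a sentinel, because
any clamped value would be fabricated data.  The masked fraction is logged
per image.

G/R and G/B are unbounded above.  For histogramming they are assigned the
fixed range [0, 5] with out-of-range pixels counted in the end bins; the
normalized indices use their theoretical ranges ([0, 1], and [−1, 1] for
(G−R)/(R+G+B)).  Fixed ranges are essential: bin-wise correlation across
samples is only meaningful if bin k means the same interval in every image.

## Vegetation segmentation

The "vegetation component" is defined on the normalized green-minus-red
index (GMRN), which highlights vegetation: pixels above a threshold are
canopy.  The default threshold is Otsu's bimodal split of the valid GMRN
values, recomputed per image so that illumination shifts move the threshold
with the data; a fixed threshold can be supplied instead.  A constant GMRN
raster (no soil/vegetation contrast) is treated as fully vegetated, with a
log notice.  If a vegetation mask comes out empty, the mean-value feature
falls back to all valid pixels rather than failing, again with a notice.

## Histogram features

Histograms use 256 equal-width bins (right-open except the last) over the
index's fixed range, expressed as pixel percentages so that image
resolution cancels.  256 matches the granularity of 8-bit imagery; fewer
bins blur the soil/crop modes, more add multinomial noise per bin.

Peak detection smooths the curve with a 5-bin centred moving average
(reflect padding) and takes local maxima; endpoints qualify only when they
strictly dominate their neighbor, and empty bins never qualify.  The two
tallest maxima at least 20 bins apart become peak *a* (smaller bin index,
soil) and peak *b* (larger, crop).  If only one mode is found it is
assigned by position relative to the range midpoint; a flat histogram
yields no peaks and a flag.  The 20-bin separation (≈ 0.16 in GMRN units)
is far smaller than the soil–crop mode distance in any realistic frame but
large enough to ignore smoothing ripples.

Bin selection intersects a 41-bin window centred on the cohort-template's
crop peak with a correlation filter: bins whose |Pearson r| with the target
(across training samples) reaches 0.5 are kept; if fewer than 8 survive,
the 8 largest-|r| window bins are taken; if more than 12 survive, the 12
largest-|r| are kept.  The cap exists because adjacent percentage bins are
strongly collinear — beyond roughly a dozen they add parameters (each bin
adds 10 hidden-layer weights) faster than information, and a 60-sample
training set cannot support a ~400-parameter input layer.  Bins with zero
variance across samples get r = 0 by convention, never NaN.  Selection is
fitted on the training split only and frozen before validation, so no
information leaks from the held-out samples into the feature definition.
A `global_corr` policy (top-k |r| anywhere) is available when no crop peak
exists.

## The diagnosis network

One hidden layer of 10 logistic units, one linear output, one network per
target.  Inputs and the target are min-max scaled onto [−1, 1] (computed
from the training data and stored with the model); without scaling, yields
of order 10³ kg ha⁻¹ would saturate the sigmoids immediately.  Weights are
initialized with a seeded Nguyen–Widrow-style scheme: uniform hidden rows
rescaled to magnitude 0.7·h^(1/d), biases spreading the active regions
across the input range.

Training is Levenberg–Marquardt: the analytic Jacobian of the residual
vector is assembled by backpropagation, the step solves
(JᵀJ + μI)Δ = Jᵀr by Cholesky factorization, a step is accepted only if the
sum-of-squares loss decreases (μ × 0.1 on acceptance, × 10 on rejection,
starting at 10⁻³), and iteration stops on a gradient infinity-norm below
10⁻⁷, a loss below 10⁻¹², 200 iterations, or damping overflow (μ > 10¹⁰).
The recorded history holds the loss at initialization and after every
accepted step and is therefore nonincreasing by construction.

A network with this topology has between ~80 and ~150 free parameters for
6–12 inputs — more than the 60 training samples.  Run to convergence, LM
interpolates the training data exactly and predictions between training
points degrade without bound; we measured validation MAPE rising
monotonically with the iteration budget on simulated cohorts.
Generalization is therefore controlled the way the classic LM fitting
tools control it: 25% of the training samples are held out as an internal
early-stopping subset, training halts after 6 consecutive iterations
without improvement on that subset, and the weights of the best-stopping
iteration are restored.  The stop subset is drawn from the training split
only — the 30 validation samples are never touched during fitting.  For
realizable noiseless targets (where the stop error tracks the training
error downward) the mechanism is inert, and it can be disabled
(`early_stop_frac=0`) for pure LM, which is what the optimizer-correctness
tests exercise.

Because the loss surface is nonconvex, fitting runs a 5-start multi-start;
all restarts share one stop subset and the restart with the lowest
stop-subset error is kept (under pure LM, the lowest final training loss).
Models serialize to JSON — weights, scalings, config, training history and
the feature recipe (index list, or bin selection) — and reload to
bit-identical predictions.

## Evaluation protocol

Each growth stage is analyzed separately.  The 90-sample cohort is split
60/30 by seeded largest-remainder apportionment over (cultivar × N rate)
strata with a floor of one training sample per stratum, so every plot
condition is represented in training; strata smaller than 2 are pooled
with a warning.  RMSE is reported in target units and MAPE in percent
(undefined and refused when a measured value is zero).  The presentation
table rounds MAPE to one decimal and RMSE to three; CSV output keeps full
precision.  Within one comparison, the IIMV and IIH networks for the same
(stage, target) share a training seed, so the contrast between feature
families is paired and restart luck cancels out of it.  Because single
splits at n = 90 are noisy, comparison verdicts in the tests and the
acceptance script use medians over 10 replicate cohorts.

## Synthetic cohorts

The generator emulates the statistical structure the method needs, not the
optics of a real canopy.  Each frame is a two-population pixel mixture:
soil background and vegetation, laid out by thresholding a Gaussian-blurred
noise field (σ = 2.5 px) so canopies are patchy; the exact pixel count
matches the target coverage.  Per plot (6 cultivars × 5 N rates
{0, 120, 180, 240, 360} kg N ha⁻¹ × 3 replicates = 90 samples):

* **Leaf N** follows a saturating response, 2.9 + 1.3·(1 − e^(−N/180)) %,
  plus a cultivar offset (sd 0.2) and plot noise (sd 0.12) — spanning
  ≈ 2.3–4.5%, the realistic field range.
* **Coverage** follows a logistic curve in the plot's latent N status plus
  a stand-density (tillering) deviation (sd 0.15 leaf-N-equivalent units):
  tillering integrates the season's N supply, so coverage is a second
  reading of N status that is independent of instantaneous leaf color.
  Reviving-stage coverage runs ≈ 0.2–0.65; the jointing preset ≈ 0.5–0.9.
* **Yield** is mediated by the same stand status (1500 kg ha⁻¹ per status
  unit above baseline) minus a one-sided over-application penalty above
  190 kg N ha⁻¹, plus a small independent cultivar offset and harvest
  noise (sd 150 each).  The combined response peaks at an intermediate
  rate and spans ≈ 4500–7900 kg ha⁻¹.  Routing the N response through
  canopy status reflects the field observation that poorly established
  stands both look sparse and yield little.
* **Color**: vegetation RGB is (90 − 8·leafN, 80 + 18·leafN, 60) plus a
  per-cultivar cast (sd 6 DN), a per-photo illumination/white-balance
  offset (sd 5 DN) applied to the whole frame, and per-pixel noise
  (sd 8 DN); soil is (120, 100, 85) with sd 6 spread.  The cast and the
  shot-to-shot jitter are what make a purely color-based reading of leaf N
  biased — and they are realistic: phone cameras are not radiometrically
  calibrated.

This structure is what gives the histogram its edge: coverage carries
diagnostic information that a vegetation-masked mean cannot see, while the
color channel both families share is confounded by cast and jitter.  The
`color_only` preset clamps coverage, removing the histogram's private
signal; the `null` preset decouples color and coverage from N entirely and
is used to verify that bin correlations are null when nothing is there.
Camera transforms (per-channel gain, shared gamma, per-channel offset,
then rounding and clipping) emulate the color tuning of different phone
brands.

What the generator does **not** emulate: leaf geometry, specular
highlights, shadows, mixed soil types, growth-stage-specific hue shifts
beyond coverage, or spatial autocorrelation between neighboring plots.
Passing tests on these cohorts shows the pipeline extracts the signals it
claims to extract under the stated noise structure — not that a particular
error level will be achieved on any real field dataset.

## Degenerate inputs and numerical conventions

Zero-size images, all-black frames, flat histograms, empty vegetation
masks, constant targets, duplicate sample ids and non-finite features are
rejected or flagged as described above.  The equal-mean image pair solves
the greenness of the higher-coverage frame analytically and realizes it by
mixing two adjacent integer green levels among vegetation pixels, so the
whole-frame means agree to 10⁻³ despite 8-bit quantization.  Tie-breaks in
bin selection and multi-start use stable sorts, and all randomness flows
from explicit integer seeds (NumPy `default_rng`), so every pipeline run is
bit-reproducible from its configuration.

## Known limitations

* The 60/30 protocol measures interpolation within the cohort's cultivar
  and treatment space; it says nothing about transfer to unseen cultivars,
  sites or seasons.
* Bin selection by marginal |r| ignores bin interactions; a multivariate
  selector could in principle find narrower, stronger regions.
* The vegetation-mean comparison inherits whatever bias the Otsu split has
  near 0% or 100% coverage, where the GMRN raster stops being bimodal.
* MAPE is scale-sensitive: with leaf N around 3–4%, one MAPE point
  corresponds to ≈ 0.035 percentage points of leaf N.
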