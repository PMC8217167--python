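# canopyhist

Histogram-based nitrogen diagnosis of crop canopies from ordinary RGB
photographs.

Leaf nitrogen status drives both the color of a cereal canopy (chlorophyll
absorbs red and blue, so well-fertilized leaves are greener) and its
fractional ground coverage (better-nourished stands tiller more).  A phone
photograph taken straight down over a plot therefore carries two diagnostic
signals at once.  The traditional approach summarizes a color-index image by
its **mean value over the vegetation component (IIMV)** — a single number
that reflects hue but discards coverage, and that drifts between cultivars
and cameras.  This package implements the alternative: the **index-image
histogram (IIH)**, the per-bin percentage distribution of a color-index
raster, which encodes hue (position of the crop peak) *and* coverage
(relative mass of the soil and crop peaks) simultaneously, and feeds the
informative part of that curve into a small neural network.

The package is aimed at agronomists and phenotyping-method developers who
want to evaluate or extend histogram-based diagnosis without field data:
a synthetic canopy generator reproduces the statistical structure the
method relies on, end to end.

## Method

For an image with 8-bit channels R, G, B, six per-pixel color indices are
computed:

    G/R,  G/B,  R/(R+G+B),  G/(R+G+B),  B/(R+G+B),  (G−R)/(R+G+B)

Pixels with a zero denominator are masked out.  The normalized
green-minus-red index (G−R)/(R+G+B) highlights vegetation and is the
default basis for both vegetation segmentation (Otsu's threshold) and the
histogram feature.

For the IIH route, each index raster is histogrammed into 256 equal-width
bins over a fixed range, as pixel percentages.  A cohort-template histogram
is smoothed and its two modes located: peak *a* (left, soil) and peak *b*
(right, crop).  Bins inside a window centred on peak *b* are ranked by the
Pearson correlation of their percentage with the diagnosis target across
the training samples, and the surviving bins become the model inputs.

The diagnosis model is a multilayer perceptron with one 10-neuron logistic
hidden layer and a linear output, trained by Levenberg–Marquardt damped
Gauss–Newton on min-max-scaled data, with an internal early-stopping subset
and a small multi-start.  One network is trained per target: leaf N content
(% of dry mass) and grain yield (kg ha⁻¹).  The protocol splits each
90-sample cohort 60/30 (stratified by cultivar × N rate), fits bin
selection and networks on the 60, and reports RMSE and MAPE on both splits
for both feature families.

## Worked example

```python
from canopyhist import EvalConfig, generate_cohort, reviving_scenario, run_comparison

cohort = generate_cohort(reviving_scenario(seed=42))     # 90 simulated plots
report = run_comparison({"reviving": cohort}, EvalConfig(seed=42))
print(report.formatted_frame().to_string(index=False))
```

prints

```
mode    stage target mape_train rmse_train mape_validation rmse_validation
iimv reviving leaf_n       5.9%      0.270            7.3%           0.309
 iih reviving leaf_n       5.3%      0.219            5.7%           0.246
iimv reviving  yield       6.6%    503.120            5.7%         462.754
 iih reviving  yield       4.4%    362.526            4.4%         373.223
```

Each row is one feature family × target.  RMSE is in target units (percent
leaf N; kg ha⁻¹ yield), MAPE in percent.  On this cohort the histogram
features beat the mean-value features on both targets on the held-out 30
samples — leaf N error drops from 7.3% to 5.7% and yield error from 5.7% to
4.4% — because the histogram also sees the coverage signal.  Single splits
are noisy at n = 90; `compare_over_seeds` repeats the protocol over
replicate cohorts and `median_cells` aggregates.

The same pipeline is available from the shell:

```
canopyhist simulate --out run/cohorts --seed 7
canopyhist features --cohort run/cohorts/reviving --out run/features
canopyhist diagnose --cohort run/cohorts/reviving --cohort run/cohorts/jointing \
                    --out run/diagnosis --seed 7
# or all three chained:
canopyhist all --out run --seed 7
```

A run directory contains the scenario snapshot, split manifest, bin
selections and model JSONs needed to reproduce every number bit-exactly;
`canopyhist diagnose --apply MODEL.json` scores new images with a frozen
model.

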