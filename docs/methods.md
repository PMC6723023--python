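# Methods

## Calibration model

For one fruit and one analyte, replicate-level contents are modeled as

    Y_i = b0 + b1 L*_i + b2 a*_i + b3 b*_i + e_i,    e_i ~ N(0, sigma^2),

with (L*, a*, b*) the CIELAB coordinates of the homogenized pulp. The
coefficients are obtained by solving the normal equations (X'X) b = X'Y
directly (`solve_normal_equations`); the solver is generic in the design,
so univariate polynomial layouts are the same code path. A rank-deficient
design raises an error rather than falling back to a pseudo-inverse: a
calibration whose color coordinates are collinear has no unique model and
silently picking one would hide a degenerate experiment.

Goodness of fit is R^2 = 1 - SSE/SST. Coefficient significance uses
t_i = b_i / sqrt(P_ii S^2), P = (X'X)^-1, S^2 = SSE/(n - 4), two-sided
p-values at n - 4 degrees of freedom. When S^2 = 0 (an exactly
interpolating fit) the t-statistics are reported as signed infinities
(zero for exactly-zero coefficients) with p = 0 instead of failing.

### Residual filtering

Homogeneity is enforced by one pass (configurable) of a residual filter:
after the initial fit, rows with |residual| > k * sigma are dropped
(sigma = dof-corrected residual SD of that fit, default k = 2) and the
model is refit on the survivors. Ties at exactly k * sigma are kept. For
Gaussian noise this retains ~95% of clean rows; a second pass removes only
a few percent more because sigma barely changes after trimming the tail.
At least 5 rows must survive for the 4-parameter refit.

### Prediction and validation

A calibrated model predicts content at any color as
b0 + b1 L* + b2 a* + b3 b*; negative predictions (extrapolation outside
the calibrated color range) are returned unclamped with a warning.

Method validation compares the coefficient of variation of the
experimental replicates (CV_E, over all rows) and of the model predictions
(CV_P, over the rows the filter retained) against an acceptance limit.
Computing both over the same filtered rows would make the experimental and
predicted means identical by the least-squares mean identity, so the
experimental summary deliberately keeps every replicate. Two limit modes:

* `fixed` (default): 16% for analytes reported in ug/g (carotenoids), 8%
  for analytes reported in mg/100 g (anthocyanins, polyphenols) — the
  conventional per-concentration-range bands;
* `horwitz`: the continuous curve CV% = 2^(1 - 0.5 log10 C) evaluated at
  the experimental mean converted to a mass fraction (ug/g -> 1e-6,
  mg/100 g -> 1e-5), which makes the verdict invariant to the unit chosen.

## Assay arithmetic

The upstream wet-chemistry conversions are deterministic formulas:

* TAC (pH differential): A = (A510 - A700)_pH1.0 - (A510 - A700)_pH4.5;
  TAC = A x MW x DF x 100 / (epsilon x W) with MW = 484.84 g/mol and
  epsilon = 34300 L mol^-1 cm^-1 for cyanidin-3-glucoside chloride, DF the
  dilution factor and W the sample weight (g). The four-absorbance
  combination is the standard AOAC form; a pre-combined A is also
  accepted. A negative A (below detection limit) yields 0 with a warning.
* TCC: TCC = A450 x VT x 10^4 / (2592 x W), VT the extract volume (mL),
  2592 the extinction coefficient of beta-carotene in hexane.
* TPC (Folin-Ciocalteu): net response = Abs_B - Abs_A (interference
  correction between the soluble and non-soluble fractions), inverted
  through the gallic-acid line y = 0.0011 x + 0.0529 to mg/L, then scaled
  by extract volume (L), dilution factor and sample weight to mg
  GAE/100 g. Extract volume, dilution and weight have no defaults: the
  mg/L -> mg/100 g link is protocol-specific and must be stated by the
  caller.
* Antioxidant capacity: Trolox lines y = 0.0007 x + 0.0671 (ABTS) and
  y = 0.0013 x + 0.007 (DPPH), scaled to umol TE/g.
* Maturity index MI = TSS/TA; chroma C* = sqrt(a*^2 + b*^2) and hue
  h = atan2(b*, a*) in degrees mapped to [0, 360), with h = 0 by
  convention at zero chroma. (Published summary tables of these
  quantities sometimes interchange the C* and h columns; the package
  always uses the standard definitions.)

All computation is in full precision; rounding to 2 decimals is left to
reporting.

## Synthetic data generator

The generator emulates the calibration study design: 15 samples x 3
replicates (45 rows) per fruit. Colors are drawn per sample from
independent Gaussians with the bundled per-fruit means and SDs (replicates
share the sample draw; optional replicate-level color noise defaults to 0,
since the within/between-sample variance split of real pulp measurements
is not known — only the totals are). L* is clipped to [0, 100]; a* and b*
are unbounded. Contents follow the linear model plus N(0, noise_sd^2)
noise; `spec_from_reference` sets noise_sd to the bundled prediction CV
times the predicted mean — the residual scatter the published calibrations
exhibit — so refitting synthetic data reproduces determination
coefficients in the published 0.75-0.98 range. Outliers are planted
deterministically: floor(outlier_fraction x n) rows chosen uniformly
without replacement, shifted by +/- outlier_shift x noise_sd with
alternating sign.

Raw absorbance records are produced by inverting the assay formulas
analytically, so assay arithmetic round-trips to <= 1e-9 relative error —
this checks the formulas, not instrument behavior.

What the generator does **not** emulate: correlated color axes (an
injectable correlation structure would be a one-line extension but the
default is independence, the simplest model consistent with the reported
means/SDs), instrument drift, pigment degradation chemistry, or ripening
kinetics. Tests passing on synthetic data therefore demonstrate the
statistical machinery, not the validity of the linear color-content
relationship in any new fruit.

## Numerical and design choices

* Normal equations are solved with a direct dense solve after an explicit
  rank check; designs here are tiny (<= a few hundred rows, 4-6 columns)
  and well-conditioned, and (X'X)^-1 is needed anyway for inference.
* Rows are replicate-level (n = 45), not per-sample means; fitting on
  means would discard the within-sample information the CVs are built
  from. Aggregation, if wanted, is a caller-side groupby.
* Filtering is per-analyte: dropping a row for one analyte does not remove
  it for the others.
* Analytes below the spectrophotometric detection limit for a fruit
  (anthocyanins in the yellow-orange fruits, carotenoids in the red-purple
  ones) are declared in the pipeline config and reported as "N.D" with no
  fit attempted.
* The pipeline isolates failures per fruit x analyte and its JSON report
  is byte-deterministic for a fixed config and seed.
* Simulation sizes in the test suite (500 replicates for parameter
  recovery, 1000 for filter retention, 2000 for type-I error and interval
  coverage) are chosen so Monte-Carlo error is well inside the asserted
  bands while the whole suite stays fast.

## Known limitations

* The calibrations are fruit-specific: coefficients fitted on one matrix
  do not transfer, and the bundled models are screening tools, not
  replacements for chromatographic quantification.
* The linear color model has no mechanistic basis; it is an empirical
  local fit over each fruit's observed color range, and predictions
  outside that range can be negative (flagged, not clamped).
* Sampled R^2 on 45-row datasets scatters around its expectation with an
  SD of roughly 0.05 for the weaker calibrations, so single-draw R^2
  values marginally below the published range are expected behavior, not
  miscalibration.
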