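# Methods

## Measured BMR from gas exchange

A ventilated-hood session is a uniformly sampled trace of oxygen
consumption (VO₂) and carbon dioxide production (VCO₂), both in L/min
STPD, by default at 5-s cadence for 30 min. Processing is:

1. **Habituation discard** — samples with t < 300 s are dropped (subjects
   settle under the hood during the first minutes; the configurable
   default is 5 min).
2. **Steady-state selection** — every window of 600 s (sliding one
   sampling interval at a time, half-open `[start, start+600)`) is scored
   by the within-window coefficient of variation (sample SD / mean,
   ddof = 1) of VO₂ and of VCO₂. Windows with both CVs ≤ 0.10 qualify; the
   qualifying window minimising CV(VO₂)+CV(VCO₂) is chosen, earliest start
   on ties. If no window qualifies the error carries the best candidate so
   the caller can inspect how close the trace came. The 10% CV rule is the
   common metabolic-cart convention; the criterion, window length and
   discard are all parameters.
3. **Weir conversion** — the window means are converted with the
   abbreviated Weir equation, EE (kcal/min) = 3.941·VO₂ + 1.106·VCO₂,
   scaled by 1440 min/d and 4.184 kJ/kcal. The protein-free form is the
   standard choice for hood measurements, where urinary nitrogen is not
   collected; omitting the correction biases EE by well under 2% at normal
   protein oxidation rates.

An `average_all_windows` flag averages the Weir value over every
qualifying window instead of using only the best one; the single-window
behaviour is the default because a hood session is conventionally reduced
to one value per subject.

## Prediction equations and BMI

The registry stores each equation as sex-specific, age-banded linear forms
in weight (kg), height (cm) and age (years), with coefficients exactly as
published (kJ/d). Single-band equations cover ages 18–120. Henry's bands
are dispatched half-open — [18, 30), [30, 60), [60, 70] — so age 30 falls
in the middle band; the top band is closed at 70, and ages outside all
bands raise an error naming the equation and age (nearest-band
extrapolation is available behind a flag, default off). BMI is
weight / (height in m)², classified at the Asian cut-offs: not overweight
≤ 23.0, overweight (23.0, 27.5], obese > 27.5 kg/m². In two-way stratified
tables a BMI of exactly 23 falls in the "≤ 23" stratum.

## Equation derivation

`StepwiseBmr` regresses measured BMR on candidate covariates (weight,
height, age, gender with men = 1, women = 0) by forward selection: at each
step the candidate producing the smallest residual standard deviation
enters if its partial t-test is significant at the entry level
(default p < 0.05); ties in RD reduction break alphabetically for
determinism; selection stops when the best remaining candidate is not
significant. Forward-only is the default because the reported derivation
path (weight, then gender, then stop) is forward-shaped; a bidirectional
variant (removal at p ≥ 0.10 after each addition) sits behind a flag.

Fit statistics: R² = 1 − SSE/SST and RD = √(SSE/(n − k − 1)) with k the
number of covariates, i.e. the residual standard deviation of the fit. At
n = 232 the choice of denominator (n vs n − k − 1) moves RD by < 0.7%.
The underlying fits are ordinary least squares via statsmodels; the test
suite cross-checks them against an explicit normal-equations solver.
Rendering a fit as an equation folds the gender coefficient into per-sex
intercepts (men's intercept = intercept + gender coefficient), giving the
familiar two-row adult form. Coefficients are carried at full precision;
rounding to reporting precision happens only in formatted output.

## Agreement and accuracy

Differences are **predicted − measured**, so a positive bias is
overestimation by the equation. For each equation the report carries the
bias, sample SD of differences, two-sided paired t-test, squared Pearson
correlation of measured vs predicted, limits of agreement defined as
bias ± 2·SD (the multiplier is a parameter; 2, not 1.96, is the package
default), and the OLS regression of differences on pairwise averages,
whose slope and slope p-value quantify directional (proportional) bias.

A prediction is *accurate* when |predicted − measured| ≤ 10% of measured
(boundary inclusive); above +10% is *over*, below −10% *under*. The three
shares partition every cohort exactly, and are reported overall and split
at BMI 23. An empty stratum is reported as absent, not as zeros. Ranking
across equations is by overall accuracy descending, ties by |bias|
ascending. p-values are reported unadjusted (a Bonferroni flag exists,
default off), matching standard practice for these descriptive
comparisons.

## Synthetic cohorts

The generator draws fixed per-sex counts (not Bernoulli sex assignment —
the study design fixed its counts, and this removes a variance source):

| preset | men | women | men weight (kg) | women weight (kg) |
|---|---|---|---|---|
| cross_sectional | 121 | 111 | 79.2 ± 14.9 | 66.1 ± 16.1 |
| cross_validation | 26 | 44 | 72.1 ± 13.3 | 59.7 ± 15.6 |

with per-sex Normal height (171.7 ± 5.9 / 159.9 ± 6.2 cm cross-sectional;
173.4 ± 6.3 / 162.3 ± 5.3 validation) and age (32.3 ± 9.9 / 33.4 ± 11.2 y;
28.2 ± 6.3 / 28.8 ± 10.2 y). Measured BMR is the equation's mean structure
plus homoscedastic Gaussian noise:
BMR = 1960 + 52.6·W + 828·G + N(0, 534) kJ/d.

Truncation: age is rejection-sampled into the adult study range
(21.6–66.8 y) and height into its observed range; **weight is deliberately
untruncated**. The pooled observed weight range's lower bound lies only
~1.7 SD below the women's mean, so per-sex truncation at that bound would
clip ~5% of women's draws, shrink their weight SD from 16.1 to ~14.4 kg
and depress the recoverable R² — the published per-sex SDs, not the pooled
extremes, are the authoritative description of weight spread. Ranges
remain per-spec parameters for any covariate. Covariates are sampled
independently within sex (no covariance is published); an optional
weight–height correlation (e.g. 0.4) is available for realism but defaults
to 0, so per-subject BMI only approximately reproduces the observed BMI
distribution and BMI-stratified accuracy shares carry wide tolerances.

Under these defaults the implied population statistics match the study's:
mean cohort BMR ≈ 6230 kJ/d, SD of the mean structure ≈ 1112 kJ/d,
weight-only residual SD ≈ 656 kJ/d, weight+gender R² ≈ 0.81. Because the
residual is homoscedastic Normal while real between-subject residuals are
heavier-tailed and mildly heteroscedastic, the expected ±10% accuracy rate
of the true equation is ≈ 75%, a few points below the observed 78% — tests
of the accuracy rate use a ±5-percentage-point band for exactly this
reason. Passing tests therefore demonstrate correct arithmetic and
parameter recovery under the stated population model, not that the model
captures every feature of real calorimetry data (no RQ physiology,
diurnal effects, or measurement-day variance components are emulated).

Gas traces invert the Weir equation at a chosen RQ
(VO₂ = EE/(3.941 + 1.106·RQ), VCO₂ = RQ·VO₂), multiply by
1 + amp·exp(−t/τ) with τ = transient_minutes·60/5 (the transient decays to
e⁻⁵ ≈ 0.7% of its amplitude by the end of the nominal transient period),
and apply per-sample multiplicative Gaussian noise (default CV 3%,
negative values clipped at 0). With the default 3% noise, a 120-sample
window mean has a standard error ≈ 0.27%, so the round-trip
generate → process recovers the target BMR within 1%.

## Randomness and determinism

All stochastic code takes either an integer seed or a numpy `Generator`
(PCG64 via `default_rng`); replicate runs spawn independent child streams
from a single `SeedSequence`, so any top-level seed fixes every draw.
Re-running any evaluation on the same cohort is bit-identical; CLI runs
write a manifest (config + seed + package version) sufficient to replay
outputs byte-for-byte.

## Problem sizes

Monte-Carlo checks use 200 replicate cohorts of n = 232 (standard error of
the mean R² ≈ 0.001, of the gender coefficient ≈ 5 kJ/d), 50-seed checks
for generator moments, and 10,000 paired differences for the
limits-of-agreement coverage property; steady-state selection is verified
against an exhaustive window scan on traces of ≤ 400 samples.

## Known limitations

- The generator's independence and homoscedasticity assumptions (above)
  bound what the accuracy-rate comparison can show.
- Equation coefficients are stored at published precision; equations not
  in the registry (e.g. Schofield/FAO originals) and body-composition
  covariates are out of scope.
- Gas-analyser physics (flow control, calibration, dilution equations) is
  not modelled: the input contract starts at VO₂/VCO₂ rates.
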