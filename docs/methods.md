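# Methods

This note documents the models, conventions and numerical choices behind
`hteda`, and what the synthetic scenarios do and do not establish about
real screening data.

## Fractionation geometry

A `FractionScheme` is defined by the collection interval (seconds), the
number of fractions, the collection start time and the plate fill
convention. Fraction windows are half-open `[start, end)` so a boundary
retention time belongs to exactly one fraction; indices are 1-based; the
fraction count for a collection window is `floor(duration / interval)`
(a partial trailing interval is discarded — 24 min at 18 s gives 80).
Fraction-collector fill patterns vary by instrument and are not always
recorded in published well labels, so the fill order (`column_major`,
`row_major`, and both serpentine variants), the start well and the start
time are configuration, defaulting to column-major from A1 at t = 0. The
well mapping is bijective for a fixed scheme and is property-tested as a
round trip over every fill order.

## Dose–response model

Responses are percentages of the maximal reference-agonist signal:
technical replicates are averaged first, then
`100·(mean − solvent background)/(reference max − solvent background)`.
The curve is a four-parameter log-logistic,
`y = bottom + (top − bottom)/(1 + (EC50/x)^h)`, fitted by nonlinear least
squares (`scipy.optimize.curve_fit`, EC50 parameterized on log10 scale,
bounded, tight `xtol`/`ftol` so noiseless inputs are recovered to float
precision). `bottom` is fixed at 0 by default because responses are
background-subtracted percentages; it can be freed.

Numerical and policy choices:

* **High-dose suppression.** Reporter-gene assays often bend downward at
  high enrichment because of cytotoxicity. Points more than 20 percentage
  points (configurable) below the running maximum seen at a lower dose
  are excluded from the fit and reported in `excluded_points`.
* **Minimum signal.** If no kept point reaches 5% response the fit is
  refused (`FitFailureError`) — there is no information about the EC.
* **Censoring.** `ec_estimate(level)` right-censors at the highest tested
  dose when neither the observed nor the fitted response reaches the
  level inside the tested range; censored values print as `>dose` and
  yield no BEQ.
* **Linear-range EC10.** When suppression makes the upper limb
  unreliable, an OLS line through the low-dose points (response below a
  30% ceiling by default, ≥3 points, positive slope required) gives
  `EC10 = (10 − b)/a`.

Bioanalytical equivalents are `BEQ = EC_ref / EC_sample` at a matched
effect level (default EC10), in reference-agonist mass per litre of
original sample; relative potency is `REP = EC50_ref / EC50_compound`.

## Toxicogram and active-fraction calling

The activity profile is scored with the modified z-score
`zᵢ = (Xᵢ − M)/MAD`, where `M` is the median over all fractions and
`MAD = median(|Xᵢ − M|)` **without** the 1.4826 normal-consistency
factor. A fraction is active when `z` is strictly greater than the
threshold (default 10). `MAD = 0` (a perfectly flat profile) is declared
"no activity detected" with a warning rather than producing infinite
scores — the natural reading for flat blanks. The median and MAD are
computed over all fractions; no QC-based exclusion is applied. Contiguous
active fractions are grouped into peaks (configurable gap tolerance,
default strict contiguity).

## Feature processing and prioritization

Two features match when the m/z difference (in ppm, computed relative to
the first argument — the asymmetry is negligible at ≤5 ppm and a fixed
convention is testable) and the RT difference are both within tolerance;
defaults are 5 ppm and 30 s everywhere, including blank matching, for
which no separate tolerance is conventionally stated. Blank subtraction
keeps a sample feature with no blank match, or one whose intensity is
strictly above `ratio` (default 3.0) times the highest-intensity matched
blank feature (the conservative choice among multiple matches); the
operation is idempotent. Shared-feature counting pairs candidates
greedily one-to-one by ascending m/z difference.

Prioritization keeps a feature when its hit probability on **any**
selected endpoint strictly exceeds the threshold (default 0.5). Features
without predictions (no MS2 spectrum) cannot be prioritized and are
tallied separately, so workload-reduction percentages can be referred to
either the all-features or the MS2-bearing denominator. Endpoint names
are configuration, not constants. Negative-mode tables are refused by
default because fingerprint-based activity prediction is unreliable
there; an explicit override exists.

## Quantification

Target compounds: peak areas are internal-standard corrected
(`area · IS_ref / IS_obs`) and inverted through a linear calibration
curve. The library-level `CalibrationCurve` default is an unweighted OLS
fit; the orchestrated pipeline uses 1/x weighting because its calibration
spans nearly four decades (0.1–750 µg/L) and an unweighted fit lets
top-of-range residuals corrupt the low end. Results above the highest
standard are right-censored and reported as ">top"; results below the
lowest standard are reported (clamped at zero) with a warning rather than
censored.

Semiquantification: a log-linear model `logRF = s·logIE + b` is fitted by
OLS over calibrant compounds; an unknown's predicted ionization
efficiency then implies its response factor and
`concentration = corrected area / RF`. Accuracy is order-of-magnitude by
design, and such results always carry medium confidence; high confidence
is reserved, by construction, for reference-standard calibrations.

## Iceberg accounting

Under concentration addition, each quantified compound explains
`100 · c · REP / BEQ_bio` percent of a location's measured activity.
Percentages above 100 are reported as-is and flagged masking-suspect
(never clipped): a co-eluting antagonist suppresses the measured
activity, so a genuine agonist can appear to over-explain it.
Fractionation separates antagonists from agonists, which is why
per-fraction accounting can close at ≈100% while the whole-extract
accounting over-explains — the pipeline demonstrates exactly this with a
synthetic antagonist (a tiny relative tolerance guards the >100% flag
against float-level overshoot of an exactly-100% contribution).
Compounds without potency data are listed as not-attributable rather
than silently dropped. Internally, fraction concentrations are µg/L and
fraction BEQs µg reference-equivalents/L; ng-based assay quantities are
converted at the interface.

## Synthetic scenarios

The generator emulates the statistical structure of a hospital-effluent
androgen screen: thousands of inactive background features (m/z uniform
over the 80–1200 scan range, RT uniform over the collection window,
log-normal intensities), a few active steroids with Gaussian elution
profiles whose per-fraction mass shares drive well luminescence through
the reference sigmoid, procedural-blank contamination, MS2-prediction
scores with configurable sensitivity and false-positive rate, and
calibration inputs for both quantification routes. Defaults (chosen once,
from the forward arithmetic):

* 80 fractions × 18 s; ~5000 ESI+ and ~1500 APCI+ background features;
  MS2 coverage 0.575.
* Reference curve EC50 43.5 ng/L with Hill slope 2, so the reference
  EC10 is 14.5 ng/L — consistent with a BEQ of ≈279 ng/L at a sample
  EC10 of REF 0.052.
* Three actives in two RT peaks (a broad conjugated-metabolite peak,
  fractions 49–55 at this geometry, and two co-eluting parent hormones
  at 58–61), sized so exactly ten fractions exceed the 5% ground-truth
  activity floor while the strongest tail fraction stays below 1.5% —
  calling is never borderline.
* Screen enrichment REF 10, placing per-fraction doses on the dynamic
  range of the sigmoid while keeping fraction EC10s inside the tested
  REF 0–16 dilution window.
* Noise: 5% multiplicative luminescence CV plus 0.5 percentage points of
  additive baseline noise (the baseline spread that the MAD sees), 20%
  feature-intensity CV, 3%/2% area/IS CVs, 0.15 residual SD on logRF.
* Prediction quality: sensitivity 1.0, false-positive rate 0.02.
* An optional antagonist subtracts reference-equivalent potency (default
  4 ng/L) from one fraction and from the whole extract before the
  sigmoid, producing the masking signature described above.

Everything is deterministic given the seed. What passing on these
scenarios shows: the arithmetic, thresholds and bookkeeping of every
stage are correct, and the pipeline recovers a known answer through
realistic noise. What it does not show: robustness to chromatographic RT
shifts between fractionation and MS runs, matrix effects and ion
suppression, isotopologue/adduct redundancy in feature tables, real
classifier error structure (errors here are independent Bernoulli), or
assay-specific cytotoxicity shapes. Scenario sizes (~6500 features, 13
plates' worth of wells) run in seconds; all sizes are configurable.

## Pipeline

Stages run strictly in order (geometry → bioassay anchors and reference
fit → toxicogram → features → prioritization → quantification →
per-location BEQ → contributions); any failure aborts with the stage
name and an error code. Every threshold actually applied is echoed in
the report, every intermediate is written as a delimiter-separated file,
and re-running on identical inputs reproduces identical reports. The
stage subcommands of the CLI are thin views over the same orchestration,
so their outputs always agree with a full run. With no active fractions
(e.g. blank-only input) the funnel and contribution table are empty but
the run completes — a report of "nothing found" is a valid result, not
an error.
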