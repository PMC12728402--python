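# Methods

This note documents the statistical models, conventions and design choices
behind labqc, and what the synthetic-data tests do and do not demonstrate.

## Conventions

All rates and relative uncertainties are percentages on the 0–100 scale.
Periods are half-open `[start, end)`; "monthly" means a calendar month with
no timezone arithmetic. A standard deviation or CV needs at least two
points; below that the statistic is *absent* (`None`), never zero, and
absent statistics propagate as indeterminate verdicts that are excluded
from failure-rate denominators. Display rounding is two decimals for
concentrations and percentages; every comparison (goal verdicts,
significance calls) uses unrounded values.

## Internal quality control

Control values are standardized against **fixed** targets from a
`ControlSpec` (`z = (x − μ_t)/σ_t`). Fixed limits reflect how control
parameters are set ahead of monitoring; `fit_control_spec` can estimate
targets from ≥ 20 baseline points but is never applied implicitly, so the
monitored data never moves its own limits.

The rule engine is configuration-driven. The default set is the classic
Westgard combination — `1_2s` as a warning, `1_3s`, `2_2s`, `R_4s`,
`4_1s`, `10_x` as rejections — with the usual error-type attribution
(`2_2s`/`4_1s`/`10_x` systematic, `R_4s` random, single-point rules
indeterminate). Numerical conventions:

* all thresholds are strict (a point exactly at 2 SD does not fire), with
  one exception: the `R_4s` *span* uses ≥ 4 SD, matching the range
  definition of that rule;
* window rules fire once per qualifying window, so overlapping windows
  produce overlapping violations — per-point firing frequencies then admit
  closed-form null probabilities (`1_3s`: 2Φ(−3) ≈ 0.27 %, `1_2s`:
  2Φ(−2) ≈ 4.55 %, consecutive-pair `2_2s`: 2Φ(−2)² ≈ 0.10 %), which the
  calibration tests check within 3 binomial SE;
* within a single series, adjacent points are treated as one analytical
  run for the pair rules (`2_2s`, `R_4s`); evaluating across control
  levels of the same run is done by interleaving the levels into one
  series.

## Interlaboratory comparison

Group statistics pool the raw observations of member laboratories (not lab
means), reporting both point and laboratory counts; a single-laboratory
group is computed but flagged `low_n`. The evaluated laboratory is included
in its own consensus group by default (consensus-program convention), with
an exclusion flag for leave-one-out scoring. Plain moments are used — no
robust/trimmed consensus estimators, which are out of scope.

Verdict tiers are configuration with conventional defaults (|SDI| ≤ 1.25 /
≤ 2.0, CVR ≤ 1.0 / ≤ 1.5). SDI is invariant under any affine rescaling of
the concentration axis and CVR under any positive rescaling, which the
property tests assert; under the null (lab drawn from the group
distribution) simulated SDI is centered at zero.

## EQA multirule screen

One series = one analyte in one scheme, events sorted by date (ties by
sample id) before analysis, so the screen is covariant under any input
permutation. The default rules and thresholds (all strict):

* `1_TEa` — |pd| > TEa: the event itself is unacceptable. Series are
  expected to be pre-filtered to acceptable events; `allow_unacceptable`
  admits mixed series and lets this rule flag them.
* `1_75%TEa` — |pd| > 0.75·TEa: early warning, error type indeterminate.
* `same_side` — all events of a series with length ≥ 5 deviate on one
  side: potential systematic error. Under a symmetric null this fires with
  probability 2·(1/2)⁵ = 6.25 % at length 5, used as a calibration check.
* `2of3_2SDI` — ≥ 2 of any 3 consecutive events with SDI beyond ±2 on the
  same side: potential systematic error. The event's own group SD is used
  (it is the only SD the EQA record carries).
* `R_range` — max SDI − min SDI > 4 over the series: potential random
  error; the flagged indices are the two extreme events.

The classification aggregates only the systematic/random-typed rules
(`no_flag` / `potential_systematic` / `potential_random` / `both`); the
TEa rules grade acceptability rather than error type. No multiplicity
correction is applied across analytes: violations are screening flags that
trigger preventive review, not inferential claims.

Indicator proportions are compared with scipy's implementations — Pearson
chi-square, Yates-corrected chi-square, or Fisher's exact test; `auto`
selects Fisher when any expected cell is below 5 and Yates otherwise. The
test suite cross-checks Fisher against an independent hypergeometric
enumeration and Yates against the hand-written formula.

## Top-down measurement uncertainty

The estimator is the standard IQC+EQA decomposition: `u_Rw` is the
long-term IQC CV (several lots pool as the square root of the
(n−1)-weighted mean of CV²), `u_bias = sqrt(RMS(pd)² + u_cref²)` over the
EQA deviation history, `u_c = sqrt(u_Rw² + u_bias²)`, `U = k·u_c` with
k = 2 (≈ 95 % coverage) by default. The quality verdict is
`U ≤ quality_goal`, unrounded.

`u_cref` (assigned-value uncertainty) is explicit configuration, default
0. The EQA record schema carries an optional per-event `u_cref`;
`default_u_cref` pools those in quadrature. Deriving it as
`group_sd/√n_labs` is impossible from the record alone (no participant
count), which is why the choice is explicit rather than a hidden policy.

Clinical applications: the coverage interval `x·(1 ∓ U/100)` and the
minimum significant difference `z·√2·(u_c/100)·x` with z = 1.96, anchored
on the **earlier** of two serial results — with z = 2 or the later result
as anchor the published worked-example threshold does not reproduce, so
the serial z is a separate parameter from k. A difference is significant
only if it strictly exceeds the threshold.

A note on the estimand: EQA results are measured values, so each percent
deviation carries the laboratory's own analytical noise on top of its true
bias — `E[pd²] = bias² + u_Rw²`. The RMS-based `u_bias` therefore targets
`sqrt(bias² + u_Rw²)`, not the pure bias; this is an inherent property of
top-down estimation from EQA data, and the parameter-recovery test
measures the estimator against that estimand
(`u_c* = sqrt(2·u_Rw² + bias²)`), recovering it with ≈ 6 % median relative
error at 150 IQC points and 6 five-sample EQA events.

## Synthetic data generator

Observations are Gaussian: `value = μ_lab + σ_lab·ε` with
`μ_lab = true_mean·(1 + bias/100)` and `σ_lab = (CV/100)·true_mean·m`
(per-lab imprecision multiplier m). This is the simplest structure under
which every statistic the engines compute (mean, SD, CV, SDI, CVR, percent
deviation) has a known truth. Injections superimpose shifts (in SD units),
linear drifts, or imprecision scaling `(1 + magnitude)` — the `1 +` makes
magnitude 0 a byte-identical null injection in every mode. EQA samples are
measured once per laboratory from its current error model; the assigned
value is either the simulated consensus (peer-grading) or the configured
truth (oracle tests). One mandatory seed drives everything; identical
configs regenerate identical CSV bytes.

Defaults model a small district network: 5 laboratories, 2 control levels,
2 points/day for 90 days, 2 % analytical CV, 10 % TEa, 6 EQA events of 5
samples — typical clinical-chemistry conditions. Problem sizes in the
statistical tests (100,000 null points for rule calibration, 10,000
replicates for the same-side null, 200 laboratories for recovery) were
chosen so that 3-SE acceptance bands are tight relative to the effects
checked.

What the generator does **not** emulate: autocorrelated or cyclic drift,
reagent-lot change points, non-Gaussian heavy-tailed error, between-day
variance components, or mixed instrument fleets with unequal group sizes.
Passing tests therefore demonstrate correctness of the statistics and
decision rules under the stated model, not robustness of consensus
grading to real-world artefacts.

## RBP worked example

The packaged retinol-binding-protein fixture carries the published summary
quantities (level means 25/46 mg/L, U₁ = 15.18 %, u_c,2 = 4.44 %, results
28/71/68 mg/L, reference range 25–70 mg/L). The underlying raw IQC/EQA
data are not public, so the fixture's component breakdown (IQC CVs, an
alternating ±3 % EQA deviation history) is a synthetic reconstruction
chosen to be exactly consistent with the published combined values under
k = 2; the published combined values are treated as *inputs* to the
downstream operations, and only the downstream outputs (interval,
threshold, verdicts) are asserted against the published numbers.

## Known limitations

* Group statistics use plain moments; a single outlier laboratory inflates
  the consensus SD and can mask true bias (no robust estimators).
* The EQA `same_side` rule evaluates the whole series, not sliding
  windows; for series much longer than 5 its null rate shrinks
  geometrically and the rule loses power against late-onset shifts.
* `u_bias` conflates bias with EQA-run imprecision (see estimand note);
  separating them needs replicate EQA measurements, which the record
  format does not carry.
* Quality indicators take numerator/denominator counts as given; item
  inventory management (what counts as an "item") is outside the package.
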