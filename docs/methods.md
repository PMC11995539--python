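# Methods

This note documents the statistical machinery in `coda24`, the assumptions
behind it, and the design decisions taken where more than one defensible
choice existed. It describes what the code computes; every empirical figure
quoted here is produced by the test suite or `scripts/acceptance.py`, not
asserted independently.

## The compositional model

Daily time use is a 4-part composition (MVPA, LPA, ST, sleep) carried on
the 1440-minute simplex. All operations act on *closed* data (parts
rescaled to sum to 1440), because only relative information is meaningful:
a participant whose device recorded 23 h and one whose device recorded 24 h
with proportional behaviour are the same datum. Zero parts are rejected by
default — log-ratios are undefined at zero — with an optional pre-closure
additive shift (`coda.shift_zeros`, default +0.5 min, logged) for cohorts
containing true zeros; the shift is an upstream repair, never applied
silently.

The ilr map used throughout is the pivot variant:
z_j = √((D−j)/(D−j+1)) · ln(x_j / gm(x_{j+1},…,x_D)), j = 1…3. Its key
properties, all property-tested: scale invariance, exact invertibility
(implemented as a softmax of the clr image with max-subtraction for
stability), and isometry with the Aitchison metric (checked against an
independent clr-based computation). The storage order is fixed as
(MVPA, LPA, ST, sleep); analyses that need another behaviour in the lead
use explicit rotations.

## Regression and per-behaviour effects

The outcome is regressed by OLS on the three ilr coordinates plus
covariates. Categorical covariates are treatment-coded with the first
declared level as reference; continuous covariates enter untransformed.
The per-behaviour effect is the first pivot coordinate's coefficient with
that behaviour rotated to the front — equivalently (2/√3)·a_b where a_b is
the behaviour's centred clr coefficient, so the four reported betas sum to
zero by construction (verified against an independent clr regression).
Rotations are orthogonal changes of basis: fitted values, R², residuals and
the joint test agree across them to < 1e-9 on a 3498-row cohort.

The "model p" is the F-test of the three ilr coordinates jointly against
the covariates-only fit on the same rows; the composition is one exposure,
so a single joint test is the appropriate summary. Confidence intervals
are Wald intervals with t critical values at the OLS residual df (the
choice between t and normal quantiles is immaterial at n ≥ 1000 but t is
used consistently). No multiple-testing correction is applied across
behaviours or strata; α = 0.05. An RSS-difference noise floor
(1e-10 of the outcome's total variation) guards the F-test against
machine-precision artifacts when both models fit perfectly.

Simulation check: over 200 synthetic cohorts of n = 1134 drawn in the
continuous-outcome mode (where the configured coefficients are exactly the
estimand), each behaviour's 95% Wald CI covers the truth at close to the
nominal rate (the acceptance suite requires 91–99%).

## Group contrasts

Urban-vs-rural differences in each behaviour are log-ratios of per-group
geometric means, computed on compositions closed to 1440 — so they compare
*relative* time use and are invariant to per-row rescaling of raw minutes.
(Whether to close before or after taking geometric means is a genuine
choice; closure-first is used and matters only if raw rows do not share a
total.) CIs are bootstrap percentile intervals, resampling each group
independently with replacement (default 1000 replicates, level 0.95);
percentile rather than BCa because the estimand is a smooth functional of
two means and the percentile interval is the simpler, standard choice
here. Per-behaviour seeds derive deterministically from the root seed and
the behaviour name (CRC32 into a SeedSequence), so adding or reordering
contrasts never perturbs existing ones. Under a single-population null
(n = 200/group, 200 replicates), the 95% CI excludes zero in about 5–7% of
500 simulations.

## Isotemporal substitution

Reallocation estimates are evaluated at the stratum's compositional mean m:
moving t minutes from behaviour a to behaviour b gives m′ with
m′_a = m_a − t, m′_b = m_b + t, and the predicted outcome change
Δ = βᵀ(z(m′) − z(m)) over the ilr block — identical to a direct
two-point prediction difference because covariate terms cancel (the
acceptance suite checks every grid cell to 1e-9). SE(Δ) = √(dᵀVd) with
d = z(m′) − z(m) and V the ilr-block coefficient covariance.

Results are percentages, 100·Δ/baseline. The baseline is the
model-predicted outcome at the compositional mean with covariates at their
stratum sample means; for OLS with an intercept this equals the stratum's
observed mean outcome exactly (the ilr of the compositional mean *is* the
mean ilr vector), so the two candidate denominators coincide and no option
flag is needed. The CI treats the baseline as a fixed constant — no
delta-method term for denominator uncertainty — a documented limitation
shared with standard practice.

The grid covers all 12 ordered pairs at 10–60 min in 10-min steps, capped
at 30 min when MVPA is involved (larger transfers would cross the sample
mean MVPA and extrapolate), giving 6×6 + 6×3 = 54 cells per stratum.
Infeasible cells (transfer exceeding the source behaviour's minutes at the
reference composition) are flagged, not dropped, so the grid shape is
stable. Because ilr coordinates are nonlinear in t, |Δ| need not be
monotone in t and its sign can flip for pairs with near-zero effects; the
sign is stable for small transfers, which is what the tests assert.

## Two-lines U-shape test

The test fits y ~ b₀ + b_low·min(x−c, 0) + b_high·max(x−c, 0), optionally
with covariates, and flags a U (or inverted U) when the slopes have
opposite signs and both p < 0.10. The breakpoint c is selected either as
the median of x or (default) as the flat point of a lowess smooth of y on
x — the x where the smoothed slope changes sign, taking the sign change at
the curve's extremum when several exist. This smoother-extremum rule
approximates published breakpoint-selection practice without implementing
the full power-balancing ("Robin Hood") adjustment; the method actually
used is recorded in the result. Two fallbacks retreat to the median, both
logged: a monotone smooth (no sign change) and a selected breakpoint
leaving fewer than 10 points on a side. Slopes at machine-noise scale
(an exactly constant outcome) are reported as zero.

Operating characteristics at the configured signal size — flat null with
residual SD 6 over a sleep-like 360–600 min predictor range, versus a
quadratic with curvature 4e-4 min⁻² (vertex depth about one residual SD) —
measured over 500 simulations of n = 300: the false-flag rate is ≤ 12%
(the double p < 0.10 gate bounds it near 10%; breakpoint selection adds
some adaptivity) and detection exceeds 80% by a wide margin.

## Accelerometry processing

Raw tri-axial acceleration (g units, constant declared rate) is segmented
into 6-s epochs aligned at the first sample; partial trailing epochs are
dropped. Epoch intensity is the mean amplitude deviation (MAD) of the
acceleration resultant — rotation-invariant by construction. Processing
order: non-wear detection, sleep-window exclusion, posture estimation,
intensity classification.

- **Non-wear**: maximal runs of below-threshold MAD (default 0.0067 g)
  lasting ≥ 60 min, absorbing interior artifact interruptions totalling
  ≤ 30 s; interruptions at run edges are never absorbed. Window length,
  tolerance and threshold are configurable.
- **Sleep exclusion**: epochs intersecting the nightly self-reported
  [bed, wake) window — the same window every day, possibly crossing
  midnight — are discarded from wear time. Wear-time validity is assessed
  on *awake* wear (after sleep removal); this is an assumption, stated
  here because the alternative (before removal) yields different valid-day
  counts.
- **Posture**: trunk inclination relative to an upright reference
  calibrated as the mean acceleration vector over detected walking epochs
  (MAD in a configurable 0.091–0.6 g band); non-upright beyond 45°
  (configurable). With no calibration epochs, posture is unknown (logged)
  and low-intensity epochs default to sedentary.
- **Classification**: MAD ≥ 0.0915 g → MVPA (boundary inclusive upward);
  ≥ 0.0225 g → LPA; below that, posture decides sedentary vs standing.
  These cut-points are implementer-chosen defaults in required
  configuration, not universal constants — published cut-points are
  device- and protocol-specific, so they must be set deliberately per
  study.
- **Summaries**: behaviour minutes per day averaged over valid days only
  (≥ 600 min awake wear); participants need ≥ 4 valid days; reported LPA
  is standing + light activity.

End-to-end check: a synthetic multi-bout schedule with known per-behaviour
minutes is recovered within 2 min/day through the full chain.

## The synthetic cohort generator

The generator defines the study conditions for every simulation-based
test. Per stratum (urban n = 2364, rural n = 1134), ilr vectors are drawn
from a multivariate normal — hence logistic-normal compositions, strictly
positive and closed to 1440. Stratum means in minutes are
urban (65, 315, 612, 448) and rural (61, 355, 576, 448): chosen once so
that urban residents show relatively more MVPA and ST and less LPA, sleep
is near 7.47 h in both strata, and overall activity levels are plausible
for a middle-aged European cohort. The ilr covariance
(diag ≈ 0.20/0.06/0.04 with small positive cross-terms) puts the largest
relative variability on MVPA, as observed in practice.

Ground-truth effects are specified per behaviour — the first-pivot
coefficients (−0.20, +0.68, +1.29, −1.77) for (MVPA, LPA, ST, sleep),
which must and do sum to zero — and converted internally to the
storage-order coefficient vector. Covariates follow documented marginals
(57.3% female; education 3.4/72.7/23.9%; smoking 53.9/27.2/18.0%;
harm avoidance N(13.1, 6.3) truncated at 0; alcohol gamma with mean 10.5
and SD 17 g/day; waist N(91.3, 13.5); season 54.1% summer), identical in
both strata. Covariate effects are fixed defaults with harm avoidance as
the dominant confounder, yielding model R² near 0.25–0.3.

Two outcome modes:

- `linear_gaussian`: y is the latent linear predictor plus N(0, σ) noise
  (σ default 4). Used for exact-recovery and coverage tests, where the
  configured coefficients are exactly the estimand.
- `skewed_count` (default study condition): the latent predictor is
  standardised and mapped through a Gaussian copula onto a
  negative-binomial marginal with mean 5.3 and SD 6.1
  (size r = μ²/(σ²−μ) ≈ 0.880), clipped to [0, 63] — a right-skewed
  bounded integer score whose marginal moments match the instrument by
  construction, with no calibration loop. The monotone marginal transform
  attenuates linear coefficients, which is the realistic situation: on
  such data the fitted betas estimate the working linear model, not the
  latent truth.

What the generator does **not** emulate: joint covariate dependence (all
covariates are mutually independent), exposure measurement error,
informative missingness (injection is MCAR and off by default), seasonal
or within-person variation in time use, and any urban–rural differences in
covariate distributions. Passing tests therefore demonstrate the
estimators' correctness and calibration under the assumed data-generating
model, not robustness to the full messiness of field data.

Raw accelerometer streams for the processing chain are built per bout: an
alternating ±MAD modulation of a 1 g resultant (making epoch MAD exactly
the target amplitude) along the behaviour's gravity direction — upright
for standing/LPA/MVPA, rotated 90° for sedentary — with small orientation
jitter that leaves the resultant unchanged. Worn-but-still bouts use
MAD 0.010 g, above non-wear stillness but below the sedentary cut-point;
non-wear is exactly still.

## Determinism and problem sizes

Every stochastic component takes an explicit seed; child streams derive
via `numpy.random.SeedSequence`. Result bundles are written with fixed
float formatting and no timestamps, so identical seeds give byte-identical
files (checked end to end). Validation experiment sizes — 1000
compositions for round-trip checks, 200 cohorts for coverage, 500
simulations each for bootstrap calibration and the two-lines
characteristics, n = 300 per two-lines dataset — were chosen to estimate
rates and errors with comfortable Monte-Carlo precision while keeping the
whole suite fast on a single CPU.

## Known limitations

- Reallocation CIs ignore uncertainty in the baseline denominator and in
  the compositional mean itself.
- The two-lines breakpoint selector is an approximation to the
  power-balancing original; its operating characteristics are validated
  only under the configured simulation conditions.
- The accelerometry module re-specifies the non-wear rule (60-min window,
  30-s tolerance) and cut-point defaults as configurable operators rather
  than reproducing any specific published algorithm end to end; posture
  calibration assumes walking occurs within the recording.
- OLS on a bounded skewed score is the standard approach this package
  implements; it estimates associations on the mean scale and is not a
  count model.
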