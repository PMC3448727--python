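# Methods

`larvaclock` implements the quantitative machinery of a common-garden
photoperiod experiment on damselfly larvae sampled along a latitudinal
gradient: the climate-chamber light schedules, the per-individual growth
statistic, the hierarchical inferential models, and a synthetic data
generator that stands in for the unpublished raw measurements.

## Solar engine and chamber photoperiod rule

Day length is computed from standard low-precision solar geometry: the
declination is a Fourier series in the fractional year (Spencer-type
expansion, evaluated at local noon; accuracy about 0.3 deg, i.e. under ~3
min of day length at the latitudes of interest), and the time the sun
spends above a given altitude follows from the hour-angle inversion
`cos(H) = (sin a − sin φ sin δ)/(cos φ cos δ)`. No equation-of-time or
longitude correction is applied because the package reports only durations
on apparent solar time, never clock times.

The chamber light phase is daylight (sun above −0.833 deg, the standard
refraction-plus-solar-radius definition of rise/set) plus half of each
civil twilight (sun between −6 deg and −0.833 deg). Two polar edge cases
are handled explicitly: when the sun never sets the phase is 24 h
(`polar_day`), and when the sun sets but never descends to −6 deg the
entire dark period is civil twilight, of which half is counted as light
(`all_night_twilight`). The latter rule is what reproduces the ~22 h
light phase at 64 degN in July; without it the computed value would be
off by more than an hour. Durations are printed in h.mm notation
(17.15 = 17 h 15 min), the convention for chamber L:D settings, with
conversion by rounding to the nearest minute.

The treatment schedule tracks the real calendar from 10 July 2010 with
piecewise-constant weekly (Saturday) updates — the chamber emulation — or
optionally daily tracking; exact-date evaluation is always available and is
what the printed anchor values correspond to. The winter blackout runs
9–22 October 2010 (0 h light, 5 °C, age frozen); from 23 October the
schedule jumps to 9 April 2011 and advances daily, at 16 °C for 15 days
(until the mapped date reaches 24 April) and 22.5 °C thereafter.

Verification: the engine agrees with a minute-sampling altitude oracle
within 5 min for |latitude| ≤ 67 deg, and reproduces all six printed
chamber anchors within 2 min (tolerance ±10 min; an almanac rounded to
whole minutes is indistinguishable from a computed table at this
precision).

## Growth-trajectory statistic

Each larva is photographed at four events on a winter-excluded age axis
(0, 42, 84, 126 days; the 14 diapause days do not advance age). Log head
width is fitted with a third-degree polynomial

  L(t) = b0 + b1 t + b2 t² + b3 t³,

which with four distinct ages is exact interpolation. Growth rates are the
analytic slopes b1 + 2 b2 t + 3 b3 t² at day 21 (mid summer/fall) and day
105 (mid spring), in d(log head width)/day. Natural log is used; a change
of base rescales all coefficients and slopes by a constant and cannot
affect orderings or test conclusions. Fitting is done on centred age
(t − 63) for Vandermonde conditioning and coefficients are mapped back to
the raw axis, which leaves the fitted curve — and hence the slopes —
mathematically unchanged.

Degenerate inputs: with 2–3 distinct ages the degree drops to n − 1 and the
fit is flagged non-interpolating; individuals with fewer than two distinct
ages are excluded and logged. Slopes requested outside the observed age
range are returned with an extrapolation warning. The day-84 size covariate
is taken from the age-84 event when present and recorded as missing
otherwise, never imputed. The hatch-size covariate is the family mean of
ten hatchlings measured in the northern-photoperiod batch, applied to all
larvae of the family in both treatments (hatching occurred before the
treatments could plausibly diverge).

## Inferential models

Seasonal growth rates are analysed with a linear mixed model per season:
region (3 levels) and photoperiod treatment (2 levels) crossed as fixed
factors, random intercepts for sub-population and for family nested within
sub-population, REML estimation by default. Fixed effects are tested with
Type II Wald chi-square statistics: main effects in the additive model,
the interaction in the full model (Type III with the full model is
available as an option). Degrees of freedom are the number of contrasts
per term; no denominator-df correction is attempted since there is no
agreed way to count denominator df in mixed models. Random-effect
variances are reported, never significance-tested — the design has too few
sub-populations for that to be meaningful.

The season's covariate (hatch size in summer/fall, day-84 size in spring)
is screened inside the full model at α = 0.05 and retained only when
significant, with the decision logged. Screening within the full model
rather than a covariate-only model is a choice; on these designs the two
differ negligibly because the covariate is nearly orthogonal to the
treatment factors.

Adult field size uses region and sex as fixed factors with a random
population intercept, and additionally reports the overall male − female
head-width contrast with its standard error from the additive model.
Hatchling size uses a classical one-way ANOVA across regions on individual
hatchlings. Hatch-size/growth regressions are OLS of a seasonal rate on
family-mean hatch size, restricted to the northern-photoperiod group
(hatch sizes exist only there); the default unit is the individual larva
with a family-mean aggregation mode available.

### Numerical choices

The mixed-model likelihood is optimised on a unit-variance-standardised
response: daily log-growth rates are of magnitude 0.01 and the profiled
REML surface is then flat enough that gradient optimisers stop early or at
boundary pathologies. Wald statistics are invariant to this scaling;
estimates and variance components are rescaled on output. Each fit is
attempted with L-BFGS, Powell and Nelder–Mead, and the converged optimum
with the highest restricted likelihood wins; fits reporting convergence
with absurd standard errors (a boundary artefact) are discarded. If no
optimizer yields an acceptable fit the nested (family) component is
dropped, and failing that the model falls back to OLS — which is exactly
the correct model in the zero-variance limit. Every fallback is logged.
Degenerate test statistics (zero within-group variance) are capped at
1e12 with the appropriate limiting p-value.

## Synthetic data generator

The generator emulates the full design: central region (62 degN, 3
sub-populations with 6/4/4 families), northern (65.5 degN, 4
sub-populations with 5/3/3/3 families), northernmost (66.5 degN, 1
sub-population with 5 families); each family is an egg-clutch split in
half across the two photoperiod treatments; 5 replicate larvae per family
per treatment, i.e. exactly 165 larvae per treatment.

Growth is stepwise, as in real insects: head width multiplies by a molt
increment ratio r (default 1.25, a typical odonate head-width step; a
free parameter, not asserted as the species' value) at each molt, and
molts arrive as a Poisson process with intensity rate/log r, so the
expected log-size slope equals the target rate. No molts occur during the
14-day winter (default start at age 63, the midpoint of the observed
54–75-day range at winter onset). Observed widths carry multiplicative
lognormal measurement error (SD 0.015 on the log scale, ~1.5%, plausible
for image-based measurement). Exponential intermolt times overdisperse
growth relative to real, more regular molt cycles; the generator is a
stochastic stand-in with the right mean structure, not a physiological
model.

Per-individual expected rates follow a hierarchical linear model per
season: cell mean(region × photoperiod) + sub-population + family +
individual deviations (SDs 0.0008 / 0.0012 / 0.002 per day; placeholders —
the real variance magnitudes are unknown — and configurable). Family
effects are shared across treatments (clutch halves). Default cell means
(per-day log units, chosen once to express the qualitative latitudinal
pattern at biologically plausible magnitudes: roughly 1.8 log-units of
growth over the experiment): summer/fall decreasing with source latitude,
northern photoperiod faster with the largest plastic gap in the central
region; spring with a crossing interaction (central faster under the
southern photoperiod, the two high-latitude regions faster under the
northern). Magnitudes are free parameters since no rate values are
published.

Because the expected log trajectory is piecewise linear with a kink at the
winter start, the estimand of the trajectory stage is the anchor-day slope
of the cubic through the expected log widths — a fixed linear functional
of the two phase rates (equal to the phase rate itself when the two rates
coincide). Recovery tests score against this functional
(`expected_cell_slopes`), not against the raw phase rates.

Hatchling head widths increase with latitude (family means 0.44 / 0.47 /
0.50 mm + family effects, SD 0.015 mm; 10 hatchlings per family at
individual SD 0.02 mm) — sizes in the range reported for coenagrionid
hatchlings. Field adults default to equal region means (3.60 mm), a
+0.06 mm male offset, per-population deviations (SD 0.02 mm), residual SD
0.21 mm (calibrated so the sex-contrast SE is ~0.03 mm at the collection's
sample sizes), and per-site counts matching the field collection,
including a second northernmost site sampled for adults only.

Reproducibility: one root seed; design effects, larvae, hatchlings and
adults use deterministically derived substreams, so identical seeds give
bit-identical tables.

## Calibration and recovery studies

`pipeline.calibration_study` measures type-I error of the fixed-effect
tests under a null configuration (all cell means equalised, variance
components retained). Two deliberate choices:

* The calibration design uses 20 sub-populations per region with 2
  families × 1 replicate. The Wald tests are asymptotic in the number of
  groups; with the field design's 8 sub-populations no asymptotic test of
  a between-group factor can calibrate (at 30 groups the region test still
  rejects at ~0.08), so calibration is run in a regime of ~60 groups where
  the asymptotics hold, while keeping the total larva count small.
  Replicates draw growth-rate records directly from the hierarchical
  model (the molt and measurement layers are irrelevant to the null
  distribution of the fixed-effect tests and would triple the cost).
* The hatchling one-way ANOVA is calibrated under its own null
  (hatchlings i.i.d. within regions, family SD 0). With family clustering
  retained the F test is anticonservative by construction — a caveat that
  applies equally to the original analysis strategy, which also ignored
  family structure in this test.

Parameter recovery runs the full generator → trajectory → models loop at
the study's size and checks that the qualitative pattern (summer/fall
region ordering, overall photoperiod advantage, spring crossing
interaction) and the per-cell expected slopes (2-SE coverage) are
recovered.

## What a green test does and does not establish

The generator emulates the design's statistical skeleton: hierarchical
structure, stepwise growth, the winter pause, measurement error. It does
not emulate temperature dependence, mortality (beyond optional uniform
dropout), size-dependent molt increments, diapause induction mechanisms,
or the size-mediated correlation between the two seasonal rates noted as
unaccountable in the original design. Green recovery tests therefore
establish that the pipeline correctly estimates what the generator
encodes — not that the biological effect sizes are as simulated, and not
that the published test statistics are reproducible (the raw data were
never deposited; reproducing printed chi-square/F/r² values is explicitly
out of scope).

## Known limitations

* The spring "region d.f. = 3" printed in the source results conflicts
  with a 3-level factor (k − 1 = 2); the package always uses k − 1 and
  surfaces df in every report.
* Wald chi-square tests at the field design's group counts are
  anticonservative for between-group factors; conclusions about the
  region main effect at n = 8 sub-populations lean on the fixed-effect
  asymptotics more than one would like. No Satterthwaite/Kenward–Roger
  correction is offered.
* The one-way hatchling ANOVA ignores family clustering (see above).
* The molt-process Poisson assumption overdisperses trajectories; fitted
  slope SEs from synthetic data are conservative relative to a
  regular-molt-cycle world.
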