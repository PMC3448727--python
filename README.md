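# larvaclock

Photoperiod-treatment schedules and latitudinal growth-pattern analysis for
common-garden experiments on aquatic insect larvae.

Temperate insects use day length as their seasonal clock. In a common-garden
design, larvae from populations along a latitudinal gradient are reared in
climate chambers that replay the photoperiod of a southern (52°N) or a
northern (64°N) latitude — including half of each civil twilight, which is
what a larva plausibly perceives as light — through a compressed season:
summer and fall with weekly day-length updates, a two-week dark winter at
5 °C, and a spring restart that jumps the chamber forward to April day
lengths. Comparing growth rates across regions and photoperiods reveals
whether time-constrained populations have evolved compensatory growth and
how they read the photoperiodic cue. `larvaclock` provides every
quantitative stage of that design for biologists running or simulating such
experiments:

* **photoperiod** — day length at any latitude/date from standard solar
  geometry (declination + hour-angle inversion), with the civil-twilight
  chamber rule, h.mm notation (`17.15` = 17 h 15 min), and the full
  treatment schedule including the winter blackout and spring date-jump;
* **trajectory** — the per-individual growth statistic: a cubic polynomial
  on log head width over winter-excluded age,
  `L(t) = b₀ + b₁t + b₂t² + b₃t³`, fitted to the four measurement events
  (days 0, 42, 84, 126), with seasonal growth rates read off as the
  analytic slopes `dL/dt = b₁ + 2b₂t + 3b₃t²` at day 21 (mid summer/fall)
  and day 105 (mid spring);
* **growth_stats** — mixed-effects ANOVAs (region × photoperiod fixed,
  sub-population and family-in-sub-population random, REML) with Type II
  Wald χ² tests, covariate screening, adult-size and hatchling-size
  analyses, and hatch-size/growth regressions;
* **synthetic_data** — a molt-based generator: head width multiplies by a
  fixed increment ratio at each molt, molts arrive as a rate-matched
  Poisson process (zero in winter), and expected rates follow a
  hierarchical region × photoperiod model — emulating the full design
  (3 regions, 8 sub-populations, 33 families split across both treatments,
  165 larvae per treatment) so every stage is testable without the
  unpublished field data;
* **pipeline** — simulate/load → trajectories → models → report, with a
  CLI (`larvaclock`), full validation and seed-reproducible outputs.

## Worked example

```sh
larvaclock photoperiod --lat 64 --date 2010-07-10 --hmm
# L:D 22.05:01.55 (all_night_twilight)
```

At 64°N on 10 July the sun sets but never drops below civil twilight, so
the whole night counts as twilight and half of it as light: a 22 h 05 min
light phase. The same engine writes complete chamber schedules
(`larvaclock schedule --treatment north --out schedule.csv`).

A full synthetic run:

```sh
larvaclock run --seed 3 --out-dir demo_run
```

prints (abridged):

```
summer_fall_growth (n=330, mixed):
  C(region)                    Wald chi2 =    34.33  df = 2  p = 3.502e-08
  C(photoperiod)               Wald chi2 =    25.15  df = 1  p = 5.305e-07
  C(region):C(photoperiod)     Wald chi2 =     4.80  df = 2  p = 0.09079

spring_growth (n=330, mixed):
  C(region)                    Wald chi2 =     9.22  df = 2  p = 0.009942
  C(photoperiod)               Wald chi2 =     0.56  df = 1  p = 0.4558
  C(region):C(photoperiod)     Wald chi2 =    18.33  df = 2  p = 0.0001044

hatchling one-way ANOVA: F_2,327 = 121.23, p = 4.078e-40
hatch_vs_summer_fall: slope = -0.09503, r^2 = 0.090, p = 8.851e-05, n = 165
```

Reading this: in summer/fall, growth rate (d log head width per day)
differs strongly between regions — under the generator's defaults the
low-latitude (central) populations grow fastest, the classic signature of
compensatory growth under time constraint — and the northern photoperiod
accelerates growth overall. In spring the main effects vanish but the
region × photoperiod interaction is strong: central larvae reverse their
photoperiod response. Hatchlings get bigger with latitude, and bigger
hatchlings grow more slowly in summer/fall (negative regression slope).
The output directory holds every stage as CSV (`growth_rates.csv`,
`model_report.csv`, `variance_components.csv`, `cell_means.csv`), a
machine-readable `report.json`, the simulation `truth.csv`, and a run log
of every screening decision and exclusion.

See `docs/methods.md` for the models, their assumptions, the generator's
default effect sizes and what the simulation does and does not emulate.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the light-phase duration (in h.mm notation) of
the six chamber anchor settings — both treatment latitudes on 10 July 2010,
8 October 2010 and 9 April 2011 — via the solar engine, and exercises the
full simulate → trajectory → models pipeline under the given seed. Results
are written as JSON to `--out`.
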