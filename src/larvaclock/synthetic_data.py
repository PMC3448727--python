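"""Synthetic common-garden datasets with molt-based stepwise growth.

Emulates the full experimental design so the whole pipeline is testable
without the original (undeposited) measurements: three latitudinal regions
(central 62degN: 3 sub-populations / 14 families; northern 65.5degN: 4
sub-populations / 14 families; northernmost 66.5degN: 1 sub-population / 5
families), egg clutches split between two photoperiod treatments, five
larval replicates per family per treatment (165 larvae per treatment), four
photographed measurement events 42 winter-excluded days apart, and a 14-day
winter during which no molting occurs.

Larval growth is stepwise, as in real insects: head width multiplies by a
fixed molt increment ratio ``r`` at each molt, and molts arrive as a Poisson
process whose intensity is rate-matched so that the expected log-size slope
equals the individual's target growth rate (intensity = rate / log r).
Expected per-individual rates follow a hierarchical linear model: a
region x photoperiod cell mean per season plus sub-population, family and
individual deviations, with family effects shared across the two treatments
(clutch halves).  Hatchling size increases with latitude; field adults have
equal region means by default, a male-female head-width offset, and
per-site sample sizes matching the field collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RegionDesign",
    "AdultDesign",
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_individual",
    "simulate_experiment",
    "simulate_hatchlings",
    "simulate_adults",
    "simulate_rate_records",
    "expected_cell_slopes",
]

REGIONS = ("central", "northern", "northernmost")
TREATMENTS = ("southern", "northern")
SEASONS = ("summer_fall", "spring")


@dataclass(frozen=True)
class RegionDesign:
    """One latitudinal region: its sub-population structure and hatch size."""

    name: str
    latitude: float
    families_per_subpop: tuple[int, ...]
    hatch_mean_mm: float

    @property
    def n_families(self) -> int:
        return sum(self.families_per_subpop)


@dataclass(frozen=True)
class AdultDesign:
    """Field adult collection: region means and per-site (males, females) counts."""

    region_mean_mm: Mapping[str, float]
    site_counts: Mapping[str, tuple[tuple[int, int], ...]]
    sex_offset_mm: float = 0.06  # male minus female head width
    population_sd_mm: float = 0.02
    residual_sd_mm: float = 0.21


def _default_regions() -> tuple[RegionDesign, ...]:
    return (
        RegionDesign("central", 62.0, (6, 4, 4), hatch_mean_mm=0.44),
        RegionDesign("northern", 65.5, (5, 3, 3, 3), hatch_mean_mm=0.47),
        RegionDesign("northernmost", 66.5, (5,), hatch_mean_mm=0.50),
    )


def _default_rates() -> dict[tuple[str, str], tuple[float, float]]:
    # (region, photoperiod) -> (summer_fall, spring) mean log-growth rates
    # per day.  Chosen to reproduce the qualitative latitudinal pattern:
    # summer/fall decreases with source latitude, the northern photoperiod
    # accelerates growth with the largest plastic gap in the central region;
    # in spring the central region reverses its photoperiod response while
    # the two high-latitude regions keep growing faster under the northern
    # photoperiod (a crossing interaction).
    return {
        ("central", "southern"): (0.016, 0.018),
        ("central", "northern"): (0.022, 0.012),
        ("northern", "southern"): (0.013, 0.011),
        ("northern", "northern"): (0.016, 0.014),
        ("northernmost", "southern"): (0.011, 0.011),
        ("northernmost", "northern"): (0.012, 0.014),
    }


def _default_adults() -> AdultDesign:
    return AdultDesign(
        region_mean_mm={r: 3.60 for r in REGIONS},
        site_counts={
            "central": ((20, 20), (20, 20), (20, 20)),
            "northern": ((15, 6), (17, 9), (20, 17), (20, 19)),
            # The second northernmost site was sampled for adults only.
            "northernmost": ((17, 7), (13, 7)),
        },
    )


@dataclass(frozen=True)
class SimulationConfig:
    """All design counts, effect sizes and variance components of the generator."""

    regions: tuple[RegionDesign, ...] = field(default_factory=_default_regions)
    treatments: tuple[str, ...] = TREATMENTS
    replicates_per_family_per_treatment: int = 5
    measurement_ages: tuple[float, ...] = (0.0, 42.0, 84.0, 126.0)
    winter_start_age: float = 63.0
    winter_days: float = 14.0
    mean_rates: Mapping[tuple[str, str], tuple[float, float]] = field(
        default_factory=_default_rates
    )
    # SDs of the hierarchical deviations added to each season's rate.
    sd_population_rate: float = 0.0008
    sd_family_rate: float = 0.0012
    sd_residual_rate: float = 0.0020
    # Molt process and measurement model.
    molt_ratio: float = 1.25
    measurement_error_sd_log: float = 0.015
    # Hatchling model.
    hatchlings_per_family: int = 10
    hatch_family_sd_mm: float = 0.015
    hatch_individual_sd_mm: float = 0.02
    # Field adults.
    adults: AdultDesign = field(default_factory=_default_adults)
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if self.molt_ratio <= 1.0:
            raise ValueError("molt_ratio must exceed 1")
        for name in ("sd_population_rate", "sd_family_rate", "sd_residual_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.replicates_per_family_per_treatment < 1:
            raise ValueError("need >= 1 replicate per family per treatment")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def larvae_per_treatment(self) -> int:
        return self.replicates_per_family_per_treatment * sum(
            r.n_families for r in self.regions
        )

    def region(self, name: str) -> RegionDesign:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated tables plus the latent truth needed to score recovery."""

    larvae: pd.DataFrame  # trajectory input schema, one row per event
    hatchlings: pd.DataFrame  # family, region, head_width_mm
    adults: pd.DataFrame  # region, population, sex, head_width_mm
    truth: pd.DataFrame  # per-individual latent rates and expected slopes


def _measurement_calendar_times(config: SimulationConfig) -> np.ndarray:
    """Calendar-day offsets of the events (winter re-inserted after its start)."""
    ages = np.asarray(config.measurement_ages, dtype=float)
    return np.where(ages > config.winter_start_age, ages + config.winter_days, ages)


def simulate_individual(
    expected_rate_fall: float,
    expected_rate_spring: float,
    hatch_width: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Observed head widths of one larva at the four measurement events.

    The true trajectory is a step function: width multiplies by the molt
    ratio at each molt, molts arrive as a Poisson process with intensity
    rate / log(molt_ratio) during the active phases (so the expected log-size
    slope equals the phase rate) and zero intensity during winter.  Observed
    widths carry multiplicative lognormal measurement error.  Non-positive
    rates yield a molt-free phase.
    """
    if hatch_width <= 0:
        raise ValueError("hatch_width must be positive")
    log_r = np.log(config.molt_ratio)
    w_start = config.winter_start_age
    w_end = w_start + config.winter_days
    times = _measurement_calendar_times(config)
    end = float(times[-1])

    def intensity_integral(t0: float, t1: float) -> float:
        """Expected molt count between calendar days t0 < t1."""
        lam_fall = max(expected_rate_fall, 0.0) / log_r
        lam_spring = max(expected_rate_spring, 0.0) / log_r
        fall = max(0.0, min(t1, w_start) - t0)
        spring = max(0.0, t1 - max(t0, w_end))
        return lam_fall * fall + lam_spring * spring

    widths = np.empty(len(times))
    n_molts = 0
    prev = 0.0
    for i, t in enumerate(times):
        n_molts += rng.poisson(intensity_integral(prev, min(t, end)))
        prev = t
        true_width = hatch_width * config.molt_ratio**n_molts
        err = rng.normal(0.0, config.measurement_error_sd_log)
        widths[i] = true_width * np.exp(err)
    return widths


def _expected_fitted_slopes(
    config: SimulationConfig, rate_fall: float, rate_spring: float
) -> tuple[float, float]:
    """Slopes at days 21/105 of the cubic through the expected log widths.

    The expected log trajectory is piecewise linear with a kink where the
    phase rate changes, so the interpolating cubic's anchor-day slopes are a
    fixed linear functional of the two phase rates.  This is the quantity the
    trajectory stage estimates, and therefore the recovery target.
    """
    ages = np.asarray(config.measurement_ages, dtype=float)
    kink = config.winter_start_age
    log_w = np.where(
        ages <= kink,
        rate_fall * ages,
        rate_fall * kink + rate_spring * (ages - kink),
    )
    coef = np.polynomial.polynomial.polyfit(ages, log_w, deg=3)
    deriv = np.polynomial.polynomial.polyder(coef)
    return (
        float(np.polynomial.polynomial.polyval(21.0, deriv)),
        float(np.polynomial.polynomial.polyval(105.0, deriv)),
    )


def expected_cell_slopes(config: SimulationConfig) -> pd.DataFrame:
    """Expected fitted summer/fall and spring slopes per region x treatment cell."""
    rows = []
    for (region, treatment), (rf, rs) in config.mean_rates.items():
        s21, s105 = _expected_fitted_slopes(config, rf, rs)
        rows.append(
            {
                "region": region,
                "photoperiod": treatment,
                "summer_fall_rate": s21,
                "spring_rate": s105,
            }
        )
    return pd.DataFrame(rows)


def _design_effects(config: SimulationConfig, rng: np.random.Generator):
    """Draw sub-population and family deviations (per season, shared across treatments)."""
    pop_eff: dict[str, np.ndarray] = {}
    fam_eff: dict[str, np.ndarray] = {}
    fam_pop: dict[str, str] = {}
    fam_region: dict[str, str] = {}
    fam_hatch: dict[str, float] = {}
    for region in config.regions:
        for p_idx, n_fam in enumerate(region.families_per_subpop, start=1):
            pop = f"{region.name}-p{p_idx}"
            pop_eff[pop] = rng.normal(0.0, config.sd_population_rate, size=2)
            for f_idx in range(1, n_fam + 1):
                fam = f"{pop}-f{f_idx}"
                fam_eff[fam] = rng.normal(0.0, config.sd_family_rate, size=2)
                fam_pop[fam] = pop
                fam_region[fam] = region.name
                fam_hatch[fam] = region.hatch_mean_mm + rng.normal(
                    0.0, config.hatch_family_sd_mm
                )
    return pop_eff, fam_eff, fam_pop, fam_region, fam_hatch


def simulate_experiment(
    config: SimulationConfig | None = None,
    seed: int | np.random.SeedSequence | None = 0,
) -> SyntheticDataset:
    """Generate the full synthetic dataset (larvae, hatchlings, adults, truth).

    Families are egg-clutch halves: each family contributes replicates to
    both photoperiod treatments and its latent effects are shared between
    them.  Under the default design each treatment holds exactly
    14 + 14 + 5 families x 5 replicates = 165 larvae.
    """
    config = config or SimulationConfig()
    root = np.random.default_rng(seed)
    rng_design = np.random.default_rng(root.integers(2**63))
    rng_larvae = np.random.default_rng(root.integers(2**63))
    rng_hatch = np.random.default_rng(root.integers(2**63))
    rng_adults = np.random.default_rng(root.integers(2**63))

    pop_eff, fam_eff, fam_pop, fam_region, fam_hatch = _design_effects(config, rng_design)
    hatchlings = _hatchling_table(config, fam_region, fam_hatch, rng_hatch)
    hatch_family_mean = hatchlings.groupby("family")["head_width_mm"].mean()

    larva_rows: list[dict] = []
    truth_rows: list[dict] = []
    ages = np.asarray(config.measurement_ages, dtype=float)
    for fam in fam_eff:
        region = fam_region[fam]
        pop = fam_pop[fam]
        for treatment in config.treatments:
            mu_fall, mu_spring = config.mean_rates[(region, treatment)]
            for rep in range(1, config.replicates_per_family_per_treatment + 1):
                if config.dropout and rng_larvae.random() < config.dropout:
                    continue
                resid = rng_larvae.normal(0.0, config.sd_residual_rate, size=2)
                rate_fall = mu_fall + pop_eff[pop][0] + fam_eff[fam][0] + resid[0]
                rate_spring = mu_spring + pop_eff[pop][1] + fam_eff[fam][1] + resid[1]
                hatch_true = fam_hatch[fam] * np.exp(
                    rng_larvae.normal(0.0, config.hatch_individual_sd_mm / fam_hatch[fam])
                )
                widths = simulate_individual(
                    rate_fall, rate_spring, hatch_true, config, rng_larvae
                )
                ind = f"{fam}-{treatment[0]}{rep}"
                for ev, (age, w) in enumerate(zip(ages, widths), start=1):
                    larva_rows.append(
                        {
                            "individual_id": ind,
                            "family": fam,
                            "sub_population": pop,
                            "region": region,
                            "photoperiod": treatment,
                            "event_index": ev,
                            "age_days": age,
                            "head_width_mm": w,
                        }
                    )
                exp_s21, exp_s105 = _expected_fitted_slopes(config, rate_fall, rate_spring)
                truth_rows.append(
                    {
                        "individual_id": ind,
                        "family": fam,
                        "sub_population": pop,
                        "region": region,
                        "photoperiod": treatment,
                        "rate_fall": rate_fall,
                        "rate_spring": rate_spring,
                        "expected_summer_fall_slope": exp_s21,
                        "expected_spring_slope": exp_s105,
                        "hatch_width_true": hatch_true,
                        "hatch_family_mean": float(hatch_family_mean[fam]),
                    }
                )
    adults = simulate_adults(config, rng_adults)
    return SyntheticDataset(
        larvae=pd.DataFrame(larva_rows),
        hatchlings=hatchlings,
        adults=adults,
        truth=pd.DataFrame(truth_rows),
    )


def _hatchling_table(
    config: SimulationConfig,
    fam_region: Mapping[str, str],
    fam_hatch: Mapping[str, float],
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows = []
    for fam, mu in fam_hatch.items():
        widths = mu + rng.normal(0.0, config.hatch_individual_sd_mm,
                                 size=config.hatchlings_per_family)
        for w in widths:
            rows.append(
                {"family": fam, "region": fam_region[fam], "head_width_mm": float(max(w, 1e-3))}
            )
    return pd.DataFrame(rows)


def simulate_hatchlings(
    config: SimulationConfig | None = None,
    seed: int | np.random.SeedSequence | None = 0,
) -> pd.DataFrame:
    """Hatchling head widths: 10 per family, northern-photoperiod batch only."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    _, _, _, fam_region, fam_hatch = _design_effects(config, rng)
    return _hatchling_table(config, fam_region, fam_hatch, rng)


def simulate_adults(
    config: SimulationConfig | None = None,
    rng: np.random.Generator | int | None = 0,
) -> pd.DataFrame:
    """Field-collected adult head widths with the collection's per-site counts."""
    config = config or SimulationConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    a = config.adults
    rows = []
    for region, sites in a.site_counts.items():
        mu_region = a.region_mean_mm[region]
        for s_idx, (n_male, n_female) in enumerate(sites, start=1):
            pop = f"{region}-a{s_idx}"
            pop_dev = rng.normal(0.0, a.population_sd_mm)
            for sex, n in (("male", n_male), ("female", n_female)):
                offset = a.sex_offset_mm / 2.0 if sex == "male" else -a.sex_offset_mm / 2.0
                widths = mu_region + pop_dev + offset + rng.normal(
                    0.0, a.residual_sd_mm, size=n
                )
                for w in widths:
                    rows.append(
                        {
                            "region": region,
                            "population": pop,
                            "sex": sex,
                            "head_width_mm": float(w),
                        }
                    )
    return pd.DataFrame(rows)


def simulate_rate_records(
    config: SimulationConfig | None = None,
    seed: int | np.random.SeedSequence | None = 0,
) -> pd.DataFrame:
    """Draw per-individual growth-rate records directly from the hierarchical model.

    Skips the molt process and trajectory fitting: the response is the
    expected fitted slope (cell mean functional) plus the hierarchical
    deviations.  This is the fast path for calibration studies of the
    inferential models, where molt/measurement noise is irrelevant to the
    null distribution of the fixed-effect tests.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    pop_eff, fam_eff, fam_pop, fam_region, fam_hatch = _design_effects(config, rng)
    rows = []
    for fam in fam_eff:
        region = fam_region[fam]
        pop = fam_pop[fam]
        for treatment in config.treatments:
            mu_fall, mu_spring = config.mean_rates[(region, treatment)]
            for rep in range(1, config.replicates_per_family_per_treatment + 1):
                resid = rng.normal(0.0, config.sd_residual_rate, size=2)
                rows.append(
                    {
                        "individual_id": f"{fam}-{treatment[0]}{rep}",
                        "family": fam,
                        "sub_population": pop,
                        "region": region,
                        "photoperiod": treatment,
                        "summer_fall_rate": mu_fall + pop_eff[pop][0] + fam_eff[fam][0] + resid[0],
                        "spring_rate": mu_spring + pop_eff[pop][1] + fam_eff[fam][1] + resid[1],
                        "hatch_size_mm": fam_hatch[fam],
                        "size_day84_mm": np.nan,
                    }
                )
    return pd.DataFrame(rows)


def calibration_design(
    config: SimulationConfig | None = None,
    subpops_per_region: int = 20,
    families_per_subpop: int = 2,
    replicates: int = 1,
) -> SimulationConfig:
    """A design for test-calibration studies: many sub-populations, few larvae.

    The fixed-effect Wald tests are asymptotic in the number of groups, so
    checking their type-I error requires far more sub-populations than the
    real collection has (with few groups a Wald test of a between-group
    factor is anticonservative no matter how it is implemented); total larva
    count is kept small by shrinking families and replicates instead.
    """
    config = config or SimulationConfig()
    regions = tuple(
        replace(r, families_per_subpop=(families_per_subpop,) * subpops_per_region)
        for r in config.regions
    )
    return replace(
        config, regions=regions, replicates_per_family_per_treatment=replicates
    )


def null_config(config: SimulationConfig | None = None) -> SimulationConfig:
    """Copy of a config with all region/photoperiod effects removed.

    Cell means are set to the grand mean of each season, so region,
    photoperiod and interaction fixed effects are all exactly zero; variance
    components are retained.  Hatchling region means are equalised too.
    """
    config = config or SimulationConfig()
    grand_fall = float(np.mean([v[0] for v in config.mean_rates.values()]))
    grand_spring = float(np.mean([v[1] for v in config.mean_rates.values()]))
    rates = {k: (grand_fall, grand_spring) for k in config.mean_rates}
    mean_hatch = float(np.mean([r.hatch_mean_mm for r in config.regions]))
    regions = tuple(replace(r, hatch_mean_mm=mean_hatch) for r in config.regions)
    adults = replace(
        config.adults,
        region_mean_mm={k: float(np.mean(list(config.adults.region_mean_mm.values())))
                        for k in config.adults.region_mean_mm},
    )
    return replace(config, mean_rates=rates, regions=regions, adults=adults)
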