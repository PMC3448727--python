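"""Inferential models for the latitudinal growth experiment.

Four analyses, mirroring a classical common-garden workflow:

* seasonal growth rates: mixed-effects ANOVA with region of origin and
  photoperiod treatment as crossed fixed factors, random intercepts for
  sub-population and for family nested within sub-population, and an
  optional screened covariate (hatch size for summer/fall, day-84 size for
  spring);
* adult field size: mixed-effects ANOVA with region and sex fixed,
  population random;
* hatchling size: classical one-way ANOVA across regions;
* hatch-size/growth regressions: ordinary least squares of a seasonal rate
  on family-mean hatchling size, within the northern-photoperiod group only
  (hatchlings were measured in that treatment).

Fixed effects are tested with Type II Wald chi-square statistics: each main
effect is tested in the model containing all terms that do not include it
(i.e. the additive model), and the interaction is tested last in the full
model.  This matches the marginality-respecting behaviour of the standard
Wald-ANOVA approach for mixed models.  Degrees of freedom are the number of
estimated contrasts per term (k-1 for a k-level factor, the product for an
interaction); no small-sample df correction is applied, because there is no
agreed way to count denominator df in mixed models and the tests are
asymptotic by construction.  Random-effect variances are reported but never
significance-tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "ModelSpec",
    "TermTest",
    "ModelFit",
    "RegressionFit",
    "fit_seasonal_model",
    "cell_estimates",
    "screen_covariate",
    "hatchling_anova",
    "adult_size_model",
    "hatch_growth_regression",
]

#: Cap applied to p-values reported for degenerate (zero-variance) fits.
_CHISQ_CAP = 1e12


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one mixed-effects ANOVA."""

    response: str
    fixed: tuple[str, str] = ("region", "photoperiod")
    interaction: bool = True
    group: str = "sub_population"
    nested: str | None = "family"
    covariate: str | None = None
    screening_alpha: float = 0.05
    reml: bool = True
    wald_type: Literal["II", "III"] = "II"


@dataclass(frozen=True)
class TermTest:
    term: str
    chisq: float
    df: int
    p: float


@dataclass(frozen=True)
class ModelFit:
    """Wald chi-square table plus variance components for one fitted model."""

    response: str
    terms: tuple[TermTest, ...]
    fixed_effects: pd.DataFrame  # index term-coded coefficient, cols estimate/se
    variance_components: dict[str, float]
    n: int
    converged: bool
    method: str  # "mixed", "mixed_no_nested" or "ols" (fallback chain)
    log: tuple[str, ...] = ()
    fixed_cov: pd.DataFrame | None = None  # covariance of the fixed effects

    def term(self, name: str) -> TermTest:
        for t in self.terms:
            if t.term == name:
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(t.term, t.chisq, t.df, t.p) for t in self.terms],
            columns=["term", "chisq", "df", "p"],
        )


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p: float
    n: int

    @property
    def sign(self) -> int:
        return int(np.sign(self.slope))


def _fixed_formula(spec: ModelSpec, interaction: bool) -> str:
    a, b = spec.fixed
    op = "*" if interaction else "+"
    rhs = f"C({a}) {op} C({b})"
    if spec.covariate is not None:
        rhs += f" + {spec.covariate}"
    return f"{spec.response} ~ {rhs}"


def _fit_one(formula: str, data: pd.DataFrame, spec: ModelSpec):
    """Fit one model, falling back through simpler random structures.

    Returns (result, method, scale, log).  The response is standardised to
    unit variance before fitting (the mixed-model optimiser is unreliable on
    responses of magnitude ~0.01, like daily log-growth rates); Wald
    chi-square statistics are invariant to this, and reported estimates and
    variance components are rescaled back by the caller via ``scale``.
    Singular or unconverged mixed fits drop the nested variance component,
    then fall back to OLS.
    """
    scale = float(data[spec.response].std(ddof=1))
    if not np.isfinite(scale) or scale <= 0:
        scale = 1.0
    data = data.copy()
    data[spec.response] = data[spec.response] / scale
    log: list[str] = []
    attempts: list[tuple[str, str | None]] = [("mixed", spec.nested)]
    if spec.nested is not None:
        attempts.append(("mixed_no_nested", None))
    attempts.append(("ols", None))
    for method, nested in attempts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if method == "ols":
                    res = smf.ols(formula, data=data).fit()
                    return res, method, scale, log
                res = _best_mixed_fit(formula, data, spec, nested)
            if res is not None:
                return res, method, scale, log
            log.append(f"{method}: singular/unconverged, dropping a variance component")
        except (np.linalg.LinAlgError, ValueError) as exc:
            log.append(f"{method}: {exc!r}, dropping a variance component")
    raise RuntimeError("unreachable: OLS fallback cannot be skipped")


def _best_mixed_fit(formula: str, data: pd.DataFrame, spec: ModelSpec, nested: str | None):
    """Fit a mixed model with several optimizers; keep the best sane optimum.

    The profiled REML surface is flat enough that gradient methods can stop
    early at materially different variance-component values, so each
    candidate optimizer is run and the converged fit with the highest
    (restricted) likelihood wins.  Boundary pathologies that report
    convergence with absurd standard errors are discarded (on the
    unit-variance response no fixed-effect SE should approach 50).  Returns
    None when no optimizer produces an acceptable fit.
    """
    if nested is not None:
        # Code the nested factor within groups (labels reused across groups):
        # the variance-component design is built per group, so this is the
        # same model with far fewer columns than globally unique labels.
        data = data.copy()
        data["_nested_code"] = (
            data.groupby(spec.group, sort=False)[nested]
            .transform(lambda s: pd.factorize(s)[0])
            .astype(str)
        )
        vc = {nested: "0 + C(_nested_code)"}
    else:
        vc = None
    def _one(optimizer):
        model = MixedLM.from_formula(
            formula, data=data, groups=data[spec.group], re_formula="1",
            vc_formula=vc,
        )
        try:
            res = model.fit(reml=spec.reml, method=optimizer, maxiter=3000)
        except (np.linalg.LinAlgError, ValueError):
            return None
        bse = np.asarray(res.bse_fe)
        if bool(res.converged) and np.isfinite(bse).all() and bse.max() < 50.0:
            return res
        return None

    # Nelder-Mead first: on the low-dimensional profiled REML surface the
    # simplex is slower per fit than L-BFGS but far more reliable about
    # where it stops (gradient methods here can report convergence at
    # materially different points under 1-ulp input perturbations).
    best = _one("nm")
    if best is not None:
        return best
    # Fallback sweep: keep the sane fit with the highest restricted likelihood.
    for optimizer in ("lbfgs", "powell"):
        res = _one(optimizer)
        if res is not None and (best is None or res.llf > best.llf):
            best = res
    return best


def _term_slice(result, term_name: str) -> slice:
    design_info = result.model.data.design_info
    return design_info.term_name_slices[term_name]


def _wald_chisq(result, term_name: str) -> TermTest:
    """Wald chi-square for all coefficients of one design term."""
    sl = _term_slice(result, term_name)
    beta = np.asarray(result.params)[sl]
    k_fe = len(result.model.data.design_info.column_names)
    cov = np.asarray(result.cov_params())[:k_fe, :k_fe][sl, sl]
    df = beta.size
    try:
        chisq = float(beta @ np.linalg.solve(cov, beta))
    except np.linalg.LinAlgError:
        chisq = float(_CHISQ_CAP)
    if not np.isfinite(chisq):
        chisq = float(_CHISQ_CAP)
    chisq = min(chisq, _CHISQ_CAP)
    p = float(scipy.stats.chi2.sf(chisq, df))
    return TermTest(term=term_name, chisq=chisq, df=df, p=p)


def _variance_components(result, method: str, spec: ModelSpec) -> dict[str, float]:
    if method == "ols":
        return {
            spec.group: 0.0,
            **({spec.nested: 0.0} if spec.nested else {}),
            "residual": float(result.mse_resid),
        }
    out = {spec.group: float(np.asarray(result.cov_re).ravel()[0])}
    if method == "mixed" and spec.nested is not None:
        out[spec.nested] = float(np.asarray(result.vcomp).ravel()[0])
    elif spec.nested is not None:
        out[spec.nested] = 0.0
    out["residual"] = float(result.scale)
    return out


def _check_levels(data: pd.DataFrame, spec: ModelSpec) -> None:
    if data.empty:
        raise ValueError("no records to fit")
    for f in spec.fixed:
        k = data[f].nunique()
        if k < 2:
            raise ValueError(f"fixed factor {f!r} has {k} level(s); need >= 2")


def fit_seasonal_model(
    records: pd.DataFrame,
    season: Literal["summer_fall", "spring"],
    spec: ModelSpec | None = None,
) -> ModelFit:
    """Mixed-effects ANOVA for one season's growth rates.

    ``records`` is the per-individual growth-rate table (one row per larva
    with ``summer_fall_rate``/``spring_rate``, design labels and covariates).
    The season's default covariate (hatch size in summer/fall, day-84 size in
    spring) is screened first and kept only when significant at
    ``spec.screening_alpha``; the returned fit records the decision in
    ``log``.
    """
    response = {"summer_fall": "summer_fall_rate", "spring": "spring_rate"}[season]
    default_cov = {"summer_fall": "hatch_size_mm", "spring": "size_day84_mm"}[season]
    if spec is None:
        spec = ModelSpec(response=response, covariate=default_cov)
    else:
        spec = replace(spec, response=response)
    log: list[str] = []
    if spec.covariate is not None:
        decision, p_cov = screen_covariate(records, spec, spec.covariate)
        log.append(f"covariate {spec.covariate}: p={p_cov:.4g} -> {decision}")
        if decision == "drop":
            spec = replace(spec, covariate=None)
    data = records.dropna(subset=[c for c in (spec.response, spec.covariate) if c])
    return _fit_anova(data, spec, extra_log=log)


def _fit_anova(data: pd.DataFrame, spec: ModelSpec, extra_log: list[str] | None = None) -> ModelFit:
    """Shared Type II/III Wald ANOVA machinery for the mixed models."""
    _check_levels(data, spec)
    log = list(extra_log or [])
    a, b = spec.fixed
    inter_name = f"C({a}):C({b})"
    full, method, scale, flog = _fit_one(
        _fixed_formula(spec, interaction=spec.interaction), data, spec
    )
    log += flog
    terms: list[TermTest] = []
    if spec.wald_type == "III" or not spec.interaction:
        source_main = full
    else:
        # Type II: main effects judged in the model without the interaction.
        source_main, _, _, flog2 = _fit_one(_fixed_formula(spec, interaction=False), data, spec)
        log += flog2
    for f in spec.fixed:
        terms.append(_wald_chisq(source_main, f"C({f})"))
    if spec.covariate is not None:
        terms.append(_wald_chisq(source_main, spec.covariate))
    if spec.interaction:
        terms.append(_wald_chisq(full, inter_name))
    k_fe = len(full.model.data.design_info.column_names)
    fixed = pd.DataFrame(
        {
            "estimate": np.asarray(full.params)[:k_fe] * scale,
            "se": np.asarray(full.bse)[:k_fe] * scale,
        },
        index=full.model.data.design_info.column_names,
    )
    vcomps = {
        k: v * scale**2 for k, v in _variance_components(full, method, spec).items()
    }
    names = full.model.data.design_info.column_names
    fixed_cov = pd.DataFrame(
        np.asarray(full.cov_params())[:k_fe, :k_fe] * scale**2,
        index=names,
        columns=names,
    )
    return ModelFit(
        response=spec.response,
        terms=tuple(terms),
        fixed_effects=fixed,
        variance_components=vcomps,
        n=int(len(data)),
        converged=True,
        method=method,
        log=tuple(log),
        fixed_cov=fixed_cov,
    )


def cell_estimates(
    fit: ModelFit,
    records: pd.DataFrame,
    factors: tuple[str, str] = ("region", "photoperiod"),
) -> pd.DataFrame:
    """Model-based cell means with standard errors for a two-factor fit.

    Builds the treatment-coded design row of every observed factor-level
    combination and propagates the fixed-effect covariance, so the intervals
    reflect the random structure the model estimated (unlike naive per-cell
    sample SEs, which ignore shared population and family effects).
    Covariates, if retained, enter at zero.
    """
    if fit.fixed_cov is None:
        raise ValueError("fit carries no fixed-effect covariance")
    names = list(fit.fixed_effects.index)
    a, b = factors
    beta = fit.fixed_effects["estimate"].to_numpy()
    cov = fit.fixed_cov.to_numpy()

    def row_for(level_a: str, level_b: str) -> np.ndarray:
        tok_a, tok_b = f"C({a})[T.{level_a}]", f"C({b})[T.{level_b}]"
        x = np.zeros(len(names))
        for i, nm in enumerate(names):
            if nm == "Intercept":
                x[i] = 1.0
            elif ":" in nm:
                parts = set(nm.split(":"))
                x[i] = float(parts == {tok_a, tok_b})
            else:
                x[i] = float(nm in (tok_a, tok_b))
        return x

    rows = []
    for level_a in sorted(records[a].unique()):
        for level_b in sorted(records[b].unique()):
            x = row_for(str(level_a), str(level_b))
            rows.append(
                {
                    a: level_a,
                    b: level_b,
                    "estimate": float(x @ beta),
                    "se": float(np.sqrt(x @ cov @ x)),
                }
            )
    return pd.DataFrame(rows)


def screen_covariate(
    records: pd.DataFrame,
    spec: ModelSpec,
    covariate: str,
) -> tuple[Literal["keep", "drop"], float]:
    """Decide whether a covariate stays in the model (Wald p < alpha).

    Rows with a missing covariate are dropped for the screening fit; an
    all-missing or constant covariate is inestimable and dropped outright.
    """
    if covariate not in records.columns or records[covariate].notna().sum() == 0:
        warnings.warn(f"covariate {covariate!r} absent or all-missing; dropped", stacklevel=2)
        return "drop", float("nan")
    data = records.dropna(subset=[spec.response, covariate])
    if data[covariate].nunique() < 2:
        return "drop", float("nan")
    screen_spec = replace(spec, covariate=covariate)
    res, _, _, _ = _fit_one(
        _fixed_formula(screen_spec, interaction=spec.interaction), data, screen_spec
    )
    p = _wald_chisq(res, covariate).p
    return ("keep" if p < spec.screening_alpha else "drop"), p


def hatchling_anova(hatchlings: pd.DataFrame) -> tuple[float, int, int, float]:
    """One-way ANOVA of hatchling head width across regions.

    ``hatchlings`` needs ``region`` and ``head_width_mm`` columns (individual
    hatchlings from the northern-photoperiod batch).  Regions with a single
    observation are excluded with a warning.  Returns (F, df1, df2, p); a
    zero within-group variance with distinct means reports an infinite F
    capped at 1e12 with p = 0, and fully constant data reports F = 0, p = 1.
    """
    groups = []
    for region, grp in hatchlings.groupby("region"):
        vals = np.asarray(grp["head_width_mm"], dtype=float)
        if vals.size < 2:
            warnings.warn(f"region {region!r} has {vals.size} hatchling(s); excluded", stacklevel=2)
            continue
        groups.append(vals)
    if len(groups) < 2:
        raise ValueError("need >= 2 regions with >= 2 hatchlings each")
    df1 = len(groups) - 1
    df2 = sum(g.size for g in groups) - len(groups)
    grand = np.concatenate(groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ss_between = sum(g.size * (g.mean() - grand.mean()) ** 2 for g in groups)
    if ss_within <= 1e-300:
        if ss_between <= 1e-300:
            return 0.0, df1, df2, 1.0
        return float(_CHISQ_CAP), df1, df2, 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, p = scipy.stats.f_oneway(*groups)
    return float(f_stat), df1, df2, float(p)


def adult_size_model(adults: pd.DataFrame, spec: ModelSpec | None = None) -> ModelFit:
    """Mixed-effects ANOVA of adult head width: region x sex fixed, population random.

    ``adults`` needs ``region``, ``population``, ``sex`` and
    ``head_width_mm``.  The reported fixed-effect table of the additive model
    carries the overall male-female head-width contrast with its standard
    error (``sex_contrast``/``sex_contrast_se`` in the log).
    """
    if spec is None:
        spec = ModelSpec(
            response="head_width_mm",
            fixed=("region", "sex"),
            group="population",
            nested=None,
            covariate=None,
        )
    fit = _fit_anova(adults, spec)
    # Male - female contrast from the additive model (averaged over regions).
    add_spec = replace(spec, interaction=False)
    res, _, scale, _ = _fit_one(_fixed_formula(add_spec, interaction=False), adults, add_spec)
    names = res.model.data.design_info.column_names
    sex_cols = [i for i, nm in enumerate(names) if nm.startswith("C(sex)")]
    if len(sex_cols) == 1:
        i = sex_cols[0]
        contrast = float(np.asarray(res.params)[i]) * scale
        se = float(np.asarray(res.bse)[i]) * scale
        fit = replace(
            fit, log=fit.log + (f"sex_contrast={contrast:.4f}", f"sex_contrast_se={se:.4f}")
        )
    return fit


def hatch_growth_regression(
    records: pd.DataFrame,
    season: Literal["summer_fall", "spring"],
    treatment_filter: str = "northern",
    unit: Literal["individual", "family"] = "individual",
) -> RegressionFit:
    """OLS of a seasonal growth rate on family-mean hatchling head width.

    Restricted to larvae from ``treatment_filter`` (hatch sizes exist only
    for the northern-photoperiod batch).  ``unit='family'`` regresses
    family-mean rates instead of individual larvae.
    """
    response = {"summer_fall": "summer_fall_rate", "spring": "spring_rate"}[season]
    data = records.loc[records["photoperiod"] == treatment_filter].dropna(
        subset=[response, "hatch_size_mm"]
    )
    if unit == "family":
        data = data.groupby("family", as_index=False)[[response, "hatch_size_mm"]].mean()
    if len(data) < 3:
        raise ValueError(f"need >= 3 points for regression, got {len(data)}")
    x = data["hatch_size_mm"].to_numpy(dtype=float)
    y = data[response].to_numpy(dtype=float)
    res = scipy.stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p=float(res.pvalue),
        n=int(len(data)),
    )
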