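"""Community- and species-level driver models.

Community models relate a plot-level borealisation index to biogeographic,
climatic and local covariates with a subsite random intercept (the nested
study-area > subsite > plot sampling design). Two data subsets are fitted
per index: *positive-only* (plots with index > 0; the magnitude of
borealisation where it occurred) and *full-range* (all eligible plots,
zeros and — for BAI — negatives included; the likelihood of borealisation).
Families follow the response structure: beta (logit) for positive-only BCI
after the 0.0001 boundary adjustment; binomial (logit) for full-range BCI
as boreal colonisers out of total colonisers; Gaussian (identity) for BAI;
negative binomial (log) for species-level colonisation/loss counts;
Gaussian for species mean abundance change.

Clear effects are coefficients whose 95% interval excludes zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from borealis.glmm import GLMMData, GLMMResult, fit_ml, fit_mcmc

logger = logging.getLogger(__name__)

FAMILIES = ("beta_logit", "binomial_logit", "gaussian_identity", "negbinom_log")

#: Reference levels for categorical predictors (first level absorbed into
#: the intercept); chosen to make the reported contrasts read naturally.
DEFAULT_REFERENCE_LEVELS = {
    "region": "Eurasia",
    "biome": "Arctic",
    "functional_group": "forb",
}


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one model fit."""

    response: str
    family: str
    fixed_effects: tuple[str, ...]
    subset: str = "not_applicable"  # positive_only | full_range | not_applicable
    random_intercept: str | None = None
    trials: str | None = None  # binomial denominator column
    reference_levels: Mapping[str, str] = field(default_factory=dict)
    log_transform: tuple[str, ...] = ()  # continuous predictors to log

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "binomial_logit" and self.trials is None:
            raise ValueError("binomial family requires a trials column")


@dataclass
class ModelFit:
    """Coefficient table plus diagnostics for one fitted model."""

    spec: ModelSpec
    backend: str
    coefficients: pd.DataFrame  # term, estimate, lower95, upper95, clear_effect
    diagnostics: dict
    n_obs: int
    converged: bool
    result: GLMMResult = field(repr=False, default=None)

    def coefficient_table(self) -> pd.DataFrame:
        return self.coefficients.copy()

    def rate_ratios(self) -> pd.DataFrame:
        """exp(coefficient) with interval, for log/logit-link effect sizes."""
        out = self.coefficients.copy()
        for col in ("estimate", "lower95", "upper95"):
            out[col] = np.exp(out[col])
        return out


def make_subsets(plot_summaries: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Positive-only and full-range observation sets per index.

    ``positive_only_bci`` = plots with BCI > 0 (true colonisation signal,
    not the zero-coloniser convention); ``positive_only_bai`` = plots with
    BAI > 0. Full-range sets keep every eligible plot. The two positive
    sets are defined independently and generally differ in membership.
    """
    positive_bci = plot_summaries[
        (plot_summaries["bci"] > 0) & ~plot_summaries["no_colonisers"]
    ]
    positive_bai = plot_summaries[plot_summaries["bai"] > 0]
    if positive_bai.empty:
        warnings.warn("positive-only BAI subset is empty")
    if positive_bci.empty:
        warnings.warn("positive-only BCI subset is empty")
    return {
        "positive_only_bci": positive_bci.reset_index(drop=True),
        "positive_only_bai": positive_bai.reset_index(drop=True),
        "full_range_bci": plot_summaries.reset_index(drop=True),
        "full_range_bai": plot_summaries.reset_index(drop=True),
    }


def prepare_beta_response(values) -> np.ndarray:
    """Shift positive-only BCI values into the open beta support.

    Subtracts the 0.0001 boundary constant (so 1.0 maps to 0.9999) and
    clamps at 0.0001 from below; inputs must be in (0, 1].
    """
    arr = np.asarray(values, dtype=float)
    if np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("beta response values must lie in (0, 1]")
    out = arr - 0.0001
    clamped = out < 0.0001
    if clamped.any():
        logger.info("%d beta response values clamped at the 0.0001 boundary",
                    int(clamped.sum()))
    return np.clip(out, 0.0001, 0.9999)


def build_design(
    data: pd.DataFrame,
    fixed_effects: Sequence[str],
    reference_levels: Mapping[str, str] | None = None,
    log_transform: Sequence[str] = (),
) -> tuple[np.ndarray, list[str]]:
    """Model matrix with intercept and treatment-coded categoricals."""
    reference_levels = {**DEFAULT_REFERENCE_LEVELS, **(reference_levels or {})}
    cols: list[np.ndarray] = [np.ones(len(data))]
    names = ["intercept"]
    for var in fixed_effects:
        series = data[var]
        if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
            levels = sorted(series.dropna().unique())
            ref = reference_levels.get(var, levels[0])
            if ref not in levels:
                ref = levels[0]
            for lvl in levels:
                if lvl == ref:
                    continue
                cols.append((series == lvl).to_numpy(dtype=float))
                names.append(f"{var}[{lvl}]")
        else:
            x = series.to_numpy(dtype=float)
            if var in log_transform:
                if np.any(x <= 0):
                    raise ValueError(f"cannot log-transform {var!r}: non-positive values")
                x = np.log(x)
                names.append(f"log_{var}")
            else:
                names.append(var)
            cols.append(x)
    return np.column_stack(cols), names


def _fit(data: GLMMData, family, backend, **mcmc_kwargs) -> GLMMResult:
    if backend == "fast":
        return fit_ml(data, family)
    if backend == "mcmc":
        return fit_mcmc(data, family, **mcmc_kwargs)
    raise ValueError(f"unknown backend {backend!r}")


def _to_modelfit(spec: ModelSpec, result: GLMMResult) -> ModelFit:
    table = pd.DataFrame(
        {
            "term": result.columns,
            "estimate": result.estimates,
            "lower95": result.lower95,
            "upper95": result.upper95,
        }
    )
    table["clear_effect"] = result.clear_effect
    return ModelFit(
        spec=spec,
        backend=result.backend,
        coefficients=table,
        diagnostics=result.diagnostics,
        n_obs=result.n_obs,
        converged=result.converged,
        result=result,
    )


def fit_community_model(
    spec: ModelSpec,
    data: pd.DataFrame,
    backend: str = "mcmc",
    **mcmc_kwargs,
) -> ModelFit:
    """Fit one community-level driver model.

    ``data`` holds one row per plot with the response, the covariates and
    the random-intercept grouping column. Rows with missing values in any
    used column are dropped (logged). For the binomial family the response
    is the boreal-coloniser count and ``spec.trials`` the total-coloniser
    count; zero-trial plots are retained and contribute no likelihood. A
    grouping factor with a single level degrades to a fixed-effects fit
    with a warning.
    """
    used = [spec.response, *spec.fixed_effects]
    if spec.trials:
        used.append(spec.trials)
    if spec.random_intercept:
        used.append(spec.random_intercept)
    rows = data.dropna(subset=[c for c in used if c in data.columns])
    if len(rows) < len(data):
        logger.info("dropped %d rows with missing values", len(data) - len(rows))

    X, names = build_design(
        rows, spec.fixed_effects, spec.reference_levels, spec.log_transform
    )
    y = rows[spec.response].to_numpy(dtype=float)
    if spec.family == "beta_logit":
        y = prepare_beta_response(y)

    trials = rows[spec.trials].to_numpy(dtype=float) if spec.trials else None
    groups = None
    if spec.random_intercept:
        codes, uniques = pd.factorize(rows[spec.random_intercept])
        if len(uniques) < 2:
            warnings.warn(
                "random-intercept factor has a single level; "
                "fitting fixed effects only"
            )
        else:
            groups = codes

    bundle = GLMMData(y=y, X=X, columns=names, trials=trials, groups=groups)
    result = _fit(bundle, spec.family, backend, **mcmc_kwargs)
    return _to_modelfit(spec, result)


def fit_species_model(
    spec: ModelSpec,
    species_summaries: pd.DataFrame,
    trait_table: pd.DataFrame | None = None,
    backend: str = "mcmc",
    **mcmc_kwargs,
) -> ModelFit:
    """Fit one species-level model (class or trait model).

    Filters follow the response: ``times_colonised`` / ``times_lost``
    models keep species that colonised at least once; ``mean_abundance_change``
    models keep species with a positive mean change. Trait predictors are
    joined from ``trait_table`` (wide, per-species means); continuous
    traits named in ``spec.log_transform`` enter on the log scale, and the
    multivariate trait model is restricted to species with all included
    traits. Traits with fewer than two distinct values are dropped with a
    warning.
    """
    data = species_summaries.copy()
    if spec.response in ("times_colonised", "times_lost"):
        data = data[data["times_colonised"] >= 1]
    elif spec.response == "mean_abundance_change":
        data = data[data["mean_abundance_change"] > 0]

    if trait_table is not None:
        data = data.merge(trait_table, on="taxon", how="left")

    effects = list(spec.fixed_effects)
    for var in list(effects):
        if var in data.columns and data[var].dropna().nunique() < 2:
            warnings.warn(f"trait {var!r} has < 2 distinct values; dropped")
            effects.remove(var)
    data = data.dropna(subset=[v for v in effects if v in data.columns])

    adjusted = ModelSpec(
        response=spec.response,
        family=spec.family,
        fixed_effects=tuple(effects),
        subset=spec.subset,
        random_intercept=spec.random_intercept,
        trials=spec.trials,
        reference_levels=spec.reference_levels,
        log_transform=spec.log_transform,
    )
    return fit_community_model(adjusted, data, backend=backend, **mcmc_kwargs)


def pairwise_contrasts(fit: ModelFit, factor: str) -> pd.DataFrame:
    """All pairwise level differences of a categorical fixed effect.

    With MCMC draws the contrast interval comes from the joint posterior;
    with the fast backend, from the normal approximation using the Wald
    covariance. The reference level's coefficient is identically zero.
    """
    result = fit.result
    prefix = f"{factor}["
    idx = {
        name[len(prefix):-1]: i
        for i, name in enumerate(result.columns)
        if name.startswith(prefix)
    }
    ref_levels = {**DEFAULT_REFERENCE_LEVELS, **dict(fit.spec.reference_levels)}
    ref = ref_levels.get(factor, "<reference>")
    levels = [ref, *idx]

    rows = []
    z = 1.959963984540054
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            ia = idx.get(a)
            ib = idx.get(b)
            if result.draws is not None:
                da = result.draws[:, ia] if ia is not None else 0.0
                db = result.draws[:, ib] if ib is not None else 0.0
                diff = da - db
                est, lo, hi = (
                    float(np.median(diff)),
                    float(np.percentile(diff, 2.5)),
                    float(np.percentile(diff, 97.5)),
                )
            else:
                ea = result.estimates[ia] if ia is not None else 0.0
                eb = result.estimates[ib] if ib is not None else 0.0
                var = 0.0
                if result.cov is not None:
                    if ia is not None:
                        var += result.cov[ia, ia]
                    if ib is not None:
                        var += result.cov[ib, ib]
                    if ia is not None and ib is not None:
                        var -= 2 * result.cov[ia, ib]
                se = np.sqrt(max(var, 0.0))
                est = float(ea - eb)
                lo, hi = est - z * se, est + z * se
            rows.append(
                {
                    "level_a": a,
                    "level_b": b,
                    "estimate": est,
                    "lower95": lo,
                    "upper95": hi,
                    "clear_effect": bool(lo > 0 or hi < 0),
                }
            )
    return pd.DataFrame(rows)


def filter_traits(records: pd.DataFrame, min_records: int = 5, sd_limit: float = 5.0) -> pd.DataFrame:
    """Species-level trait means after outlier and sample-size filtering.

    ``records`` is long format (taxon, trait, value), already restricted to
    the latitude-eligible observations. Per species × trait, records more
    than ``sd_limit`` SDs from the species-trait mean are removed first;
    combinations with fewer than ``min_records`` surviving records are
    dropped. Returns a wide table of means with one row per species.

    Each record is scored against the mean and SD of the *other* records of
    its species × trait (leave-one-out): a gross outlier inflates any SD it
    is part of enough to mask itself at realistic record counts, so the
    rule is only self-consistent when the candidate is excluded from its
    own reference distribution.
    """
    def keep(group: pd.DataFrame) -> pd.DataFrame:
        v = group["value"].to_numpy(dtype=float)
        n = len(v)
        if n < 3:
            return group
        total, total_sq = v.sum(), (v**2).sum()
        loo_mean = (total - v) / (n - 1)
        loo_var = (total_sq - v**2 - (n - 1) * loo_mean**2) / (n - 2)
        loo_sd = np.sqrt(np.maximum(loo_var, 0.0))
        dev = np.abs(v - loo_mean)
        # zero reference SD: keep only records equal to the rest
        ok = np.where(loo_sd > 0, dev <= sd_limit * loo_sd, dev == 0)
        return group[ok]

    cleaned = (
        records.groupby(["taxon", "trait"], group_keys=False)[records.columns]
        .apply(keep)
    )
    counts = cleaned.groupby(["taxon", "trait"])["value"].agg(["count", "mean"])
    counts = counts[counts["count"] >= min_records]
    wide = counts["mean"].unstack("trait")
    wide.columns.name = None
    return wide.reset_index()


def correlate_methods(values_a, values_b) -> float:
    """Pearson correlation between two index variants (e.g. end−start BAI
    vs OLS-slope BAI); raises on zero variance."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need >= 3 paired values")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(stats.pearsonr(a, b).statistic)
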