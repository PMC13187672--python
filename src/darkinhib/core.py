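"""Dark-inhibition statistic, species-level aggregation, and the QC screens
used to justify keeping a single assay method.

The statistic is ``1 - dark/light`` on total-activity pairs; it is unit-free
(any common activity unit cancels) and multiplied by 100 for percent scale.
Aggregation to species level is an unweighted mean over genotype-level data
points with the sample (n-1) standard deviation.
"""
from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .stats import DegenerateDataError, kruskal_wallis
from .types import (
    ActivityObservation,
    AssayMethod,
    DarkInhibition,
    Dataset,
    SpeciesSummary,
)

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


def dark_inhibition(light_activity: float, dark_activity: float) -> DarkInhibition:
    """Compute the dark-inhibition statistic for one light/dark pair.

    ``ratio = 1 - dark/light``; negative values indicate higher activity in
    the dark (daytime-inhibitor artifacts) and are retained.

    Raises
    ------
    ValueError
        If ``light_activity <= 0`` (the ratio is undefined).
    """
    if not (light_activity > 0):
        raise ValueError(f"light_activity must be > 0, got {light_activity!r}")
    if dark_activity < 0:
        raise ValueError(f"dark_activity must be >= 0, got {dark_activity!r}")
    return DarkInhibition(ratio=1.0 - dark_activity / light_activity)


def observation_percent(obs: ActivityObservation) -> float:
    return dark_inhibition(obs.light_activity, obs.dark_activity).percent


def aggregate_species(
    ds: Dataset, method_filter: Optional[AssayMethod] = None
) -> list[SpeciesSummary]:
    """Aggregate observations to per-species mean/SD of percent inhibition.

    The mean is unweighted over data points (genotypes / growth stages pooled);
    SD is the sample standard deviation and is omitted for n = 1. Species with
    zero retained observations are excluded with a log note.
    """
    by_species: dict[str, list[ActivityObservation]] = defaultdict(list)
    for obs in ds.observations:
        if method_filter is not None and obs.method is not method_filter:
            continue
        by_species[obs.taxonomy.species].append(obs)

    all_species = {o.taxonomy.species for o in ds.observations}
    for name in sorted(all_species - set(by_species)):
        logger.info("species %s has no observations after method filter; excluded", name)

    summaries = []
    for name in sorted(by_species):
        group = by_species[name]
        percents = np.array([observation_percent(o) for o in group])
        sd = float(percents.std(ddof=1)) if percents.size >= 2 else None
        summaries.append(
            SpeciesSummary(
                taxonomy=group[0].taxonomy,
                mean_di_percent=float(percents.mean()),
                sd_di_percent=sd,
                n_datapoints=int(percents.size),
            )
        )
    return summaries


@dataclass
class MethodFilterReport:
    kept: AssayMethod
    removed_per_method: dict[str, int]
    n_kept: int


def filter_by_method(
    ds: Dataset, keep: AssayMethod
) -> tuple[Dataset, MethodFilterReport]:
    """Restrict observations to one assay method, reporting removals."""
    kept = [o for o in ds.observations if o.method is keep]
    removed = Counter(o.method.value for o in ds.observations if o.method is not keep)
    if not kept:
        logger.warning("method %s absent from dataset; no observations remain", keep.value)
    report = MethodFilterReport(
        kept=keep, removed_per_method=dict(removed), n_kept=len(kept)
    )
    return (
        Dataset(observations=kept, summaries=ds.summaries, provenance=ds.provenance),
        report,
    )


@dataclass(frozen=True)
class CovariateScreenResult:
    covariate: str
    test_kind: str  # rank_test | linear_trend | meta_regression
    statistic: Optional[float]
    p_value: Optional[float]
    flagged: bool
    note: str = ""

    @property
    def insufficient(self) -> bool:
        return self.p_value is None


def _insufficient(covariate: str, kind: str, note: str) -> CovariateScreenResult:
    return CovariateScreenResult(
        covariate=covariate, test_kind=kind, statistic=None, p_value=None,
        flagged=False, note=note,
    )


def method_concordance(
    ds: Dataset, species: str, alpha: float = DEFAULT_ALPHA
) -> CovariateScreenResult:
    """Rank-based k-sample comparison of one species' percent values by method.

    Requires at least two methods with at least two observations each;
    otherwise an explicit insufficient-data result is returned.
    """
    groups: dict[str, list[float]] = defaultdict(list)
    for o in ds.observations:
        if o.taxonomy.species == species:
            groups[o.method.value].append(observation_percent(o))
    usable = {k: v for k, v in groups.items() if len(v) >= 2}
    if len(usable) < 2:
        return _insufficient(
            "method", "rank_test",
            f"species {species}: need >=2 methods with >=2 observations each",
        )
    try:
        h, _, p = kruskal_wallis(list(usable.values()))
    except DegenerateDataError:
        return CovariateScreenResult(
            covariate="method", test_kind="rank_test", statistic=0.0,
            p_value=1.0, flagged=False, note="all values identical",
        )
    return CovariateScreenResult(
        covariate="method", test_kind="rank_test", statistic=h, p_value=p,
        flagged=p < alpha,
    )


def _covariate_value(obs: ActivityObservation, name: str):
    if hasattr(obs, name):
        return getattr(obs, name)
    raise KeyError(f"unknown covariate column {name!r}")


def linear_trend_screen(
    ds: Dataset, covariate: str, alpha: float = DEFAULT_ALPHA
) -> CovariateScreenResult:
    """OLS slope of percent inhibition on a numeric covariate with t-test p."""
    import statsmodels.api as sm

    pairs = [
        (float(_covariate_value(o, covariate)), observation_percent(o))
        for o in ds.observations
        if _covariate_value(o, covariate) is not None
    ]
    xs = np.array([p[0] for p in pairs])
    ys = np.array([p[1] for p in pairs])
    if np.unique(xs).size < 3:
        return _insufficient(covariate, "linear_trend", "<3 distinct covariate values")
    model = sm.OLS(ys, sm.add_constant(xs)).fit()
    slope_t = float(model.tvalues[1])
    p = float(model.pvalues[1])
    return CovariateScreenResult(
        covariate=covariate, test_kind="linear_trend", statistic=slope_t,
        p_value=p, flagged=p < alpha,
    )


def rank_screen(
    ds: Dataset, covariate: str, alpha: float = DEFAULT_ALPHA
) -> CovariateScreenResult:
    """Kruskal-Wallis screen of percent inhibition across covariate categories."""
    groups: dict[object, list[float]] = defaultdict(list)
    for o in ds.observations:
        v = _covariate_value(o, covariate)
        if v is not None:
            groups[v].append(observation_percent(o))
    usable = [v for v in groups.values() if v]
    if len(usable) < 2:
        return _insufficient(covariate, "rank_test", "<2 covariate categories")
    try:
        h, _, p = kruskal_wallis(usable)
    except (DegenerateDataError, ValueError) as e:
        return _insufficient(covariate, "rank_test", str(e))
    return CovariateScreenResult(
        covariate=covariate, test_kind="rank_test", statistic=h, p_value=p,
        flagged=p < alpha,
    )


def dl_meta_regression(
    effects: Sequence[float],
    variances: Sequence[float],
    moderator: Sequence[float],
) -> tuple[float, float, float, float]:
    """Random-effects meta-regression with DerSimonian-Laird tau^2.

    Parameters are per-study effects, their within-study variances and a
    single numeric moderator. Returns ``(coef, se, z, tau2)`` for the
    moderator coefficient (Wald test against 0).

    The DL estimator generalised to meta-regression: fit weighted LS with
    fixed-effect weights ``w_i = 1/v_i``, compute the residual heterogeneity
    ``Q_E = sum w_i r_i^2``, and set
    ``tau2 = max(0, (Q_E - (k - p)) / (tr(W) - tr[(X'WX)^{-1} X'W^2 X]))``;
    then refit with weights ``1/(v_i + tau2)``.
    """
    y = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    x = np.asarray(moderator, dtype=float)
    k = y.size
    if k < 3:
        raise ValueError("need >= 3 studies for meta-regression")
    X = np.column_stack([np.ones(k), x])
    p = X.shape[1]

    w = 1.0 / v
    XtW = X.T * w
    xtwx_inv = np.linalg.inv(XtW @ X)
    beta_fe = xtwx_inv @ (XtW @ y)
    resid = y - X @ beta_fe
    q_e = float((w * resid**2).sum())
    trace_w = float(w.sum())
    trace_corr = float(np.trace(xtwx_inv @ (X.T * w**2) @ X))
    denom = trace_w - trace_corr
    tau2 = max(0.0, (q_e - (k - p)) / denom) if denom > 0 else 0.0

    w_re = 1.0 / (v + tau2)
    XtW = X.T * w_re
    cov = np.linalg.inv(XtW @ X)
    beta = cov @ (XtW @ y)
    se = float(np.sqrt(cov[1, 1]))
    coef = float(beta[1])
    return coef, se, coef / se, tau2


def meta_regression_screen(
    ds: Dataset, covariate: str, alpha: float = DEFAULT_ALPHA
) -> CovariateScreenResult:
    """DL meta-regression of per-source mean percent on a numeric covariate.

    Unit of analysis is the literature source: within-source variance is the
    squared standard error of that source's mean (pooled-variance fallback for
    single-observation sources).
    """
    from scipy import stats as sps

    by_source: dict[str, list[ActivityObservation]] = defaultdict(list)
    for o in ds.observations:
        if _covariate_value(o, covariate) is not None:
            by_source[o.source_id].append(o)
    effects, variances, moderator = [], [], []
    sds = []
    for obs_list in by_source.values():
        vals = np.array([observation_percent(o) for o in obs_list])
        if vals.size >= 2:
            sds.append(vals.std(ddof=1))
    fallback_var = float(np.mean([s**2 for s in sds])) if sds else 1.0
    for obs_list in by_source.values():
        vals = np.array([observation_percent(o) for o in obs_list])
        covs = np.array([float(_covariate_value(o, covariate)) for o in obs_list])
        n = vals.size
        var = vals.var(ddof=1) / n if n >= 2 and vals.var(ddof=1) > 0 else fallback_var / n
        effects.append(float(vals.mean()))
        variances.append(max(var, 1e-8))
        moderator.append(float(covs.mean()))
    if len(effects) < 3 or np.unique(moderator).size < 3:
        return _insufficient(covariate, "meta_regression", "<3 sources with distinct covariate values")
    coef, se, z, tau2 = dl_meta_regression(effects, variances, moderator)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return CovariateScreenResult(
        covariate=covariate, test_kind="meta_regression", statistic=z,
        p_value=p, flagged=p < alpha, note=f"tau2={tau2:.4g}",
    )


#: Numeric covariates get trend + meta-regression; everything else a rank test.
NUMERIC_COVARIATES = {
    "dark_treatment_light_level",
    "assay_pH",
    "assay_temperature_C",
    "edta_mM",
}


def covariate_screen(
    ds: Dataset, covariate: str, alpha: float = DEFAULT_ALPHA
) -> list[CovariateScreenResult]:
    """Screen one covariate with the tests appropriate to its type."""
    if covariate in NUMERIC_COVARIATES:
        return [
            linear_trend_screen(ds, covariate, alpha),
            meta_regression_screen(ds, covariate, alpha),
        ]
    return [rank_screen(ds, covariate, alpha)]
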