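"""Flower longevity, the Relative Pollination Rate index and its models.

Potential flower longevity (PFL) is the life-span of a pollinator-excluded
flower — the maximum time a flower can stay open.  Actual flower longevity
(AFL) is the life-span of an open-pollinated flower, shortened when
pollination triggers senescence.  The Relative Pollination Rate index

    RPR = 1 - AFL/PFL

is a proxy for site-level flower visitation rates: RPR near 0 means the
average flower waited out most of its potential life-span (slow
pollination); values near 1 mean early pollen receipt.

The unit of analysis throughout is the mean over the flowers of a plant;
site summaries are means of plant means, optionally weighted by floral
abundance so that batches placed at the height of the season dominate the
seasonal estimate.  Temperature responses are modelled by ordinary least
squares at batch level, compared between PFL and AFL with a Chow
coincidence test, and by a linear mixed model with batch nested in site.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .thermal import DailySeries

__all__ = [
    "RPRResult",
    "RegressionResult",
    "ChowResult",
    "WarmingContrast",
    "MixedAncovaResult",
    "lifespan_days",
    "plant_mean_longevity",
    "rpr",
    "abundance_weighted_mean",
    "batch_ambient",
    "soil_moisture_fill",
    "summarize_batches",
    "rpr_by_site",
    "longevity_temp_regression",
    "chow_compare",
    "warming_contrast",
    "mixed_ancova",
    "floral_abundance_weights",
]

logger = logging.getLogger(__name__)


def lifespan_days(anthesis, closure) -> int:
    """Days a flower stayed open, counting both endpoints.

    A flower that opened and closed the same day lived 1 day, which makes
    the shortest observable life-span 1 d.
    """
    anthesis, closure = pd.Timestamp(anthesis), pd.Timestamp(closure)
    if closure < anthesis:
        raise ValueError(f"closure {closure.date()} precedes anthesis {anthesis.date()}")
    return int((closure - anthesis).days) + 1


def plant_mean_longevity(lifespans: Sequence[float]) -> float:
    """Arithmetic mean of a plant's flower life-spans (the unit of analysis)."""
    arr = np.asarray(lifespans, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one flower")
    return float(arr.mean())


def rpr(afl: float, pfl: float) -> float:
    """Relative Pollination Rate, 1 − AFL/PFL.

    Negative values (sampling noise pushing AFL above PFL) are returned
    as-is so that site aggregation stays unbiased; flagging is left to
    :func:`rpr_by_site`.
    """
    if pfl <= 0:
        raise ValueError("PFL must be positive")
    return 1.0 - afl / pfl


def abundance_weighted_mean(
    values: Sequence[float], weights: Sequence[float], normalized: bool = True
) -> float:
    """Floral-abundance weighted mean of per-batch values.

    With ``normalized`` (default) this is Σ(v·w)/Σ(w), which preserves the
    units of ``values``; the unnormalized variant Σ(v·w)/n is exposed for
    comparison.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ValueError("values and weights differ in length")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if w.sum() == 0:
        raise ValueError("all weights are zero")
    if normalized:
        return float(np.sum(v * w) / np.sum(w))
    return float(np.mean(v * w))


def batch_ambient(series: DailySeries, open_spans: Sequence[tuple]) -> float:
    """Mean ambient temperature over flowers' open days.

    Each span (anthesis, closure) yields the mean daily tmean over its
    inclusive date range; the plant (or batch) value is the mean of the
    per-flower means.  Gaps in the series are an error.
    """
    per_flower = []
    for start, end in open_spans:
        frame = series.window(start, end)
        per_flower.append(float(((frame["tmax"] + frame["tmin"]) / 2.0).mean()))
    if not per_flower:
        raise ValueError("no open spans supplied")
    return float(np.mean(per_flower))


def soil_moisture_fill(readings: pd.Series, open_dates: Sequence) -> float:
    """Mean soil moisture over open days, nearest-dated reading for gaps.

    ``readings`` is indexed by date.  For a day without a reading the
    closest available date is substituted; ties go to the earlier date.
    """
    readings = pd.Series(readings).dropna()
    if readings.empty:
        raise ValueError("need at least one soil-moisture reading")
    readings.index = pd.DatetimeIndex(readings.index)
    readings = readings.sort_index()
    values = []
    for day in pd.DatetimeIndex(open_dates):
        if day in readings.index:
            values.append(float(readings[day]))
            continue
        deltas = np.abs((readings.index - day).days)
        best = np.flatnonzero(deltas == deltas.min())[0]  # earlier date wins ties
        values.append(float(readings.iloc[best]))
    return float(np.mean(values))


def summarize_batches(
    records: pd.DataFrame, series: Mapping[str, DailySeries]
) -> pd.DataFrame:
    """Collapse flower-level records to the plant-level analysis table.

    ``records`` needs columns site, batch, plant, treatment, anthesis,
    closure, diameter_mm, soil_moisture.  Returns one row per plant with
    mean longevity, the mean ambient temperature over its flowers' open
    days, and covariate means.
    """
    frame = records.copy()
    frame["anthesis"] = pd.to_datetime(frame["anthesis"])
    frame["closure"] = pd.to_datetime(frame["closure"])
    frame["lifespan"] = [
        lifespan_days(a, c) for a, c in zip(frame["anthesis"], frame["closure"])
    ]
    rows = []
    for (site, batch, plant, treatment), grp in frame.groupby(
        ["site", "batch", "plant", "treatment"], sort=False
    ):
        spans = list(zip(grp["anthesis"], grp["closure"]))
        rows.append(
            {
                "site": site,
                "batch": batch,
                "plant": plant,
                "treatment": treatment,
                "n_flowers": len(grp),
                "longevity": plant_mean_longevity(grp["lifespan"]),
                "temperature": batch_ambient(series[site], spans),
                "diameter": float(grp["diameter_mm"].mean()),
                "soil_moisture": float(grp["soil_moisture"].mean()),
            }
        )
    return pd.DataFrame(rows)


@dataclasses.dataclass(frozen=True)
class RPRResult:
    site: str
    afl: float
    pfl: float
    rpr: float
    weighted: bool
    negative_flagged: bool


def rpr_by_site(
    plants: pd.DataFrame,
    weights: Mapping | pd.Series | None = None,
    excluded_label: str = "excluded",
    open_label: str = "open",
) -> list[RPRResult]:
    """Site-level RPR from plant means; optionally abundance-weighted.

    ``plants`` is the table from :func:`summarize_batches`.  With
    ``weights`` (batch → floral abundance) PFL and AFL become weighted
    means of batch means of plant means before the index is formed.
    """
    results = []
    for site, grp in plants.groupby("site", sort=False):
        def _level(label: str) -> float:
            arm = grp[grp["treatment"] == label]
            if arm.empty:
                raise ValueError(f"{site}: no {label} plants")
            batch_means = arm.groupby("batch")["longevity"].mean()
            if weights is None:
                return float(batch_means.mean())
            w = np.array([float(weights[b]) for b in batch_means.index])
            return abundance_weighted_mean(batch_means.to_numpy(), w)

        pfl = _level(excluded_label)
        afl = _level(open_label)
        value = rpr(afl, pfl)
        results.append(RPRResult(str(site), afl, pfl, value, weights is not None, value < 0))
    return results


@dataclasses.dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    fvalue: float
    pvalue: float
    r_squared: float
    n: int


def longevity_temp_regression(pairs: Sequence[tuple]) -> RegressionResult:
    """OLS of batch-mean longevity (d) on batch-mean temperature (°C)."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (temperature, longevity) batches")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("temperature is constant; regression is degenerate")
    if np.ptp(y) == 0:
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, 0.0, len(y))
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        fvalue=float(res.fvalue),
        pvalue=float(res.f_pvalue),
        r_squared=float(res.rsquared),
        n=len(y),
    )


@dataclasses.dataclass(frozen=True)
class ChowResult:
    f_coincidence: float
    p_coincidence: float
    df_coincidence: tuple
    t_slope: float
    p_slope: float
    df_slope: int


def chow_compare(fit_a: Sequence[tuple], fit_b: Sequence[tuple]) -> ChowResult:
    """Chow coincidence test plus an equal-slopes t test for two regressions.

    Coincidence pools both datasets into one line and compares residual
    sums of squares:

        F = [(SSR_pooled − SSR_A − SSR_B)/2] / [(SSR_A + SSR_B)/(n_A + n_B − 4)]

    Slope equality is the t test on the interaction term of the combined
    model y ~ x * group.
    """
    a = np.asarray(fit_a, dtype=float)
    b = np.asarray(fit_b, dtype=float)
    if a.shape[0] < 3 or b.shape[0] < 3:
        raise ValueError("each dataset needs >= 3 points")
    if np.ptp(a[:, 0]) == 0 or np.ptp(b[:, 0]) == 0:
        raise ValueError("degenerate (constant-x) dataset")

    def _ssr(xy: np.ndarray) -> float:
        res = sm.OLS(xy[:, 1], sm.add_constant(xy[:, 0])).fit()
        return float(res.ssr)

    ssr_a, ssr_b = _ssr(a), _ssr(b)
    pooled = np.vstack([a, b])
    ssr_pooled = _ssr(pooled)
    n = a.shape[0] + b.shape[0]
    df_denom = n - 4
    f = ((ssr_pooled - ssr_a - ssr_b) / 2.0) / ((ssr_a + ssr_b) / df_denom)
    p_f = float(scipy.stats.f.sf(f, 2, df_denom))

    group = np.concatenate([np.zeros(a.shape[0]), np.ones(b.shape[0])])
    x = pooled[:, 0]
    design = np.column_stack([np.ones(n), x, group, x * group])
    res = sm.OLS(pooled[:, 1], design).fit()
    t = float(res.tvalues[3])
    p_t = float(2.0 * scipy.stats.t.sf(abs(t), df_denom))
    return ChowResult(float(f), p_f, (2, df_denom), t, p_t, df_denom)


@dataclasses.dataclass(frozen=True)
class WarmingContrast:
    per_site: pd.DataFrame  # site, u, pvalue (Mann–Whitney, two-sided)
    ancova: pd.DataFrame  # effect, df, F, p for longevity ~ diameter + treatment*site


def warming_contrast(data: pd.DataFrame) -> WarmingContrast:
    """Passive-warming experiment: rank tests per site plus factorial ANCOVA.

    ``data`` holds plant-mean longevities with columns site, treatment
    (control/warmed), longevity, diameter.
    """
    rows = []
    for site, grp in data.groupby("site", sort=False):
        arms = grp.groupby("treatment")["longevity"].apply(list)
        if len(arms) != 2 or any(len(v) < 2 for v in arms):
            raise ValueError(f"{site}: both arms need >= 2 plants")
        (label_a, a), (label_b, b) = arms.items()
        u, p = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"site": site, "arm_a": label_a, "arm_b": label_b, "u": float(u), "pvalue": float(p)})
    per_site = pd.DataFrame(rows)

    model = smf.ols("longevity ~ diameter + C(treatment) * C(site)", data=data).fit()
    table = anova_lm(model, typ=2)
    ancova = (
        table.rename(
            columns={"df": "df", "F": "F", "PR(>F)": "p"},
        )
        .reset_index()
        .rename(columns={"index": "effect"})
    )
    return WarmingContrast(per_site, ancova)


@dataclasses.dataclass(frozen=True)
class MixedAncovaResult:
    table: pd.DataFrame  # effect, estimate, std_error, statistic, pvalue
    metadata: dict


def mixed_ancova(
    plants: pd.DataFrame,
    response: str = "longevity",
    treatment: str = "treatment",
    covariates: Sequence[str] = ("diameter", "temperature", "soil_moisture"),
    site: str = "site",
    batch: str = "batch",
) -> MixedAncovaResult:
    """Linear mixed ANCOVA with batch nested in site as random intercepts.

    Model: response ~ treatment + covariates + (1 | site/batch), fitted by
    REML via statsmodels MixedLM.  Constant predictors are dropped (their
    rows are absent from the table).  A singular nested fit falls back to a
    site-only random intercept, recorded in the metadata and logged.
    Inference on fixed effects uses the normal approximation (z statistic).
    """
    frame = plants.copy()
    terms = []
    dropped = []
    if frame[treatment].nunique() > 1:
        terms.append(f"C({treatment})")
    else:
        dropped.append(treatment)
    for cov in covariates:
        if frame[cov].nunique() > 1:
            terms.append(cov)
        else:
            dropped.append(cov)
    if not terms:
        raise ValueError("no non-constant predictors")
    formula = f"{response} ~ " + " + ".join(terms)

    def _fit(vc: dict | None):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                formula,
                frame,
                groups=frame[site],
                re_formula="1",
                vc_formula=vc,
            )
            return model.fit(reml=True)

    random_structure = f"(1 | {site}/{batch})"
    try:
        result = _fit({batch: f"0 + C({batch})"})
        singular = not np.all(np.isfinite(result.bse_fe))
    except (np.linalg.LinAlgError, ValueError):
        result, singular = None, True
    if result is None or singular:
        logger.warning("nested random effects singular; falling back to site-only intercept")
        result = _fit(None)
        random_structure = f"(1 | {site})"

    fe = result.fe_params
    table = pd.DataFrame(
        {
            "effect": fe.index,
            "estimate": fe.to_numpy(),
            "std_error": result.bse_fe.to_numpy(),
            "statistic": (fe / result.bse_fe).to_numpy(),
            "pvalue": result.pvalues[fe.index].to_numpy(),
        }
    )
    metadata = {
        "method": "REML",
        "random_effects": random_structure,
        "converged": bool(result.converged),
        "dropped_constant_terms": dropped,
        "n_obs": int(len(frame)),
        "inference": "normal approximation (z)",
    }
    return MixedAncovaResult(table, metadata)


def floral_abundance_weights(
    census: pd.DataFrame, batches: pd.DataFrame
) -> pd.Series:
    """Floral abundance per batch from the nearest census dates.

    ``census`` has columns site, plant, date, n_open_flowers; ``batches``
    has columns site, batch, date (a representative open date).  For each
    batch the site's total open-flower counts on the nearest census date
    before and after (usually two, sometimes one at the season edges) are
    averaged.
    """
    census = census.copy()
    census["date"] = pd.to_datetime(census["date"])
    totals = census.groupby(["site", "date"])["n_open_flowers"].sum()
    batches = batches.copy()
    batches["date"] = pd.to_datetime(batches["date"])
    weights = {}
    for _, row in batches.iterrows():
        site_totals = totals.loc[row["site"]]
        dates = site_totals.index
        before = dates[dates <= row["date"]]
        after = dates[dates >= row["date"]]
        picks = []
        if len(before):
            picks.append(float(site_totals[before.max()]))
        if len(after) and (not len(before) or after.min() != before.max()):
            picks.append(float(site_totals[after.min()]))
        if not picks:
            raise ValueError(f"no census dates for site {row['site']}")
        weights[row["batch"]] = float(np.mean(picks))
    return pd.Series(weights, name="abundance")
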