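"""Flowering metrics, synchrony and thermal-sum regressions.

Per-plant open-flower censuses are resampled onto a regular (default
3-day) interval grid.  From the resulting plant × interval matrix six
metrics are extracted:

* FF       — first interval with any plant in the flowering phenophase
* FL50     — first interval with ≥ 50 % of monitored plants simultaneously
             in phenophase (a cumulative-onset variant is also computed)
* FLP      — earliest interval attaining the maximum simultaneous plant count
* FLSP     — earliest interval attaining the maximum summed open-flower count
* FF_POP   — per-plant first-flowering intervals (summarised by medians)
* FLP_POP  — per-plant peak-flower intervals (summarised by medians)

A plant observed in flower on both sides of a missing or zero census is
considered in phenophase across the gap (bracketing rule); counts are
never invented for bracketed gaps.  Flowering overlap among individuals
uses Augspurger's synchrony index

    X_i = 1/(n-1) * 1/f_i * sum_{j != i} e_ij

where f_i is the number of intervals plant i is in phenophase and e_ij
the number of intervals i and j are simultaneously in phenophase; the
site value Z is the mean of X_i.
"""
from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .thermal import DailySeries, GDDResult, TbaseScenario, accumulate_gdd

__all__ = [
    "FloweringMatrix",
    "PhenoMetrics",
    "PerPlantMetrics",
    "SynchronyResult",
    "SeasonFit",
    "ElevationTrend",
    "RankSiteTest",
    "build_matrix",
    "extrapolate_season",
    "backfill_early_flowering",
    "population_metrics",
    "per_plant_metrics",
    "synchrony",
    "event_gdd",
    "elevation_trend",
    "days_per_100m",
    "rank_site_test",
    "peak_gap_deficit",
]


@dataclasses.dataclass
class FloweringMatrix:
    """Plant × interval open-flower counts and in-phenophase booleans."""

    site: str
    intervals: pd.DatetimeIndex  # representative date of each grid interval
    counts: pd.DataFrame  # plants × intervals; NaN = not observed
    phenophase: pd.DataFrame  # plants × intervals; bool
    grid_step: int = 3

    @property
    def plants(self) -> pd.Index:
        return self.counts.index


def build_matrix(
    census: pd.DataFrame,
    grid_step: int = 3,
    bracket_fill: bool = True,
) -> FloweringMatrix:
    """Snap per-plant visit counts onto a regular interval grid.

    ``census`` needs columns plant, date, n_open_flowers (and at most one
    distinct site).  Visits are assigned to the nearest interval; when two
    visits fall in one interval the larger count is kept.  With
    ``bracket_fill`` every zero/missing interval between a plant's first
    and last in-flower intervals is marked in-phenophase (boolean only).
    """
    frame = census.copy()
    if "site" in frame.columns:
        sites = frame["site"].unique()
        if len(sites) > 1:
            raise ValueError(f"one site per matrix; got {list(sites)} (group first)")
        site = str(sites[0])
    else:
        site = ""
    frame["date"] = pd.to_datetime(frame["date"])
    if frame.duplicated(subset=["plant", "date"]).any():
        dup = frame[frame.duplicated(subset=["plant", "date"])].iloc[0]
        raise ValueError(f"duplicate census record for plant {dup['plant']} on {dup['date'].date()}")
    if frame["date"].nunique() < 2:
        raise ValueError("need at least two visits per site")

    origin = frame["date"].min()
    idx = np.rint((frame["date"] - origin).dt.days / grid_step).astype(int)
    frame = frame.assign(_interval=idx)
    n_intervals = int(idx.max()) + 1
    intervals = pd.DatetimeIndex(origin + pd.to_timedelta(np.arange(n_intervals) * grid_step, unit="D"))

    counts = (
        frame.pivot_table(index="plant", columns="_interval", values="n_open_flowers", aggfunc="max")
        .reindex(columns=range(n_intervals))
        .astype(float)
    )
    counts.columns = intervals

    phenophase = counts.fillna(0.0) > 0
    if bracket_fill:
        values = phenophase.to_numpy()
        for row in values:
            hits = np.flatnonzero(row)
            if hits.size >= 2:
                row[hits[0] : hits[-1] + 1] = True
        phenophase = pd.DataFrame(values, index=counts.index, columns=counts.columns)
    return FloweringMatrix(site, intervals, counts, phenophase, grid_step)


@dataclasses.dataclass(frozen=True)
class SeasonFit:
    """Quadratic season extrapolation: total flowers vs day number."""

    start: pd.Timestamp
    end: pd.Timestamp
    coefficients: tuple | None  # numpy polyfit order (a, b, c), or None on fallback
    from_quadratic: bool


def extrapolate_season(site_totals: pd.DataFrame | Sequence[tuple]) -> SeasonFit:
    """Fit a concave quadratic to (date, total flowers) and solve its roots.

    The real roots of the least-squares quadratic give the extrapolated
    season start/end.  A convex or complex-root fit falls back to the
    first/last nonzero observation dates, flagged via ``from_quadratic``.
    """
    frame = pd.DataFrame(site_totals, columns=["date", "total"]) if not isinstance(
        site_totals, pd.DataFrame
    ) else site_totals.rename(columns=dict(zip(site_totals.columns, ["date", "total"])))
    frame = frame.copy()
    frame["date"] = pd.to_datetime(frame["date"])
    frame = frame.sort_values("date")
    if len(frame) < 4:
        raise ValueError("need at least 4 observation dates")
    if (frame["total"] == 0).all():
        raise ValueError("totals are all zero")

    origin = frame["date"].iloc[0]
    t = (frame["date"] - origin).dt.days.to_numpy(dtype=float)
    y = frame["total"].to_numpy(dtype=float)
    coef = np.polyfit(t, y, 2)

    nonzero = frame.loc[frame["total"] > 0, "date"]
    fallback = SeasonFit(nonzero.iloc[0], nonzero.iloc[-1], None, False)
    if coef[0] >= 0:
        return fallback
    roots = np.roots(coef)
    if np.iscomplexobj(roots) and np.abs(roots.imag).max() > 1e-9:
        return fallback
    lo, hi = sorted(roots.real)
    start = origin + pd.Timedelta(days=round(float(lo)))
    end = origin + pd.Timedelta(days=round(float(hi)))
    return SeasonFit(start, end, tuple(coef), True)


def backfill_early_flowering(matrix: FloweringMatrix, season_start) -> FloweringMatrix:
    """Extend phenophase before the first visit for plants already in flower.

    The extrapolated season start defines ``k`` leading grid intervals
    between it and the first visit.  A plant with ``c`` open flowers at
    the first visit is granted ``round(k * c / c_max)`` extra in-phenophase
    intervals, ``c_max`` being the site maximum at that visit — plants with
    large displays are assumed to have been in flower for longer.  Counts
    are not invented.
    """
    season_start = pd.Timestamp(season_start)
    first = matrix.intervals[0]
    k = max(0, int(round((first - season_start).days / matrix.grid_step)))
    if k == 0:
        return matrix
    lead = pd.DatetimeIndex(
        first - pd.to_timedelta(np.arange(k, 0, -1) * matrix.grid_step, unit="D")
    )
    new_intervals = lead.append(matrix.intervals)
    counts = matrix.counts.reindex(columns=new_intervals)
    phenophase = matrix.phenophase.reindex(columns=new_intervals, fill_value=False)

    first_counts = matrix.counts.iloc[:, 0].fillna(0.0)
    c_max = float(first_counts.max())
    if c_max > 0:
        for plant, c in first_counts.items():
            if c <= 0:
                continue
            extra = int(round(k * float(c) / c_max))
            if extra > 0:
                phenophase.loc[plant, new_intervals[k - extra : k]] = True
    return FloweringMatrix(matrix.site, new_intervals, counts, phenophase, matrix.grid_step)


@dataclasses.dataclass(frozen=True)
class PhenoMetrics:
    """Population-level flowering dates and days since snowmelt."""

    site: str
    melt: pd.Timestamp
    ff: pd.Timestamp
    fl50: pd.Timestamp | None
    flp: pd.Timestamp
    flsp: pd.Timestamp
    fl50_cumulative: pd.Timestamp
    n_plants: int

    def days_since_melt(self, date: pd.Timestamp | None) -> float | None:
        if date is None:
            return None
        return float((pd.Timestamp(date) - self.melt).days)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("ff", "fl50", "flp", "flsp"):
            date = getattr(self, name)
            rows.append(
                {
                    "site": self.site,
                    "metric": name.upper(),
                    "date": None if date is None else date.date(),
                    "days_since_melt": self.days_since_melt(date),
                }
            )
        return pd.DataFrame(rows)


def population_metrics(matrix: FloweringMatrix, melt) -> PhenoMetrics:
    """FF, FL50, FLP and FLSP for a site, with days-since-melt."""
    melt = pd.Timestamp(melt)
    ph = matrix.phenophase
    if ph.empty or not ph.to_numpy().any():
        raise ValueError(f"{matrix.site}: no plant ever flowers")
    simultaneous = ph.sum(axis=0)
    any_flower = simultaneous > 0
    ff = any_flower.idxmax()

    n = len(ph)
    half = simultaneous >= 0.5 * n
    fl50 = half.idxmax() if half.any() else None

    started = ph.cumsum(axis=1) > 0  # plant has begun flowering by interval
    cumulative_half = started.sum(axis=0) >= 0.5 * n
    fl50_cum = cumulative_half.idxmax()

    flp = simultaneous.idxmax()  # idxmax → earliest interval at the maximum
    totals = matrix.counts.fillna(0.0).sum(axis=0)
    flsp = totals.idxmax()
    return PhenoMetrics(matrix.site, melt, ff, fl50, flp, flsp, fl50_cum, n)


@dataclasses.dataclass(frozen=True)
class PerPlantMetrics:
    """Per-plant first-flowering and own-peak intervals, with medians."""

    site: str
    melt: pd.Timestamp
    ff_pop: pd.Series  # plant -> first in-phenophase interval
    flp_pop: pd.Series  # plant -> earliest interval of maximal own count
    never_flowered: tuple

    @property
    def ff_pop_days(self) -> pd.Series:
        return (self.ff_pop - self.melt).dt.days.astype(float)

    @property
    def flp_pop_days(self) -> pd.Series:
        return (self.flp_pop - self.melt).dt.days.astype(float)

    @property
    def ff_pop_median_days(self) -> float:
        return float(np.median(self.ff_pop_days))

    @property
    def flp_pop_median_days(self) -> float:
        return float(np.median(self.flp_pop_days))


def per_plant_metrics(matrix: FloweringMatrix, melt) -> PerPlantMetrics:
    melt = pd.Timestamp(melt)
    ph = matrix.phenophase
    flowered = ph.any(axis=1)
    never = tuple(ph.index[~flowered])
    ph = ph.loc[flowered]
    if ph.empty:
        raise ValueError(f"{matrix.site}: no plant ever flowers")
    ff_pop = ph.idxmax(axis=1)
    counts = matrix.counts.loc[flowered].fillna(0.0)
    flp_pop = counts.idxmax(axis=1)  # earliest column at the row maximum
    return PerPlantMetrics(matrix.site, melt, ff_pop, flp_pop, never)


@dataclasses.dataclass(frozen=True)
class SynchronyResult:
    site: str
    x: pd.Series  # per-plant index in [0, 1]
    z: float  # site mean
    excluded: tuple  # plants with no in-phenophase interval


def synchrony(matrix: FloweringMatrix) -> SynchronyResult:
    """Augspurger's flowering synchrony index per plant and its site mean."""
    ph = matrix.phenophase
    f = ph.sum(axis=1)
    excluded = tuple(ph.index[f == 0])
    active = ph.loc[f > 0]
    n = len(active)
    if n < 2:
        raise ValueError(f"{matrix.site}: need >= 2 plants with flowering records")
    b = active.to_numpy(dtype=float)
    overlap = b @ b.T  # e_ij incl. diagonal f_i
    f_vec = np.diag(overlap)
    x = (overlap.sum(axis=1) - f_vec) / ((n - 1) * f_vec)
    series = pd.Series(x, index=active.index, name="synchrony")
    return SynchronyResult(matrix.site, series, float(series.mean()), excluded)


def event_gdd(
    events: Mapping[str, pd.Timestamp] | pd.Series,
    series: DailySeries,
    melt,
    scenario: TbaseScenario | float,
    snow_free_days: int | None = None,
) -> dict[str, GDDResult]:
    """Accumulated GDD from snowmelt to each labelled event date."""
    items = events.items() if isinstance(events, Mapping) else events.items()
    return {
        str(label): accumulate_gdd(series, melt, date, scenario, snow_free_days)
        for label, date in items
        if date is not None
    }


@dataclasses.dataclass(frozen=True)
class ElevationTrend:
    slope_per_100m: float
    slope_se_per_100m: float
    intercept: float
    fvalue: float
    pvalue: float
    r_squared: float
    n: int


def elevation_trend(values: Sequence[float], elevations: Sequence[float]) -> ElevationTrend:
    """OLS of a per-site scalar on elevation (slope reported per 100 m)."""
    y = np.asarray(values, dtype=float)
    x = np.asarray(elevations, dtype=float)
    if len(y) != len(x):
        raise ValueError("values and elevations differ in length")
    if len(y) < 3:
        raise ValueError("need at least 3 sites")
    if np.ptp(y) == 0:
        return ElevationTrend(0.0, 0.0, float(y[0]), 0.0, 1.0, 0.0, len(y))
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return ElevationTrend(
        slope_per_100m=float(res.params[1] * 100.0),
        slope_se_per_100m=float(res.bse[1] * 100.0),
        intercept=float(res.params[0]),
        fvalue=float(res.fvalue),
        pvalue=float(res.f_pvalue),
        r_squared=float(res.rsquared),
        n=len(y),
    )


def days_per_100m(
    event_dates: Mapping[str, pd.Timestamp],
    elevations: Mapping[str, float],
    site_lo: str,
    site_hi: str,
) -> float:
    """Elevational delay of an event in days per 100 m (1 decimal, half-up)."""
    e_lo, e_hi = float(elevations[site_lo]), float(elevations[site_hi])
    if e_lo == e_hi:
        raise ValueError("sites have equal elevations")
    d_lo = pd.Timestamp(event_dates[site_lo])
    d_hi = pd.Timestamp(event_dates[site_hi])
    rate = (d_hi - d_lo).days / ((e_hi - e_lo) / 100.0)
    return float(Decimal(str(rate)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclasses.dataclass(frozen=True)
class RankSiteTest:
    h: float
    df: int
    pvalue: float
    posthoc: pd.DataFrame  # pairwise Dunn comparisons (z, p, p_adjusted)


def rank_site_test(groups: Mapping[str, Sequence[float]], adjust: str = "bonferroni") -> RankSiteTest:
    """Kruskal–Wallis across sites with Dunn pairwise follow-up on ranks."""
    labels = list(groups)
    if len(labels) < 2 or any(len(groups[g]) == 0 for g in labels):
        raise ValueError("need >= 2 nonempty groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        posthoc = pd.DataFrame(
            [(a, b, 0.0, 1.0, 1.0) for i, a in enumerate(labels) for b in labels[i + 1 :]],
            columns=["site_a", "site_b", "z", "pvalue", "p_adjusted"],
        )
        return RankSiteTest(0.0, len(labels) - 1, 1.0, posthoc)
    h, p = scipy.stats.kruskal(*arrays)

    # Dunn's test: z on mean ranks with tie-corrected variance.
    ranks = scipy.stats.rankdata(pooled)
    n_total = len(pooled)
    sizes = [len(a) for a in arrays]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = {
        g: ranks[bounds[i] : bounds[i + 1]].mean() for i, g in enumerate(labels)
    }
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    m = len(labels) * (len(labels) - 1) // 2
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            se = np.sqrt(base_var * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p_raw = 2.0 * scipy.stats.norm.sf(abs(z))
            if adjust == "bonferroni":
                p_adj = min(1.0, p_raw * m)
            else:
                raise ValueError(f"unknown adjustment {adjust!r}")
            rows.append((a, b, float(z), float(p_raw), float(p_adj)))
    posthoc = pd.DataFrame(rows, columns=["site_a", "site_b", "z", "pvalue", "p_adjusted"])
    return RankSiteTest(float(h), len(labels) - 1, float(p), posthoc)


def peak_gap_deficit(lapse_gap: float, t_low_site: float, t_high_site: float) -> float:
    """How much smaller the peak-flowering temperature gap is than the lapse.

    ``lapse_gap`` is the full elevational temperature drop over the range;
    the difference between the low- and high-site temperatures at peak
    flowering is subtracted from it.
    """
    return float(lapse_gap - (t_low_site - t_high_site))
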