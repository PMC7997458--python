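"""Snow-season detection from daily percent snow-cover series.

Daily satellite snow-cover products (e.g. 500 m MODIS-type pixels) report,
per site, the percentage of the pixel covered by snow.  The definitive
spring melt date — the *biofix* from which thermal time is accumulated —
is taken as the first date after which cover never again exceeds a small
margin (default 10 %).  The first permanent winter snow is the mirror
image: the first post-melt date from which cover stays above the margin
through the end of the record.  Cloud-obscured days carry no information
and are skipped rather than treated as violations of either criterion.

Day-count convention: the snow-free period is inclusive of the melt date
and exclusive of the winter-onset date, so ``snow_free_days`` equals the
plain difference in days between the two dates.
"""
from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SnowSeries",
    "SnowSeason",
    "NoMeltError",
    "NoWinterOnsetError",
    "detect_snowmelt",
    "detect_winter_onset",
    "snow_free_days",
    "days_to_months",
    "snow_season",
    "read_snow_csv",
    "season_table",
]

DAYS_PER_MONTH = 365.25 / 12.0


class NoMeltError(ValueError):
    """No date qualifies as a definitive snowmelt under the margin."""


class NoWinterOnsetError(ValueError):
    """No date qualifies as permanent winter snow (series ends snow-free)."""


@dataclasses.dataclass
class SnowSeries:
    """Daily percent snow cover for one site.

    ``cover`` is indexed by date; NaN marks cloud-obscured (missing) days.
    Dates must be strictly increasing and non-missing values in [0, 100].
    """

    site: str
    cover: pd.Series

    def __post_init__(self) -> None:
        cover = pd.Series(self.cover, dtype=float)
        cover.index = pd.DatetimeIndex(cover.index)
        if not cover.index.is_monotonic_increasing or cover.index.has_duplicates:
            raise ValueError(f"{self.site}: dates must be strictly increasing")
        obs = cover.dropna()
        if ((obs < 0) | (obs > 100)).any():
            raise ValueError(f"{self.site}: percent cover outside [0, 100]")
        self.cover = cover

    @property
    def observed(self) -> pd.Series:
        """Non-missing (cloud-free) observations."""
        return self.cover.dropna()


def detect_snowmelt(series: SnowSeries, margin: float = 10.0) -> pd.Timestamp:
    """First date from which every later non-missing cover value is <= margin.

    Raises :class:`NoMeltError` when the series never settles below the
    margin (e.g. it ends under snow).
    """
    if not 0 <= margin < 100:
        raise ValueError("margin must be in [0, 100)")
    obs = series.observed
    if obs.empty:
        raise NoMeltError(f"{series.site}: no observations")
    suffix_max = obs[::-1].cummax()[::-1]
    qualifying = suffix_max <= margin
    if not qualifying.any():
        raise NoMeltError(f"{series.site}: no melt detected (margin {margin}%)")
    return qualifying.idxmax()


def detect_winter_onset(
    series: SnowSeries,
    margin: float = 10.0,
    after: pd.Timestamp | None = None,
) -> pd.Timestamp:
    """First post-melt date from which cover stays above the margin to the end.

    ``after`` defaults to the detected melt date.  Raises
    :class:`NoWinterOnsetError` when the series ends snow-free.
    """
    if after is None:
        try:
            after = detect_snowmelt(series, margin)
        except NoMeltError:
            # series starts snow-free (or melt is off-record): search from start
            after = series.observed.index[0] - pd.Timedelta(days=1)
    obs = series.observed
    obs = obs[obs.index > pd.Timestamp(after)]
    if obs.empty:
        raise NoWinterOnsetError(f"{series.site}: no observations after {after}")
    suffix_min = obs[::-1].cummin()[::-1]
    qualifying = suffix_min > margin
    if not qualifying.any():
        raise NoWinterOnsetError(
            f"{series.site}: no winter onset (series ends snow-free)"
        )
    return qualifying.idxmax()


def snow_free_days(melt: pd.Timestamp, onset: pd.Timestamp) -> int:
    """Day count inclusive of the melt date, exclusive of the onset date."""
    melt, onset = pd.Timestamp(melt), pd.Timestamp(onset)
    if melt >= onset:
        raise ValueError(f"melt date {melt.date()} not before onset {onset.date()}")
    return int((onset - melt).days)


def days_to_months(days: float) -> float:
    """Convert a day count to calendar months (365.25/12 d), 1 decimal, half-up."""
    if days < 0:
        raise ValueError("day count must be non-negative")
    months = Decimal(str(days / DAYS_PER_MONTH))
    return float(months.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclasses.dataclass(frozen=True)
class SnowSeason:
    """Melt-to-winter summary for one site."""

    site: str
    melt_date: pd.Timestamp
    winter_onset_date: pd.Timestamp
    snow_free_days: int
    snow_free_months: float


def snow_season(series: SnowSeries, margin: float = 10.0) -> SnowSeason:
    """Melt, winter onset and snow-free-day count for a full-year series.

    A series covering the whole hydrological year returns to snow in
    winter, so the plain suffix criterion of :func:`detect_snowmelt`
    cannot apply to it directly.  The snow-free season is instead the
    longest run of consecutive below-margin observations (cloud days do
    not break a run): the melt date is its first day — which coincides
    with :func:`detect_snowmelt` on the series truncated before the
    winter return — and winter onset is detected after the run's end.
    """
    obs = series.observed
    if obs.empty:
        raise NoMeltError(f"{series.site}: no observations")
    low = (obs <= margin).to_numpy()
    if not low.any():
        raise NoMeltError(f"{series.site}: no melt detected (margin {margin}%)")
    # longest run of True in `low`; ties resolved to the earliest run
    edges = np.flatnonzero(np.diff(np.concatenate([[0], low.astype(int), [0]])))
    starts, ends = edges[::2], edges[1::2]
    best = int(np.argmax(ends - starts))
    melt = obs.index[starts[best]]
    last_low = obs.index[ends[best] - 1]
    onset = detect_winter_onset(series, margin, after=last_low)
    n = snow_free_days(melt, onset)
    return SnowSeason(series.site, melt, onset, n, days_to_months(n))


def read_snow_csv(path) -> dict[str, SnowSeries]:
    """Read a ``site,date,percent_cover`` CSV into per-site series."""
    frame = pd.read_csv(path, parse_dates=["date"])
    out: dict[str, SnowSeries] = {}
    for site, grp in frame.groupby("site", sort=False):
        cover = grp.set_index("date")["percent_cover"].sort_index()
        out[str(site)] = SnowSeries(str(site), cover)
    return out


def season_table(seasons: Mapping[str, SnowSeason]) -> pd.DataFrame:
    """Tabulate seasons as ``site,melt_date,winter_onset,snow_free_days,snow_free_months``."""
    rows = [
        {
            "site": s.site,
            "melt_date": s.melt_date.date(),
            "winter_onset": s.winter_onset_date.date(),
            "snow_free_days": s.snow_free_days,
            "snow_free_months": s.snow_free_months,
        }
        for s in seasons.values()
    ]
    return pd.DataFrame(rows)
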