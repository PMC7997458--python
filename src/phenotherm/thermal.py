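"""Per-site temperature reconstruction and growing-degree-day (GDD) sums.

A single weather station provides the continuous daily record; short
paired-logger deployments on the study sites provide average monthly
temperature differences between contiguous sites.  Each site's daily
series is the station series, shifted once to match the reference site's
loggers (``station_offset``) and then by the accumulated pairwise monthly
offsets along the chain of sites.

Thermal time uses the standard daily-mean formulation:

    GDD increment = max((Tmax + Tmin)/2 - T_BASE, 0)

with a day whose mean exactly equals the base contributing zero.  Base
temperatures come in two flavours: *fixed* (one value for every site) and
*graded* (per-site values lowered in step with the elevational drop in
mean snow-free-period temperature).
"""
from __future__ import annotations

import dataclasses
from collections import deque
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DailySeries",
    "TbaseScenario",
    "GDDResult",
    "MissingDaysError",
    "gdd_increment",
    "accumulate_gdd",
    "calibrate_station_offset",
    "reconstruct_site_series",
    "pairwise_monthly_offsets",
    "graded_tbase",
    "site_mean_temperature",
    "daily_from_logger",
    "read_station_csv",
]


class MissingDaysError(ValueError):
    """A requested window contains days absent from the series."""


@dataclasses.dataclass
class DailySeries:
    """Daily Tmin/Tmax (°C) for one site; tmean = (tmax + tmin)/2."""

    site: str
    data: pd.DataFrame  # index: date; columns: tmin, tmax

    def __post_init__(self) -> None:
        data = self.data[["tmin", "tmax"]].copy()
        data.index = pd.DatetimeIndex(data.index)
        if not data.index.is_monotonic_increasing or data.index.has_duplicates:
            raise ValueError(f"{self.site}: dates must be strictly increasing")
        if (data["tmin"] > data["tmax"]).any():
            bad = data.index[data["tmin"] > data["tmax"]][0]
            raise ValueError(f"{self.site}: tmin > tmax on {bad.date()}")
        self.data = data

    @property
    def tmean(self) -> pd.Series:
        return (self.data["tmax"] + self.data["tmin"]) / 2.0

    def window(self, start, end) -> pd.DataFrame:
        """Slice [start, end] inclusive, raising on missing days."""
        start, end = pd.Timestamp(start), pd.Timestamp(end)
        expected = pd.date_range(start, end, freq="D")
        missing = expected.difference(self.data.index)
        if len(missing):
            listed = ", ".join(str(d.date()) for d in missing[:5])
            more = "" if len(missing) <= 5 else f" (+{len(missing) - 5} more)"
            raise MissingDaysError(f"{self.site}: missing days {listed}{more}")
        return self.data.loc[start:end]

    def shifted(self, offset_by_month: Mapping[int, float] | float) -> "DailySeries":
        """Return a copy with a constant or per-calendar-month shift applied
        equally to tmin and tmax."""
        if isinstance(offset_by_month, Mapping):
            months = self.data.index.month
            try:
                shift = np.array([offset_by_month[m] for m in months])
            except KeyError as exc:
                raise ValueError(f"{self.site}: no offset for month {exc}") from exc
        else:
            shift = float(offset_by_month)
        data = self.data.add(shift, axis=0)
        return DailySeries(self.site, data)


@dataclasses.dataclass(frozen=True)
class TbaseScenario:
    """A base-temperature scenario, fixed across sites or graded per site."""

    label: str
    mode: str  # "fixed" | "graded"
    bases: float | Mapping[str, float]

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "graded"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "fixed":
            if not np.isfinite(float(self.bases)):  # type: ignore[arg-type]
                raise ValueError("fixed base must be finite")
        else:
            if not isinstance(self.bases, Mapping) or not all(
                np.isfinite(v) for v in self.bases.values()
            ):
                raise ValueError("graded mode requires a finite base per site")

    @classmethod
    def fixed(cls, base: float, label: str | None = None) -> "TbaseScenario":
        return cls(label or f"fixed_{base:g}C", "fixed", float(base))

    def base_for(self, site: str) -> float:
        if self.mode == "fixed":
            return float(self.bases)  # type: ignore[arg-type]
        try:
            return float(self.bases[site])  # type: ignore[index]
        except KeyError:
            raise ValueError(f"scenario {self.label!r} has no base for site {site!r}")


@dataclasses.dataclass(frozen=True)
class GDDResult:
    site: str
    biofix: pd.Timestamp
    end: pd.Timestamp
    scenario: str
    gdd: float
    n_growth_days: int
    gs_fraction: float | None = None


def gdd_increment(tmax, tmin, tbase):
    """Daily thermal units max((tmax+tmin)/2 - tbase, 0); vectorised."""
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    if np.any(tmin > tmax):
        raise ValueError("tmin exceeds tmax")
    inc = np.maximum((tmax + tmin) / 2.0 - tbase, 0.0)
    return float(inc) if inc.ndim == 0 else inc


def accumulate_gdd(
    series: DailySeries,
    biofix,
    end,
    scenario: TbaseScenario | float,
    snow_free_days: int | None = None,
    include_end: bool = True,
) -> GDDResult:
    """Sum daily GDD increments from the biofix to the event date.

    The window is inclusive of both endpoints by default (``include_end``
    exposes the alternative convention).  Missing days are a hard error;
    nothing is interpolated.
    """
    biofix, end = pd.Timestamp(biofix), pd.Timestamp(end)
    if biofix > end:
        raise ValueError("biofix after end date")
    if isinstance(scenario, TbaseScenario):
        base = scenario.base_for(series.site)
        label = scenario.label
    else:
        base = float(scenario)
        label = f"fixed_{base:g}C"
    stop = end if include_end else end - pd.Timedelta(days=1)
    if stop < biofix:
        inc = np.zeros(0)
    else:
        frame = series.window(biofix, stop)
        inc = gdd_increment(frame["tmax"].to_numpy(), frame["tmin"].to_numpy(), base)
    n_growth = int(np.count_nonzero(inc > 0))
    fraction = None
    if snow_free_days is not None and snow_free_days > 0:
        fraction = n_growth / snow_free_days
    return GDDResult(series.site, biofix, end, label, float(np.sum(inc)), n_growth, fraction)


def calibrate_station_offset(
    station: DailySeries,
    reference_logger: DailySeries,
    window: tuple | None = None,
    min_overlap: int = 30,
) -> float:
    """Mean(logger tmean) − mean(station tmean) over the overlap window.

    Adding the returned value to the station series brings it into line
    with the reference site's loggers.
    """
    common = station.data.index.intersection(reference_logger.data.index)
    if window is not None:
        start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
        common = common[(common >= start) & (common <= end)]
    if len(common) < min_overlap:
        raise ValueError(
            f"insufficient overlap ({len(common)} days < {min_overlap}) for calibration"
        )
    return float(reference_logger.tmean[common].mean() - station.tmean[common].mean())


def reconstruct_site_series(
    station: DailySeries,
    logger_offsets: Mapping[tuple[str, str], Mapping[int, float]],
    reference_site: str,
    station_offset: float = 0.0,
    sites: Iterable[str] | None = None,
) -> dict[str, DailySeries]:
    """Propagate the station series to every site through pairwise offsets.

    ``logger_offsets[(a, b)][month]`` is the mean monthly difference
    ``T(b) − T(a)`` estimated from paired loggers.  The station series plus
    ``station_offset`` defines the reference site; other sites accumulate
    signed offsets along the chain.  Offsets are applied to tmin and tmax
    equally.  A site not connected to the reference raises an error naming it.
    """
    adjacency: dict[str, list[tuple[str, int]]] = {}
    signed: list[tuple[str, str, Mapping[int, float]]] = []
    for (a, b), offsets in logger_offsets.items():
        signed.append((a, b, offsets))
        adjacency.setdefault(a, []).append((b, len(signed) - 1))
        adjacency.setdefault(b, []).append((a, -(len(signed))))

    all_sites = set(adjacency) | {reference_site}
    if sites is not None:
        all_sites |= set(sites)

    months = sorted({m for _, _, off in signed for m in off})
    cumulative: dict[str, dict[int, float]] = {reference_site: {m: 0.0 for m in months}}
    queue = deque([reference_site])
    while queue:
        node = queue.popleft()
        for neighbour, idx in adjacency.get(node, []):
            if neighbour in cumulative:
                continue
            if idx >= 0:
                _, _, off = signed[idx]
                sign = 1.0
            else:
                _, _, off = signed[-idx - 1]
                sign = -1.0
            cumulative[neighbour] = {
                m: cumulative[node].get(m, 0.0) + sign * off[m] for m in off
            }
            queue.append(neighbour)

    orphans = sorted(all_sites - set(cumulative))
    if orphans:
        raise ValueError(f"sites not connected to reference {reference_site!r}: {orphans}")

    reference = DailySeries(reference_site, station.data.add(station_offset, axis=0).copy())
    out: dict[str, DailySeries] = {}
    for site in sorted(all_sites):
        shifts = cumulative[site]
        shifted = reference.shifted(shifts) if shifts else reference
        out[site] = DailySeries(site, shifted.data.copy())
    return out


def pairwise_monthly_offsets(
    loggers: Mapping[str, DailySeries], order: Sequence[str]
) -> dict[tuple[str, str], dict[int, float]]:
    """Average monthly tmean differences between contiguous site pairs."""
    offsets: dict[tuple[str, str], dict[int, float]] = {}
    for a, b in zip(order, order[1:]):
        common = loggers[a].data.index.intersection(loggers[b].data.index)
        if common.empty:
            raise ValueError(f"loggers for {a} and {b} share no dates")
        diff = loggers[b].tmean[common] - loggers[a].tmean[common]
        offsets[(a, b)] = {int(m): float(v) for m, v in diff.groupby(common.month).mean().items()}
    return offsets


def graded_tbase(
    ref_base: float,
    site_means: Mapping[str, float],
    ref_site: str,
    label: str = "graded",
) -> TbaseScenario:
    """Per-site bases lowered by each site's mean-temperature deficit.

    base(site) = ref_base − (mean(ref_site) − mean(site)); the reference
    site keeps ``ref_base``.
    """
    if ref_site not in site_means:
        raise ValueError(f"reference site {ref_site!r} missing from site means")
    ref_mean = site_means[ref_site]
    bases = {site: float(ref_base - (ref_mean - mean)) for site, mean in site_means.items()}
    return TbaseScenario(label, "graded", bases)


def site_mean_temperature(series: DailySeries, window: tuple) -> float:
    """Mean daily tmean over [start, end] inclusive; gaps are an error."""
    frame = series.window(window[0], window[1])
    return float(((frame["tmax"] + frame["tmin"]) / 2.0).mean())


def daily_from_logger(records: pd.DataFrame) -> dict[str, DailySeries]:
    """Aggregate ``site,timestamp,temp`` logger records to daily min/max."""
    frame = records.copy()
    frame["timestamp"] = pd.to_datetime(frame["timestamp"])
    frame["date"] = frame["timestamp"].dt.normalize()
    out: dict[str, DailySeries] = {}
    for site, grp in frame.groupby("site", sort=False):
        daily = grp.groupby("date")["temp"].agg(tmin="min", tmax="max")
        out[str(site)] = DailySeries(str(site), daily)
    return out


def read_station_csv(path, site: str = "station") -> DailySeries:
    """Read a ``date,tmin,tmax`` station CSV."""
    frame = pd.read_csv(path, parse_dates=["date"]).set_index("date")
    return DailySeries(site, frame[["tmin", "tmax"]])


def read_scenario_yaml(path) -> TbaseScenario:
    """Read a ``{label, mode, bases}`` YAML scenario file.

    ``bases`` is a single number for fixed mode or a site → °C mapping
    for graded mode.
    """
    import yaml

    raw = yaml.safe_load(open(path))
    return TbaseScenario(str(raw["label"]), str(raw["mode"]), raw["bases"])
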