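"""Synthetic alpine phenology worlds with exported ground truth.

The generator emulates the structure of an elevational field campaign:
a transect of sites, a seasonal temperature field declining with
elevation at a fixed lapse rate, snow-cover series whose melt date lags
with elevation, plants whose flowering onset is triggered by an
accumulated thermal-sum threshold, flower batches whose life-spans
respond linearly to ambient temperature (shortened by stochastic
pollinator arrival in the open-pollination arm), and fruit outcomes.

Every stochastic component draws from a substream derived from one
global seed, so adding a generator does not perturb the others and the
same seed reproduces every table bit for bit.  The true parameters are
exported as :class:`GroundTruth` for parameter-recovery tests.

Default sizes mirror the emulated campaign: five sites spanning 810 m,
a 4.6 d/100 m melt lag, 75 flower batches split 17/17/16/16/9 across
sites, six plants per treatment arm and five flowers per plant, a
longevity temperature slope of −0.132 d/°C, and a 1.1 % autonomous
selfing rate.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .snow import SnowSeries
from .thermal import DailySeries, gdd_increment

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimBundle",
    "site_ids",
    "gen_temperature",
    "gen_snowcover",
    "true_melt_dates",
    "winter_onset_date",
    "truth_tbase",
    "gen_flowering",
    "gen_longevity",
    "simulate",
    "write_bundle",
]

logger = logging.getLogger(__name__)

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]
_STREAMS = {"temperature": 1, "snow": 2, "flowering": 3, "longevity": 4}


@dataclasses.dataclass
class SimConfig:
    """Ground-truth parameters of a synthetic elevational study.

    Temperatures follow a single annual harmonic peaking on ``peak_doy``
    (mid-January, austral summer) minus a lapse term, with iid daily
    noise; Tmax/Tmin sit a fixed diurnal half-range around the mean.
    """

    elevations: Sequence[float] = (2341.0, 2596.0, 2736.0, 2967.0, 3151.0)
    n_sites: int | None = None
    lapse_rate: float = 4.8  # °C per 1000 m
    season_mean: float = 7.0  # annual mean °C at the lowest site
    season_amplitude: float = 9.0  # °C
    peak_doy: int = 15  # day of year of the seasonal maximum (mid-January)
    temp_noise_sd: float = 1.5  # °C
    diurnal_half_range: float = 6.0  # °C
    year: int = 2016  # season runs 1 Jul year → 30 Jun year+1

    melt_day_base: int = 244  # day of year of snowmelt at the lowest site (31 Aug)
    melt_lag_per_100m: float = 4.6  # days
    snow_ramp_days: int = 5
    winter_onset_doy: int = 128  # 8 May of year+1 (common to all sites)
    resnow_spikes: int = 0
    spike_cover: float = 8.0  # % cover of transient post-melt spikes

    n_plants_per_site: int = 50
    gdd_onset_mean: float = 150.0  # degree-days
    gdd_onset_sd: float = 40.0
    flowering_duration_mean: float = 45.0  # days
    flowering_duration_sd: float = 10.0
    peak_flowers_mean: float = 20.0
    tbase_truth_mode: str = "graded"  # thermal-threshold rule behind onset
    tbase_truth_ref: float = 5.0  # °C at the lowest site

    longevity_intercept: float = 4.5  # days
    longevity_temp_slope: float = -0.132  # days per °C
    longevity_noise_sd: float = 0.6  # days, flower level
    plant_longevity_sd: float = 0.3  # days, plant random effect
    visit_rate_per_degree: float = 0.07  # visits / day / °C above T_activity
    t_activity: float = 10.0  # °C below which pollinators are inactive
    senescence_lag_days: float = 1.0
    selfing_rate: float = 0.011
    batches_per_site: Sequence[int] | int = (17, 17, 16, 16, 9)
    plants_per_arm: int = 6
    flowers_per_plant: int = 5
    diameter_mean: float = 12.0  # mm
    diameter_sd: float = 1.5
    soil_mean: float = 20.0  # %
    soil_sd: float = 6.0
    ovule_mean: float = 8.0
    seed_success: float = 0.75

    seed: int = 0

    def __post_init__(self) -> None:
        elev = tuple(float(e) for e in self.elevations)
        if any(b <= a for a, b in zip(elev, elev[1:])):
            raise ValueError("elevations must be strictly increasing")
        self.elevations = elev
        if self.n_sites is None:
            self.n_sites = len(elev)
        elif self.n_sites != len(elev):
            raise ValueError("n_sites disagrees with elevations")
        for name in ("temp_noise_sd", "gdd_onset_sd", "flowering_duration_sd",
                     "longevity_noise_sd", "plant_longevity_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_plants_per_site < 2:
            raise ValueError("n_plants_per_site must be >= 2")
        if isinstance(self.batches_per_site, int):
            self.batches_per_site = (self.batches_per_site,) * self.n_sites
        else:
            self.batches_per_site = tuple(int(b) for b in self.batches_per_site)
            if len(self.batches_per_site) != self.n_sites:
                raise ValueError("batches_per_site length must match sites")


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, _STREAMS[stream]]))


def site_ids(config: SimConfig) -> list[str]:
    if config.n_sites <= len(_ROMAN):
        return _ROMAN[: config.n_sites]
    return [f"S{i + 1}" for i in range(config.n_sites)]


def _season_index(config: SimConfig) -> pd.DatetimeIndex:
    return pd.date_range(f"{config.year}-07-01", f"{config.year + 1}-06-30", freq="D")


def gen_temperature(config: SimConfig) -> dict[str, DailySeries]:
    """Per-site daily Tmin/Tmax from harmonic + lapse + noise."""
    rng = _rng(config, "temperature")
    dates = _season_index(config)
    doy = dates.dayofyear.to_numpy(dtype=float)
    seasonal = config.season_mean + config.season_amplitude * np.cos(
        2.0 * np.pi * (doy - config.peak_doy) / 365.25
    )
    out: dict[str, DailySeries] = {}
    base_elev = config.elevations[0]
    for site, elev in zip(site_ids(config), config.elevations):
        noise = rng.normal(0.0, config.temp_noise_sd, size=len(dates)) if config.temp_noise_sd > 0 else 0.0
        tmean = seasonal - config.lapse_rate * (elev - base_elev) / 1000.0 + noise
        data = pd.DataFrame(
            {"tmin": tmean - config.diurnal_half_range, "tmax": tmean + config.diurnal_half_range},
            index=dates,
        )
        out[site] = DailySeries(site, data)
    return out


def true_melt_dates(config: SimConfig) -> dict[str, pd.Timestamp]:
    base = pd.Timestamp(f"{config.year}-01-01") + pd.Timedelta(days=config.melt_day_base - 1)
    out = {}
    for site, elev in zip(site_ids(config), config.elevations):
        lag = round(config.melt_lag_per_100m * (elev - config.elevations[0]) / 100.0)
        out[site] = base + pd.Timedelta(days=int(lag))
    return out


def winter_onset_date(config: SimConfig) -> pd.Timestamp:
    return pd.Timestamp(f"{config.year + 1}-01-01") + pd.Timedelta(days=config.winter_onset_doy - 1)


def gen_snowcover(config: SimConfig) -> tuple[dict[str, SnowSeries], dict[str, pd.Timestamp]]:
    """Snow-cover series: full cover, a melt ramp, snow-free summer, winter return.

    The ramp reaches 0 % on the true melt date and stays above 10 % before
    it, so margin-based detection recovers the truth exactly on clean
    series.  Optional transient post-melt spikes stay at ``spike_cover``.
    """
    rng = _rng(config, "snow")
    dates = _season_index(config)
    melts = true_melt_dates(config)
    onset = winter_onset_date(config)
    ramp = max(1, int(config.snow_ramp_days))
    out: dict[str, SnowSeries] = {}
    for site in site_ids(config):
        melt = melts[site]
        cover = np.full(len(dates), 100.0)
        days_from_melt = (dates - melt).days.to_numpy()
        in_summer = (days_from_melt >= 0) & (dates < onset)
        cover[in_summer] = 0.0
        on_ramp = (days_from_melt < 0) & (days_from_melt > -ramp)
        cover[on_ramp] = 100.0 * (-days_from_melt[on_ramp]) / ramp
        if config.resnow_spikes > 0:
            candidates = np.flatnonzero((days_from_melt > 5) & (dates < onset - pd.Timedelta(days=20)))
            spikes = rng.choice(candidates, size=min(config.resnow_spikes, len(candidates)), replace=False)
            cover[spikes] = config.spike_cover
        out[site] = SnowSeries(site, pd.Series(cover, index=dates))
    return out, melts


def truth_tbase(
    config: SimConfig,
    series: Mapping[str, DailySeries],
    melts: Mapping[str, pd.Timestamp],
) -> dict[str, float]:
    """Per-site thermal threshold actually driving flowering onset.

    Graded mode lowers the base from the reference value in step with the
    elevational drop of mean snow-free-period temperature; fixed mode uses
    the reference value everywhere.
    """
    sites = site_ids(config)
    if config.tbase_truth_mode == "fixed":
        return {s: config.tbase_truth_ref for s in sites}
    onset = winter_onset_date(config)
    means = {
        s: float(series[s].window(melts[s], onset - pd.Timedelta(days=1))[["tmin", "tmax"]].mean(axis=1).mean())
        for s in sites
    }
    ref = means[sites[0]]
    return {s: config.tbase_truth_ref - (ref - means[s]) for s in sites}


def gen_flowering(
    config: SimConfig,
    series: Mapping[str, DailySeries],
    melts: Mapping[str, pd.Timestamp],
) -> tuple[pd.DataFrame, dict]:
    """Per-plant open-flower censuses on 3–5 day visit intervals.

    Plant *i* begins flowering once accumulated GDD since melt (at the
    site's true threshold temperature) crosses a normal per-plant
    threshold; open-flower counts follow a concave parabola over a normal
    flowering duration, observed only on visit dates.
    """
    rng = _rng(config, "flowering")
    season_end = pd.Timestamp(f"{config.year + 1}-02-28")
    tbase = truth_tbase(config, series, melts)
    records = []
    truth_rows = []
    for site in site_ids(config):
        melt = melts[site]
        frame = series[site].window(melt, season_end)
        inc = gdd_increment(frame["tmax"].to_numpy(), frame["tmin"].to_numpy(), tbase[site])
        cum = np.cumsum(inc)
        dates = frame.index

        visits = []
        day = melt + pd.Timedelta(days=5)
        while day <= season_end:
            visits.append(day)
            day += pd.Timedelta(days=int(rng.integers(3, 6)))

        site_flowered = False
        for p in range(config.n_plants_per_site):
            plant = f"{site}-P{p + 1:03d}"
            threshold = max(10.0, rng.normal(config.gdd_onset_mean, config.gdd_onset_sd))
            duration = max(9.0, rng.normal(config.flowering_duration_mean, config.flowering_duration_sd))
            peak = max(1, int(rng.poisson(config.peak_flowers_mean)))
            pos = int(np.searchsorted(cum, threshold))
            onset = dates[pos] if pos < len(dates) else None
            truth_rows.append(
                {
                    "site": site,
                    "plant": plant,
                    "gdd_threshold": threshold,
                    "onset_date": None if onset is None else str(onset.date()),
                    "duration_days": duration,
                    "peak_flowers": peak,
                }
            )
            for visit in visits:
                if onset is None:
                    count = 0
                else:
                    s = (visit - onset).days / duration
                    count = int(round(4.0 * peak * s * (1.0 - s))) if 0.0 < s < 1.0 else 0
                if count > 0:
                    site_flowered = True
                records.append(
                    {"site": site, "plant": plant, "date": visit, "n_open_flowers": count}
                )
        if not site_flowered:
            logger.warning("site %s: season too short, no plant flowered", site)
            records = [r for r in records if r["site"] != site]
    census = pd.DataFrame(records)
    truth = {"tbase": tbase, "plants": truth_rows}
    return census, truth


def gen_longevity(
    config: SimConfig,
    series: Mapping[str, DailySeries],
    melts: Mapping[str, pd.Timestamp] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Flower-batch longevity and fruit records for both treatments.

    Potential longevity is linear in the mean ambient temperature over a
    flower's realized open days (solved as a fixed point so the measurable
    covariate is also the generative one), floored at 1 day.  Open-arm
    flowers close early when an exponential pollinator arrival (rate
    proportional to warmth above ``t_activity``) beats the potential
    life-span; pollinated flowers form fruit, excluded flowers self at
    ``selfing_rate``.
    """
    rng = _rng(config, "longevity")
    if melts is None:
        melts = true_melt_dates(config)
    rows = []
    latent = []
    for si, site in enumerate(site_ids(config)):
        melt = melts[site]
        # cumulative tmean for O(1) window means in the fixed-point loop
        tmean = series[site].tmean
        origin = tmean.index[0]
        cum = np.concatenate([[0.0], np.cumsum(tmean.to_numpy())])

        def _mean_t(start: pd.Timestamp, n_days: int) -> float:
            p = (start - origin).days
            if p < 0 or p + n_days > len(cum) - 1:
                raise ValueError(f"{site}: open window outside temperature series")
            return (cum[p + n_days] - cum[p]) / n_days

        n_batches = config.batches_per_site[si]
        offsets = np.linspace(50.0, 140.0, n_batches) + rng.uniform(-2.0, 2.0, n_batches)
        for bi in range(n_batches):
            batch = f"{site}-B{bi + 1:02d}"
            bdate = melt + pd.Timedelta(days=int(round(offsets[bi])))
            t_batch = _mean_t(bdate, 3)
            lam = config.visit_rate_per_degree * max(t_batch - config.t_activity, 0.0)
            for treatment, tag in (("excluded", "X"), ("open", "O")):
                for k in range(config.plants_per_arm):
                    plant = f"{batch}-{tag}{k + 1}"
                    plant_re = rng.normal(0.0, config.plant_longevity_sd)
                    soil = float(np.clip(rng.normal(config.soil_mean, config.soil_sd), 0.0, 100.0))
                    for f in range(config.flowers_per_plant):
                        anthesis = bdate + pd.Timedelta(days=int(rng.integers(0, 3)))
                        eps = rng.normal(0.0, config.longevity_noise_sd)
                        arrival = rng.exponential(1.0 / lam) if lam > 0 else np.inf
                        life = 3
                        pfl = afl = np.nan
                        for _ in range(8):
                            t_open = _mean_t(anthesis, life)
                            pfl = max(
                                config.longevity_intercept
                                + config.longevity_temp_slope * t_open
                                + plant_re
                                + eps,
                                1.0,
                            )
                            afl = min(pfl, arrival + config.senescence_lag_days)
                            target = pfl if treatment == "excluded" else afl
                            new_life = max(1, int(np.rint(target)))
                            if new_life == life:
                                break
                            life = new_life
                        if treatment == "excluded":
                            fruit = bool(rng.random() < config.selfing_rate)
                        else:
                            fruit = bool(arrival < pfl)
                        ovules = 2 + int(rng.poisson(max(config.ovule_mean - 2.0, 0.0)))
                        seeds = int(rng.binomial(ovules, config.seed_success)) if fruit else 0
                        rows.append(
                            {
                                "site": site,
                                "batch": batch,
                                "plant": plant,
                                "treatment": treatment,
                                "flower": f"{plant}-F{f + 1}",
                                "anthesis": anthesis,
                                "closure": anthesis + pd.Timedelta(days=life - 1),
                                "diameter_mm": float(rng.normal(config.diameter_mean, config.diameter_sd)),
                                "soil_moisture": soil,
                                "fruit": int(fruit),
                                "seeds": seeds,
                                "ovules": ovules,
                            }
                        )
                        latent.append(
                            {
                                "flower": rows[-1]["flower"],
                                "treatment": treatment,
                                "pfl": float(pfl),
                                "afl": float(afl),
                                "arrival": float(arrival) if np.isfinite(arrival) else None,
                            }
                        )
    flowers = pd.DataFrame(rows)
    truth = {
        "intercept": config.longevity_intercept,
        "temp_slope": config.longevity_temp_slope,
        "visit_rate_per_degree": config.visit_rate_per_degree,
        "t_activity": config.t_activity,
        "flowers": latent,
    }
    return flowers, truth


@dataclasses.dataclass
class GroundTruth:
    """Serializable record of every parameter behind a simulated world."""

    melt_dates: dict
    winter_onset: str
    tbase: dict
    flowering_plants: list
    longevity: dict
    lapse_rate: float
    melt_lag_per_100m: float
    config: dict

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


@dataclasses.dataclass
class SimBundle:
    config: SimConfig
    sites: pd.DataFrame
    temperatures: dict
    snow: dict
    census: pd.DataFrame
    flowers: pd.DataFrame
    station: DailySeries
    loggers: pd.DataFrame
    truth: GroundTruth


def simulate(config: SimConfig) -> SimBundle:
    """Generate the full study bundle: all input tables plus ground truth."""
    temps = gen_temperature(config)
    snow, melts = gen_snowcover(config)
    census, flowering_truth = gen_flowering(config, temps, melts)
    flowers, longevity_truth = gen_longevity(config, temps, melts)
    ids = site_ids(config)

    reference = ids[len(ids) // 2]
    station = DailySeries("station", temps[reference].data + 0.04)

    logger_rows = []
    for site in ids:
        data = temps[site].data
        for date, row in data.iterrows():
            logger_rows.append({"site": site, "timestamp": date + pd.Timedelta(hours=6), "temp": row["tmin"]})
            logger_rows.append({"site": site, "timestamp": date + pd.Timedelta(hours=15), "temp": row["tmax"]})
    loggers = pd.DataFrame(logger_rows)

    sites = pd.DataFrame(
        {"site": ids, "elevation": config.elevations, "n_plants": config.n_plants_per_site}
    )
    longevity_summary = {k: v for k, v in longevity_truth.items() if k != "flowers"}
    truth = GroundTruth(
        melt_dates={s: str(d.date()) for s, d in melts.items()},
        winter_onset=str(winter_onset_date(config).date()),
        tbase=flowering_truth["tbase"],
        flowering_plants=flowering_truth["plants"],
        longevity=longevity_summary,
        lapse_rate=config.lapse_rate,
        melt_lag_per_100m=config.melt_lag_per_100m,
        config=dataclasses.asdict(config),
    )
    return SimBundle(config, sites, temps, snow, census, flowers, station, loggers, truth)


def write_bundle(bundle: SimBundle, outdir) -> dict[str, Path]:
    """Write the bundle as the pipeline's CSV inputs plus ``truth.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["sites"] = outdir / "sites.csv"
    bundle.sites.to_csv(paths["sites"], index=False)

    snow_rows = []
    for site, series in bundle.snow.items():
        for date, value in series.cover.items():
            snow_rows.append({"site": site, "date": date.date(), "percent_cover": value})
    paths["snow"] = outdir / "snowcover.csv"
    pd.DataFrame(snow_rows).to_csv(paths["snow"], index=False)

    station = bundle.station.data.reset_index(names="date")
    station["date"] = station["date"].dt.date
    paths["station"] = outdir / "station.csv"
    station.to_csv(paths["station"], index=False)

    paths["loggers"] = outdir / "loggers.csv"
    bundle.loggers.to_csv(paths["loggers"], index=False)

    census = bundle.census.copy()
    census["date"] = pd.to_datetime(census["date"]).dt.date
    paths["census"] = outdir / "censuses.csv"
    census.to_csv(paths["census"], index=False)

    flowers = bundle.flowers.copy()
    flowers["anthesis"] = pd.to_datetime(flowers["anthesis"]).dt.date
    flowers["closure"] = pd.to_datetime(flowers["closure"]).dt.date
    paths["flowers"] = outdir / "flowers.csv"
    flowers[
        ["site", "plant", "batch", "treatment", "flower", "anthesis", "closure", "diameter_mm", "soil_moisture"]
    ].to_csv(paths["flowers"], index=False)

    paths["fruit"] = outdir / "fruit.csv"
    bundle.flowers[["site", "batch", "treatment", "flower", "fruit", "seeds", "ovules"]].to_csv(
        paths["fruit"], index=False
    )

    paths["truth"] = outdir / "truth.json"
    bundle.truth.to_json(paths["truth"])
    return paths
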