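"""Synthetic multi-city daily series with a known lagged temperature-YLL truth.

The generator emulates the structure the first-stage model assumes: daily
YLL = smooth seasonal baseline + weekly cycle + holiday bumps + a lagged
temperature contribution + Gaussian noise.  The temperature contribution
is ``sum_l w_l * f(temp[t-l])`` where ``f`` is a V-shaped cumulative
excess-YLL curve (distinct cold/heat slopes around a known minimum-YLL
temperature) and the non-negative lag weights ``w_l`` sum to one — the
simplest exposure-lag surface consistent with a DLNM, so recovery targets
are well defined.

Because the truth is known, the module also provides a brute-force oracle
for the attributable fraction: direct daily summation of the noise-free
temperature contribution relative to an all-MMT exposure history, divided
by total simulated YLL.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .life_table import DeathRecord
from .series import CityDailySeries

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_city_series",
    "simulate_multicity",
    "true_attributable_fraction",
    "simulate_death_records",
    "META_PREDICTOR_COLUMNS",
]

META_PREDICTOR_COLUMNS = [
    "longitude",
    "latitude",
    "altitude",
    "pop_density",
    "pop_growth",
    "urbanization",
    "gdp_per_capita",
    "gdp_growth",
    "employment",
    "health_technicians",
    "hospital_beds",
]

# pseudo-holidays: New Year Jan 1-3 plus ten fixed (month, day) dates per year
PSEUDO_HOLIDAYS = [
    (1, 1), (1, 2), (1, 3),
    (2, 15), (2, 16), (2, 17),
    (4, 5), (5, 1), (6, 20),
    (9, 15), (10, 1), (10, 2), (10, 3),
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated city.

    Defaults reproduce the descriptive climate of the study setting: a
    2557-day window (2014-01-01..2020-12-31), daily mean temperature with
    mean ~17.4 degC and SD ~5.5 (annual sinusoid of amplitude 7 degC plus
    AR(1) weather noise), and correlated meteorological covariates.  The
    outcome scale (baseline 150 person-years/day per city) and the V-curve
    slopes are set so that the true attributable fraction is ~7%, split
    ~2:1 cold vs heat as in multi-city YLL analyses of this kind.
    """

    start: str = "2014-01-01"
    end: str = "2020-12-31"
    # temperature process
    temp_mean: float = 17.4
    temp_seasonal_amplitude: float = 7.0
    temp_peak_doy: float = 200.0
    temp_ar_rho: float = 0.7
    temp_ar_sd: float = 1.5
    # covariates
    rh_mean: float = 71.6
    rh_amplitude: float = 8.0
    rh_sd: float = 6.0
    ws_mean: float = 1.8
    ws_sd: float = 0.5
    sunshine_mean: float = 5.7
    sunshine_amplitude: float = 2.0
    sunshine_sd: float = 1.5
    ap_mean: float = 844.4
    ap_amplitude: float = 5.0
    ap_sd: float = 3.0
    # outcome
    baseline: float = 150.0
    baseline_seasonal_amplitude: float = 10.0
    baseline_peak_doy: float = 15.0
    weekly_amplitude: float = 3.0
    holiday_bump: float = 8.0
    noise_sd: float = 15.0
    # true exposure-lag-response
    mmt_true: float = 20.0
    cold_slope: float = 2.2   # person-years per degC below MMT, lag-cumulated
    heat_slope: float = 5.6   # person-years per degC above MMT, lag-cumulated
    kink_halfwidth: float = 3.0  # degC over which the V junction is smoothed
    effect_scale: float = 1.0
    max_lag: int = 21
    lag_decay: float = 5.0    # e-folding of lag weights, days


@dataclass(frozen=True)
class SimulationTruth:
    """Everything needed to evaluate the generator's ground truth."""

    mmt_true: float
    cold_slope: float
    heat_slope: float
    lag_weights: np.ndarray
    noise_sd: float
    temp_history: np.ndarray = field(repr=False)  # burn-in + window temperatures
    n_burn: int = 0
    kink_halfwidth: float = 3.0
    config: SimulationConfig | None = None

    def cumulative_curve(self, x) -> np.ndarray:
        """True lag-cumulated excess YLL at sustained temperature x (0 at MMT).

        V-shaped with distinct asymptotic cold/heat slopes; the junction at
        the MMT is blended quadratically over ``kink_halfwidth`` degC
        (Huber-style), so the curve is C1-smooth like observed
        temperature-mortality curves and lies within reach of the
        first-stage spline family.  ``kink_halfwidth = 0`` gives a hard V.
        """
        x = np.asarray(x, dtype=float)
        d_cold = np.maximum(self.mmt_true - x, 0.0)
        d_heat = np.maximum(x - self.mmt_true, 0.0)
        return self.cold_slope * _huber(d_cold, self.kink_halfwidth) + self.heat_slope * _huber(
            d_heat, self.kink_halfwidth
        )

    def to_dict(self) -> dict:
        d = {
            "mmt_true": self.mmt_true,
            "cold_slope": self.cold_slope,
            "heat_slope": self.heat_slope,
            "lag_weights": [float(w) for w in self.lag_weights],
            "noise_sd": self.noise_sd,
            "n_burn": self.n_burn,
            "kink_halfwidth": self.kink_halfwidth,
            "temp_history": [float(t) for t in self.temp_history],
        }
        if self.config is not None:
            d["config"] = asdict(self.config)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationTruth":
        cfg = SimulationConfig(**d["config"]) if "config" in d else None
        return cls(
            mmt_true=d["mmt_true"],
            cold_slope=d["cold_slope"],
            heat_slope=d["heat_slope"],
            lag_weights=np.asarray(d["lag_weights"], dtype=float),
            noise_sd=d["noise_sd"],
            temp_history=np.asarray(d["temp_history"], dtype=float),
            n_burn=int(d["n_burn"]),
            kink_halfwidth=float(d.get("kink_halfwidth", 0.0)),
            config=cfg,
        )


def _huber(d: np.ndarray, w: float) -> np.ndarray:
    """Quadratic below w, linear (unit slope, continuous derivative) above."""
    if w <= 0:
        return d
    return np.where(d < w, d * d / (2.0 * w), d - w / 2.0)


def _seasonal(doy: np.ndarray, mean: float, amplitude: float, peak_doy: float) -> np.ndarray:
    return mean + amplitude * np.cos(2.0 * np.pi * (doy - peak_doy) / 365.25)


def _holiday_mask(dates: pd.DatetimeIndex) -> np.ndarray:
    md = set(PSEUDO_HOLIDAYS)
    return np.array([(d.month, d.day) in md for d in dates])


def simulate_city_series(
    config: SimulationConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    city_id: str = "city",
) -> tuple[CityDailySeries, SimulationTruth]:
    """Simulate one city's daily series; deterministic in (config, seed).

    Temperature gets a burn-in of ``max_lag`` extra days before the window
    so every in-window day has a complete lag history; the burn-in is kept
    on the truth object so the attributable-fraction oracle can replay the
    exact generative contributions.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    dates = pd.date_range(cfg.start, cfg.end, freq="D")
    n = len(dates)
    L = cfg.max_lag
    if n < 2 * (L + 1):
        raise ValueError(f"window of {n} days is shorter than 2*(max_lag+1)={2 * (L + 1)}")

    full_dates = pd.date_range(dates[0] - pd.Timedelta(days=L), dates[-1], freq="D")
    doy_full = full_dates.dayofyear.to_numpy(dtype=float)

    # temperature: annual sinusoid + stationary AR(1)
    eps = rng.normal(0.0, cfg.temp_ar_sd, n + L)
    ar = np.empty(n + L)
    ar[0] = rng.normal(0.0, cfg.temp_ar_sd / np.sqrt(1.0 - cfg.temp_ar_rho**2))
    for t in range(1, n + L):
        ar[t] = cfg.temp_ar_rho * ar[t - 1] + eps[t]
    temp_full = _seasonal(doy_full, cfg.temp_mean, cfg.temp_seasonal_amplitude, cfg.temp_peak_doy) + ar
    temp = temp_full[L:]

    doy = dates.dayofyear.to_numpy(dtype=float)
    rh = np.clip(
        _seasonal(doy, cfg.rh_mean, cfg.rh_amplitude, cfg.temp_peak_doy) + rng.normal(0, cfg.rh_sd, n),
        0.0,
        100.0,
    )
    ws = np.maximum(rng.normal(cfg.ws_mean, cfg.ws_sd, n), 0.05)
    sunshine = np.clip(
        _seasonal(doy, cfg.sunshine_mean, cfg.sunshine_amplitude, cfg.temp_peak_doy)
        + rng.normal(0, cfg.sunshine_sd, n),
        0.0,
        24.0,
    )
    ap = _seasonal(doy, cfg.ap_mean, cfg.ap_amplitude, cfg.baseline_peak_doy) + rng.normal(
        0, cfg.ap_sd, n
    )

    w = np.exp(-np.arange(L + 1) / cfg.lag_decay)
    w /= w.sum()
    truth = SimulationTruth(
        mmt_true=cfg.mmt_true,
        cold_slope=cfg.cold_slope * cfg.effect_scale,
        heat_slope=cfg.heat_slope * cfg.effect_scale,
        lag_weights=w,
        noise_sd=cfg.noise_sd,
        temp_history=temp_full,
        n_burn=L,
        kink_halfwidth=cfg.kink_halfwidth,
        config=cfg,
    )

    holiday = _holiday_mask(dates)
    dow = dates.dayofweek.to_numpy()
    baseline = (
        _seasonal(doy, cfg.baseline, cfg.baseline_seasonal_amplitude, cfg.baseline_peak_doy)
        + cfg.weekly_amplitude * np.sin(2.0 * np.pi * dow / 7.0)
        + cfg.holiday_bump * holiday
    )
    yll = baseline + _lagged_contribution(truth) + rng.normal(0.0, cfg.noise_sd, n)

    data = pd.DataFrame(
        {
            "yll": yll,
            "temp": temp,
            "rh": rh,
            "ws": ws,
            "sunshine": sunshine,
            "ap": ap,
            "holiday": holiday,
        },
        index=dates,
    )
    return CityDailySeries(city_id=city_id, data=data), truth


def _lagged_contribution(truth: SimulationTruth) -> np.ndarray:
    """Noise-free temperature contribution per in-window day."""
    f = truth.cumulative_curve(truth.temp_history)
    L = truth.n_burn
    n = truth.temp_history.size - L
    out = np.zeros(n)
    for l, w in enumerate(truth.lag_weights):
        out += w * f[L - l : L - l + n]
    return out


def true_attributable_fraction(
    series: CityDailySeries, truth: SimulationTruth
) -> tuple[float, float, float]:
    """Generator-side oracle for (af_total, af_cold, af_heat), as fractions.

    Sums each day's noise-free lagged contribution (zero under an all-MMT
    history, since the curve vanishes at the MMT), split into cold/heat by
    the sign of each lagged temperature's departure from the true MMT, and
    divides by the total simulated YLL.  af_cold + af_heat == af_total
    exactly by construction.
    """
    L = truth.n_burn
    if truth.temp_history.size - L != len(series):
        raise ValueError(
            f"truth covers {truth.temp_history.size - L} days but series has {len(series)}"
        )
    f = truth.cumulative_curve(truth.temp_history)
    cold = truth.temp_history < truth.mmt_true
    n = len(series)
    tot = 0.0
    tot_cold = 0.0
    for l, w in enumerate(truth.lag_weights):
        seg = w * f[L - l : L - l + n]
        tot += seg.sum()
        tot_cold += seg[cold[L - l : L - l + n]].sum()
    denom = float(series.yll.sum())
    if denom <= 0:
        raise ValueError("total simulated YLL is not positive")
    af_cold = tot_cold / denom
    af_heat = (tot - tot_cold) / denom
    return af_cold + af_heat, af_cold, af_heat


def simulate_multicity(
    n_cities: int,
    config: SimulationConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    heterogeneity: float = 0.0,
) -> tuple[list[tuple[CityDailySeries, SimulationTruth]], pd.DataFrame]:
    """Simulate ``n_cities`` cities plus a city-level meta-predictor table.

    ``heterogeneity = 0`` gives a shared truth (identical curve in every
    city).  For ``heterogeneity = h > 0`` each city's curve is scaled by
    ``1 + h * z_i`` where ``z_i`` is that city's standardized urbanization
    rate, so the true effect (and true AF) varies monotonically with the
    generated "urbanization" meta-predictor.
    """
    if n_cities < 1:
        raise ValueError("n_cities must be >= 1")
    cfg = config or SimulationConfig()
    master = np.random.SeedSequence(seed)
    meta_rng = np.random.default_rng(master.spawn(1)[0])
    city_seeds = master.spawn(n_cities)

    meta = pd.DataFrame(
        {
            "longitude": meta_rng.uniform(98.0, 106.0, n_cities),
            "latitude": meta_rng.uniform(21.5, 28.5, n_cities),
            "altitude": meta_rng.uniform(800.0, 2400.0, n_cities),
            "pop_density": meta_rng.uniform(40.0, 700.0, n_cities),
            "pop_growth": meta_rng.uniform(2.0, 9.0, n_cities),
            "urbanization": meta_rng.uniform(30.0, 75.0, n_cities),
            "gdp_per_capita": meta_rng.uniform(20.0, 90.0, n_cities),
            "gdp_growth": meta_rng.uniform(4.0, 11.0, n_cities),
            "employment": meta_rng.uniform(55.0, 75.0, n_cities),
            "health_technicians": meta_rng.uniform(4.0, 9.0, n_cities),
            "hospital_beds": meta_rng.uniform(3.5, 8.0, n_cities),
        },
        index=[f"city{i + 1:02d}" for i in range(n_cities)],
    )
    meta.index.name = "city_id"

    urb = meta["urbanization"].to_numpy()
    if n_cities > 1 and urb.std(ddof=0) > 0:
        z = (urb - urb.mean()) / urb.std(ddof=0)
    else:
        z = np.zeros(n_cities)
    scales = 1.0 + heterogeneity * z
    scales = np.maximum(scales, 0.05)  # keep effects positive

    out = []
    for i, cid in enumerate(meta.index):
        cfg_i = replace(cfg, effect_scale=cfg.effect_scale * float(scales[i]))
        out.append(simulate_city_series(cfg_i, seed=city_seeds[i], city_id=cid))
    return out, meta


def simulate_death_records(
    window,
    mean_deaths_per_day: float = 8.0,
    seed: int = 0,
) -> list[DeathRecord]:
    """Poisson death counts per day with ages ~ N(70, 15) clipped to [0, 100];
    feeds the life-table pathway in end-to-end tests."""
    rng = np.random.default_rng(seed)
    dates = pd.date_range(window[0], window[1], freq="D")
    records = []
    for d in dates:
        for _ in range(rng.poisson(mean_deaths_per_day)):
            age = float(np.clip(rng.normal(70.0, 15.0), 0.0, 100.0))
            sex = "male" if rng.random() < 0.55 else "female"
            records.append(DeathRecord(date=d, age_at_death=age, sex=sex))
    return records
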