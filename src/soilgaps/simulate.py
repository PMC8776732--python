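"""Synthetic microsite soil-moisture generator with known ground truth.

The generator emulates the monitoring design the package targets: a
Mediterranean-semiarid station logging volumetric water content in five
microsites (Stipa and Retama plant patches, open areas with low/medium/high
biocrust cover), three replicate probes per microsite, sub-daily cadence
with a mid-record cadence change, and heavy contiguous missingness from
battery failures and wildlife damage to sensor wires.

The pieces, each driven by its own random stream so changing one mechanism
leaves the others bit-identical:

weather
    Daily rain occurrence follows a two-state Markov chain whose dry-to-wet
    transition probability is modulated by a seasonal sinusoid (wet winters,
    dry summers); wet-day depth is gamma distributed.  Defaults are set so
    the long-run climate matches a semiarid site with ~349 mm mean annual
    rainfall and 15 degC mean temperature.  Temperature, relative humidity
    and solar radiation are seasonal sinusoids plus noise.

truth
    Each microsite's moisture follows a daily bucket model

        theta_{d+1} = theta_d + a * P_d * (1 - theta_d / theta_sat)
                              - k * (theta_d - theta_res)

    clipped to [theta_res, theta_sat]: rain infiltrates with efficiency *a*
    (m3/m3 per mm, damped as the soil saturates) and the soil dries toward
    the residual level at rate *k* (per day).  Plant patches get higher
    infiltration and slower drydown than open biocrust areas.  The daily
    series is interpolated onto the sub-daily logger grid.  Replicates share
    the microsite curve rescaled by a small replicate-specific factor on the
    (theta - theta_res) anomaly, keeping within-microsite sensors exactly
    affine in one another and inside [theta_res, theta_sat].

observation
    I.i.d. Gaussian sensor noise (default sd 0.01 m3/m3, consistent with a
    +/-3% VWC probe accuracy class); per-sensor outages as a Poisson process of
    lognormal-duration blocks (defaults give ~55% missing in long runs); and
    occasional small negative anomalies injected into near-dry readings, the
    signature miscalibration artifact the QC stage removes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import MICROSITES, SensorMeta, build_time_grid, default_network

#: mask codes
OBSERVED, OUTAGE, ANOMALY = 0, 1, 2


@dataclass(frozen=True)
class MicrositeParams:
    """Bucket-model parameters for one microsite.

    a: infiltration gain, (m3/m3) of moisture per mm of rain at dry soil.
    k: drydown rate, per day.
    theta_res / theta_sat: residual and saturation moisture, m3/m3.
    """

    a: float
    k: float
    theta_res: float
    theta_sat: float

    def __post_init__(self) -> None:
        if not (0 <= self.theta_res < self.theta_sat <= 1):
            raise ValueError("require 0 <= theta_res < theta_sat <= 1")
        if self.a <= 0 or self.k <= 0:
            raise ValueError("a and k must be positive")


def default_microsite_params() -> dict[str, MicrositeParams]:
    """Plant patches infiltrate more and dry slower than open biocrust soil."""
    return {
        "Retama": MicrositeParams(a=0.0085, k=0.10, theta_res=0.040, theta_sat=0.45),
        "Stipa": MicrositeParams(a=0.0075, k=0.12, theta_res=0.035, theta_sat=0.42),
        "BSCh": MicrositeParams(a=0.0065, k=0.14, theta_res=0.030, theta_sat=0.40),
        "BSCm": MicrositeParams(a=0.0055, k=0.16, theta_res=0.025, theta_sat=0.38),
        "BSCl": MicrositeParams(a=0.0045, k=0.18, theta_res=0.020, theta_sat=0.36),
    }


@dataclass
class SimConfig:
    """Full parameterization of the synthetic generator.

    Defaults reproduce the monitored period: 120-min cadence from
    2006-11-17, switching to 150-min on 2017-02-01, through 2020-12-16,
    with 3 replicate probes in each of the five microsites.
    """

    start: str = "2006-11-17 00:00"
    end: str = "2020-12-16 23:59"
    cadence_switch: str = "2017-02-01 00:00"
    cadence1: int = 120
    cadence2: int = 150
    n_replicates: int = 3
    microsite_params: dict[str, MicrositeParams] = field(
        default_factory=default_microsite_params
    )
    theta_init_frac: float = 0.25  # initial (theta-theta_res)/(theta_sat-theta_res)
    replicate_spread: float = 0.05  # max relative shrink of the replicate anomaly

    # sensor noise, m3/m3
    noise_sd: float = 0.01

    # daily rain: two-state Markov occurrence with seasonal modulation
    p_ww: float = 0.45  # wet day follows wet day
    p_wd: float = 0.12  # wet day follows dry day (annual mean)
    seasonal_amplitude: float = 0.6  # relative modulation of p_wd, peak in winter
    rain_peak_doy: int = 330  # late-autumn/winter rainfall maximum
    rain_shape: float = 0.7  # gamma shape of wet-day depth
    rain_scale: float = 7.8  # gamma scale, mm

    # temperature / humidity / radiation sinusoids
    temp_mean: float = 15.0  # degC annual mean
    temp_amplitude: float = 9.5  # degC, peak in late July
    temp_peak_doy: int = 203
    temp_noise_sd: float = 2.0
    rh_mean: float = 60.0
    rh_amplitude: float = 18.0  # peaks in winter (opposite phase to temperature)
    rh_noise_sd: float = 8.0
    solar_mean: float = 210.0  # W/m2
    solar_amplitude: float = 130.0  # peak at summer solstice
    solar_peak_doy: int = 172
    solar_noise_sd: float = 30.0

    # missingness: Poisson outage arrivals, lognormal block durations (days)
    outage_rate_per_year: float = 12.0
    outage_log_mean: float = 2.87  # exp(mu + sigma^2/2) ~ 24 days
    outage_log_sd: float = 0.8
    outage_burn_in_days: float = 120.0  # arrivals may start before the record

    # negative anomalies in near-dry readings
    anomaly_prob: float = 0.01
    anomaly_margin: float = 0.015  # only cells with truth < theta_res + margin
    anomaly_max_depth: float = 0.008  # injected values in (-max_depth, 0)

    # validation-pair noise (reference instrument)
    reference_noise_sd: float = 0.01

    seed: int = 0


@dataclass
class SimOutput:
    """Everything one simulation run produces."""

    weather: pd.DataFrame
    truth: pd.DataFrame
    observed: pd.DataFrame
    mask: pd.DataFrame
    meta: list[SensorMeta]


def _streams(config: SimConfig) -> dict[str, np.random.Generator]:
    """Independent child streams per mechanism from the one seed."""
    names = ("weather", "truth", "noise", "outage", "anomaly", "validation")
    children = np.random.SeedSequence(config.seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _doy_cos(dates: pd.DatetimeIndex, peak_doy: float) -> np.ndarray:
    doy = dates.dayofyear.to_numpy(dtype=float)
    return np.cos(2 * np.pi * (doy - peak_doy) / 365.25)


def simulate_weather(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Daily weather over the configured period (one row per calendar day).

    Columns ``tmean`` (degC), ``precip`` (mm), ``rh`` (%), ``solar`` (W/m2),
    indexed by date.  Deterministic for a fixed seed.
    """
    rng = rng if rng is not None else _streams(config)["weather"]
    dates = pd.date_range(
        pd.Timestamp(config.start).normalize(),
        pd.Timestamp(config.end).normalize(),
        freq="D",
    )
    n = len(dates)
    season = _doy_cos(dates, config.rain_peak_doy)
    p_wd = np.clip(config.p_wd * (1.0 + config.seasonal_amplitude * season), 0.0, 1.0)

    wet = np.zeros(n, dtype=bool)
    u = rng.random(n)
    state = False
    for i in range(n):
        p = config.p_ww if state else p_wd[i]
        state = u[i] < p
        wet[i] = state
    depths = rng.gamma(config.rain_shape, config.rain_scale, size=n)
    precip = np.where(wet, depths, 0.0)

    tmean = (
        config.temp_mean
        + config.temp_amplitude * _doy_cos(dates, config.temp_peak_doy)
        + rng.normal(0.0, config.temp_noise_sd, size=n)
    )
    rh = np.clip(
        config.rh_mean
        - config.rh_amplitude * _doy_cos(dates, config.temp_peak_doy)
        + rng.normal(0.0, config.rh_noise_sd, size=n),
        5.0,
        100.0,
    )
    solar = np.clip(
        config.solar_mean
        + config.solar_amplitude * _doy_cos(dates, config.solar_peak_doy)
        + rng.normal(0.0, config.solar_noise_sd, size=n),
        10.0,
        None,
    )
    weather = pd.DataFrame(
        {"tmean": tmean, "precip": precip, "rh": rh, "solar": solar}, index=dates
    )
    weather.index.name = "date"
    return weather


def _bucket_series(precip: np.ndarray, p: MicrositeParams, theta0: float) -> np.ndarray:
    """Daily bucket recursion; returns len(precip)+1 values (day starts)."""
    theta = np.empty(len(precip) + 1)
    theta[0] = np.clip(theta0, p.theta_res, p.theta_sat)
    for d in range(len(precip)):
        nxt = (
            theta[d]
            + p.a * precip[d] * (1.0 - theta[d] / p.theta_sat)
            - p.k * (theta[d] - p.theta_res)
        )
        theta[d + 1] = np.clip(nxt, p.theta_res, p.theta_sat)
    return theta


def simulate_truth(
    weather: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, list[SensorMeta]]:
    """Complete (gap-free) ground-truth table on the logger grid.

    Each microsite's daily bucket trajectory is linearly interpolated onto
    the sub-daily grid; replicate r of a microsite carries
    ``theta_res + f_r * (theta - theta_res)`` with a per-replicate factor
    ``f_r`` drawn once from [1 - replicate_spread, 1], so replicates are
    exactly affine in one another and bounded by [theta_res, theta_sat].
    """
    rng = rng if rng is not None else _streams(config)["truth"]
    grid = build_time_grid(
        config.start, config.end, config.cadence_switch, config.cadence1, config.cadence2
    )
    meta = default_network(config.n_replicates)
    precip = weather["precip"].to_numpy(dtype=float)
    # day-start anchors; one extra day so interpolation covers the grid tail
    anchors = pd.date_range(weather.index[0], periods=len(precip) + 1, freq="D")

    truth = pd.DataFrame(index=grid, columns=[m.sensor_id for m in meta], dtype=float)
    factors = {
        m.sensor_id: 1.0 - config.replicate_spread * rng.random() for m in meta
    }
    for site in MICROSITES:
        p = config.microsite_params[site]
        theta0 = p.theta_res + config.theta_init_frac * (p.theta_sat - p.theta_res)
        daily = _bucket_series(precip, p, theta0)
        base = (
            pd.Series(daily, index=anchors)
            .reindex(anchors.union(grid))
            .interpolate(method="time")
            .reindex(grid)
        )
        for m in meta:
            if m.microsite == site:
                truth[m.sensor_id] = p.theta_res + factors[m.sensor_id] * (
                    base.to_numpy() - p.theta_res
                )
    truth.index.name = "timestamp"
    return truth, meta


def _outage_mask(
    index: pd.DatetimeIndex, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Boolean outage indicator for one sensor on the grid."""
    t0 = index[0] - pd.Timedelta(days=config.outage_burn_in_days)
    span_days = (index[-1] - t0).total_seconds() / 86400.0
    rate_per_day = config.outage_rate_per_year / 365.0
    n_events = rng.poisson(rate_per_day * span_days)
    out = np.zeros(len(index), dtype=bool)
    if n_events == 0:
        return out
    starts_days = np.sort(rng.uniform(0.0, span_days, size=n_events))
    durations = rng.lognormal(config.outage_log_mean, config.outage_log_sd, size=n_events)
    tvals = ((index - t0).total_seconds() / 86400.0).to_numpy()
    for s, d in zip(starts_days, durations):
        out |= (tvals >= s) & (tvals < s + d)
    return out


def observe(
    truth: pd.DataFrame,
    config: SimConfig,
    streams: dict[str, np.random.Generator] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Degrade the truth into what the loggers would record.

    Adds Gaussian sensor noise, blanks outage blocks, and injects small
    negative anomalies into a random subset of near-dry readings.  Returns
    ``(observed, mask)`` where the mask codes each cell OBSERVED (0),
    OUTAGE (1) or ANOMALY (2).
    """
    streams = streams or _streams(config)
    noise_rng, outage_rng, anom_rng = (
        streams["noise"],
        streams["outage"],
        streams["anomaly"],
    )
    observed = truth.copy()
    mask = pd.DataFrame(
        OBSERVED, index=truth.index, columns=truth.columns, dtype=np.int8
    )
    if config.noise_sd > 0:
        observed += noise_rng.normal(0.0, config.noise_sd, size=truth.shape)
    for col in truth.columns:
        out = _outage_mask(truth.index, config, outage_rng)
        observed.loc[out, col] = np.nan
        mask.loc[out, col] = OUTAGE

        site = col.rsplit("_", 1)[0]
        p = config.microsite_params[site]
        near_dry = (
            (~out)
            & (truth[col].to_numpy() < p.theta_res + config.anomaly_margin)
            & (anom_rng.random(len(truth)) < config.anomaly_prob)
        )
        if near_dry.any():
            observed.loc[near_dry, col] = -anom_rng.uniform(
                1e-4, config.anomaly_max_depth, size=int(near_dry.sum())
            )
            mask.loc[near_dry, col] = ANOMALY
    return observed, mask


def simulate_dataset(config: SimConfig | None = None) -> SimOutput:
    """Run the full generator: weather -> truth -> observed records."""
    config = config or SimConfig()
    streams = _streams(config)
    weather = simulate_weather(config, streams["weather"])
    truth, meta = simulate_truth(weather, config, streams["truth"])
    observed, mask = observe(truth, config, streams)
    return SimOutput(weather=weather, truth=truth, observed=observed, mask=mask, meta=meta)


def make_validation_pairs(
    truth: pd.DataFrame,
    config: SimConfig,
    n_pairs: int,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Synthetic paired sensor/reference measurements for the validation stage.

    Samples random (timestamp, microsite) combinations; the sensor value is
    the microsite replicate mean plus sensor noise, the reference value the
    same underlying truth plus reference-instrument noise, both clipped to
    [0, 1].  Returns columns ``date, microsite, sensor_vwc, reference_vwc``.
    """
    if n_pairs < 3:
        raise ValueError(f"need n_pairs >= 3, got {n_pairs}")
    rng = rng if rng is not None else _streams(config)["validation"]
    sites = [c.rsplit("_", 1)[0] for c in truth.columns]
    rows = []
    for _ in range(n_pairs):
        i = int(rng.integers(len(truth.index)))
        site = MICROSITES[int(rng.integers(len(MICROSITES)))]
        cols = [c for c, s in zip(truth.columns, sites) if s == site]
        base = float(truth.iloc[i][cols].mean())
        rows.append(
            {
                "date": truth.index[i],
                "microsite": site,
                "sensor_vwc": float(
                    np.clip(base + rng.normal(0.0, config.noise_sd), 0.0, 1.0)
                ),
                "reference_vwc": float(
                    np.clip(base + rng.normal(0.0, config.reference_noise_sd), 0.0, 1.0)
                ),
            }
        )
    return pd.DataFrame(rows)
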