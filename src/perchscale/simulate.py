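"""Synthetic perch-scale signal generator with ground-truth annotations.

The generator emits the 1 Hz gram-valued stream the acquisition software
would log, reproducing the signal classes seen on a real perch-scale:

* **baseline** readings in the 0–1 g range while the perch is unoccupied
  (the dominant class in raw data);
* an **on-perch band** at the bird's true mass (15–25 g for canaries)
  plus Gaussian sensor jitter (SD ~0.04–0.08 g);
* **wing-flap transients** (0–5 g), **partial-perching plateaus**
  (5–15 g, stable but misleading), and rare **impact spikes** (>30 g)
  from the bird flying onto the perch;
* an optional multiplicative **calibration bias** applied to every
  emitted value, emulating a mis-calibrated channel.

The true-mass trajectory follows the documented biology: the bird is
heaviest in the late afternoon / at first evening perching, loses mass
linearly through the dark period (0.2–0.5 % of body weight per hour),
and regains it during the day — a fast post-fasting regain in the
morning, a midday plateau at the daily mean, and a late-afternoon rise
back to the evening maximum.  Nightly perch use is a single
lights-off→lights-on roost occurring with probability ``roost_prob``;
daytime use is an alternating renewal process with log-normal bout
lengths.

Every stream is exactly reproducible from its seed, and every emitted
second carries a ground-truth state label so downstream filtering and
estimation can be scored without animal data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date as Date
from typing import Mapping

import numpy as np
import pandas as pd

from .calibration import LOAD_CELL_CAPACITY_G
from .io import LightSchedule

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_recording",
    "simulate_inert_object",
    "simulate_overnight_session",
    "simulate_experiment",
    "manual_weights_from_truth",
]

#: Ground-truth occupancy states.
STATES = ("off", "perched", "partial", "flap", "impact")


@dataclass(frozen=True)
class SimulationConfig:
    """Generative settings for one bird's recording.

    The defaults describe a healthy lab canary: 20 g body mass in the
    middle of the species' 15–25 g range, a ~5 % diurnal fluctuation
    realised as a linear overnight decline over a 12 h dark period
    (equivalent to ~0.42 % of body weight per hour, inside the observed
    0.2–0.5 %/h range) with full regain the next day, and sensor jitter
    of 0.06 g (mid-range of the device's 0.04–0.08 g repeatability).
    """

    bird_id: str = "bird1"
    base_weight: float = 20.0            # g; daily-mean body mass
    days: int = 10
    start: str = "2024-03-01"            # midnight local time, day 0
    schedule: LightSchedule = field(
        default_factory=lambda: LightSchedule.from_strings("19:00", "07:00")
    )
    #: fraction of body weight lost per hour of darkness; None derives it
    #: from ``diurnal_amplitude`` spread over the night.
    overnight_loss_rate: float | None = None
    diurnal_amplitude: float = 0.05      # peak-to-trough, fraction of body weight
    day_regain: bool = True              # regain the overnight loss next day
    morning_regain_h: float = 2.0        # fast post-fasting regain
    evening_rise_h: float = 2.0          # late-afternoon rise to evening max
    #: SD of the day-to-day random-walk drift of the daily mean mass,
    #: as a fraction of body weight (slow trends across the recording).
    day_to_day_sd: float = 0.01
    roost_prob: float = 0.4              # P(full overnight roost on the scale)
    day_occupancy: float = 0.3           # long-run perched fraction in daytime
    bout_mean_s: float = 300.0           # log-normal daytime bout length
    bout_sd_s: float = 300.0
    sensor_jitter_sd: float = 0.06       # g
    baseline_range: tuple[float, float] = (0.0, 1.0)   # g, off-perch readings
    flap_rate_per_h: float = 6.0
    flap_range: tuple[float, float] = (0.0, 5.0)       # g
    flap_max_s: int = 3
    partial_rate_per_h: float = 1.0
    partial_range: tuple[float, float] = (5.0, 15.0)   # g
    partial_mean_s: float = 30.0
    impact_rate_per_day: float = 5.0
    impact_range: tuple[float, float] = (30.0, 100.0)  # g
    calibration_bias: float = 1.0        # multiplies every emitted value
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_weight <= 0:
            raise ValueError("base_weight must be positive")
        if self.days <= 0:
            raise ValueError("days must be positive")
        for name in ("roost_prob", "day_occupancy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("flap_rate_per_h", "partial_rate_per_h", "impact_rate_per_day",
                     "sensor_jitter_sd", "bout_mean_s", "day_to_day_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.overnight_loss_rate is not None and self.overnight_loss_rate < 0:
            raise ValueError("overnight_loss_rate must be non-negative")
        if self.schedule.night_hours <= 0:
            raise ValueError("light schedule must define a nonempty night")
        if not (self.schedule.lights_on < self.schedule.lights_off):
            raise ValueError("night must span midnight (lights_off after lights_on)")

    @property
    def loss_rate(self) -> float:
        """Effective overnight loss rate, fraction of body weight per hour."""
        if self.overnight_loss_rate is not None:
            return self.overnight_loss_rate
        return self.diurnal_amplitude / self.schedule.night_hours


@dataclass
class GroundTruth:
    """Simulator oracle: what the signal actually encoded.

    ``per_second`` has one row per emitted sample (timestamp, true_mass,
    state); ``nightly`` one row per night (night_date = evening date,
    roosted, slope_g_per_h); ``daily`` one row per calendar day with the
    true mean daytime (lights-on interval) mass and the true mean mass
    over that day's perched seconds.
    """

    per_second: pd.DataFrame
    nightly: pd.DataFrame
    daily: pd.DataFrame


def _clock_seconds(t) -> int:
    return t.hour * 3600 + t.minute * 60 + t.second


def _true_mass_trajectory(cfg: SimulationConfig, n: int) -> np.ndarray:
    """Piecewise-linear true mass for each of *n* seconds from midnight."""
    sod = np.arange(n, dtype=np.int64) % 86400
    base = cfg.base_weight
    night_h = cfg.schedule.night_hours
    rate_g = cfg.loss_rate * base                 # g per hour of darkness
    loss = rate_g * night_h                       # total overnight loss, g
    l_on = _clock_seconds(cfg.schedule.lights_on)
    l_off = _clock_seconds(cfg.schedule.lights_off)
    peak = base + loss / 2.0                      # evening maximum

    night = (sod >= l_off) | (sod < l_on)
    if not cfg.day_regain:
        # cumulative decline: lose mass each dark second, hold flat by day
        dark_h = np.cumsum(night) / 3600.0
        return peak - rate_g * dark_h

    mass = np.full(n, base, dtype=float)
    # evening portion of the night (lights_off → midnight)
    sel = sod >= l_off
    mass[sel] = peak - rate_g * (sod[sel] - l_off) / 3600.0
    # morning portion (midnight → lights_on); darkness began the prior evening
    sel = sod < l_on
    mass[sel] = peak - rate_g * (sod[sel] + 86400 - l_off) / 3600.0
    # fast morning regain of half the loss, back to the daily mean
    r1 = int(cfg.morning_regain_h * 3600)
    if r1 > 0:
        sel = (sod >= l_on) & (sod < l_on + r1)
        frac = (sod[sel] - l_on) / r1
        mass[sel] = (base - loss / 2.0) + frac * (loss / 2.0)
    # late-afternoon rise to the evening maximum
    r2 = int(cfg.evening_rise_h * 3600)
    if r2 > 0:
        sel = (sod >= l_off - r2) & (sod < l_off)
        frac = (sod[sel] - (l_off - r2)) / r2
        mass[sel] = base + frac * (loss / 2.0)
    return mass


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def simulate_recording(cfg: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one bird's 1 Hz stream plus its ground truth.

    Returns ``(samples, truth)`` where ``samples`` has columns
    ``[timestamp, weight]`` (grams, including sensor noise, artifacts and
    calibration bias) and ``truth`` is a :class:`GroundTruth`.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.days * 86400
    t0 = pd.Timestamp(cfg.start)
    mass = _true_mass_trajectory(cfg, n)
    if cfg.day_to_day_sd > 0:
        # slow random-walk drift of the daily mean, anchored at each noon
        # and interpolated through the day so overnight declines stay smooth
        innovations = rng.normal(0.0, cfg.day_to_day_sd, size=cfg.days)
        anchors = np.concatenate(([0.0], np.cumsum(innovations)[:-1]))
        noons = np.arange(cfg.days) * 86400.0 + 12 * 3600.0
        drift = np.interp(np.arange(n, dtype=float), noons, anchors)
        mass = mass * (1.0 + drift)

    l_on = _clock_seconds(cfg.schedule.lights_on)
    l_off = _clock_seconds(cfg.schedule.lights_off)

    # --- occupancy -------------------------------------------------------
    perched = np.zeros(n, dtype=bool)
    night_dates: list[Date] = []
    roosted: list[bool] = []
    # night d spans lights_off of day d to lights_on of day d+1; d = -1 is
    # the partial night the recording starts in
    for d in range(-1, cfg.days):
        roost = bool(rng.random() < cfg.roost_prob)
        start = max(d * 86400 + l_off, 0)
        end = min((d + 1) * 86400 + l_on, n)
        if roost and start < end:
            perched[start:end] = True
        night_dates.append((t0 + pd.Timedelta(days=d)).date())
        roosted.append(roost)

    # daytime bouts: alternating renewal with log-normal on-times and
    # exponential off-times tuned to the target occupancy fraction
    p = cfg.day_occupancy
    if p > 0 and cfg.bout_mean_s > 0:
        mu, sigma = _lognormal_params(cfg.bout_mean_s, max(cfg.bout_sd_s, 1e-9))
        off_mean = cfg.bout_mean_s * (1.0 - p) / p if p < 1 else 0.0
        for d in range(cfg.days):
            lo, hi = d * 86400 + l_on, d * 86400 + l_off
            cur = lo + (rng.exponential(off_mean) if off_mean > 0 else 0.0)
            while cur < hi:
                bout = rng.lognormal(mu, sigma)
                perched[int(cur):min(int(cur + bout), hi)] = True
                cur += bout + (rng.exponential(off_mean) if off_mean > 0 else 1.0)

    state = np.zeros(n, dtype=np.int8)            # 0 = off
    state[perched] = 1                            # perched

    # --- artifacts -------------------------------------------------------
    values = np.empty(n, dtype=float)
    hours = cfg.days * 24.0

    sod_all = np.arange(n, dtype=np.int64) % 86400
    daytime_seconds = np.flatnonzero((sod_all >= l_on) & (sod_all < l_off))

    def _event_seconds(n_events: int, mean_dur: float, sd_dur: float,
                       daytime_only: bool = False) -> list[np.ndarray]:
        spans = []
        if n_events > 0:
            pool = daytime_seconds if daytime_only else n
            starts = rng.choice(pool, size=n_events) if daytime_only \
                else rng.integers(0, n, size=n_events)
            if sd_dur > 0:
                mu_d, sg_d = _lognormal_params(mean_dur, sd_dur)
                durs = np.maximum(1, rng.lognormal(mu_d, sg_d, size=n_events)).astype(int)
            else:
                durs = np.full(n_events, max(int(mean_dur), 1))
            for s, dur in zip(starts, durs):
                spans.append(np.arange(s, min(s + dur, n)))
        return spans

    # wing flaps: short transients while off the perch
    for span in _event_seconds(rng.poisson(cfg.flap_rate_per_h * hours),
                               (1 + cfg.flap_max_s) / 2.0, 1.0):
        sel = span[state[span] == 0]
        state[sel] = 3
        values[sel] = rng.uniform(*cfg.flap_range, size=sel.size)
    # partial perching: stable plateaus at a misleading value
    for span in _event_seconds(rng.poisson(cfg.partial_rate_per_h * hours),
                               cfg.partial_mean_s, cfg.partial_mean_s):
        sel = span[state[span] == 0]
        level = rng.uniform(*cfg.partial_range)
        state[sel] = 2
        values[sel] = level + rng.normal(0.0, cfg.sensor_jitter_sd, size=sel.size)
    # impacts: 1-2 s unrealistically high spikes from the bird flying onto
    # the perch; a daytime event, may interrupt a perched bout
    for span in _event_seconds(rng.poisson(cfg.impact_rate_per_day * cfg.days),
                               1.5, 0.5, daytime_only=True):
        state[span] = 4
        values[span] = rng.uniform(*cfg.impact_range, size=span.size)

    off = state == 0
    values[off] = rng.uniform(*cfg.baseline_range, size=int(off.sum()))
    on = state == 1
    values[on] = mass[on] + (
        rng.normal(0.0, cfg.sensor_jitter_sd, size=int(on.sum()))
        if cfg.sensor_jitter_sd > 0 else 0.0
    )

    timestamps = t0 + pd.to_timedelta(np.arange(n), unit="s")
    samples = pd.DataFrame(
        {"timestamp": timestamps, "weight": cfg.calibration_bias * values}
    )

    per_second = pd.DataFrame(
        {
            "timestamp": timestamps,
            "true_mass": mass,
            "state": pd.Categorical.from_codes(state, categories=list(STATES)),
        }
    )
    nightly = pd.DataFrame(
        {
            "night_date": night_dates,
            "roosted": roosted,
            "slope_g_per_h": -cfg.loss_rate * cfg.base_weight,
        }
    )
    day_idx = np.arange(n) // 86400
    sod = np.arange(n) % 86400
    daytime = (sod >= l_on) & (sod < l_off)
    daily_rows = []
    for d in range(cfg.days):
        sel_day = day_idx == d
        sel_perch = sel_day & (state == 1)
        daily_rows.append(
            {
                "date": (t0 + pd.Timedelta(days=d)).date(),
                "true_daytime_mean": float(mass[sel_day & daytime].mean()),
                "true_perched_mean": float(mass[sel_perch].mean())
                if sel_perch.any() else np.nan,
            }
        )
    truth = GroundTruth(per_second=per_second, nightly=nightly,
                        daily=pd.DataFrame(daily_rows))
    return samples, truth


def simulate_inert_object(
    mass_g: float,
    duration_s: int = 86400,
    jitter_sd: float = 0.06,
    seed: int = 0,
    start: str = "2024-03-01",
) -> pd.DataFrame:
    """Constant mass plus sensor jitter: the inert-object control protocol."""
    if not 0 < mass_g <= LOAD_CELL_CAPACITY_G:
        raise ValueError(
            f"mass_g must be in (0, {LOAD_CELL_CAPACITY_G}] g, got {mass_g}"
        )
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, jitter_sd, size=duration_s) if jitter_sd > 0 else 0.0
    return pd.DataFrame(
        {
            "timestamp": pd.Timestamp(start) + pd.to_timedelta(np.arange(duration_s), unit="s"),
            "weight": mass_g + noise,
        }
    )


def simulate_overnight_session(
    start_weight_g: float,
    slope_g_per_h: float,
    duration_h: float,
    jitter_sd: float = 0.0,
    seed: int = 0,
    start: str = "2024-03-01 19:00:00",
) -> pd.DataFrame:
    """Perched samples along ``w(t) = start_weight - slope * t`` at 1 Hz.

    ``slope_g_per_h`` is the loss rate (positive = losing mass); samples
    cover t = 0 .. duration_h inclusive.
    """
    if duration_h <= 0:
        raise ValueError("duration_h must be positive")
    n = int(round(duration_h * 3600)) + 1
    t_h = np.arange(n) / 3600.0
    rng = np.random.default_rng(seed)
    w = start_weight_g - slope_g_per_h * t_h
    if jitter_sd > 0:
        w = w + rng.normal(0.0, jitter_sd, size=n)
    return pd.DataFrame(
        {
            "timestamp": pd.Timestamp(start) + pd.to_timedelta(np.arange(n), unit="s"),
            "weight": w,
        }
    )


def manual_weights_from_truth(
    truth: GroundTruth, bird_id: str, at: str = "15:00:00"
) -> pd.DataFrame:
    """Daily manual weighings derived from ground truth.

    The manual weight for a day is the true mass at the weighing time
    (afternoon by default, matching a 2–4 PM handling routine); the
    laboratory balance is treated as exact, and is unaffected by any
    perch-scale calibration bias.
    """
    ps = truth.per_second
    tod = ps["timestamp"].dt.strftime("%H:%M:%S")
    sel = ps[tod == at]
    return pd.DataFrame(
        {
            "bird_id": bird_id,
            "date": sel["timestamp"].dt.date.to_numpy(),
            "grams": sel["true_mass"].to_numpy(),
        }
    )


def simulate_experiment(
    n_birds: int = 6,
    days: int = 10,
    seed: int = 0,
    biased_bird_index: int | None = None,
    calibration_bias: float = 1.1,
    base_weight_range: tuple[float, float] = (15.0, 25.0),
    loss_rate_range: tuple[float, float] = (0.002, 0.005),
    **overrides,
) -> tuple[dict[str, pd.DataFrame], dict[str, GroundTruth], pd.DataFrame]:
    """Simulate a multi-bird monitoring experiment with daily manual weights.

    Body masses are drawn uniformly from the canary range and per-bird
    overnight loss rates from the observed 0.2–0.5 %/h range.  At most
    one bird can carry a mis-calibrated perch-scale
    (``biased_bird_index``/``calibration_bias``).  Extra keyword
    arguments override :class:`SimulationConfig` fields for every bird.

    Returns ``(samples_by_bird, truth_by_bird, manual_weights)``.
    """
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_birds)
    bases = rng.uniform(*base_weight_range, size=n_birds)
    rates = rng.uniform(*loss_rate_range, size=n_birds)

    samples_by_bird: dict[str, pd.DataFrame] = {}
    truth_by_bird: dict[str, GroundTruth] = {}
    manual_frames = []
    for i in range(n_birds):
        bird = f"bird{i + 1}"
        cfg = SimulationConfig(
            bird_id=bird,
            base_weight=float(bases[i]),
            overnight_loss_rate=float(rates[i]),
            days=days,
            calibration_bias=calibration_bias if i == biased_bird_index else 1.0,
            seed=int(child_seeds[i]),
            **overrides,
        )
        samples, truth = simulate_recording(cfg)
        samples_by_bird[bird] = samples
        truth_by_bird[bird] = truth
        manual_frames.append(manual_weights_from_truth(truth, bird))
    manual = pd.concat(manual_frames, ignore_index=True)
    return samples_by_bird, truth_by_bird, manual
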