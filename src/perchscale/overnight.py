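"""Overnight perched sessions and weight-loss regression.

Birds that roost on the perch-scale through the dark period produce an
uninterrupted run of on-perch samples along which body mass declines
approximately linearly (typically 0.2–0.5 % of body weight per hour).
This module finds those runs, fits an ordinary least-squares line of
weight on elapsed hours to each, drops the sessions that show no loss
(non-negative slope), and summarises loss rates across sessions and
birds.

A *session* is the longest run of above-baseline samples (internal gaps
≤ ``max_gap_s``) that overlaps a night's dark interval, searched inside
the dark interval extended one hour on each side so the first evening
perch is captured; at most one session is kept per bird per night.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date, datetime, timedelta
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import LightSchedule, get_logger

__all__ = [
    "OvernightSession",
    "OvernightSummary",
    "detect_sessions",
    "fit_session",
    "classify_sessions",
    "global_summary",
]

log = get_logger("overnight")

#: How far beyond the dark interval a session may extend (h).
SESSION_CONTEXT_H = 1.0


@dataclass
class OvernightSession:
    """One contiguous perched night, before or after fitting."""

    bird_id: str
    night_date: Date                      # date of the evening the night began
    start: pd.Timestamp
    end: pd.Timestamp
    samples: pd.DataFrame = field(repr=False)
    # fitted fields
    slope: float | None = None            # g/h, signed (negative = losing)
    intercept: float | None = None        # g, at session start
    r_squared: float | None = None
    mean_weight: float | None = None      # g, over the perched period
    total_loss: float | None = None       # g, -slope * duration when losing
    loss_fraction_per_h: float | None = None       # |slope| / reference
    loss_fraction_per_h_mean: float | None = None  # |slope| / mean_weight
    exclusion_reason: str | None = None

    @property
    def duration_h(self) -> float:
        return (self.end - self.start).total_seconds() / 3600.0

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def _runs(timestamps: np.ndarray, max_gap_s: float) -> list[slice]:
    """Slices of maximal runs with consecutive gaps ≤ max_gap_s."""
    if len(timestamps) == 0:
        return []
    gaps = np.diff(timestamps).astype("timedelta64[s]").astype(float)
    breaks = np.flatnonzero(gaps > max_gap_s) + 1
    edges = np.concatenate(([0], breaks, [len(timestamps)]))
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


def detect_sessions(
    samples: pd.DataFrame,
    schedule: LightSchedule,
    bird_id: str = "",
    min_duration_h: float = 4.0,
    max_gap_s: float = 5.0,
    baseline_cutoff: float = 1.0,
) -> list[OvernightSession]:
    """Find at most one overnight perched session per night.

    ``samples`` is one bird's stream; baseline readings are removed here
    (cutoff inclusive) so interleaved off-perch seconds outside the
    night window never affect detection.
    """
    if samples.empty:
        return []
    perched = samples[samples["weight"] > baseline_cutoff]
    if perched.empty:
        return []
    ts_all = pd.DatetimeIndex(perched["timestamp"])
    first_day = ts_all.min().date() - timedelta(days=1)
    last_day = ts_all.max().date()
    context = timedelta(hours=SESSION_CONTEXT_H)

    sessions: list[OvernightSession] = []
    day = first_day
    while day <= last_day:
        dark_start = pd.Timestamp(datetime.combine(day, schedule.lights_off))
        on_day = day if schedule.lights_on > schedule.lights_off else day + timedelta(days=1)
        dark_end = pd.Timestamp(datetime.combine(on_day, schedule.lights_on))
        window = perched[
            (perched["timestamp"] >= dark_start - context)
            & (perched["timestamp"] <= dark_end + context)
        ].reset_index(drop=True)
        best = None
        for run in _runs(window["timestamp"].to_numpy(), max_gap_s):
            seg = window.iloc[run]
            start, end = seg["timestamp"].iloc[0], seg["timestamp"].iloc[-1]
            if end <= dark_start or start >= dark_end:
                continue  # run never overlaps the dark interval
            duration_h = (end - start).total_seconds() / 3600.0
            if duration_h < min_duration_h:
                continue
            if best is None or duration_h > best[0]:
                best = (duration_h, seg, start, end)
        if best is not None:
            _, seg, start, end = best
            sessions.append(
                OvernightSession(
                    bird_id=bird_id,
                    night_date=day,
                    start=start,
                    end=end,
                    samples=seg.reset_index(drop=True),
                )
            )
        day += timedelta(days=1)
    return sessions


def fit_session(
    session: OvernightSession, reference_g: float | None = None
) -> OvernightSession:
    """OLS fit of weight on elapsed hours; fills the session in place.

    ``total_loss`` is the loss implied by the fitted line over the
    session (zero when the slope is non-negative).  The hourly loss
    fraction is reported against both the external reference weight
    (manual weighing, when available) and the session's own mean weight,
    since either normalisation is defensible.
    """
    ts = session.samples["timestamp"]
    w = session.samples["weight"].to_numpy(dtype=float)
    t_h = (ts - ts.iloc[0]).dt.total_seconds().to_numpy() / 3600.0
    if len(np.unique(t_h)) < 2:
        raise ValueError("session needs at least two distinct timestamps")
    fit = stats.linregress(t_h, w)
    session.slope = float(fit.slope)
    session.intercept = float(fit.intercept)
    session.r_squared = float(fit.rvalue**2)
    session.mean_weight = float(w.mean())
    duration = session.duration_h
    session.total_loss = float(-fit.slope * duration) if fit.slope < 0 else 0.0
    denom_mean = session.mean_weight
    session.loss_fraction_per_h_mean = abs(session.slope) / denom_mean
    denom = reference_g if reference_g is not None else denom_mean
    session.loss_fraction_per_h = abs(session.slope) / denom
    return session


def classify_sessions(
    sessions: Sequence[OvernightSession],
) -> tuple[list[OvernightSession], list[OvernightSession]]:
    """Partition fitted sessions into (weight-loss, excluded).

    Sessions whose fitted slope is not negative did not exhibit weight
    loss and are excluded, with the reason recorded on the session.
    Fit instability (low r²) is reported but never used to exclude.
    """
    kept, excluded = [], []
    for s in sessions:
        if s.slope is None:
            raise ValueError("classify_sessions requires fitted sessions")
        if s.slope < 0:
            kept.append(s)
        else:
            s.exclusion_reason = f"no weight loss (slope {s.slope:+.4f} g/h)"
            excluded.append(s)
    return kept, excluded


@dataclass
class OvernightSummary:
    n_sessions: int
    mean_loss_g_per_h: float      # mean |slope| across sessions, unweighted
    sd_loss_g_per_h: float
    per_bird: pd.DataFrame        # bird_id, n, mean loss g/h and fraction/h


def global_summary(sessions: Sequence[OvernightSession]) -> OvernightSummary:
    """Unweighted mean and SD of |slope| across weight-loss sessions."""
    if not sessions:
        raise ValueError("global_summary requires at least one session")
    rows = [
        {
            "bird_id": s.bird_id,
            "loss_g_per_h": abs(s.slope),
            "loss_fraction_per_h": s.loss_fraction_per_h,
        }
        for s in sessions
    ]
    df = pd.DataFrame(rows)
    per_bird = (
        df.groupby("bird_id")
        .agg(
            n=("loss_g_per_h", "size"),
            mean_loss_g_per_h=("loss_g_per_h", "mean"),
            mean_loss_fraction_per_h=("loss_fraction_per_h", "mean"),
        )
        .reset_index()
    )
    losses = df["loss_g_per_h"].to_numpy()
    return OvernightSummary(
        n_sessions=len(sessions),
        mean_loss_g_per_h=float(losses.mean()),
        sd_loss_g_per_h=float(losses.std(ddof=1)) if len(losses) > 1 else 0.0,
        per_bird=per_bird,
    )


def sessions_table(sessions: Sequence[OvernightSession]) -> pd.DataFrame:
    """Flat per-session table for reporting/CSV output."""
    return pd.DataFrame(
        [
            {
                "bird_id": s.bird_id,
                "night_date": s.night_date,
                "start": s.start,
                "end": s.end,
                "duration_h": s.duration_h,
                "n_samples": s.n_samples,
                "slope_g_per_h": s.slope,
                "intercept_g": s.intercept,
                "r_squared": s.r_squared,
                "mean_weight_g": s.mean_weight,
                "total_loss_g": s.total_loss,
                "loss_fraction_per_h": s.loss_fraction_per_h,
                "loss_fraction_per_h_mean": s.loss_fraction_per_h_mean,
                "excluded": s.exclusion_reason,
            }
            for s in sessions
        ]
    )
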