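"""Filtering and daily weight estimation from raw perch-scale streams.

The raw 1 Hz stream is dominated by near-zero baseline readings from the
unoccupied perch, with additional artifacts (wing-flap transients,
partial-perching plateaus, impact spikes).  Two filters isolate the
on-perch band:

1. **baseline cutoff** — remove every reading ≤ 1 g (inclusive, so a
   reading of exactly 1 g, ambiguous between classes, never enters an
   estimate);
2. **reference band** — remove readings outside ±30 % of the bird's
   manually measured weight.  The 30 % combines the 20 % humane-endpoint
   threshold with a 10 % allowance for device bias, so genuine welfare
   red flags are never filtered away.

Two daily estimators then summarise the filtered day:

* the **daily mode** — centre of the most populated 0.01 g histogram
  bin, a fast frequency-based estimate;
* the **daily stable estimate** — mean of all *stable estimates*, where
  a stable estimate is the mean of a 10-sample rolling window whose
  sample SD is at most 9 % of the reference weight.  Windows are never
  allowed to span acquisition gaps longer than 2 s, so a "10-sample ≈
  10-second" window always describes a contiguous perched stretch.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import get_logger

__all__ = [
    "HUMANE_ENDPOINT_FRACTION",
    "DEVICE_BIAS_ALLOWANCE",
    "FilterParams",
    "StableParams",
    "filter_baseline",
    "filter_band",
    "daily_mode",
    "stable_windows",
    "daily_stable_estimate",
    "moving_average",
    "daily_estimates",
]

log = get_logger("estimate")

#: Welfare red flag: loss of 20 % or more from baseline body weight.
HUMANE_ENDPOINT_FRACTION = 0.20
#: Allowance for systematic measurement bias of the device.
DEVICE_BIAS_ALLOWANCE = 0.10


@dataclass(frozen=True)
class FilterParams:
    """Baseline cutoff (g) and reference-band half-width (fraction)."""

    baseline_cutoff: float = 1.0
    band_fraction: float = HUMANE_ENDPOINT_FRACTION + DEVICE_BIAS_ALLOWANCE

    def __post_init__(self) -> None:
        if self.baseline_cutoff < 0:
            raise ValueError("baseline_cutoff must be >= 0")
        if not 0.0 < self.band_fraction < 1.0:
            raise ValueError("band_fraction must be in (0, 1)")


@dataclass(frozen=True)
class StableParams:
    """Rolling-window settings for stable-estimate extraction."""

    window_len: int = 10          # samples (~seconds at 1 Hz)
    sd_fraction: float = 0.09     # window SD bound, fraction of reference
    smoothing_window: int = 100   # samples, for moving-average display
    max_gap_s: float = 2.0        # windows never span gaps longer than this

    def __post_init__(self) -> None:
        if self.window_len < 2:
            raise ValueError("window_len must be >= 2")
        if self.sd_fraction <= 0:
            raise ValueError("sd_fraction must be > 0")
        if self.smoothing_window < 1:
            raise ValueError("smoothing_window must be >= 1")


def filter_baseline(
    samples: pd.DataFrame, params: FilterParams = FilterParams()
) -> tuple[pd.DataFrame, int]:
    """Drop off-perch baseline readings (weight ≤ cutoff, inclusive).

    Returns ``(kept, n_removed)``; kept + removed always equals the
    input count.
    """
    keep = samples["weight"] > params.baseline_cutoff
    kept = samples[keep].reset_index(drop=True)
    return kept, int((~keep).sum())


def filter_band(
    samples: pd.DataFrame,
    reference_g: float,
    params: FilterParams = FilterParams(),
) -> tuple[pd.DataFrame, int]:
    """Keep readings within ±band_fraction of the reference weight.

    Boundaries are inclusive, so the kept set is closed and boundary
    jitter is deterministic.
    """
    if reference_g <= 0:
        raise ValueError("reference_g must be positive")
    lo = reference_g * (1.0 - params.band_fraction)
    hi = reference_g * (1.0 + params.band_fraction)
    keep = (samples["weight"] >= lo) & (samples["weight"] <= hi)
    kept = samples[keep].reset_index(drop=True)
    return kept, int((~keep).sum())


def daily_mode(weights: Iterable[float], bin_width_g: float = 0.01) -> float | None:
    """Centre of the most populated histogram bin; ties go to the lower bin.

    Bins are centred on integer multiples of ``bin_width_g`` so that
    values printed at 2-decimal precision fall on bin centres.  Returns
    ``None`` for empty input (day yields no mode estimate).
    """
    w = np.asarray(list(weights) if not isinstance(weights, (np.ndarray, pd.Series))
                   else weights, dtype=float)
    if w.size == 0:
        return None
    if bin_width_g <= 0:
        raise ValueError("bin_width_g must be positive")
    idx = np.floor(w / bin_width_g + 0.5).astype(np.int64)
    base = idx.min()
    counts = np.bincount(idx - base)
    best = int(np.flatnonzero(counts == counts.max()).min()) + base
    return float(best * bin_width_g)


def stable_windows(
    samples: pd.DataFrame,
    reference_g: float,
    params: StableParams = StableParams(),
) -> pd.DataFrame:
    """Extract stable estimates from a filtered stream.

    Every stride-1 run of ``window_len`` consecutive samples whose
    sample SD (ddof=1) is at most ``sd_fraction * reference_g``
    contributes one estimate equal to the window mean.  Windows are
    evaluated independently within contiguous segments (timestamp steps
    ≤ ``max_gap_s``); a window never spans an acquisition gap.

    Returns a DataFrame ``[window_start, mean_weight, window_sd]`` in
    input order.
    """
    if reference_g <= 0:
        raise ValueError("reference_g must be positive")
    L = params.window_len
    bound = params.sd_fraction * reference_g
    if len(samples) < L:
        return pd.DataFrame(columns=["window_start", "mean_weight", "window_sd"])
    ts = pd.Series(samples["timestamp"].to_numpy())
    w = pd.Series(samples["weight"].to_numpy(dtype=float))
    gaps = ts.diff().dt.total_seconds()
    seg = (gaps > params.max_gap_s).cumsum()

    out = []
    for _, idx in w.groupby(seg).groups.items():
        if len(idx) < L:
            continue
        ww = w.loc[idx]
        roll = ww.rolling(L)
        means = roll.mean()
        sds = roll.std(ddof=1)
        ok = sds.notna() & (sds <= bound)
        if not ok.any():
            continue
        pos = np.flatnonzero(ok.to_numpy())
        starts = ts.loc[idx].to_numpy()[pos - (L - 1)]
        out.append(
            pd.DataFrame(
                {
                    "window_start": starts,
                    "mean_weight": means.to_numpy()[pos],
                    "window_sd": sds.to_numpy()[pos],
                }
            )
        )
    if not out:
        return pd.DataFrame(columns=["window_start", "mean_weight", "window_sd"])
    return pd.concat(out, ignore_index=True)


def daily_stable_estimate(
    stable: pd.DataFrame,
) -> tuple[float | None, float, int]:
    """Mean of a day's stable estimates.

    Returns ``(estimate, sd, n_stable)``; the estimate is ``None`` when
    the day produced no stable windows (the day is then excluded from
    downstream comparisons).
    """
    n = len(stable)
    if n == 0:
        return None, float("nan"), 0
    vals = stable["mean_weight"].to_numpy(dtype=float)
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    return float(vals.mean()), sd, n


def moving_average(values: Iterable[float], window: int) -> np.ndarray:
    """Centred moving mean; edges use however many points are available."""
    if window < 1:
        raise ValueError("window must be >= 1")
    s = pd.Series(np.asarray(list(values) if not isinstance(values, (np.ndarray, pd.Series))
                             else values, dtype=float))
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def _reference_for_day(
    manual: pd.DataFrame | None, bird_id: str, day: Date
) -> float | None:
    """Manual weight for the day, else the nearest preceding one."""
    if manual is None or manual.empty:
        return None
    mine = manual[manual["bird_id"] == bird_id]
    if mine.empty:
        return None
    eligible = mine[mine["date"] <= day]
    if eligible.empty:
        return None
    row = eligible.loc[eligible["date"].map(lambda d: d.toordinal()).idxmax()]
    return float(row["grams"])


def daily_estimates(
    samples: pd.DataFrame,
    manual: pd.DataFrame | None,
    bird_id: str,
    fparams: FilterParams = FilterParams(),
    sparams: StableParams = StableParams(),
    mode_on_band_filtered: bool = True,
    collect_windows: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full per-day pipeline for one bird.

    For each calendar day: baseline filter, band filter against that
    day's manual weight (or the nearest preceding one), daily mode and
    daily stable estimate.  When no manual weight exists at all for the
    bird, band filtering is skipped with a warning and the stable-window
    SD bound falls back to the day's median filtered weight.

    Returns a DataFrame ``[bird_id, date, mode_estimate, stable_estimate,
    n_stable, stable_sd, n_raw, n_removed_baseline, n_removed_band,
    reference_g]``; with ``collect_windows=True`` also returns the
    per-window stable-estimate table (with a ``date`` column).
    """
    rows = []
    window_frames = []
    for day, day_samples in samples.groupby(samples["timestamp"].dt.date, sort=True):
        day_samples = day_samples.reset_index(drop=True)
        kept, n_base = filter_baseline(day_samples, fparams)
        reference = _reference_for_day(manual, bird_id, day)
        if reference is not None:
            kept, n_band = filter_band(kept, reference, fparams)
            sd_reference = reference
        else:
            n_band = 0
            sd_reference = (
                float(kept["weight"].median()) if len(kept) else None
            )
            log.warning(
                "no manual weight for %s on or before %s; band filter skipped",
                bird_id, day,
            )
        mode = daily_mode(kept["weight"]) if mode_on_band_filtered else (
            daily_mode(filter_baseline(day_samples, fparams)[0]["weight"])
        )
        if sd_reference is not None and len(kept) >= sparams.window_len:
            windows = stable_windows(kept, sd_reference, sparams)
        else:
            windows = pd.DataFrame(columns=["window_start", "mean_weight", "window_sd"])
        est, sd, n_stable = daily_stable_estimate(windows)
        rows.append(
            {
                "bird_id": bird_id,
                "date": day,
                "mode_estimate": mode if mode is not None else np.nan,
                "stable_estimate": est if est is not None else np.nan,
                "n_stable": n_stable,
                "stable_sd": sd,
                "n_raw": len(day_samples),
                "n_removed_baseline": n_base,
                "n_removed_band": n_band,
                "reference_g": reference if reference is not None else np.nan,
            }
        )
        if collect_windows and len(windows):
            wf = windows.copy()
            wf.insert(0, "date", day)
            window_frames.append(wf)
    daily = pd.DataFrame(rows)
    if collect_windows:
        all_windows = (
            pd.concat(window_frames, ignore_index=True)
            if window_frames
            else pd.DataFrame(columns=["date", "window_start", "mean_weight", "window_sd"])
        )
        return daily, all_windows
    return daily
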