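"""Validation of perch-scale daily estimates against manual weighing.

Daily estimates (mode or stable) are paired with same-date manual
weights; agreement is summarised by the mean absolute error (MAE, grams)
and the Pearson correlation across pairs.  Fractional normalisation
(subtract and divide by each bird's across-day mean) makes day-to-day
changes comparable across birds of different size.  A bias screen flags
birds whose estimates are systematically offset from their manual
weights — the signature of a mis-calibrated channel — and a grid search
tunes the stable-estimator hyperparameters (window length, SD fraction)
against the manual record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimate import FilterParams, StableParams, daily_estimates
from .io import get_logger

__all__ = [
    "ValidationReport",
    "build_pairs",
    "mae",
    "correlate",
    "normalize_fractional",
    "validation_report",
    "bias_screen",
    "grid_search",
]

log = get_logger("validate")


def build_pairs(
    daily: pd.DataFrame, manual: pd.DataFrame, method: str = "stable"
) -> pd.DataFrame:
    """Pair daily estimates with same-date manual weights.

    ``daily`` is the output of :func:`perchscale.estimate.daily_estimates`
    (possibly concatenated over birds); ``method`` selects
    ``stable_estimate`` or ``mode_estimate``.  Days without an estimate
    are dropped before pairing.
    """
    col = {"stable": "stable_estimate", "mode": "mode_estimate"}[method]
    est = daily[["bird_id", "date", col]].dropna(subset=[col])
    merged = est.merge(manual, on=["bird_id", "date"], how="inner")
    return merged.rename(columns={col: "estimate", "grams": "manual"})[
        ["bird_id", "date", "estimate", "manual"]
    ]


def mae(pairs: pd.DataFrame) -> float:
    """Mean absolute error |estimate - manual| in grams."""
    if len(pairs) == 0:
        raise ValueError("mae requires at least one pair")
    return float(np.abs(pairs["estimate"] - pairs["manual"]).mean())


def correlate(pairs: pd.DataFrame) -> tuple[float, float]:
    """Pearson product-moment r and two-sided p across pairs."""
    if len(pairs) < 3:
        raise ValueError("correlation requires at least three pairs")
    x = pairs["estimate"].to_numpy(dtype=float)
    y = pairs["manual"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def normalize_fractional(series: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Per-bird fractional change: (value - mean) / mean across days.

    ``series`` needs columns ``bird_id`` and *value_col*.  Every bird
    must have at least two days and a positive mean.  The returned frame
    carries an extra ``normalized`` column; each bird's normalised
    values average to zero, and the transform is invariant to scaling a
    bird's series by any positive constant.
    """
    out = series.copy()
    normalized = np.empty(len(out), dtype=float)
    for bird, group in out.groupby("bird_id"):
        vals = group[value_col].to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError(f"bird {bird} has a single day; cannot normalise")
        mean = vals.mean()
        if mean <= 0:
            raise ValueError(f"bird {bird} has non-positive mean {mean}")
        normalized[out.index.get_indexer(group.index)] = (vals - mean) / mean
    out["normalized"] = normalized
    return out


@dataclass
class ValidationReport:
    n_pairs: int
    mae: float
    pearson_r: float
    p_value: float
    per_bird_mae: pd.DataFrame


def validation_report(pairs: pd.DataFrame) -> ValidationReport:
    per_bird = (
        pairs.assign(abs_err=lambda d: (d["estimate"] - d["manual"]).abs())
        .groupby("bird_id")
        .agg(n=("abs_err", "size"), mae=("abs_err", "mean"),
             mean_signed_error=("abs_err", lambda _: np.nan))
        .reset_index()
    )
    signed = (
        pairs.assign(err=lambda d: d["estimate"] - d["manual"])
        .groupby("bird_id")["err"].mean()
    )
    per_bird["mean_signed_error"] = per_bird["bird_id"].map(signed)
    r, p = correlate(pairs)
    return ValidationReport(
        n_pairs=len(pairs),
        mae=mae(pairs),
        pearson_r=r,
        p_value=p,
        per_bird_mae=per_bird,
    )


def bias_screen(
    pairs: pd.DataFrame, k: float = 3.0, min_abs_g: float = 0.5
) -> tuple[list[str], pd.DataFrame]:
    """Flag birds with systematically biased estimates.

    A bird is flagged when the absolute value of its mean signed error
    (estimate − manual) exceeds *k* times the cross-bird median absolute
    signed error **and** exceeds ``min_abs_g``.  The absolute floor
    keeps the relative rule from firing on sub-device-accuracy
    differences when every bird is essentially unbiased.  With only two
    birds carrying identical bias the screen cannot flag either — it
    needs a majority baseline.

    Returns ``(flagged_bird_ids, per_bird_error_table)``.
    """
    birds = pairs["bird_id"].unique()
    if len(birds) < 2:
        raise ValueError("bias_screen requires at least two birds")
    err = (
        pairs.assign(err=lambda d: d["estimate"] - d["manual"])
        .groupby("bird_id")["err"].mean()
        .rename("mean_signed_error")
        .reset_index()
    )
    abs_err = err["mean_signed_error"].abs()
    median_abs = float(abs_err.median())
    flagged = err.loc[
        (abs_err > k * median_abs) & (abs_err > min_abs_g), "bird_id"
    ].tolist()
    err["flagged"] = err["bird_id"].isin(flagged)
    if flagged:
        log.warning("bias screen flagged: %s", ", ".join(flagged))
    return flagged, err


def grid_search(
    samples_by_bird: Mapping[str, pd.DataFrame],
    manual: pd.DataFrame,
    window_grid: Sequence[int] = (5, 10, 20, 30),
    sd_fraction_grid: Sequence[float] = (0.03, 0.06, 0.09, 0.12),
    fparams: FilterParams = FilterParams(),
    objective: str = "stable",
) -> tuple[StableParams, pd.DataFrame]:
    """Tune (window_len, sd_fraction) by exhaustive search.

    Every grid point is scored by the MAE of the chosen daily estimate
    (default: the stable method) against the manual weights, pooled over
    birds.  The score table always has |window_grid| × |sd_fraction_grid|
    rows; grid points yielding no valid pairs score NaN.  Ties are broken
    toward the smaller window, then the smaller SD fraction.
    """
    if not window_grid or not sd_fraction_grid:
        raise ValueError("grids must be non-empty")
    rows = []
    for window_len in window_grid:
        for sd_fraction in sd_fraction_grid:
            sparams = StableParams(window_len=int(window_len),
                                   sd_fraction=float(sd_fraction))
            frames = [
                daily_estimates(samples, manual, bird, fparams, sparams)
                for bird, samples in samples_by_bird.items()
            ]
            daily = pd.concat(frames, ignore_index=True)
            pairs = build_pairs(daily, manual, method=objective)
            rows.append(
                {
                    "window_len": int(window_len),
                    "sd_fraction": float(sd_fraction),
                    "n_pairs": len(pairs),
                    "mae": mae(pairs) if len(pairs) else np.nan,
                }
            )
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["mae"])
    if valid.empty:
        raise ValueError("no grid point produced any estimate/manual pairs")
    best = valid.sort_values(
        ["mae", "window_len", "sd_fraction"], kind="stable"
    ).iloc[0]
    return (
        StableParams(window_len=int(best["window_len"]),
                     sd_fraction=float(best["sd_fraction"])),
        table,
    )
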