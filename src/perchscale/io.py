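"""Reading and writing the perch-scale CSV dialects, plus run configuration.

Two on-disk formats are supported:

* **Weight log** — wide CSV, header ``timestamp,<bird_1>,...,<bird_k>``,
  nominally one row per second with timestamps in ``YYYY-MM-DD HH:MM:SS``
  and gram values at 2-decimal precision.  Acquisition gaps appear as
  absent rows (or empty cells), never as imputed values.
* **Manual weights** — long CSV with header ``bird_id,date,grams``, at
  most one entry per bird per calendar date.

In memory a bird's stream is a :class:`pandas.DataFrame` with columns
``timestamp`` (datetime64, 1 s resolution, naive local time) and
``weight`` (grams, float).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import time
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LOG_TIME_FMT",
    "LightSchedule",
    "LogReadReport",
    "read_weight_log",
    "write_weight_log",
    "read_manual_weights",
    "write_manual_weights",
    "load_config",
    "save_config",
    "default_config",
    "validate_channel_map",
    "get_logger",
    "setup_logging",
]

LOG_TIME_FMT = "%Y-%m-%d %H:%M:%S"

log = logging.getLogger("perchscale.io")


def get_logger(name: str) -> logging.Logger:
    return logging.getLogger(f"perchscale.{name}")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


@dataclass(frozen=True)
class LightSchedule:
    """Times the artificial lights switch off/on; defines one nightly
    dark interval per date (lights_off on date d to lights_on on d+1 when
    lights_off is the later clock time)."""

    lights_off: time
    lights_on: time

    @property
    def night_hours(self) -> float:
        off = self.lights_off.hour * 3600 + self.lights_off.minute * 60 + self.lights_off.second
        on = self.lights_on.hour * 3600 + self.lights_on.minute * 60 + self.lights_on.second
        return ((on - off) % 86400) / 3600.0

    @classmethod
    def from_strings(cls, lights_off: str, lights_on: str) -> "LightSchedule":
        return cls(_parse_clock(lights_off), _parse_clock(lights_on))


def _parse_clock(value: str | time) -> time:
    if isinstance(value, time):
        return value
    parts = [int(p) for p in str(value).split(":")]
    while len(parts) < 3:
        parts.append(0)
    return time(*parts[:3])


@dataclass
class LogReadReport:
    """What happened while parsing a weight log."""

    n_rows: int = 0
    n_skipped_rows: int = 0          # unparseable timestamp
    n_skipped_cells: int = 0         # non-empty, non-numeric weight cell
    monotonicity_violations: dict[str, int] = field(default_factory=dict)

    @property
    def clean(self) -> bool:
        return (
            self.n_skipped_rows == 0
            and self.n_skipped_cells == 0
            and not any(self.monotonicity_violations.values())
        )


def validate_channel_map(channel_map: Mapping[int, str]) -> dict[int, str]:
    """Channel→bird map: channels 0-7, bird ids unique."""
    out: dict[int, str] = {}
    for ch, bird in channel_map.items():
        ch = int(ch)
        if not 0 <= ch <= 7:
            raise ValueError(f"channel index {ch} out of range [0, 7]")
        out[ch] = str(bird)
    birds = list(out.values())
    if len(set(birds)) != len(birds):
        raise ValueError("bird_id must be unique per channel")
    return out


def read_weight_log(
    path: str | Path,
    channel_map: Mapping[int, str] | None = None,
) -> tuple[dict[str, pd.DataFrame], LogReadReport]:
    """Read a weight log into per-bird sample frames.

    Parameters
    ----------
    path:
        CSV file with header ``timestamp,<col_1>,...``.  Columns may be
        bird ids directly, or channel labels translated via *channel_map*
        (keys matched against the column name or its trailing integer,
        e.g. ``ch0``).
    channel_map:
        Optional channel→bird translation.

    Returns
    -------
    (birds, report):
        ``birds`` maps bird_id to a DataFrame ``[timestamp, weight]``.
        Rows with unparseable timestamps and non-numeric weight cells are
        skipped and counted in ``report``; empty cells are treated as
        acquisition gaps and skipped silently.  Out-of-order timestamps
        are reported, never reordered.  An empty file (header only, or no
        header at all) yields an empty dict and ``report.n_rows == 0``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        log.warning("weight log %s is empty", path)
        return {}, LogReadReport()
    if raw.shape[1] < 2 or raw.columns[0].strip().lower() != "timestamp":
        raise ValueError(
            f"malformed header in {path}: expected 'timestamp,<bird>,...', "
            f"got {list(raw.columns)!r}"
        )
    report = LogReadReport(n_rows=len(raw))
    if raw.empty:
        log.warning("weight log %s has a header but no data rows", path)

    ts = pd.to_datetime(raw.iloc[:, 0], format=LOG_TIME_FMT, errors="coerce")
    bad_ts = ts.isna()
    report.n_skipped_rows = int(bad_ts.sum())

    def _bird_for(col: str) -> str:
        if channel_map is None:
            return col
        cmap = validate_channel_map(channel_map)
        digits = "".join(c for c in col if c.isdigit())
        if col in map(str, cmap):
            return cmap[int(col)]
        if digits and int(digits) in cmap:
            return cmap[int(digits)]
        return col

    birds: dict[str, pd.DataFrame] = {}
    for col in raw.columns[1:]:
        cells = raw[col]
        weights = pd.to_numeric(cells, errors="coerce")
        nonempty = cells.notna() & (cells.astype(str).str.strip() != "")
        unparseable = nonempty & ~np.isfinite(weights.to_numpy(dtype=float, na_value=np.nan))
        report.n_skipped_cells += int((unparseable & ~bad_ts).sum())
        keep = nonempty & ~unparseable & ~bad_ts
        bird = _bird_for(col)
        frame = pd.DataFrame(
            {"timestamp": ts[keep], "weight": weights[keep].astype(float)}
        ).reset_index(drop=True)
        violations = int((frame["timestamp"].diff().dt.total_seconds() <= 0).sum())
        if violations:
            report.monotonicity_violations[bird] = violations
            log.warning(
                "%d non-increasing timestamps in stream for bird %s", violations, bird
            )
        birds[bird] = frame
    return birds, report


def write_weight_log(birds: Mapping[str, pd.DataFrame], path: str | Path) -> None:
    """Write per-bird sample frames as one wide CSV.

    One row per distinct second, one column per bird, grams formatted to
    2 decimals (device precision is 0.1 g; one extra digit keeps the
    round trip lossless).  Seconds a bird has no sample for are empty
    cells.  write→read→write is byte-identical.
    """
    path = Path(path)
    series = {}
    for bird, frame in birds.items():
        s = pd.Series(
            frame["weight"].to_numpy(dtype=float),
            index=pd.DatetimeIndex(frame["timestamp"]),
            name=str(bird),
        )
        series[str(bird)] = s
    wide = pd.DataFrame(series).sort_index()
    wide.index.name = "timestamp"
    wide.to_csv(path, float_format="%.2f", date_format=LOG_TIME_FMT, na_rep="")


def read_manual_weights(path: str | Path) -> pd.DataFrame:
    """Read the daily manual-weight table.

    Returns a DataFrame ``[bird_id, date, grams]`` with ``date`` as
    :class:`datetime.date`.  Non-positive grams and duplicate
    (bird_id, date) keys raise :class:`ValueError`.
    """
    df = pd.read_csv(path, dtype={"bird_id": str})
    expected = ["bird_id", "date", "grams"]
    if list(df.columns[:3]) != expected:
        raise ValueError(
            f"manual-weight file must have header {','.join(expected)}, "
            f"got {list(df.columns)!r}"
        )
    df = df[expected].copy()
    df["date"] = pd.to_datetime(df["date"]).dt.date
    df["grams"] = df["grams"].astype(float)
    bad = df[~(df["grams"] > 0) | ~np.isfinite(df["grams"])]
    if len(bad):
        first = bad.iloc[0]
        raise ValueError(
            f"non-positive manual weight {first['grams']} for bird "
            f"{first['bird_id']} on {first['date']}"
        )
    dup = df.duplicated(subset=["bird_id", "date"], keep=False)
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            f"duplicate manual weight for bird {first['bird_id']} on {first['date']}"
        )
    return df.reset_index(drop=True)


def write_manual_weights(df: pd.DataFrame, path: str | Path) -> None:
    out = df[["bird_id", "date", "grams"]].copy()
    out["grams"] = out["grams"].map(lambda g: f"{g:.2f}")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

def default_config() -> dict:
    """Default run configuration (deep-copied on every call)."""
    return {
        "seed": 0,
        "channel_map": {},
        "light_schedule": {"lights_off": "19:00", "lights_on": "07:00"},
        "filter": {"baseline_cutoff": 1.0, "band_fraction": 0.30},
        "stable": {"window_len": 10, "sd_fraction": 0.09, "smoothing_window": 100,
                   "max_gap_s": 2.0},
        "overnight": {"min_duration_h": 4.0, "max_gap_s": 5.0},
        "simulate": {"days": 10, "n_birds": 6, "base_weight_range": [15.0, 25.0],
                     "loss_rate_range": [0.002, 0.005]},
    }


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config, merged over :func:`default_config`."""
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config {path} must be a YAML mapping")
        cfg = _deep_merge(cfg, user)
    if cfg.get("channel_map"):
        cfg["channel_map"] = validate_channel_map(cfg["channel_map"])
    return cfg


def save_config(cfg: Mapping, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dict(cfg), sort_keys=False))


def light_schedule_from_config(cfg: Mapping) -> LightSchedule:
    ls = cfg["light_schedule"]
    return LightSchedule.from_strings(ls["lights_off"], ls["lights_on"])
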