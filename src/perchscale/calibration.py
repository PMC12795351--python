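"""Load-cell calibration: conversion between raw sensor units and grams.

A perch-scale is a load cell whose (amplified, digitized) output is linear
in the applied mass.  Two per-channel constants convert a raw reading to
grams:

    weight_g = (raw_value - zero_offset) / calibration_factor

``zero_offset`` is the raw reading of the empty perch and
``calibration_factor`` is raw units per gram, estimated by placing an item
of known mass on the perch.  Both are obtained once per channel during
setup and stored in a small registry (the software analogue of the
microcontroller's per-channel non-volatile memory slots); recalibrating a
channel overwrites its previous record.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import yaml

__all__ = [
    "LOAD_CELL_CAPACITY_G",
    "CalibrationRecord",
    "CalibrationRegistry",
    "compute_zero_offset",
    "compute_calibration_factor",
    "calibrate_channel",
    "raw_to_grams",
    "grams_to_raw",
]

#: Rated capacity of the load cell used by the device, in grams.
LOAD_CELL_CAPACITY_G = 500.0

#: Number of MUX channels one control unit can address.
N_CHANNELS = 8

ArrayLike = Union[float, Iterable[float], np.ndarray]


def _check_channel(channel_index: int) -> None:
    if not (0 <= int(channel_index) < N_CHANNELS):
        raise ValueError(
            f"channel_index must be in [0, {N_CHANNELS - 1}], got {channel_index}"
        )


@dataclass(frozen=True)
class CalibrationRecord:
    """Per-channel conversion constants.

    Attributes
    ----------
    channel_index:
        MUX channel (0-7) the record belongs to.
    zero_offset:
        Raw sensor value of the unloaded perch.
    calibration_factor:
        Raw sensor units per gram; must be nonzero.
    calibrated_at:
        When the calibration was performed.  Carried so downstream analysis
        can segment a stream at recalibration events.
    """

    channel_index: int
    zero_offset: float
    calibration_factor: float
    calibrated_at: datetime

    def __post_init__(self) -> None:
        _check_channel(self.channel_index)
        if not np.isfinite(self.zero_offset):
            raise ValueError("zero_offset must be finite")
        if not np.isfinite(self.calibration_factor) or self.calibration_factor == 0:
            raise ValueError("calibration_factor must be finite and nonzero")


def compute_zero_offset(readings: ArrayLike) -> float:
    """Mean raw value of the empty perch.

    By construction, converting this value back through the resulting
    record yields exactly 0 g.
    """
    raw = np.asarray(list(readings) if not isinstance(readings, np.ndarray) else readings,
                     dtype=float)
    if raw.size == 0:
        raise ValueError("need at least one zero reading")
    if not np.all(np.isfinite(raw)):
        raise ValueError("zero readings must be finite")
    return float(raw.mean())


def compute_calibration_factor(
    readings: ArrayLike, known_mass_g: float, zero_offset: float
) -> float:
    """Raw units per gram from readings of a known mass.

    factor = (mean(raw) - zero_offset) / known_mass_g
    """
    if known_mass_g <= 0:
        raise ValueError(f"known_mass_g must be positive, got {known_mass_g}")
    raw = np.asarray(list(readings) if not isinstance(readings, np.ndarray) else readings,
                     dtype=float)
    if raw.size == 0:
        raise ValueError("need at least one mass reading")
    if not np.all(np.isfinite(raw)):
        raise ValueError("mass readings must be finite")
    diff = raw.mean() - zero_offset
    if diff == 0:
        raise ValueError(
            "mean mass reading equals zero_offset; calibration factor would be 0"
        )
    return float(diff / known_mass_g)


def calibrate_channel(
    channel_index: int,
    zero_readings: ArrayLike,
    mass_readings: ArrayLike,
    known_mass_g: float,
    calibrated_at: datetime | None = None,
) -> CalibrationRecord:
    """Run the two-step calibration procedure and return the record."""
    offset = compute_zero_offset(zero_readings)
    factor = compute_calibration_factor(mass_readings, known_mass_g, offset)
    return CalibrationRecord(
        channel_index=int(channel_index),
        zero_offset=offset,
        calibration_factor=factor,
        calibrated_at=calibrated_at or datetime.now(),
    )


def raw_to_grams(raw_value: ArrayLike, record: CalibrationRecord):
    """Convert raw sensor units to grams: (raw - zero_offset) / factor."""
    raw = np.asarray(raw_value, dtype=float)
    grams = (raw - record.zero_offset) / record.calibration_factor
    return float(grams) if grams.ndim == 0 else grams


def grams_to_raw(grams: ArrayLike, record: CalibrationRecord):
    """Exact inverse of :func:`raw_to_grams` (used by the simulator)."""
    g = np.asarray(grams, dtype=float)
    raw = g * record.calibration_factor + record.zero_offset
    return float(raw) if raw.ndim == 0 else raw


class CalibrationRegistry:
    """Per-channel store of calibration records.

    Mirrors the device's behaviour: each of the 8 MUX channels has one
    slot; setting a channel replaces any previous record, and reading a
    never-calibrated channel is an error.  Persistable as a small YAML
    key-value file.
    """

    _TIME_FMT = "%Y-%m-%d %H:%M:%S"

    def __init__(self) -> None:
        self._records: dict[int, CalibrationRecord] = {}

    def set(self, record: CalibrationRecord) -> None:
        self._records[record.channel_index] = record

    def get(self, channel_index: int) -> CalibrationRecord:
        _check_channel(channel_index)
        try:
            return self._records[int(channel_index)]
        except KeyError:
            raise KeyError(
                f"channel {channel_index} has never been calibrated"
            ) from None

    def channels(self) -> list[int]:
        return sorted(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, channel_index: int) -> bool:
        return int(channel_index) in self._records

    def save(self, path: str | Path) -> None:
        payload = {
            ch: {
                "zero_offset": rec.zero_offset,
                "calibration_factor": rec.calibration_factor,
                "calibrated_at": rec.calibrated_at.strftime(self._TIME_FMT),
            }
            for ch, rec in sorted(self._records.items())
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationRegistry":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        reg = cls()
        for ch, fields in payload.items():
            reg.set(
                CalibrationRecord(
                    channel_index=int(ch),
                    zero_offset=float(fields["zero_offset"]),
                    calibration_factor=float(fields["calibration_factor"]),
                    calibrated_at=datetime.strptime(
                        fields["calibrated_at"], cls._TIME_FMT
                    ),
                )
            )
        return reg
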