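"""Baseline trimming and middle-cycle selection.

A raw assessment recording contains quasi-static holds around five
flexion-extension cycles. Preprocessing first locates the active stretch
by thresholding the gyroscope vector magnitude, then keeps the middle
three of five equal-duration subsets, yielding the most stable portion
of the movement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .simulate import IMURecording

logger = logging.getLogger(__name__)

#: Default gyro-magnitude threshold (deg/s) separating quasi-static hold
#: from stretch motion, and the minimum contiguous supra-threshold
#: duration (s) counted as genuine movement.
DEFAULT_GYRO_THRESHOLD_DPS = 10.0
DEFAULT_MIN_ACTIVE_S = 0.25


class NoMovementError(ValueError):
    """Raised when no supra-threshold movement is found in a recording."""


@dataclass(frozen=True)
class MovementPortion:
    """The three-cycle sub-series surviving baseline trimming.

    ``source_bounds`` are 0-based half-open sample indices into the
    parent recording.
    """

    subject_id: str
    mas_label: int
    sample_rate_hz: float
    accel: np.ndarray
    gyro: np.ndarray
    source_bounds: tuple[int, int]

    def __post_init__(self) -> None:
        if self.accel.shape[0] != self.gyro.shape[0]:
            raise ValueError("accel and gyro must have equal length")
        if self.accel.shape[0] < 3:
            raise ValueError("portion must contain at least 3 samples")
        start, end = self.source_bounds
        if not 0 <= start < end:
            raise ValueError("source_bounds must be a nonempty half-open interval")
        if end - start != self.accel.shape[0]:
            raise ValueError("source_bounds inconsistent with portion length")

    def __len__(self) -> int:
        return self.accel.shape[0]


def _active_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, end) runs of True in a boolean mask."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def trim_baseline(
    recording: IMURecording,
    gyro_threshold_dps: float = DEFAULT_GYRO_THRESHOLD_DPS,
    min_active_s: float = DEFAULT_MIN_ACTIVE_S,
) -> tuple[int, int]:
    """Locate the active movement as a half-open sample interval.

    Returns the smallest interval containing every sample whose gyro
    vector magnitude stays at or above ``gyro_threshold_dps`` for at
    least ``min_active_s`` of contiguous duration; the debounce rejects
    isolated noise spikes during the quasi-static holds.
    """
    if gyro_threshold_dps <= 0 or min_active_s <= 0:
        raise ValueError("gyro_threshold_dps and min_active_s must be positive")
    magnitude = np.linalg.norm(recording.gyro, axis=1)
    mask = magnitude >= gyro_threshold_dps
    min_len = max(1, round(min_active_s * recording.sample_rate_hz))
    runs = [(s, e) for s, e in _active_runs(mask) if e - s >= min_len]
    if not runs:
        raise NoMovementError(
            f"no movement detected in {recording.subject_id!r}: no gyro-magnitude run "
            f">= {gyro_threshold_dps} deg/s lasting {min_active_s} s"
        )
    return int(runs[0][0]), int(runs[-1][1])


def extract_middle_cycles(
    recording: IMURecording, active_interval: tuple[int, int]
) -> MovementPortion:
    """Keep the middle three of five equal subsets of the active interval.

    The interval is divided into five contiguous blocks of
    ``floor(L/5)`` samples (remainder assigned to the last block and
    truncated with it); blocks 2-4 are concatenated, so the portion
    length is exactly ``3 * floor(L/5)``.
    """
    start, end = active_interval
    n = len(recording)
    if not 0 <= start < end <= n:
        raise ValueError(f"active interval {active_interval} out of bounds for length {n}")
    length = end - start
    if length < 5:
        raise ValueError(f"active interval too short to split into five subsets (L={length})")
    block = length // 5
    lo, hi = start + block, start + 4 * block
    return MovementPortion(
        subject_id=recording.subject_id,
        mas_label=recording.mas_label,
        sample_rate_hz=recording.sample_rate_hz,
        accel=recording.accel[lo:hi],
        gyro=recording.gyro[lo:hi],
        source_bounds=(lo, hi),
    )


def preprocess_recording(
    recording: IMURecording,
    gyro_threshold_dps: float = DEFAULT_GYRO_THRESHOLD_DPS,
    min_active_s: float = DEFAULT_MIN_ACTIVE_S,
) -> MovementPortion:
    """trim_baseline followed by extract_middle_cycles."""
    interval = trim_baseline(recording, gyro_threshold_dps, min_active_s)
    portion = extract_middle_cycles(recording, interval)
    logger.debug(
        "preprocessed %s: active=[%d, %d) portion=[%d, %d)",
        recording.subject_id, interval[0], interval[1], *portion.source_bounds,
    )
    return portion
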