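"""Feature extraction from IMU segments.

Two feature sets are computed per segment:

* **FS1** (42 features): seven statistics — root mean square, mean,
  standard deviation, energy, spectral energy, absolute difference,
  variance — on each of the six raw channels (ax, ay, az, gx, gy, gz).
* **FS2** (58 features): FS1 plus the same seven statistics on the
  per-sample roll and pitch series derived from the accelerometer
  (Equations: roll = (180/pi) atan2(y, z), pitch = (180/pi) atan2(x, z)),
  plus the signal magnitude area (SMA) and signal vector magnitude (SV)
  over the accelerometer x and y axes.

Definitions: variance and standard deviation are population statistics
(ddof=0); energy is the mean square; spectral energy is the
Parseval-normalized DFT energy sum(|X_k|^2)/n^2, which equals the energy
and is retained as a numerical cross-check feature; absolute difference
is the mean absolute successive difference.

Feature ordering is fixed (channel-major, statistics in the order above,
then sma, sv) so feature matrices are reproducible bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segment import Segment

STAT_NAMES = ("rms", "mean", "std", "energy", "spectral_energy", "abs_diff", "variance")
RAW_CHANNELS = ("ax", "ay", "az", "gx", "gy", "gz")
FEATURE_SETS = ("FS1", "FS2")

#: Metadata columns attached to every feature matrix.
META_COLUMNS = ("subject_id", "mas_label", "scheme")


@dataclass(frozen=True)
class FeatureVector:
    """Ordered named feature values for one segment."""

    subject_id: str
    mas_label: int
    scheme: str
    feature_set: str
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        expected = {"FS1": 42, "FS2": 58}[self.feature_set]
        if len(self.names) != expected or self.values.shape != (expected,):
            raise ValueError(f"{self.feature_set} requires exactly {expected} features")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")


def channel_stats(x: np.ndarray, sample_rate_hz: float | None = None) -> dict[str, float]:
    """The seven per-channel statistics, in canonical order.

    Requires at least two samples (the absolute difference needs a
    successive pair). ``sample_rate_hz`` is accepted for interface
    uniformity; none of the seven statistics depend on it.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError(f"channel_stats requires at least 2 samples, got {n}")
    mean = float(np.mean(x))
    variance = float(np.mean((x - mean) ** 2))
    energy = float(np.mean(x**2))
    spectral = float(np.sum(np.abs(np.fft.fft(x)) ** 2) / n**2)
    return {
        "rms": float(np.sqrt(energy)),
        "mean": mean,
        "std": float(np.sqrt(variance)),
        "energy": energy,
        "spectral_energy": spectral,
        "abs_diff": float(np.mean(np.abs(np.diff(x)))),
        "variance": variance,
    }


def _tilt_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    degenerate = (a == 0) & (b == 0)
    if np.any(degenerate):
        warnings.warn(
            "degenerate (0, 0) accelerometer pair; tilt angle defined as 0",
            RuntimeWarning,
            stacklevel=3,
        )
    return np.degrees(np.arctan2(a, b))


def roll(accel: np.ndarray) -> np.ndarray | float:
    """Roll angle (deg) from accelerometer samples: (180/pi) atan2(y, z).

    Accepts a single 3-vector or an (n, 3) array; range (-180, 180].
    """
    arr = np.asarray(accel, dtype=float)
    if arr.ndim == 1:
        return float(_tilt_deg(arr[1], arr[2]))
    return _tilt_deg(arr[:, 1], arr[:, 2])


def pitch(accel: np.ndarray) -> np.ndarray | float:
    """Pitch angle (deg) from accelerometer samples: (180/pi) atan2(x, z)."""
    arr = np.asarray(accel, dtype=float)
    if arr.ndim == 1:
        return float(_tilt_deg(arr[0], arr[2]))
    return _tilt_deg(arr[:, 0], arr[:, 2])


def sma(x: np.ndarray, y: np.ndarray) -> float:
    """Signal magnitude area: mean of |x_i| + |y_i| (activity-vs-rest indicator)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or x.shape != y.shape:
        raise ValueError("sma requires two equal-length nonempty sequences")
    return float(np.mean(np.abs(x) + np.abs(y)))


def sv(x: np.ndarray, y: np.ndarray) -> float:
    """Signal vector magnitude: mean of sqrt(x_i^2 + y_i^2) (movement intensity)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or x.shape != y.shape:
        raise ValueError("sv requires two equal-length nonempty sequences")
    return float(np.mean(np.hypot(x, y)))


def feature_names(feature_set: str) -> tuple[str, ...]:
    """Canonical ordered feature names for FS1 or FS2."""
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
    channels = RAW_CHANNELS if feature_set == "FS1" else RAW_CHANNELS + ("roll", "pitch")
    names = [f"{ch}_{stat}" for ch in channels for stat in STAT_NAMES]
    if feature_set == "FS2":
        names += ["sma", "sv"]
    return tuple(names)


def featurize(segment: Segment, feature_set: str = "FS2") -> FeatureVector:
    """Compute FS1 (42) or FS2 (58) for one segment."""
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
    series: dict[str, np.ndarray] = {
        "ax": segment.accel[:, 0],
        "ay": segment.accel[:, 1],
        "az": segment.accel[:, 2],
        "gx": segment.gyro[:, 0],
        "gy": segment.gyro[:, 1],
        "gz": segment.gyro[:, 2],
    }
    if feature_set == "FS2":
        series["roll"] = roll(segment.accel)
        series["pitch"] = pitch(segment.accel)
    values: list[float] = []
    for channel in series:
        stats = channel_stats(series[channel], segment.sample_rate_hz)
        values.extend(stats[stat] for stat in STAT_NAMES)
    if feature_set == "FS2":
        values.append(sma(series["ax"], series["ay"]))
        values.append(sv(series["ax"], series["ay"]))
    return FeatureVector(
        subject_id=segment.subject_id,
        mas_label=segment.mas_label,
        scheme=segment.scheme,
        feature_set=feature_set,
        names=feature_names(feature_set),
        values=np.asarray(values, dtype=float),
    )


def feature_table(segments: list[Segment], feature_set: str = "FS2") -> pd.DataFrame:
    """Feature matrix: metadata columns plus one column per feature, one
    row per segment."""
    vectors = [featurize(s, feature_set) for s in segments]
    names = feature_names(feature_set)
    data = {
        "subject_id": [v.subject_id for v in vectors],
        "mas_label": [v.mas_label for v in vectors],
        "scheme": [v.scheme for v in vectors],
    }
    matrix = (
        np.vstack([v.values for v in vectors]) if vectors else np.empty((0, len(names)))
    )
    for j, name in enumerate(names):
        data[name] = matrix[:, j]
    return pd.DataFrame(data)
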