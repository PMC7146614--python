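"""Synthetic passive-stretch IMU recordings for elbow spasticity grading.

The generator emulates a bedside modified Ashworth scale (MAS) assessment:
the therapist holds the relaxed limb still (quasi-static baseline), then
moves the elbow through five flexion-extension cycles at one cycle per
second while a forearm-mounted IMU samples triaxial acceleration (in g)
and triaxial angular velocity (in deg/s) at 256 Hz.

Spasticity enters the kinematics through two grade-dependent effects:

* the achievable range of motion (ROM) shrinks with grade, down to a
  near-rigid elbow at MAS 4 (label 5), and
* a "catch" — a localized, velocity-dependent resistance during the
  extension half-cycle — appears from MAS 1 upward, modeled as a
  multiplicative Gaussian notch in the angular-velocity profile centered
  at a grade-dependent fraction of the excursion.

The elbow is modeled as a single-axis hinge. The sensor rotates with the
forearm, so gravity sweeps through the sensor's y-z plane: with the arm
fully flexed (angle 0) gravity lies along +z, and the per-sample roll
angle atan2(ay, az) recovers the elbow angle exactly in the noiseless
case. The designated gyroscope axis is x.

Labels follow the supervised-learning encoding of the six MAS grades:
MAS 0 -> 0, 1 -> 1, 1+ -> 2, 2 -> 3, 3 -> 4, 4 -> 5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Integer class labels for the six MAS grades.
MAS_LABELS = (0, 1, 2, 3, 4, 5)

#: Clinical grade name for each integer label.
MAS_GRADE_NAMES = {0: "0", 1: "1", 2: "1+", 3: "2", 4: "3", 5: "4"}

#: Grade composition of the reference 48-participant cohort
#: (17/13/7/6/4/1 subjects for MAS 0, 1, 1+, 2, 3, 4).
STUDY_COHORT = {0: 17, 1: 13, 2: 7, 3: 6, 4: 4, 5: 1}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the passive-stretch protocol and the sensor model.

    Per-grade tuples are indexed by the integer label 0..5. ROM must be
    non-increasing with grade and the catch depth non-decreasing, with
    zero depth for MAS 0 (no increase in muscle tone, hence no catch).
    """

    sample_rate_hz: float = 256.0
    n_cycles: int = 5
    cycle_period_s: float = 1.0
    baseline_lead_s: float = 1.0
    baseline_trail_s: float = 1.0
    #: Full flexion-extension excursion (deg) per grade; near zero at MAS 4.
    rom_deg: tuple[float, ...] = (150.0, 135.0, 120.0, 100.0, 65.0, 15.0)
    #: Fraction of the excursion at which the catch occurs, per grade.
    catch_angle_frac: tuple[float, ...] = (0.5, 0.8, 0.65, 0.5, 0.45, 0.4)
    #: Fractional transient velocity drop at the catch, per grade.
    catch_depth: tuple[float, ...] = (0.0, 0.30, 0.45, 0.60, 0.75, 0.90)
    #: Width (SD) of the velocity notch as a fraction of the extension half-cycle.
    catch_width_frac: float = 0.08
    #: Inter-subject variability: relative SD of the subject's ROM,
    #: absolute SD of the catch angle fraction and catch depth.
    rom_jitter_frac: float = 0.03
    catch_angle_jitter: float = 0.03
    catch_depth_jitter: float = 0.03
    #: Cycle-to-cycle variability within a recording: relative SD applied
    #: to each cycle's excursion and catch depth (hand-moved cycles are
    #: never identical).
    cycle_jitter_frac: float = 0.05
    accel_noise_sd_g: float = 0.02
    gyro_noise_sd_dps: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.n_cycles <= 0 or int(self.n_cycles) != self.n_cycles:
            raise ValueError("n_cycles must be a positive integer")
        if self.cycle_period_s <= 0:
            raise ValueError("cycle_period_s must be positive")
        if self.baseline_lead_s < 0 or self.baseline_trail_s < 0:
            raise ValueError("baseline holds must be nonnegative")
        if self.accel_noise_sd_g < 0 or self.gyro_noise_sd_dps < 0:
            raise ValueError("noise scales must be nonnegative")
        jitters = (
            self.rom_jitter_frac,
            self.catch_angle_jitter,
            self.catch_depth_jitter,
            self.cycle_jitter_frac,
        )
        if any(j < 0 for j in jitters):
            raise ValueError("jitter scales must be nonnegative")
        for name in ("rom_deg", "catch_angle_frac", "catch_depth"):
            if len(getattr(self, name)) != len(MAS_LABELS):
                raise ValueError(f"{name} must have one value per MAS label")
        rom = np.asarray(self.rom_deg, dtype=float)
        if np.any(rom <= 0):
            raise ValueError("rom_deg values must be positive")
        if np.any(np.diff(rom) > 0):
            raise ValueError("rom_deg must be non-increasing with MAS label")
        depth = np.asarray(self.catch_depth, dtype=float)
        if depth[0] != 0.0:
            raise ValueError("catch_depth must be 0 for MAS label 0")
        if np.any(np.diff(depth) < 0):
            raise ValueError("catch_depth must be non-decreasing with MAS label")
        if np.any(depth < 0) or np.any(depth >= 1):
            raise ValueError("catch_depth values must lie in [0, 1)")
        if not 0 < self.catch_width_frac < 1:
            raise ValueError("catch_width_frac must lie in (0, 1)")


@dataclass(frozen=True)
class IMURecording:
    """One subject's labeled six-channel inertial time series.

    ``accel`` is an (n, 3) array in units of g; ``gyro`` an (n, 3) array
    in deg/s, both sampled at ``sample_rate_hz``.
    """

    subject_id: str
    mas_label: int
    sample_rate_hz: float
    accel: np.ndarray
    gyro: np.ndarray

    def __post_init__(self) -> None:
        accel = np.atleast_2d(np.asarray(self.accel, dtype=float))
        gyro = np.atleast_2d(np.asarray(self.gyro, dtype=float))
        object.__setattr__(self, "accel", accel)
        object.__setattr__(self, "gyro", gyro)
        if self.mas_label not in MAS_LABELS:
            raise ValueError(f"mas_label must be one of {MAS_LABELS}, got {self.mas_label}")
        if accel.ndim != 2 or accel.shape[1] != 3 or gyro.shape[1] != 3:
            raise ValueError("accel and gyro must be (n, 3) arrays")
        if accel.shape[0] != gyro.shape[0] or accel.shape[0] < 1:
            raise ValueError("accel and gyro must have identical nonzero length")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    def __len__(self) -> int:
        return self.accel.shape[0]


def _subject_params(
    config: SimulationConfig, mas_label: int, rng: np.random.Generator | None
) -> tuple[float, float, float]:
    """Draw one subject's (rom, catch_frac, catch_depth).

    Without an ``rng`` the nominal grade parameters are returned. The
    number of random draws is independent of the grade so that streams
    stay aligned across configurations differing only in scale factors.
    """
    rom = float(config.rom_deg[mas_label])
    frac = float(config.catch_angle_frac[mas_label])
    depth = float(config.catch_depth[mas_label])
    if rng is not None:
        r_j, f_j, d_j = rng.standard_normal(3)
        rom = max(1.0, rom * (1.0 + config.rom_jitter_frac * r_j))
        frac = float(np.clip(frac + config.catch_angle_jitter * f_j, 0.05, 0.95))
        if depth > 0.0:
            # MAS 0 has no catch by definition; its depth stays exactly 0.
            depth = float(np.clip(depth + config.catch_depth_jitter * d_j, 0.0, 0.98))
    return rom, frac, depth


def _half_cycle(rom: float, n: int, depth: float, frac: float, width: float) -> np.ndarray:
    """Angles of one half-cycle sweeping 0 -> rom over n samples.

    The base velocity profile is a half-sine (raised-cosine angle). A
    catch of relative depth ``depth`` multiplies the velocity by a
    Gaussian notch centered where the angle passes ``frac`` of the
    excursion. The cumulative sum is renormalized so the half-cycle ends
    exactly at ``rom`` regardless of the notch.
    """
    u = (np.arange(n) + 0.5) / n
    v = np.sin(np.pi * u)
    if depth > 0.0:
        s_c = np.arccos(1.0 - 2.0 * np.clip(frac, 0.02, 0.98)) / np.pi
        v = v * (1.0 - depth * np.exp(-0.5 * ((u - s_c) / width) ** 2))
    return rom * np.cumsum(v) / np.sum(v)


def simulate_angle_trajectory(
    config: SimulationConfig, mas_label: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Elbow-angle time series (deg) for one passive-stretch assessment.

    Structure: quasi-static hold at full flexion (angle 0), then
    ``n_cycles`` flexion-extension cycles of period ``cycle_period_s``
    and grade-dependent excursion, then a trailing hold. For labels > 0
    each extension half-cycle carries the grade's velocity notch.

    ``rng`` is used only for the subject-level kinematic jitter; the
    trajectory is deterministic given the generator state (pass ``None``
    for the nominal grade kinematics).
    """
    if mas_label not in MAS_LABELS:
        raise ValueError(f"unknown MAS label {mas_label!r}; expected one of {MAS_LABELS}")
    fs = config.sample_rate_hz
    n_lead = round(config.baseline_lead_s * fs)
    n_trail = round(config.baseline_trail_s * fs)
    n_cycle = round(config.cycle_period_s * fs)
    if n_cycle < 4:
        raise ValueError("cycle_period_s too short for the sample rate")
    rom, frac, depth = _subject_params(config, mas_label, rng)
    n_ext = n_cycle // 2
    n_flex = n_cycle - n_ext
    if rng is not None:
        cycle_noise = config.cycle_jitter_frac * rng.standard_normal((config.n_cycles, 2))
    else:
        cycle_noise = np.zeros((config.n_cycles, 2))
    cycles = []
    for r_j, d_j in cycle_noise:
        rom_c = max(1.0, rom * (1.0 + r_j))
        depth_c = float(np.clip(depth * (1.0 + d_j), 0.0, 0.98)) if depth > 0 else 0.0
        extension = _half_cycle(rom_c, n_ext, depth_c, frac, config.catch_width_frac)
        flexion = rom_c - _half_cycle(rom_c, n_flex, 0.0, 0.5, config.catch_width_frac)
        cycles.append(np.concatenate([extension, flexion]))
    return np.concatenate([np.zeros(n_lead), *cycles, np.zeros(n_trail)])


def angle_to_imu(
    angles: np.ndarray, config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Forward sensor model: elbow angles -> (accel, gyro) channels.

    The gyroscope x axis carries the first difference of the angle times
    the sample rate; the accelerometer reads the gravity unit vector
    rotated through the elbow angle (ay = sin, az = cos), so the roll
    angle of the noiseless accelerometer recovers the trajectory. With an
    ``rng``, i.i.d. Gaussian noise at the configured scales is added to
    all six channels.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("angles must be nonempty")
    n = angles.size
    rad = np.radians(angles)
    accel = np.column_stack([np.zeros(n), np.sin(rad), np.cos(rad)])
    rate = np.diff(angles, prepend=angles[:1]) * config.sample_rate_hz
    gyro = np.column_stack([rate, np.zeros(n), np.zeros(n)])
    if rng is not None:
        accel = accel + config.accel_noise_sd_g * rng.standard_normal((n, 3))
        gyro = gyro + config.gyro_noise_sd_dps * rng.standard_normal((n, 3))
    return accel, gyro


def simulate_recording(
    config: SimulationConfig,
    mas_label: int,
    subject_id: str,
    rng: np.random.Generator | None = None,
) -> IMURecording:
    """One labeled recording for one subject."""
    angles = simulate_angle_trajectory(config, mas_label, rng)
    accel, gyro = angle_to_imu(angles, config, rng)
    return IMURecording(
        subject_id=subject_id,
        mas_label=int(mas_label),
        sample_rate_hz=config.sample_rate_hz,
        accel=accel,
        gyro=gyro,
    )


def simulate_cohort(
    cohort_spec: dict[int, int],
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> list[IMURecording]:
    """Simulate one recording per subject for a labeled cohort.

    ``cohort_spec`` maps MAS label -> number of subjects. Subject ids are
    unique and stable; the output is bitwise reproducible for a fixed
    (config, seed). ``seed`` defaults to ``config.seed``.
    """
    config = config if config is not None else SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    recordings: list[IMURecording] = []
    idx = 0
    for label in sorted(cohort_spec):
        count = cohort_spec[label]
        if count < 0:
            raise ValueError(f"negative subject count for label {label}")
        for _ in range(int(count)):
            subject_id = f"subj{idx:03d}_mas{MAS_GRADE_NAMES[label].replace('+', 'p')}"
            recordings.append(simulate_recording(config, label, subject_id, rng))
            idx += 1
    logger.info("simulated cohort: %d recordings across %d grades", len(recordings), len(cohort_spec))
    return recordings
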