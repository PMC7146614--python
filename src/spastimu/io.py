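"""CSV/YAML readers and writers for recordings, portions, segments and
feature matrices.

All on-disk formats are plain text: one CSV per recording with columns
``t_s, ax_g, ay_g, az_g, gx_dps, gy_dps, gz_dps``, manifests tying files
to subject ids and MAS labels, feature matrices with a fixed header, and
a flat YAML configuration mirroring the dataclasses.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import MovementPortion
from .segment import SCHEMES, Segment
from .simulate import IMURecording, SimulationConfig

RECORDING_COLUMNS = ["t_s", "ax_g", "ay_g", "az_g", "gx_dps", "gy_dps", "gz_dps"]
ACCEL_COLUMNS = RECORDING_COLUMNS[1:4]
GYRO_COLUMNS = RECORDING_COLUMNS[4:7]


class DataFormatError(ValueError):
    """Malformed or incomplete on-disk data."""


def _channels_frame(accel: np.ndarray, gyro: np.ndarray, fs: float) -> pd.DataFrame:
    n = accel.shape[0]
    frame = pd.DataFrame({"t_s": np.arange(n) / fs})
    for j, col in enumerate(ACCEL_COLUMNS):
        frame[col] = accel[:, j]
    for j, col in enumerate(GYRO_COLUMNS):
        frame[col] = gyro[:, j]
    return frame


def write_recording_csv(recording: IMURecording, path: str | Path) -> Path:
    path = Path(path)
    frame = _channels_frame(recording.accel, recording.gyro, recording.sample_rate_hz)
    # 17 significant digits: exact binary64 round-trip
    frame.to_csv(path, index=False, float_format="%.17g")
    return path


def _read_channels(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise DataFormatError(f"{path}: {exc}") from exc
    missing = [c for c in RECORDING_COLUMNS if c not in frame.columns]
    if missing:
        raise DataFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    if frame.empty:
        raise DataFormatError(f"{path}: no data rows")
    numeric = frame[RECORDING_COLUMNS].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        # +2: one for the header line, one for 1-based line numbering.
        lines = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())[:10]]
        raise DataFormatError(f"{path}: non-numeric or missing values at line(s) {lines}")
    return (
        numeric["t_s"].to_numpy(),
        numeric[ACCEL_COLUMNS].to_numpy(),
        numeric[GYRO_COLUMNS].to_numpy(),
    )


def read_recording_csv(
    path: str | Path,
    subject_id: str = "unknown",
    mas_label: int = 0,
    sample_rate_hz: float | None = None,
) -> IMURecording:
    """Parse one recording CSV; the sample rate comes from the manifest
    or, failing that, from the median time step."""
    path = Path(path)
    t, accel, gyro = _read_channels(path)
    if sample_rate_hz is None:
        steps = np.diff(t)
        if steps.size == 0 or np.median(steps) <= 0:
            raise DataFormatError(f"{path}: cannot infer sample rate from t_s")
        sample_rate_hz = 1.0 / float(np.median(steps))
    return IMURecording(
        subject_id=subject_id,
        mas_label=int(mas_label),
        sample_rate_hz=float(sample_rate_hz),
        accel=accel,
        gyro=gyro,
    )


def write_cohort(recordings: list[IMURecording], out_dir: str | Path) -> Path:
    """Write one CSV per recording plus a cohort manifest; returns the
    manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        fname = f"{rec.subject_id}.csv"
        write_recording_csv(rec, out_dir / fname)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "mas_label": rec.mas_label,
                "file": fname,
                "sample_rate_hz": rec.sample_rate_hz,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: str | Path) -> list[IMURecording]:
    manifest_path = Path(manifest_path)
    try:
        manifest = pd.read_csv(manifest_path)
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise DataFormatError(f"{manifest_path}: {exc}") from exc
    required = {"subject_id", "mas_label", "file", "sample_rate_hz"}
    missing = required - set(manifest.columns)
    if missing:
        raise DataFormatError(f"{manifest_path}: missing column(s) {sorted(missing)}")
    return [
        read_recording_csv(
            manifest_path.parent / row.file,
            subject_id=str(row.subject_id),
            mas_label=int(row.mas_label),
            sample_rate_hz=float(row.sample_rate_hz),
        )
        for row in manifest.itertuples()
    ]


def write_portions(portions: list[MovementPortion], out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for portion in portions:
        fname = f"{portion.subject_id}_portion.csv"
        frame = _channels_frame(portion.accel, portion.gyro, portion.sample_rate_hz)
        frame.to_csv(out_dir / fname, index=False, float_format="%.17g")
        rows.append(
            {
                "subject_id": portion.subject_id,
                "mas_label": portion.mas_label,
                "file": fname,
                "sample_rate_hz": portion.sample_rate_hz,
                "source_start": portion.source_bounds[0],
                "source_end": portion.source_bounds[1],
            }
        )
    manifest = out_dir / "portions.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_portions(manifest_path: str | Path) -> list[MovementPortion]:
    manifest_path = Path(manifest_path)
    try:
        manifest = pd.read_csv(manifest_path)
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise DataFormatError(f"{manifest_path}: {exc}") from exc
    portions = []
    for row in manifest.itertuples():
        _, accel, gyro = _read_channels(manifest_path.parent / row.file)
        portions.append(
            MovementPortion(
                subject_id=str(row.subject_id),
                mas_label=int(row.mas_label),
                sample_rate_hz=float(row.sample_rate_hz),
                accel=accel,
                gyro=gyro,
                source_bounds=(int(row.source_start), int(row.source_end)),
            )
        )
    return portions


def write_segments(segments: list[Segment], out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for seg in segments:
        fname = f"{seg.subject_id}_{seg.scheme}_{seg.index}.csv"
        frame = _channels_frame(seg.accel, seg.gyro, seg.sample_rate_hz)
        frame.to_csv(out_dir / fname, index=False, float_format="%.17g")
        rows.append(
            {
                "subject_id": seg.subject_id,
                "mas_label": seg.mas_label,
                "scheme": seg.scheme,
                "index": seg.index,
                "file": fname,
                "sample_rate_hz": seg.sample_rate_hz,
            }
        )
    manifest = out_dir / "segments.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_segments(manifest_path: str | Path) -> list[Segment]:
    manifest_path = Path(manifest_path)
    try:
        manifest = pd.read_csv(manifest_path)
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise DataFormatError(f"{manifest_path}: {exc}") from exc
    segments = []
    for row in manifest.itertuples():
        if row.scheme not in SCHEMES:
            raise DataFormatError(f"{manifest_path}: unknown scheme {row.scheme!r}")
        _, accel, gyro = _read_channels(manifest_path.parent / row.file)
        segments.append(
            Segment(
                subject_id=str(row.subject_id),
                mas_label=int(row.mas_label),
                scheme=str(row.scheme),
                index=int(row.index),
                accel=accel,
                gyro=gyro,
                sample_rate_hz=float(row.sample_rate_hz),
            )
        )
    return segments


def write_feature_csv(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_feature_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise DataFormatError(f"{path}: {exc}") from exc
    missing = {"subject_id", "mas_label", "scheme"} - set(table.columns)
    if missing:
        raise DataFormatError(f"{path}: missing metadata column(s) {sorted(missing)}")
    return table


def load_simulation_config(data: dict) -> SimulationConfig:
    """Build a SimulationConfig from a flat mapping, with list -> tuple
    coercion for the per-grade parameters."""
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown simulation config key(s): {sorted(unknown)}")
    coerced = {
        key: tuple(value) if isinstance(value, list) else value
        for key, value in data.items()
    }
    return SimulationConfig(**coerced)


def load_config_yaml(path: str | Path) -> dict:
    """Flat YAML config file -> dict (empty file -> empty dict)."""
    with open(path) as handle:
        data = yaml.safe_load(handle)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise DataFormatError(f"{path}: config must be a mapping")
    return data
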