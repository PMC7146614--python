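"""Windowing of movement portions into the two segmentation schemes.

Non-overlapping segmentation yields 3 windows per portion (dataset DS1);
50%-overlapping segmentation yields 5 windows (dataset DS2). Window
length is floor(L/3) under both schemes; trailing remainder samples are
discarded, never padded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .preprocess import MovementPortion

SCHEMES = ("nonoverlap", "overlap50")

#: Dataset names conventionally attached to the two schemes.
DATASET_BY_SCHEME = {"nonoverlap": "DS1", "overlap50": "DS2"}
SCHEME_BY_DATASET = {v: k for k, v in DATASET_BY_SCHEME.items()}


@dataclass(frozen=True)
class Segment:
    """One fixed-length window of a movement portion."""

    subject_id: str
    mas_label: int
    scheme: str
    index: int
    accel: np.ndarray
    gyro: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        n_windows = 3 if self.scheme == "nonoverlap" else 5
        if not 0 <= self.index < n_windows:
            raise ValueError(f"index {self.index} invalid for scheme {self.scheme}")
        if self.accel.shape[0] != self.gyro.shape[0] or self.accel.shape[0] < 1:
            raise ValueError("all six channels must share a positive window length")

    def __len__(self) -> int:
        return self.accel.shape[0]


def _window(portion: MovementPortion, scheme: str, index: int, offset: int, width: int) -> Segment:
    return Segment(
        subject_id=portion.subject_id,
        mas_label=portion.mas_label,
        scheme=scheme,
        index=index,
        accel=portion.accel[offset : offset + width],
        gyro=portion.gyro[offset : offset + width],
        sample_rate_hz=portion.sample_rate_hz,
    )


def segment_nonoverlap(portion: MovementPortion) -> list[Segment]:
    """Three disjoint windows of width floor(L/3) at offsets 0, w, 2w."""
    length = len(portion)
    if length < 3:
        raise ValueError(f"portion too short to segment (L={length})")
    w = length // 3
    return [_window(portion, "nonoverlap", i, i * w, w) for i in range(3)]


def segment_overlap50(portion: MovementPortion) -> list[Segment]:
    """Five windows of width floor(L/3) hopping by floor(w/2).

    Consecutive windows share w - h samples (exactly half when w is
    even). Requires L >= 6 so the hop is at least one sample.
    """
    length = len(portion)
    if length < 6:
        raise ValueError(f"portion too short for five overlapping windows (L={length})")
    w = length // 3
    h = w // 2
    return [_window(portion, "overlap50", i, i * h, w) for i in range(5)]


def segment_portion(portion: MovementPortion, scheme: str) -> list[Segment]:
    if scheme == "nonoverlap":
        return segment_nonoverlap(portion)
    if scheme == "overlap50":
        return segment_overlap50(portion)
    raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


def build_segment_table(portions: list[MovementPortion], scheme: str) -> list[Segment]:
    """Segment every portion, preserving subject order.

    Per-label counts come out as 3x (nonoverlap) or 5x (overlap50) the
    number of subjects carrying that label.
    """
    segments: list[Segment] = []
    for portion in portions:
        segments.extend(segment_portion(portion, scheme))
    return segments


def label_counts(segments: list[Segment]) -> dict[int, int]:
    """Segment count per MAS label."""
    return dict(sorted(Counter(s.mas_label for s in segments).items()))
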