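"""Frame-differencing motion detection with rectangular exclusion masks.

A movement is declared for a pair of consecutive grayscale frames when the
fraction of *unmasked* pixels whose intensity changed by at least
``pixel_threshold`` reaches ``area_fraction``.  This is the simplest scheme
consistent with a binary "motion detected" signal from a surveillance feed; the
magnitude (changed-pixel fraction) is kept so downstream consumers can grade
movements if they wish.

Conventions, used everywhere in the package:

* pixel coordinates are 0-based;
* rectangles are half-open ``[x0, x1) x [y0, y1)``;
* intensities are 8-bit grayscale (0-255).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import BoundsError, ConfigError, InputError, ShapeError

__all__ = [
    "Frame",
    "Mask",
    "DetectorConfig",
    "MotionSample",
    "MotionEvent",
    "build_mask",
    "detect_pair",
    "detect_sequence",
    "movement_events",
]

Rect = tuple[int, int, int, int]  # (x0, y0, x1, y1), half-open


@dataclass(frozen=True)
class Frame:
    """One grayscale frame with its timestamp in seconds from session start."""

    pixels: np.ndarray  # uint8, shape (height, width)
    timestamp: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ShapeError(f"frame pixels must be a 2-D grid, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise InputError("frame intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class Mask:
    """Boolean exclusion grid; True marks pixels ignored by the detector."""

    excluded: np.ndarray  # bool, shape (height, width)

    @property
    def width(self) -> int:
        return self.excluded.shape[1]

    @property
    def height(self) -> int:
        return self.excluded.shape[0]

    @property
    def n_excluded(self) -> int:
        return int(self.excluded.sum())


@dataclass(frozen=True)
class DetectorConfig:
    """Detector thresholds.

    pixel_threshold
        Minimum absolute intensity change (1-255) for a pixel to count as
        changed.
    area_fraction
        Minimum fraction of unmasked pixels changed, in (0, 1], to declare
        motion for the frame pair.
    debounce_ticks
        Movement-onset events separated by fewer than this many still samples
        are merged into one event.
    """

    pixel_threshold: int = 15
    area_fraction: float = 0.01
    debounce_ticks: int = 0

    def __post_init__(self) -> None:
        bad = []
        if not 1 <= self.pixel_threshold <= 255:
            bad.append("pixel_threshold must be in [1, 255]")
        if not 0 < self.area_fraction <= 1:
            bad.append("area_fraction must be in (0, 1]")
        if self.debounce_ticks < 0:
            bad.append("debounce_ticks must be >= 0")
        if bad:
            raise ConfigError("; ".join(bad))


@dataclass(frozen=True)
class MotionSample:
    """Per-tick observation: did anything move, and how much of the view."""

    timestamp: float
    moved: bool
    magnitude: float = 0.0


@dataclass(frozen=True)
class MotionEvent:
    """A debounced movement episode derived from a sample stream."""

    onset: float  # timestamp of first moved sample
    n_samples: int  # moved samples in the (merged) episode
    peak_magnitude: float


def build_mask(regions: Sequence[Rect], width: int, height: int) -> Mask:
    """Build an exclusion mask from a union of axis-aligned rectangles.

    Each rectangle is ``(x0, y0, x1, y1)``, half-open, and must lie within
    ``[0, width) x [0, height)`` (i.e. ``x1 <= width``); rectangles may overlap.
    """
    if width < 1 or height < 1:
        raise ShapeError(f"mask dimensions must be positive, got {width}x{height}")
    excluded = np.zeros((height, width), dtype=bool)
    for rect in regions:
        x0, y0, x1, y1 = rect
        if not (0 <= x0 <= x1 <= width and 0 <= y0 <= y1 <= height):
            raise BoundsError(
                f"mask rectangle {rect} outside frame bounds {width}x{height}"
            )
        excluded[y0:y1, x0:x1] = True
    return Mask(excluded=excluded)


def _check_geometry(prev: Frame, cur: Frame, mask: Mask) -> None:
    if prev.pixels.shape != cur.pixels.shape:
        raise ShapeError(
            f"frame shapes differ: {prev.pixels.shape} vs {cur.pixels.shape}"
        )
    if mask.excluded.shape != cur.pixels.shape:
        raise ShapeError(
            f"mask shape {mask.excluded.shape} does not match frames {cur.pixels.shape}"
        )


def detect_pair(prev: Frame, cur: Frame, mask: Mask, cfg: DetectorConfig) -> MotionSample:
    """Compare two consecutive frames and report a motion sample.

    magnitude = changed unmasked pixels / unmasked pixels;
    moved     = magnitude >= cfg.area_fraction.
    """
    _check_geometry(prev, cur, mask)
    visible = ~mask.excluded
    n_visible = int(visible.sum())
    if n_visible == 0:
        raise ConfigError("mask excludes every pixel: the detector is blind")
    diff = np.abs(cur.pixels.astype(np.int16) - prev.pixels.astype(np.int16))
    changed = int(((diff >= cfg.pixel_threshold) & visible).sum())
    magnitude = changed / n_visible
    return MotionSample(
        timestamp=cur.timestamp,
        moved=magnitude >= cfg.area_fraction,
        magnitude=magnitude,
    )


def detect_sequence(
    frames: Iterable[Frame], mask: Mask, cfg: DetectorConfig
) -> list[MotionSample]:
    """Run pairwise detection over a frame sequence.

    Returns one sample per consecutive pair, in order. Debouncing does not
    alter the samples themselves; use :func:`movement_events` to obtain merged
    movement-onset events.
    """
    frames = list(frames)
    if len(frames) < 2:
        raise InputError(f"need at least 2 frames, got {len(frames)}")
    samples = []
    for prev, cur in zip(frames, frames[1:]):
        if cur.timestamp <= prev.timestamp:
            raise InputError(
                f"timestamps must be strictly increasing "
                f"({prev.timestamp} -> {cur.timestamp})"
            )
        samples.append(detect_pair(prev, cur, mask, cfg))
    return samples


def movement_events(
    samples: Sequence[MotionSample], debounce_ticks: int = 0
) -> list[MotionEvent]:
    """Group moved samples into onset events, merging across short still gaps.

    A run of consecutive moved samples is one episode; two episodes separated
    by fewer than ``debounce_ticks`` still samples are merged into a single
    event (the merged event keeps the first onset and counts only moved
    samples).
    """
    events: list[MotionEvent] = []
    onset: float | None = None
    n = 0
    peak = 0.0
    still_gap = 0
    in_event = False
    for s in samples:
        if s.moved:
            if not in_event:
                onset, n, peak = s.timestamp, 0, 0.0
                in_event = True
            elif still_gap > 0 and still_gap >= debounce_ticks:
                # gap long enough: close previous, start fresh
                events.append(MotionEvent(onset, n, peak))
                onset, n, peak = s.timestamp, 0, 0.0
            n += 1
            peak = max(peak, s.magnitude)
            still_gap = 0
        elif in_event:
            still_gap += 1
    if in_event:
        events.append(MotionEvent(onset, n, peak))
    return events
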