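"""Shared data model for foot-worn IMU gait analysis.

Conventions used throughout the package:

* Signals are fixed-rate, 6-channel: tri-axial accelerometer ``AX, AY, AZ``
  in g and tri-axial gyroscope ``GX, GY, GZ`` in °/s.  ``GZ`` is the
  sagittal-plane angular velocity of the foot — the primary segmentation
  signal (mid-swing produces its dominant positive peak, the stride borders
  sit on its negative troughs).
* Intervals are half-open ``[start, end)`` in 0-based sample indices.  Two
  consecutive strides share a border sample: ``stride_k.end ==
  stride_{k+1}.start``.
* Every millisecond quantity is converted to samples through
  :func:`ms_to_samples` (round half away from zero), the single conversion
  point for all modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

CHANNELS = ("AX", "AY", "AZ", "GX", "GY", "GZ")
ACCEL_CHANNELS = ("AX", "AY", "AZ")
GYRO_CHANNELS = ("GX", "GY", "GZ")

#: Segment classes, in canonical order.
SEGMENT_CLASSES = ("stride", "transition", "rest")

DEFAULT_SAMPLE_RATE_HZ = 102.4
DEFAULT_ACCEL_RANGE_G = 6.0
DEFAULT_GYRO_RANGE_DPS = 500.0

#: Stride duration bounds applied as a post-filter by every segmenter.
MIN_STRIDE_MS = 600.0
MAX_STRIDE_MS = 2500.0


class FormatError(ValueError):
    """Malformed input file or signal container."""


class ParameterError(ValueError):
    """Invalid parameter value."""


def ms_to_samples(ms: float, sample_rate_hz: float) -> int:
    """Convert a duration in milliseconds to a sample count.

    Rounds half away from zero, e.g. 600 ms at 102.4 Hz (61.44 samples)
    gives 61.  All modules must use this single conversion point so that
    thresholds stated in milliseconds stay consistent across methods.
    """
    if ms < 0:
        raise ParameterError(f"ms must be >= 0, got {ms}")
    if sample_rate_hz <= 0:
        raise ParameterError(f"sample_rate_hz must be > 0, got {sample_rate_hz}")
    return int(math.floor(ms * sample_rate_hz / 1000.0 + 0.5))


@dataclass
class ImuRecording:
    """A fixed-rate 6-channel IMU signal with sensor-range metadata.

    ``data`` is a (T, 6) float array with columns ordered as
    :data:`CHANNELS`.  Accelerometer channels are in g, gyroscope channels
    in °/s, unless ``meta['normalized']`` is set, in which case every
    sample lies in [-1, 1] (divided by the sensor ranges).
    """

    data: np.ndarray
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    accel_range_g: float = DEFAULT_ACCEL_RANGE_G
    gyro_range_dps: float = DEFAULT_GYRO_RANGE_DPS
    subject_id: str = ""
    foot: str = "left"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(CHANNELS):
            raise FormatError(
                f"data must be (T, 6) for channels {CHANNELS}, got {self.data.shape}"
            )
        if self.data.shape[0] < 1:
            raise FormatError("recording must contain at least one sample")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("recording contains non-finite samples")
        if self.sample_rate_hz <= 0:
            raise ParameterError("sample_rate_hz must be positive")
        if self.accel_range_g <= 0 or self.gyro_range_dps <= 0:
            raise ParameterError("sensor ranges must be positive")
        if self.foot not in ("left", "right"):
            raise ParameterError(f"foot must be 'left' or 'right', got {self.foot!r}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def channel(self, name: str) -> np.ndarray:
        """Return one named channel as a 1-D view."""
        try:
            return self.data[:, CHANNELS.index(name)]
        except ValueError:
            raise FormatError(f"unknown channel {name!r}") from None

    @property
    def is_normalized(self) -> bool:
        return bool(self.meta.get("normalized", False))


def normalize_to_sensor_range(rec: ImuRecording) -> ImuRecording:
    """Scale a recording into [-1, 1] by its sensor ranges.

    Accelerometer channels are divided by ``accel_range_g``, gyroscope
    channels by ``gyro_range_dps``; the result is clipped to [-1, 1] and
    flagged in ``meta['normalized']``.  Applying the function to an
    already-normalized recording raises, preventing silent double scaling.
    """
    if rec.is_normalized:
        raise ParameterError("recording is already normalized to sensor range")
    scale = np.array(
        [rec.accel_range_g] * 3 + [rec.gyro_range_dps] * 3, dtype=float
    )
    data = np.clip(rec.data / scale, -1.0, 1.0)
    meta = dict(rec.meta)
    meta["normalized"] = True
    return replace(rec, data=data, meta=meta)


@dataclass
class Segment:
    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        self.start = int(self.start)
        self.end = int(self.end)
        if self.start < 0:
            raise ParameterError(f"segment start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ParameterError(
                f"segment start must precede end, got [{self.start}, {self.end})"
            )
        if self.label not in SEGMENT_CLASSES:
            raise ParameterError(
                f"segment class must be one of {SEGMENT_CLASSES}, got {self.label!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.end - self.start


@dataclass
class SegmentLabelSet:
    """Ordered labeled intervals (stride / transition / rest).

    Half-open sample intervals sorted by start.  Consecutive strides may
    share a border sample (``end == next.start``); a stride never overlaps
    a rest or transition, and same-class segments never overlap.
    """

    segments: list[Segment]
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        self.segments = [
            s if isinstance(s, Segment) else Segment(*s) for s in self.segments
        ]
        self.segments.sort(key=lambda s: (s.start, s.end))
        if self.sample_rate_hz <= 0:
            raise ParameterError("sample_rate_hz must be positive")
        self._validate()

    def _validate(self) -> None:
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start < a.end:  # genuine overlap (shared border is b.start == a.end)
                if a.label == b.label:
                    raise ParameterError(
                        f"overlapping {a.label} segments [{a.start},{a.end}) "
                        f"and [{b.start},{b.end})"
                    )
                if "stride" in (a.label, b.label):
                    raise ParameterError(
                        f"stride segment overlaps a {a.label if b.label == 'stride' else b.label}"
                        f" segment at [{b.start},{a.end})"
                    )

    def of_class(self, label: str) -> list[Segment]:
        return [s for s in self.segments if s.label == label]

    @property
    def strides(self) -> list[Segment]:
        return self.of_class("stride")

    def stride_intervals(self) -> np.ndarray:
        """(n, 2) int array of stride [start, end) pairs."""
        st = self.strides
        if not st:
            return np.empty((0, 2), dtype=int)
        return np.array([[s.start, s.end] for s in st], dtype=int)


@dataclass
class StrideDetection:
    """Output of a segmenter: stride intervals, or bare peaks for the
    event-based method (which marks mid-swing only, no borders)."""

    method: str
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    intervals: np.ndarray | None = None  # (n, 2) int, half-open
    peaks: np.ndarray | None = None  # (n,) int sample indices

    def __post_init__(self) -> None:
        if self.method not in ("peak", "edtw", "pdtw", "hhmm"):
            raise ParameterError(f"unknown method {self.method!r}")
        if self.intervals is not None:
            iv = np.asarray(self.intervals, dtype=int).reshape(-1, 2)
            order = np.argsort(iv[:, 0], kind="stable") if len(iv) else []
            iv = iv[order] if len(iv) else iv
            if len(iv) and np.any(iv[:, 0] >= iv[:, 1]):
                raise ParameterError("detection intervals must satisfy start < end")
            if len(iv) > 1 and np.any(iv[1:, 0] < iv[:-1, 1] - 0):
                # overlaps beyond a shared border are checked by the caller
                # (msDTW tolerates < 200 ms path overlap before resolution)
                pass
            self.intervals = iv
        if self.peaks is not None:
            pk = np.sort(np.asarray(self.peaks, dtype=int).ravel())
            self.peaks = pk

    @property
    def is_peak_based(self) -> bool:
        return self.intervals is None

    @property
    def n_detections(self) -> int:
        if self.is_peak_based:
            return 0 if self.peaks is None else len(self.peaks)
        return len(self.intervals)
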