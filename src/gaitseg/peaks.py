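"""Event-based stride segmentation by GZ mid-swing peak detection.

A sample is a detected mid-swing event iff

* its sagittal angular velocity (GZ, °/s) exceeds an amplitude threshold
  (default 150 °/s),
* it is a strict local maximum (plateaus contribute their first sample),
* it lies at least one refractory period (default 600 ms, the lower bound
  on stride duration) away from every other accepted event; conflicts
  within a refractory window are resolved greedily by descending
  amplitude, so only the highest peak in a window survives.

The method marks one point per stride and no borders; scoring uses the
peak-in-stride rule implemented in :mod:`gaitseg.evaluation`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base import BaseSegmenter
from .core import (
    ImuRecording,
    MAX_STRIDE_MS,
    MIN_STRIDE_MS,
    ParameterError,
    StrideDetection,
    ms_to_samples,
)


@dataclass
class PeakConfig:
    amp_threshold_dps: float = 150.0
    min_separation_ms: float = 600.0

    def __post_init__(self) -> None:
        if self.amp_threshold_dps <= 0:
            raise ParameterError("amp_threshold_dps must be positive")
        if self.min_separation_ms <= 0:
            raise ParameterError("min_separation_ms must be positive")


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Strict local maxima; a flat plateau yields its first sample.

    Interior points only — a monotone run ending at the signal edge is not
    a peak.
    """
    n = len(x)
    if n < 3:
        return np.empty(0, dtype=int)
    out = []
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j < n - 1 and x[j + 1] == x[i]:
                j += 1
            if j < n - 1 and x[j + 1] < x[i]:
                out.append(i)  # first sample of the plateau
            i = j + 1
        else:
            i += 1
    return np.asarray(out, dtype=int)


def detect_peaks(rec: ImuRecording, cfg: PeakConfig | None = None) -> StrideDetection:
    """Detect mid-swing GZ peaks in a physical-unit recording."""
    cfg = cfg or PeakConfig()
    if rec.is_normalized:
        raise ParameterError(
            "peak detection operates on physical units (°/s); "
            "recording is normalized to sensor range"
        )
    gz = rec.channel("GZ")
    sep = ms_to_samples(cfg.min_separation_ms, rec.sample_rate_hz)
    cand = _local_maxima(gz)
    cand = cand[gz[cand] > cfg.amp_threshold_dps]
    # greedy by descending amplitude; ties broken toward the earlier sample
    order = np.lexsort((cand, -gz[cand]))
    accepted: list[int] = []
    for idx in cand[order]:
        if all(abs(idx - a) >= sep for a in accepted):
            accepted.append(int(idx))
    return StrideDetection(
        method="peak", sample_rate_hz=rec.sample_rate_hz, peaks=np.sort(accepted)
    )


def peaks_to_intervals(
    detection: StrideDetection,
    rec: ImuRecording,
    min_stride_ms: float = MIN_STRIDE_MS,
    max_stride_ms: float = MAX_STRIDE_MS,
) -> StrideDetection:
    """Convenience conversion of peaks to rough stride intervals.

    Borders are placed on the deepest (most negative) GZ local minimum
    within half the maximal stride duration on each side of a peak —
    stride borders sit on the prominent foot-rotation troughs, and a
    shallow stance dip closer to the peak must not capture them.  Clipped
    to the signal edges.  Used for downstream parameter extraction only —
    scoring of the peak method always uses the bare peaks.
    """
    gz = rec.channel("GZ")
    n = len(gz)
    half_max = ms_to_samples(max_stride_ms, rec.sample_rate_hz) // 2
    # negative local minima = local maxima of -gz with value < 0
    minima = _local_maxima(-gz)
    minima = minima[gz[minima] < 0]
    intervals = []
    peaks = detection.peaks if detection.peaks is not None else np.empty(0, int)
    for p in peaks:
        left_cand = minima[(minima < p) & (minima >= p - half_max)]
        right_cand = minima[(minima > p) & (minima <= p + half_max)]
        start = (
            int(left_cand[np.argmin(gz[left_cand])])
            if len(left_cand)
            else max(0, p - half_max)
        )
        end = (
            int(right_cand[np.argmin(gz[right_cand])]) + 1
            if len(right_cand)
            else min(n, p + half_max)
        )
        intervals.append((start, end))
    # drop overlaps beyond a shared border (can occur for clipped edges)
    cleaned = []
    for iv in sorted(intervals):
        if cleaned and iv[0] < cleaned[-1][1]:
            continue
        cleaned.append(iv)
    return StrideDetection(
        method="peak",
        sample_rate_hz=rec.sample_rate_hz,
        intervals=np.asarray(cleaned, dtype=int).reshape(-1, 2),
        peaks=peaks,
    )


class PeakDetector(BaseSegmenter):
    """Event-based segmenter; needs no training (``fit`` records nothing).

    Parameters
    ----------
    amp_threshold_dps : float, default 150
        Minimum GZ amplitude of a mid-swing event.
    min_separation_ms : float, default 600
        Refractory period between events (lower bound on stride duration).
    """

    method = "peak"

    def __init__(self, amp_threshold_dps: float = 150.0, min_separation_ms: float = 600.0):
        self.amp_threshold_dps = amp_threshold_dps
        self.min_separation_ms = min_separation_ms

    def fit(self, X=None, y=None):
        self.fitted_ = True
        return self

    def _predict_one(self, rec: ImuRecording) -> StrideDetection:
        cfg = PeakConfig(self.amp_threshold_dps, self.min_separation_ms)
        return detect_peaks(rec, cfg)
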