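"""Readers and writers for signals, labels, detections and models.

File dialects (fixed for reproducibility; the storage format is ours):

* signals — comma-separated text, one header line ``AX,AY,AZ,GX,GY,GZ``;
* labels / detections — JSON with explicit sample-rate and interval fields.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    CHANNELS,
    DEFAULT_ACCEL_RANGE_G,
    DEFAULT_GYRO_RANGE_DPS,
    FormatError,
    ImuRecording,
    Segment,
    SegmentLabelSet,
    StrideDetection,
)


def read_imu(
    path: str | Path,
    sample_rate_hz: float,
    accel_range_g: float = DEFAULT_ACCEL_RANGE_G,
    gyro_range_dps: float = DEFAULT_GYRO_RANGE_DPS,
    **kwargs,
) -> ImuRecording:
    """Read a 6-column CSV signal file into an :class:`ImuRecording`."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty signal file") from None
    missing = [c for c in CHANNELS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing channel columns {missing}")
    block = df[list(CHANNELS)]
    if len(block) == 0:
        raise FormatError(f"{path}: signal file has a header but no samples")
    try:
        data = block.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric samples ({exc})") from None
    return ImuRecording(
        data=data,
        sample_rate_hz=sample_rate_hz,
        accel_range_g=accel_range_g,
        gyro_range_dps=gyro_range_dps,
        **kwargs,
    )


def write_imu(rec: ImuRecording, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rec.data, columns=list(CHANNELS)).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_labels(path: str | Path) -> SegmentLabelSet:
    with open(path) as fh:
        doc = json.load(fh)
    segments = [
        Segment(int(s["start"]), int(s["end"]), str(s["class"]))
        for s in doc["segments"]
    ]
    return SegmentLabelSet(segments=segments, sample_rate_hz=float(doc["sample_rate_hz"]))


def write_labels(labels: SegmentLabelSet, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "sample_rate_hz": labels.sample_rate_hz,
        "segments": [
            {"start": s.start, "end": s.end, "class": s.label}
            for s in labels.segments
        ],
    }
    path.write_text(json.dumps(doc, indent=1) + "\n")


def read_detection(path: str | Path) -> StrideDetection:
    with open(path) as fh:
        doc = json.load(fh)
    return StrideDetection(
        method=doc["method"],
        sample_rate_hz=float(doc["sample_rate_hz"]),
        intervals=np.asarray(doc["intervals"], dtype=int) if doc.get("intervals") is not None else None,
        peaks=np.asarray(doc["peaks"], dtype=int) if doc.get("peaks") is not None else None,
    )


def write_detection(det: StrideDetection, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "method": det.method,
        "sample_rate_hz": det.sample_rate_hz,
        "intervals": None if det.intervals is None else np.asarray(det.intervals).tolist(),
        "peaks": None if det.peaks is None else np.asarray(det.peaks).tolist(),
    }
    path.write_text(json.dumps(doc, indent=1) + "\n")
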