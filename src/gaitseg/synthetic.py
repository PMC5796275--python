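"""Synthetic foot-worn IMU gait generator with ground-truth labels.

The generator emulates two supervised gait-test designs:

* homogeneous straight walks — an uninterrupted run of strides, every
  sample belonging to exactly one stride, consecutive strides sharing a
  border sample; and
* TUG-like sequences (Timed Up-and-Go: rise from a chair, walk, 180° turn,
  walk back, sit) — rest and sit↔stand transition blocks around straight
  and turning stride runs.

Stride waveforms are sums of smooth Gaussian bump/trough kernels on a
normalized phase axis: the sagittal gyroscope channel GZ carries one
dominant positive mid-swing peak (well above the 150 °/s event-detection
threshold in the clean presets) and negative troughs at both borders,
matching the labeling convention that stride borders sit on negative GZ
minima.  The remaining channels are smooth quasi-periodic waveforms; AZ,
GX and GY are nearly flat, mirroring their low information content in real
foot-mounted recordings.

Variability knobs: per-stride duration jitter, shape jitter (kernel
amplitude/width perturbations), additive sensor noise, and per-subject
random effects (duration and amplitude multipliers drawn once per
subject, before any stride-level noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    DEFAULT_SAMPLE_RATE_HZ,
    ImuRecording,
    MAX_STRIDE_MS,
    MIN_STRIDE_MS,
    ParameterError,
    Segment,
    SegmentLabelSet,
    ms_to_samples,
)

#: Constant gravity component on the vertical accelerometer axis (g).
GRAVITY_AY_G = 1.0


def _bump(u: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((u - center) / width) ** 2)


@dataclass
class StrideShapeParams:
    """Parametric description of one stride's 6-channel waveform.

    Amplitudes are physical (g / °/s); jitter and noise are standard
    deviations — ``duration_jitter_sd`` and ``shape_jitter_sd`` relative,
    ``noise_sd_g`` / ``noise_sd_dps`` additive per-sample.
    """

    duration_ms: float = 1100.0
    midswing_gz_peak_dps: float = 350.0
    border_trough_gz_dps: float = -180.0
    ax_amp_g: float = 1.2
    ay_amp_g: float = 0.7
    az_amp_g: float = 0.06
    gx_amp_dps: float = 20.0
    gy_amp_dps: float = 20.0
    gx_offset_dps: float = 0.0  # sustained yaw component (turning strides)
    duration_jitter_sd: float = 0.0
    shape_jitter_sd: float = 0.0
    noise_sd_g: float = 0.0
    noise_sd_dps: float = 0.0

    def __post_init__(self) -> None:
        if not (MIN_STRIDE_MS <= self.duration_ms <= MAX_STRIDE_MS):
            raise ParameterError(
                f"duration_ms must lie in [{MIN_STRIDE_MS}, {MAX_STRIDE_MS}], "
                f"got {self.duration_ms}"
            )
        if self.border_trough_gz_dps >= 0:
            raise ParameterError("border_trough_gz_dps must be negative")
        if self.midswing_gz_peak_dps <= 0:
            raise ParameterError("midswing_gz_peak_dps must be positive")
        for name in ("duration_jitter_sd", "shape_jitter_sd", "noise_sd_g", "noise_sd_dps"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


#: Low-variability straight-walk preset: duration jitter 5 %, additive
#: noise two orders of magnitude below the 150 °/s peak-detection margin.
CLEAN_STRAIGHT = StrideShapeParams(
    duration_jitter_sd=0.05,
    shape_jitter_sd=0.02,
    noise_sd_g=0.01,
    noise_sd_dps=2.0,
)

#: Noise-free, jitter-free preset used by construction-oracle tests.
NOISELESS = StrideShapeParams()


def make_stride(
    params: StrideShapeParams,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    rng: np.random.Generator | None = None,
    duration_ms: float | None = None,
) -> np.ndarray:
    """Synthesize one stride as a (n, 6) array in physical units.

    GZ gets a dominant positive mid-swing bump of amplitude
    ``midswing_gz_peak_dps`` and negative border troughs; deterministic
    given the generator state.  ``duration_ms`` overrides the params value
    (used when the caller has already drawn a jittered duration).
    """
    rng = np.random.default_rng() if rng is None else rng
    dur = params.duration_ms if duration_ms is None else duration_ms
    n = ms_to_samples(dur, sample_rate_hz)
    if n < 2:
        raise ParameterError(f"stride duration {dur} ms gives {n} < 2 samples")
    u = np.arange(n) / n  # phase in [0, 1); sample n would be the next border

    j = params.shape_jitter_sd

    def amp(a: float) -> float:
        return a * (1.0 + j * rng.standard_normal()) if j > 0 else a

    def wid(w: float) -> float:
        return w * float(np.clip(1.0 + j * rng.standard_normal(), 0.5, 1.5)) if j > 0 else w

    gz = (
        amp(params.midswing_gz_peak_dps) * _bump(u, 0.55, wid(0.09))
        + params.border_trough_gz_dps * (_bump(u, 0.0, wid(0.07)) + _bump(u, 1.0, wid(0.07)))
        + amp(0.15 * params.border_trough_gz_dps) * _bump(u, 0.25, wid(0.10))
    )
    ax = amp(params.ax_amp_g) * (
        _bump(u, 0.08, wid(0.05)) - 0.8 * _bump(u, 0.62, wid(0.06)) + 0.5 * _bump(u, 0.78, wid(0.05))
    )
    ay = GRAVITY_AY_G + amp(params.ay_amp_g) * (
        -_bump(u, 0.50, wid(0.15)) + 0.7 * _bump(u, 0.92, wid(0.06))
    )
    az = amp(params.az_amp_g) * np.sin(2 * np.pi * u)
    gx = params.gx_offset_dps + amp(params.gx_amp_dps) * np.sin(2 * np.pi * u + 0.7)
    gy = amp(params.gy_amp_dps) * np.sin(4 * np.pi * u)

    out = np.column_stack([ax, ay, az, gx, gy, gz])
    if params.noise_sd_g > 0 or params.noise_sd_dps > 0:
        sd = np.array([params.noise_sd_g] * 3 + [params.noise_sd_dps] * 3)
        out = out + rng.standard_normal(out.shape) * sd
    return out


def _rest_block(n: int, params: StrideShapeParams, rng: np.random.Generator) -> np.ndarray:
    out = np.zeros((n, 6))
    out[:, 1] = GRAVITY_AY_G
    sd = np.array([params.noise_sd_g] * 3 + [params.noise_sd_dps] * 3)
    if np.any(sd > 0):
        out += rng.standard_normal(out.shape) * sd
    return out


def _transition_block(
    n: int,
    params: StrideShapeParams,
    rng: np.random.Generator,
    accel_excursion_g: float = 1.5,
    gz_burst_dps: float = 180.0,
) -> np.ndarray:
    """Sit↔stand block: low-frequency, high-amplitude accelerometer
    excursion plus a short foot-adjustment rotation burst on GZ (no
    mid-swing signature: the burst is narrow and sub-stride in extent)."""
    u = np.arange(n) / max(n, 1)
    out = np.zeros((n, 6))
    out[:, 0] = accel_excursion_g * np.sin(np.pi * u)
    out[:, 1] = GRAVITY_AY_G + 0.8 * accel_excursion_g * (1 - np.cos(2 * np.pi * u)) / 2
    out[:, 3] = 40.0 * np.sin(np.pi * u)
    out[:, 5] = gz_burst_dps * _bump(u, 0.5, 0.06)
    sd = np.array([params.noise_sd_g] * 3 + [params.noise_sd_dps] * 3)
    if np.any(sd > 0):
        out += rng.standard_normal(out.shape) * sd
    return out


def _draw_duration(params: StrideShapeParams, rng: np.random.Generator) -> float:
    d = params.duration_ms * (1.0 + params.duration_jitter_sd * rng.standard_normal())
    return float(np.clip(d, MIN_STRIDE_MS, MAX_STRIDE_MS))


def generate_straight_walk(
    n_strides: int,
    params: StrideShapeParams = CLEAN_STRAIGHT,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    seed: int | np.random.Generator = 0,
    subject_id: str = "S00",
    foot: str = "left",
) -> tuple[ImuRecording, SegmentLabelSet]:
    """Generate an uninterrupted run of ``n_strides`` labeled strides.

    Consecutive strides share border samples; the recording contains
    nothing but strides (total length equals the sum of stride lengths).
    """
    if n_strides < 1:
        raise ParameterError("n_strides must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chunks, segments, pos = [], [], 0
    for _ in range(n_strides):
        chunk = make_stride(params, sample_rate_hz, rng, duration_ms=_draw_duration(params, rng))
        chunks.append(chunk)
        segments.append(Segment(pos, pos + len(chunk), "stride"))
        pos += len(chunk)
    rec = ImuRecording(
        data=np.vstack(chunks),
        sample_rate_hz=sample_rate_hz,
        subject_id=subject_id,
        foot=foot,
        meta={"preset": "straight"},
    )
    return rec, SegmentLabelSet(segments=segments, sample_rate_hz=sample_rate_hz)


# ---------------------------------------------------------------------------
# TUG-like heterogeneous sequences


@dataclass
class Block:
    """One building block of a sequence recipe.

    ``kind`` ∈ {rest, transition, straight_stride_run, turn_stride_run};
    ``count`` is the number of strides for stride runs, ``duration_ms`` the
    block length for rest/transition; ``overrides`` patches the stride
    shape parameters for this block only.
    """

    kind: str
    count: int = 0
    duration_ms: float = 0.0
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        kinds = ("rest", "transition", "straight_stride_run", "turn_stride_run")
        if self.kind not in kinds:
            raise ParameterError(f"block kind must be one of {kinds}, got {self.kind!r}")
        if self.kind.endswith("stride_run") and self.count < 1:
            raise ParameterError(f"{self.kind} needs count >= 1")


#: Turning strides: slower, smaller sagittal swing, sustained yaw, more
#: shape variability than straight strides.
TURN_OVERRIDES = {
    "duration_ms": 1.3,       # multiplier on the straight duration
    "midswing_gz_peak_dps": 0.8,  # multiplier
    "gx_offset_dps": 60.0,    # absolute
    "shape_jitter_sd": 0.10,  # absolute
}


@dataclass
class SequenceRecipe:
    """Ordered blocks plus subject-level random effects and a seed."""

    blocks: list[Block]
    base_params: StrideShapeParams = field(default_factory=lambda: CLEAN_STRAIGHT)
    duration_multiplier: float = 1.0
    amplitude_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not any(b.kind.endswith("stride_run") for b in self.blocks):
            raise ParameterError("recipe must contain at least one stride block")


def default_tug_recipe(
    base_params: StrideShapeParams | None = None,
    n_straight: int = 4,
    n_turn: int = 3,
    seed: int = 0,
) -> SequenceRecipe:
    """Rest → stand-up → straight strides → turning strides → straight
    strides → sit-down → rest."""
    params = CLEAN_STRAIGHT if base_params is None else base_params
    blocks = [
        Block("rest", duration_ms=2000.0),
        Block("transition", duration_ms=1500.0),
        Block("straight_stride_run", count=n_straight),
        Block("turn_stride_run", count=n_turn, overrides=dict(TURN_OVERRIDES)),
        Block("straight_stride_run", count=n_straight),
        Block("transition", duration_ms=1500.0),
        Block("rest", duration_ms=2000.0),
    ]
    return SequenceRecipe(blocks=blocks, base_params=params, seed=seed)


def _apply_overrides(params: StrideShapeParams, overrides: dict) -> StrideShapeParams:
    """Multiplicative overrides for amplitude/duration-like fields listed
    in TURN_OVERRIDES semantics; other keys replace the value."""
    multiplicative = {"duration_ms", "midswing_gz_peak_dps"}
    changes = {}
    for key, val in overrides.items():
        base = getattr(params, key)
        changes[key] = base * val if key in multiplicative else val
    return replace(params, **changes)


def _scale_subject(params: StrideShapeParams, dur_mult: float, amp_mult: float) -> StrideShapeParams:
    dur = float(np.clip(params.duration_ms * dur_mult, MIN_STRIDE_MS, MAX_STRIDE_MS))
    return replace(
        params,
        duration_ms=dur,
        midswing_gz_peak_dps=params.midswing_gz_peak_dps * amp_mult,
        border_trough_gz_dps=params.border_trough_gz_dps * amp_mult,
        ax_amp_g=params.ax_amp_g * amp_mult,
        ay_amp_g=params.ay_amp_g * amp_mult,
    )


def generate_tug(
    recipe: SequenceRecipe,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    subject_id: str = "S00",
    foot: str = "left",
) -> tuple[ImuRecording, SegmentLabelSet]:
    """Generate one TUG-like sequence; labels cover every sample."""
    rng = np.random.default_rng(recipe.seed)
    params = _scale_subject(
        recipe.base_params, recipe.duration_multiplier, recipe.amplitude_multiplier
    )
    chunks, segments, pos = [], [], 0
    for block in recipe.blocks:
        if block.kind in ("rest", "transition"):
            n = ms_to_samples(block.duration_ms, sample_rate_hz)
            if n == 0:
                continue
            chunk = (
                _rest_block(n, params, rng)
                if block.kind == "rest"
                else _transition_block(n, params, rng)
            )
            chunks.append(chunk)
            segments.append(Segment(pos, pos + n, block.kind))
            pos += n
        else:
            p = _apply_overrides(params, block.overrides)
            for _ in range(block.count):
                chunk = make_stride(p, sample_rate_hz, rng, duration_ms=_draw_duration(p, rng))
                chunks.append(chunk)
                segments.append(Segment(pos, pos + len(chunk), "stride"))
                pos += len(chunk)
    rec = ImuRecording(
        data=np.vstack(chunks),
        sample_rate_hz=sample_rate_hz,
        subject_id=subject_id,
        foot=foot,
        meta={"preset": "tug"},
    )
    return rec, SegmentLabelSet(segments=segments, sample_rate_hz=sample_rate_hz)


# ---------------------------------------------------------------------------
# Cohorts


def generate_cohort(
    n_subjects: int,
    preset: str = "straight",
    seed: int = 0,
    n_strides: int = 20,
    base_params: StrideShapeParams = CLEAN_STRAIGHT,
    inter_subject_duration_sd: float = 0.08,
    inter_subject_amplitude_sd: float = 0.08,
    foot_asymmetry_sd: float = 0.02,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
) -> list[tuple[ImuRecording, SegmentLabelSet]]:
    """Generate a cohort with both feet per subject.

    Subject-level random effects (duration and amplitude multipliers) are
    drawn once per subject before any stride-level randomness, so the
    cohort structure is stable when only noise settings change.  Returns
    2 × ``n_subjects`` (recording, labels) pairs.
    """
    if n_subjects < 2:
        raise ParameterError("cross-validation requires n_subjects >= 2")
    if preset not in ("straight", "tug"):
        raise ParameterError(f"preset must be 'straight' or 'tug', got {preset!r}")
    rng = np.random.default_rng(seed)
    dur_mults = 1.0 + inter_subject_duration_sd * rng.standard_normal(n_subjects)
    amp_mults = 1.0 + inter_subject_amplitude_sd * rng.standard_normal(n_subjects)
    dur_mults = np.clip(dur_mults, 0.6, 1.6)
    amp_mults = np.clip(amp_mults, 0.5, 1.5)

    cohort = []
    for i in range(n_subjects):
        sid = f"S{i:02d}"
        for foot in ("left", "right"):
            foot_mult = 1.0 + foot_asymmetry_sd * rng.standard_normal()
            params = _scale_subject(base_params, dur_mults[i] * foot_mult, amp_mults[i])
            sub_seed = int(rng.integers(0, 2**31 - 1))
            if preset == "straight":
                rec, labels = generate_straight_walk(
                    n_strides, params, sample_rate_hz, seed=sub_seed,
                    subject_id=sid, foot=foot,
                )
            else:
                recipe = default_tug_recipe(base_params=params, seed=sub_seed)
                rec, labels = generate_tug(
                    recipe, sample_rate_hz, subject_id=sid, foot=foot
                )
            cohort.append((rec, labels))
    return cohort
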