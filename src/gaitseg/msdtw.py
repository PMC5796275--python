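"""Multi-subsequence DTW stride segmentation.

Subsequence DTW locates multiple warped occurrences of a short stride
template X = (x_1..x_M) inside a long gait sequence Y = (y_1..y_T):

* distance matrix ``D`` (M×T): pointwise template/sequence distances,
  summed over the selected axes;
* accumulated cost ``C``: free start along the first template row
  (C(1,t) = D(1,t)), first column C(m,1) = Σ_{i<=m} D(i,1), and
  C(m,t) = D(m,t) + min{C(m-1,t-1), C(m-1,t), C(m,t-1)} elsewhere;
* matching function ``Δ(t) = C(M,t)``: local minima below a threshold mark
  candidate stride end points; the start is found by backtracking to the
  first row (step condition: predecessor ∈ {(m-1,t-1), (m-1,t), (m,t-1)},
  ties broken diagonal → vertical → horizontal);
* post-filters: pairwise interval overlap < 200 ms (the lower-Δ match
  wins), stride duration within 600–2500 ms.

Two cost families are provided.  The Euclidean variant compares against
an averaged template (per-sample absolute difference per axis by default;
squared difference by option).  The probabilistic variant models each of
the M template positions as a diagonal Gaussian over the axes and turns
the likelihood P(y) of a sample under a position into a distance
D(y) = exp(-P(y)).  Two likelihood mappings are available:

* ``"density"`` (pipeline default): P is the Gaussian density itself.
  In normalized sensor units the per-position densities at the mean are
  well above 1, so D ≈ 0 for samples within a couple of standard
  deviations and D ≈ 1 in the far tail — the accumulated cost counts the
  poorly matching samples along a path, which is the scale the match
  thresholds (8–15 for a 200-sample template) are written in.
* ``"rescaled"``: P = exp(-½·Mahalanobis²) ∈ (0, 1], the density divided
  by its value at the mean, giving D ∈ [e^-1, 1].  This honors the view
  of the likelihood as a bounded similarity score, but compresses the
  cost scale so strongly that every path cost grows linearly with path
  length regardless of fit; it is kept for comparison, not as default.

Templates and inputs are both normalized to the sensor ranges (±6 g,
±500 °/s) so that match thresholds are scale-free.  The uninformative
axes AZ, GX, GY are excluded from templates by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .base import BaseSegmenter
from .core import (
    ImuRecording,
    MAX_STRIDE_MS,
    MIN_STRIDE_MS,
    ParameterError,
    SegmentLabelSet,
    StrideDetection,
    ms_to_samples,
    normalize_to_sensor_range,
)

DEFAULT_M = 200
DEFAULT_AXES = ("GZ",)
TEMPLATE_AXES_CHOICES = ("AX", "AY", "GZ")
MAX_OVERLAP_MS = 200.0

#: Mid-grid match thresholds per axes combination (Euclidean cost).
EUCLIDEAN_THRESHOLDS = {
    ("GZ",): 15.0,
    ("AX", "GZ"): 25.0,
    ("AY", "GZ"): 25.0,
    ("AX", "AY", "GZ"): 30.0,
}
#: Probabilistic-cost thresholds are axis-count independent; mid-grid 11.
PROBABILISTIC_THRESHOLD = 11.0


# ---------------------------------------------------------------------------
# Templates


@dataclass
class StrideTemplate:
    """Averaged stride template: (M, n_axes) values in normalized units."""

    values: np.ndarray
    axes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.axes = tuple(self.axes)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.axes):
            raise ParameterError(
                f"template values must be (M, {len(self.axes)}), got {self.values.shape}"
            )
        if self.values.shape[0] < 2:
            raise ParameterError("template length M must be >= 2")
        if np.any(np.abs(self.values) > 1.0 + 1e-12):
            raise ParameterError("template values must lie in [-1, 1]")

    @property
    def m(self) -> int:
        return self.values.shape[0]


@dataclass
class ProbabilisticTemplate:
    """Per-position diagonal Gaussians over the selected axes."""

    means: np.ndarray  # (M, n_axes)
    variances: np.ndarray  # (M, n_axes), floored strictly positive
    axes: tuple[str, ...]
    var_floor: float = 1e-4

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        self.axes = tuple(self.axes)
        if self.means.shape != self.variances.shape:
            raise ParameterError("means and variances must have identical shape")
        if self.means.shape[0] < 2:
            raise ParameterError("template length M must be >= 2")
        if np.any(self.variances <= 0):
            raise ParameterError("variances must be strictly positive (floor applied)")

    @property
    def m(self) -> int:
        return self.means.shape[0]


def _check_axes(axes) -> tuple[str, ...]:
    axes = tuple(axes)
    bad = [a for a in axes if a not in TEMPLATE_AXES_CHOICES]
    if bad:
        raise ParameterError(
            f"template axes must come from {TEMPLATE_AXES_CHOICES} "
            f"(AZ, GX, GY carry no stride information), got {bad}"
        )
    if not axes:
        raise ParameterError("at least one template axis is required")
    return axes


def _interp_to_m(segment: np.ndarray, m: int) -> np.ndarray:
    """Linearly resample a (n, k) stride segment to (m, k)."""
    n = segment.shape[0]
    if n < 2:
        raise ParameterError("training strides must have at least 2 samples")
    src = np.linspace(0.0, 1.0, n)
    dst = np.linspace(0.0, 1.0, m)
    return np.column_stack([np.interp(dst, src, segment[:, j]) for j in range(segment.shape[1])])


def extract_training_strides(
    recordings: list[ImuRecording],
    labelsets: list[SegmentLabelSet],
    axes: tuple[str, ...],
) -> list[np.ndarray]:
    """Collect labeled stride segments (physical units) on the given axes."""
    axes = _check_axes(axes)
    strides = []
    for rec, labels in zip(recordings, labelsets):
        cols = np.column_stack([rec.channel(a) for a in axes])
        for seg in labels.strides:
            strides.append(cols[seg.start : seg.end])
    return strides


def _axis_scales(axes: tuple[str, ...], accel_range_g: float, gyro_range_dps: float) -> np.ndarray:
    return np.array(
        [accel_range_g if a.startswith("A") else gyro_range_dps for a in axes]
    )


def build_average_template(
    strides: list[np.ndarray],
    m: int = DEFAULT_M,
    axes: tuple[str, ...] = DEFAULT_AXES,
    accel_range_g: float = 6.0,
    gyro_range_dps: float = 500.0,
) -> StrideTemplate:
    """Average template: each stride linearly interpolated to M samples,
    averaged positionwise, then normalized to the sensor ranges."""
    axes = _check_axes(axes)
    if not strides:
        raise ParameterError("template generation needs at least one training stride")
    resampled = np.stack([_interp_to_m(s, m) for s in strides])  # (n, M, k)
    avg = resampled.mean(axis=0)
    scale = _axis_scales(axes, accel_range_g, gyro_range_dps)
    return StrideTemplate(values=np.clip(avg / scale, -1.0, 1.0), axes=axes)


def build_probabilistic_template(
    strides: list[np.ndarray],
    m: int = DEFAULT_M,
    axes: tuple[str, ...] = DEFAULT_AXES,
    var_floor: float = 1e-4,
    accel_range_g: float = 6.0,
    gyro_range_dps: float = 500.0,
) -> ProbabilisticTemplate:
    """Probabilistic template: per-position mean and floored variance of
    the aligned training strides, in normalized units."""
    axes = _check_axes(axes)
    if len(strides) < 2:
        raise ParameterError("probabilistic template needs >= 2 training strides")
    if var_floor <= 0:
        raise ParameterError("var_floor must be positive")
    scale = _axis_scales(axes, accel_range_g, gyro_range_dps)
    resampled = np.stack([_interp_to_m(s, m) / scale for s in strides])
    means = resampled.mean(axis=0)
    variances = np.maximum(resampled.var(axis=0, ddof=0), var_floor)
    return ProbabilisticTemplate(means=means, variances=variances, axes=axes, var_floor=var_floor)


# ---------------------------------------------------------------------------
# Distance matrices


def _sequence_matrix(rec: ImuRecording, axes: tuple[str, ...]) -> np.ndarray:
    if not rec.is_normalized:
        raise ParameterError("msDTW input must be normalized to sensor range")
    return np.column_stack([rec.channel(a) for a in axes])


def distance_matrix_euclidean(
    tpl: StrideTemplate, rec: ImuRecording, squared: bool = False
) -> np.ndarray:
    """Per-axis pointwise distances summed over axes: |x_m - y_t| by
    default, (x_m - y_t)² with ``squared=True``.  Shape (M, T)."""
    seq = _sequence_matrix(rec, tpl.axes)  # (T, k)
    diff = tpl.values[:, None, :] - seq[None, :, :]  # (M, T, k)
    if squared:
        return np.square(diff).sum(axis=2)
    return np.abs(diff).sum(axis=2)


def position_likelihood(
    ptpl: ProbabilisticTemplate, seq: np.ndarray, mapping: str = "density"
) -> np.ndarray:
    """Likelihood P(y_t under position m), shape (M, T).

    ``mapping="density"``: multivariate Gaussian density (diagonal
    covariance, product over axes).  ``mapping="rescaled"``: density
    divided by its value at the mean, exp(-½ Σ_axes (y-μ)²/σ²) ∈ (0, 1].
    """
    maha = (
        np.square(seq[None, :, :] - ptpl.means[:, None, :]) / ptpl.variances[:, None, :]
    ).sum(axis=2)
    if mapping == "rescaled":
        return np.exp(-0.5 * maha)
    if mapping != "density":
        raise ParameterError(f"unknown likelihood mapping {mapping!r}")
    k = ptpl.means.shape[1]
    lognorm = 0.5 * (k * np.log(2 * np.pi) + np.log(ptpl.variances).sum(axis=1))
    return np.exp(-0.5 * maha - lognorm[:, None])


def distance_matrix_probabilistic(
    ptpl: ProbabilisticTemplate, rec: ImuRecording, mapping: str = "density"
) -> np.ndarray:
    """D(m,t) = exp(-P(y_t under position m)).

    With the rescaled mapping the entries lie in [e^-1, 1] (a sample at
    the position mean gives exactly e^-1); with the density mapping a
    well-matching sample drives D toward 0 whenever the per-position
    density at the mean exceeds 1, as it does in normalized sensor units.
    """
    seq = _sequence_matrix(rec, ptpl.axes)
    return np.exp(-position_likelihood(ptpl, seq, mapping=mapping))


# ---------------------------------------------------------------------------
# Accumulated cost, matching, backtracking


def accumulate_cost(D: np.ndarray) -> np.ndarray:
    """Subsequence-DTW accumulated cost with a free start along row 1."""
    D = np.asarray(D, dtype=float)
    if D.ndim != 2:
        raise ParameterError("D must be 2-D (M, T)")
    if not np.all(np.isfinite(D)):
        raise ParameterError("D must be finite")
    M, T = D.shape
    C = np.empty_like(D)
    C[0, :] = D[0, :]
    C[:, 0] = np.cumsum(D[:, 0])
    for t in range(1, T):
        col = C[:, t - 1]
        # C[m,t] depends on C[m-1,t] -> sequential in m, vectorized via
        # minimum.accumulate of the two column-(t-1) predecessors
        best_prev = np.minimum(col[:-1], col[1:])  # min(C(m-1,t-1), C(m,t-1)) for m>=1
        c = np.empty(M)
        c[0] = D[0, t]
        # running recursion: c[m] = D[m,t] + min(best_prev[m-1], c[m-1])
        acc = c[0]
        for m in range(1, M):
            acc = D[m, t] + min(best_prev[m - 1], acc)
            c[m] = acc
        C[:, t] = c
    return C


def _accumulate_cost_fast(D: np.ndarray) -> np.ndarray:
    """Anti-diagonal vectorized variant of :func:`accumulate_cost`."""
    M, T = D.shape
    C = np.full((M, T), np.inf)
    C[0, :] = D[0, :]
    C[:, 0] = np.cumsum(D[:, 0])
    # process anti-diagonals m + t = s; cells with m>=1, t>=1
    for s in range(2, M + T - 1):
        m_lo = max(1, s - (T - 1))
        m_hi = min(M - 1, s - 1)
        if m_lo > m_hi:
            continue
        m = np.arange(m_lo, m_hi + 1)
        t = s - m
        prev = np.minimum(
            np.minimum(C[m - 1, t - 1], C[m - 1, t]), C[m, t - 1]
        )
        C[m, t] = D[m, t] + prev
    return C


def matching_function(C: np.ndarray) -> np.ndarray:
    """Δ(t): accumulated cost of warping the full template to a
    subsequence ending at t (the row of C for the last template position)."""
    return C[-1, :]


def backtrack(C: np.ndarray, t_end: int) -> list[tuple[int, int]]:
    """Warping path from (M-1, t_end) down to row 0, in ascending order.

    Ties among the three predecessors prefer diagonal, then vertical,
    then horizontal.  Row 0 has a free start, so the path terminates the
    moment it reaches it.
    """
    M = C.shape[0]
    m, t = M - 1, int(t_end)
    path = [(m, t)]
    while m > 0:
        if t == 0:
            m -= 1
        else:
            options = (
                (C[m - 1, t - 1], m - 1, t - 1),  # diagonal
                (C[m - 1, t], m - 1, t),  # vertical
                (C[m, t - 1], m, t - 1),  # horizontal
            )
            best = min(options, key=lambda o: o[0])
            m, t = best[1], best[2]
        path.append((m, t))
    path.reverse()
    return path


@dataclass
class MsdtwConfig:
    cost: str = "euclidean"  # {"euclidean", "probabilistic"}
    axes: tuple[str, ...] = DEFAULT_AXES
    threshold: float | None = None  # None -> mid-grid default for the cost/axes
    max_overlap_ms: float = MAX_OVERLAP_MS
    min_stride_ms: float = MIN_STRIDE_MS
    max_stride_ms: float = MAX_STRIDE_MS
    squared: bool = False  # squared-difference pointwise metric (Euclidean)
    likelihood_mapping: str = "density"  # {"density", "rescaled"} for pDTW
    var_floor: float = 1e-4

    def __post_init__(self) -> None:
        if self.cost not in ("euclidean", "probabilistic"):
            raise ParameterError(f"unknown cost {self.cost!r}")
        self.axes = _check_axes(self.axes)
        if self.threshold is None:
            if self.cost == "euclidean":
                self.threshold = EUCLIDEAN_THRESHOLDS.get(tuple(sorted(self.axes)), 15.0)
            else:
                self.threshold = PROBABILISTIC_THRESHOLD
        if self.threshold <= 0:
            raise ParameterError("threshold must be positive")
        if self.min_stride_ms >= self.max_stride_ms:
            raise ParameterError("min_stride_ms must be below max_stride_ms")


@dataclass
class MsdtwWorkspace:
    """Intermediate matrices of one segmentation run (for inspection)."""

    D: np.ndarray
    C: np.ndarray
    delta: np.ndarray
    paths: list[list[tuple[int, int]]] = field(default_factory=list)


def _local_minima_below(
    delta: np.ndarray, threshold: float, half_width: int
) -> list[int]:
    """Indices t with Δ(t) below threshold and minimal within a
    neighborhood of ±half_width; ties go to the earlier index."""
    T = len(delta)
    out = []
    for t in range(T):
        if delta[t] >= threshold:
            continue
        lo, hi = max(0, t - half_width), min(T, t + half_width + 1)
        window = delta[lo:hi]
        if delta[t] > window.min():
            continue
        if int(np.argmin(window)) + lo == t:  # first index attaining the min
            out.append(t)
    return out


def find_matches(
    workspace: MsdtwWorkspace,
    cfg: MsdtwConfig,
    sample_rate_hz: float,
) -> StrideDetection:
    """Extract stride intervals from the matching function.

    Candidate end points are local minima of Δ below the threshold;
    starts come from backtracking.  Candidates are then filtered: stride
    duration must lie within the configured bounds and pairwise temporal
    overlap must stay below 200 ms, lower-Δ matches taking precedence.
    """
    delta = workspace.delta
    min_len = ms_to_samples(cfg.min_stride_ms, sample_rate_hz)
    max_len = ms_to_samples(cfg.max_stride_ms, sample_rate_hz)
    max_overlap = ms_to_samples(cfg.max_overlap_ms, sample_rate_hz)
    half_width = max(1, min_len // 2)

    candidates = []
    for t_end in _local_minima_below(delta, cfg.threshold, half_width):
        path = backtrack(workspace.C, t_end)
        t_start = path[0][1]
        length = t_end + 1 - t_start
        if min_len <= length <= max_len:
            candidates.append((delta[t_end], t_start, t_end, path))

    accepted: list[tuple[float, int, int, list]] = []
    for cand in sorted(candidates, key=lambda c: (c[0], c[1])):
        _, s, e, _ = cand
        ok = True
        for _, s2, e2, _ in accepted:
            overlap = min(e + 1, e2 + 1) - max(s, s2)
            if overlap >= max_overlap:
                ok = False
                break
        if ok:
            accepted.append(cand)

    accepted.sort(key=lambda c: c[1])
    workspace.paths = [c[3] for c in accepted]
    intervals = np.asarray([[s, e + 1] for _, s, e, _ in accepted], dtype=int).reshape(-1, 2)
    method = "edtw" if cfg.cost == "euclidean" else "pdtw"
    return StrideDetection(method=method, sample_rate_hz=sample_rate_hz, intervals=intervals)


def segment_msdtw(
    rec: ImuRecording,
    template: StrideTemplate | ProbabilisticTemplate,
    cfg: MsdtwConfig | None = None,
    return_workspace: bool = False,
):
    """Full msDTW segmentation of one recording against a template."""
    cfg = cfg or MsdtwConfig(
        cost="euclidean" if isinstance(template, StrideTemplate) else "probabilistic"
    )
    if not rec.is_normalized:
        rec = normalize_to_sensor_range(rec)
    if cfg.cost == "euclidean":
        if not isinstance(template, StrideTemplate):
            raise ParameterError("euclidean cost requires a StrideTemplate")
        D = distance_matrix_euclidean(template, rec, squared=cfg.squared)
    else:
        if not isinstance(template, ProbabilisticTemplate):
            raise ParameterError("probabilistic cost requires a ProbabilisticTemplate")
        D = distance_matrix_probabilistic(template, rec, mapping=cfg.likelihood_mapping)
    C = _accumulate_cost_fast(D)
    workspace = MsdtwWorkspace(D=D, C=C, delta=matching_function(C))
    detection = find_matches(workspace, cfg, rec.sample_rate_hz)
    if return_workspace:
        return detection, workspace
    return detection


# ---------------------------------------------------------------------------
# Estimators


class _DtwSegmenterBase(BaseSegmenter):
    def _template_from(self, X, y):
        strides = extract_training_strides(X, y, _check_axes(self.axes))
        if not strides:
            raise ParameterError("no labeled strides in the training data")
        ranges = (X[0].accel_range_g, X[0].gyro_range_dps)
        return strides, ranges


class EuclideanDtwSegmenter(_DtwSegmenterBase):
    """msDTW segmenter with an averaged (Euclidean-cost) template.

    Parameters
    ----------
    axes : tuple of str, default ("GZ",)
        Template axes, a subset of {AX, AY, GZ}.
    threshold : float or None
        Match threshold on the accumulated cost; None selects the
        mid-grid default for the axes combination (GZ alone: 15).
    m : int, default 200
        Template length in samples.
    squared : bool, default False
        Use squared differences instead of absolute differences.
    """

    method = "edtw"

    def __init__(
        self,
        axes: tuple[str, ...] = DEFAULT_AXES,
        threshold: float | None = None,
        m: int = DEFAULT_M,
        squared: bool = False,
        min_stride_ms: float = MIN_STRIDE_MS,
        max_stride_ms: float = MAX_STRIDE_MS,
    ):
        self.axes = axes
        self.threshold = threshold
        self.m = m
        self.squared = squared
        self.min_stride_ms = min_stride_ms
        self.max_stride_ms = max_stride_ms

    def fit(self, X, y):
        strides, (ar, gr) = self._template_from(X, y)
        self.template_ = build_average_template(
            strides, self.m, tuple(self.axes), accel_range_g=ar, gyro_range_dps=gr
        )
        self.fitted_ = True
        return self

    def _config(self) -> MsdtwConfig:
        return MsdtwConfig(
            cost="euclidean",
            axes=tuple(self.axes),
            threshold=self.threshold,
            squared=self.squared,
            min_stride_ms=self.min_stride_ms,
            max_stride_ms=self.max_stride_ms,
        )

    def _predict_one(self, rec: ImuRecording) -> StrideDetection:
        return segment_msdtw(rec, self.template_, self._config())


class ProbabilisticDtwSegmenter(_DtwSegmenterBase):
    """msDTW segmenter with a per-position Gaussian template.

    The match threshold (default 11, mid-grid) does not depend on the
    axes combination: the distance is built from a rescaled likelihood
    and is bounded per cell regardless of dimensionality.
    """

    method = "pdtw"

    def __init__(
        self,
        axes: tuple[str, ...] = DEFAULT_AXES,
        threshold: float | None = None,
        m: int = DEFAULT_M,
        var_floor: float = 1e-4,
        likelihood_mapping: str = "density",
        min_stride_ms: float = MIN_STRIDE_MS,
        max_stride_ms: float = MAX_STRIDE_MS,
    ):
        self.axes = axes
        self.threshold = threshold
        self.m = m
        self.var_floor = var_floor
        self.likelihood_mapping = likelihood_mapping
        self.min_stride_ms = min_stride_ms
        self.max_stride_ms = max_stride_ms

    def fit(self, X, y):
        strides, (ar, gr) = self._template_from(X, y)
        self.template_ = build_probabilistic_template(
            strides, self.m, tuple(self.axes), var_floor=self.var_floor,
            accel_range_g=ar, gyro_range_dps=gr,
        )
        self.fitted_ = True
        return self

    def _config(self) -> MsdtwConfig:
        return MsdtwConfig(
            cost="probabilistic",
            axes=tuple(self.axes),
            threshold=self.threshold,
            likelihood_mapping=self.likelihood_mapping,
            var_floor=self.var_floor,
            min_stride_ms=self.min_stride_ms,
            max_stride_ms=self.max_stride_ms,
        )

    def _predict_one(self, rec: ImuRecording) -> StrideDetection:
        return segment_msdtw(rec, self.template_, self._config())
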