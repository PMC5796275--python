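"""Two-level hierarchical HMM stride segmentation.

Top-level states are movement classes (stride / transition / rest); each
expands into a left-to-right chain of emitting sub-states with Gaussian
mixture (diagonal-covariance) observation densities.  The model is
trained semi-supervised: the top-level state of every frame is clamped to
its label during Baum–Welch (realized by masking emission likelihoods of
other states to -inf), while the sub-state alignment within each class is
learned unsupervised.  Decoding runs an unconstrained Viterbi over the
flattened two-level transition structure; each completed pass through the
stride sub-chain yields one stride interval.

Observations are sliding-window features: each axis of a Hann-weighted
window contributes its windowed samples (the "raw" feature), mean,
variance, energy (sum of squares) and the three coefficients of a
second-order polynomial fit.  Features are z-scored and reduced by PCA,
both fitted on training frames only.

The flattened transition matrix stays row-stochastic under a structural
mask: a sub-state may move to itself or its successor; the last sub-state
of a chain may also exit to the entry sub-state of any top-level
successor (including its own chain, which is what lets consecutive
strides follow each other back to back).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import hann
from scipy.special import logsumexp
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture
from sklearn.preprocessing import StandardScaler

from .base import BaseSegmenter
from .core import (
    ImuRecording,
    MAX_STRIDE_MS,
    MIN_STRIDE_MS,
    ParameterError,
    SegmentLabelSet,
    StrideDetection,
    ms_to_samples,
)

LOG_ZERO = -1e30  # soft -inf: keeps arithmetic finite while forbidding a path

#: Parameter grid explored by grid search (window length in s; sub-state
#: counts for stride / transition; GMM components; PCA components).
DEFAULT_GRID = {
    "window_len_s": [0.10, 0.30, 0.50, 0.70],
    "n_substates_stride": [4, 6, 8, 10, 12],
    "n_substates_transition": [2, 4],
    "n_mix": [8, 10, 12],
    "n_pca": [1, 3, 5, 7, 9, 11, 13, 15],
}


def mid_grid(grid: dict[str, list]) -> dict:
    """Middle element of each grid axis (lower middle for even lengths)."""
    return {k: v[(len(v) - 1) // 2] for k, v in grid.items()}


# ---------------------------------------------------------------------------
# Feature extraction


@dataclass
class FeatureConfig:
    """Sliding-window feature extraction settings.

    ``raw_mode`` selects what the "raw data" feature contributes per axis:
    the full Hann-windowed sample vector (``"windowed"``, dimension grows
    with the window) or only the center sample (``"center"``).
    ``weight_stats`` applies the Hann weights before computing mean /
    variance / energy / polynomial features as well; with ``False`` those
    statistics are computed on the unweighted window.
    """

    window_len_s: float = 0.30
    hop_frac: float = 0.25
    raw_mode: str = "windowed"
    weight_stats: bool = True

    def __post_init__(self) -> None:
        if self.window_len_s <= 0:
            raise ParameterError("window_len_s must be positive")
        if not (0 < self.hop_frac <= 1):
            raise ParameterError("hop_frac must lie in (0, 1]")
        if self.raw_mode not in ("windowed", "center"):
            raise ParameterError("raw_mode must be 'windowed' or 'center'")

    def window_samples(self, sample_rate_hz: float) -> int:
        win = ms_to_samples(self.window_len_s * 1000.0, sample_rate_hz)
        if win < 3:
            raise ParameterError(
                f"window of {self.window_len_s} s is {win} samples; need >= 3"
            )
        return win

    def hop_samples(self, sample_rate_hz: float) -> int:
        return max(1, int(round(self.window_samples(sample_rate_hz) * self.hop_frac)))


def frame_centers(n_samples: int, win: int, hop: int) -> np.ndarray:
    n_frames = (n_samples - win) // hop + 1
    return np.arange(n_frames) * hop + win // 2


def extract_features(rec: ImuRecording, cfg: FeatureConfig) -> np.ndarray:
    """(n_frames, n_features) sliding-window feature matrix.

    Frame f covers samples [f*hop, f*hop + win); frame count is
    floor((T - win)/hop) + 1.  Raises if the recording is shorter than
    one window.
    """
    win = cfg.window_samples(rec.sample_rate_hz)
    hop = cfg.hop_samples(rec.sample_rate_hz)
    T = rec.n_samples
    if T < win:
        raise ParameterError(
            f"recording of {T} samples is shorter than the {win}-sample window"
        )
    w = hann(win, sym=True)
    x_poly = np.linspace(-1.0, 1.0, win)

    blocks = []
    for j in range(rec.data.shape[1]):
        frames = sliding_window_view(rec.data[:, j], win)[::hop]  # (F, win)
        windowed = frames * w
        stats_src = windowed if cfg.weight_stats else frames
        mean = stats_src.mean(axis=1)
        var = stats_src.var(axis=1)
        energy = np.square(stats_src).sum(axis=1)
        # 2nd-order polynomial fit coefficients (constant, linear, quadratic)
        coefs = np.polynomial.polynomial.polyfit(x_poly, stats_src.T, 2).T  # (F, 3)
        if cfg.raw_mode == "windowed":
            raw = windowed
        else:
            raw = frames[:, win // 2 : win // 2 + 1]
        blocks.append(np.column_stack([raw, mean, var, energy, coefs]))
    return np.concatenate(blocks, axis=1)


def fit_normalizer_and_pca(
    train_features: np.ndarray, n_components: int
) -> tuple[StandardScaler, PCA]:
    """Z-score normalization then PCA, both fitted on training frames."""
    if n_components > train_features.shape[1]:
        raise ParameterError(
            f"n_components={n_components} exceeds feature dimension "
            f"{train_features.shape[1]}"
        )
    scaler = StandardScaler().fit(train_features)
    pca = PCA(n_components=n_components).fit(scaler.transform(train_features))
    return scaler, pca


def frame_labels(
    labels: SegmentLabelSet, centers: np.ndarray, background: str = "rest"
) -> list[str]:
    """Top-level class of each frame = class of the segment containing its
    window center; uncovered samples fall to the background class."""
    out = []
    for c in centers:
        hit = background
        for seg in labels.segments:
            if seg.start <= c < seg.end:
                hit = seg.label  # later segments win a shared border sample
        out.append(hit)
    return out


# ---------------------------------------------------------------------------
# Model


@dataclass
class HhmmModel:
    """Flattened two-level model: every (state, sub-state) pair is one row
    of the transition matrix; the left-to-right mask is structural and
    survives every Baum–Welch update."""

    states: tuple[str, ...]
    n_substates: dict[str, int]
    log_pi: np.ndarray  # (S,)
    log_A: np.ndarray  # (S, S)
    mask: np.ndarray  # (S, S) bool, allowed transitions
    gmm_weights: list[np.ndarray]  # per flat state: (K_s,)
    gmm_means: list[np.ndarray]  # per flat state: (K_s, D)
    gmm_vars: list[np.ndarray]  # per flat state: (K_s, D)
    scaler: StandardScaler | None = None
    pca: PCA | None = None
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    cov_floor: float = 1e-6
    trained: bool = False

    @property
    def flat_states(self) -> list[tuple[str, int]]:
        return [(s, j) for s in self.states for j in range(self.n_substates[s])]

    @property
    def n_flat(self) -> int:
        return sum(self.n_substates[s] for s in self.states)

    def top_of(self) -> np.ndarray:
        """Index of the top-level state of each flat state."""
        return np.array(
            [self.states.index(s) for s, _ in self.flat_states], dtype=int
        )

    def validate(self, tol: float = 1e-8) -> None:
        A = np.exp(self.log_A)
        if not np.allclose(A.sum(axis=1), 1.0, atol=tol):
            raise ParameterError("transition rows must sum to 1")
        if not math.isclose(float(np.exp(self.log_pi).sum()), 1.0, abs_tol=tol):
            raise ParameterError("initial probabilities must sum to 1")
        if np.any(np.exp(self.log_A[~self.mask]) > tol):
            raise ParameterError("left-to-right mask violated")
        for w in self.gmm_weights:
            if not math.isclose(float(w.sum()), 1.0, abs_tol=1e-6):
                raise ParameterError("GMM weights must sum to 1")
        for v in self.gmm_vars:
            if np.any(v < self.cov_floor * (1 - 1e-9)):
                raise ParameterError("GMM variance below floor")

    def transform(self, features: np.ndarray) -> np.ndarray:
        out = features
        if self.scaler is not None:
            out = self.scaler.transform(out)
        if self.pca is not None:
            out = self.pca.transform(out)
        return out

    def emission_loglik(self, Z: np.ndarray) -> np.ndarray:
        """(T, S) log p(z_t | flat state s) under the per-sub-state GMMs."""
        T = Z.shape[0]
        B = np.empty((T, self.n_flat))
        for s in range(self.n_flat):
            w, mu, var = self.gmm_weights[s], self.gmm_means[s], self.gmm_vars[s]
            # (T, K): log w_k + log N(z; mu_k, diag var_k)
            quad = np.square(Z[:, None, :] - mu[None, :, :]) / var[None, :, :]
            logdet = np.log(var).sum(axis=1)
            ll = -0.5 * (quad.sum(axis=2) + logdet + mu.shape[1] * np.log(2 * np.pi))
            B[:, s] = logsumexp(ll + np.log(np.maximum(w, 1e-300))[None, :], axis=1)
        return B


def build_mask(states: tuple[str, ...], n_substates: dict[str, int]) -> np.ndarray:
    """Structural transition mask of the flattened two-level model."""
    flat = [(s, j) for s in states for j in range(n_substates[s])]
    S = len(flat)
    mask = np.zeros((S, S), dtype=bool)
    index = {fs: i for i, fs in enumerate(flat)}
    for s in states:
        n = n_substates[s]
        for j in range(n):
            i = index[(s, j)]
            mask[i, i] = True  # self loop
            if j + 1 < n:
                mask[i, index[(s, j + 1)]] = True  # advance
            else:
                for s2 in states:  # exit to any top-level successor's entry
                    mask[i, index[(s2, 0)]] = True
    return mask


def init_model(
    recordings_features: list[np.ndarray],
    labelsets: list[SegmentLabelSet],
    sample_rate_hz: float,
    n_substates: dict[str, int],
    n_mix: int = 10,
    feature_config: FeatureConfig | None = None,
    cov_floor: float = 1e-6,
    seed: int = 0,
    transition_smoothing: float = 1e-3,
) -> HhmmModel:
    """Initialize the flattened model from labeled training data.

    ``recordings_features`` are already-transformed (normalized + PCA)
    frame matrices.  The top-level transition matrix comes from
    frame-level label bigrams; frames are assigned to sub-states by
    uniform temporal slicing within each labeled segment, and each
    sub-state's GMM is fitted on the frames so assigned.  Second-level
    transitions are uniform over the allowed left-to-right entries.
    """
    cfg = feature_config or FeatureConfig()
    win = cfg.window_samples(sample_rate_hz)
    hop = cfg.hop_samples(sample_rate_hz)

    # frame labels and per-segment frame spans
    all_frame_labels: list[list[str]] = []
    per_sub_frames: dict[tuple[str, int], list[np.ndarray]] = {}
    observed = set()
    for Z, labels in zip(recordings_features, labelsets):
        centers = frame_centers(len(Z) * hop + win - hop, win, hop)[: len(Z)]
        fl = frame_labels(labels, centers)
        all_frame_labels.append(fl)
        observed.update(seg.label for seg in labels.segments)
        observed.update(fl)  # background class if any frame is uncovered
        for seg in labels.segments:
            idx = np.where((centers >= seg.start) & (centers < seg.end))[0]
            if len(idx) == 0:
                continue
            n_sub = n_substates.get(seg.label, 1)
            for j, chunk in enumerate(np.array_split(idx, n_sub)):
                if len(chunk):
                    per_sub_frames.setdefault((seg.label, j), []).append(Z[chunk])
        # frames outside any segment belong to the background class, sub 0
        covered = np.zeros(len(centers), dtype=bool)
        for seg in labels.segments:
            covered |= (centers >= seg.start) & (centers < seg.end)
        if np.any(~covered):
            per_sub_frames.setdefault(("rest", 0), []).append(Z[~covered])

    states = tuple(s for s in ("stride", "transition", "rest") if s in observed)
    for s in states:
        if not any(k[0] == s for k in per_sub_frames):
            raise ParameterError(f"state {s!r} has no labeled frames")
    n_sub_eff = {s: n_substates.get(s, 1) for s in states}

    # top-level bigrams at frame level
    S_top = len(states)
    top_counts = np.full((S_top, S_top), transition_smoothing)
    init_counts = np.full(S_top, transition_smoothing)
    for fl in all_frame_labels:
        init_counts[states.index(fl[0])] += 1
        for a, b in zip(fl, fl[1:]):
            top_counts[states.index(a), states.index(b)] += 1
    top_A = top_counts / top_counts.sum(axis=1, keepdims=True)
    top_pi = init_counts / init_counts.sum()

    # GMMs per sub-state
    rng = np.random.default_rng(seed)
    weights, means, variances = [], [], []
    flat = [(s, j) for s in states for j in range(n_sub_eff[s])]
    D = recordings_features[0].shape[1]
    for s, j in flat:
        frames = per_sub_frames.get((s, j))
        if frames is None:
            # a sub-state starved by short segments: reuse the state's pool
            pool = [f for (s2, _), fl2 in per_sub_frames.items() if s2 == s for f in fl2]
            frames = pool
        X = np.vstack(frames)
        k = int(min(n_mix, max(1, len(X) // 2)))
        if len(X) >= 2 * k and k > 1:
            gm = GaussianMixture(
                n_components=k,
                covariance_type="diag",
                reg_covar=cov_floor,
                random_state=int(rng.integers(0, 2**31 - 1)),
                max_iter=50,
            ).fit(X)
            w, mu, var = gm.weights_, gm.means_, gm.covariances_
        else:
            w = np.ones(1)
            mu = X.mean(axis=0, keepdims=True)
            var = np.maximum(X.var(axis=0, keepdims=True), cov_floor)
        weights.append(np.asarray(w))
        means.append(np.asarray(mu).reshape(-1, D))
        variances.append(np.maximum(np.asarray(var).reshape(-1, D), cov_floor))

    # flattened transitions: uniform within-chain, exits weighted by top_A
    mask = build_mask(states, n_sub_eff)
    S = len(flat)
    index = {fs: i for i, fs in enumerate(flat)}
    A = np.zeros((S, S))
    for s in states:
        n = n_sub_eff[s]
        si = states.index(s)
        for j in range(n):
            i = index[(s, j)]
            if j + 1 < n:
                A[i, i] = 0.5
                A[i, index[(s, j + 1)]] = 0.5
            else:
                A[i, i] = 0.5
                exit_mass = 0.5 * top_A[si] / top_A[si].sum()
                for s2 in states:
                    A[i, index[(s2, 0)]] += exit_mass[states.index(s2)]
    A /= A.sum(axis=1, keepdims=True)

    pi = np.zeros(S)
    for s in states:
        si = states.index(s)
        n = n_sub_eff[s]
        if n == 1:
            pi[index[(s, 0)]] = top_pi[si]
        else:
            pi[index[(s, 0)]] = top_pi[si] * 0.9
            for j in range(1, n):
                pi[index[(s, j)]] = top_pi[si] * 0.1 / (n - 1)
    pi /= pi.sum()

    with np.errstate(divide="ignore"):
        log_A = np.where(A > 0, np.log(np.maximum(A, 1e-300)), LOG_ZERO)
        log_pi = np.where(pi > 0, np.log(np.maximum(pi, 1e-300)), LOG_ZERO)
    model = HhmmModel(
        states=states,
        n_substates=n_sub_eff,
        log_pi=log_pi,
        log_A=log_A,
        mask=mask,
        gmm_weights=weights,
        gmm_means=means,
        gmm_vars=variances,
        feature_config=cfg,
        cov_floor=cov_floor,
    )
    model.validate(tol=1e-6)
    return model


# ---------------------------------------------------------------------------
# Baum-Welch (clamped) and Viterbi


def _clamp_emissions(model: HhmmModel, B: np.ndarray, fl: list[str]) -> np.ndarray:
    """Mask emission log-likelihoods so each frame can only occupy flat
    states of its labeled top-level state (training only)."""
    tops = model.top_of()
    label_idx = np.array([model.states.index(l) for l in fl])
    out = B.copy()
    out[label_idx[:, None] != tops[None, :]] = LOG_ZERO
    return out


def _forward_backward(log_pi, log_A, B):
    """Log-domain forward-backward; returns (log_gamma, log_xi_sum, ll)."""
    T, S = B.shape
    alpha = np.empty((T, S))
    beta = np.empty((T, S))
    alpha[0] = log_pi + B[0]
    for t in range(1, T):
        alpha[t] = B[t] + logsumexp(alpha[t - 1][:, None] + log_A, axis=0)
    ll = float(logsumexp(alpha[-1]))
    beta[-1] = 0.0
    for t in range(T - 2, -1, -1):
        beta[t] = logsumexp(log_A + (B[t + 1] + beta[t + 1])[None, :], axis=1)
    log_gamma = alpha + beta - ll
    if T > 1:
        log_xi = (
            alpha[:-1, :, None] + log_A[None, :, :] + (B[1:] + beta[1:])[:, None, :] - ll
        )
        xi_sum = np.exp(np.clip(log_xi, -700, 50)).sum(axis=0)
    else:
        xi_sum = np.zeros((S, S))
    return log_gamma, xi_sum, ll


def train_bw(
    model: HhmmModel,
    recordings_features: list[np.ndarray],
    frame_label_lists: list[list[str]],
    max_iter: int = 20,
    tol: float = 1e-4,
) -> HhmmModel:
    """Semi-supervised Baum–Welch on the flattened model (in place).

    The top level is supervised: each frame's state occupancy is clamped
    to its label.  Sub-state responsibilities are free.  Stops after
    ``max_iter`` iterations (default 20) or when the relative improvement
    of the total log-likelihood falls below ``tol``.  The per-iteration
    log-likelihood history is stored in ``model.ll_history_``.
    """
    S = model.n_flat
    D = model.gmm_means[0].shape[1]
    ll_history: list[float] = []
    for iteration in range(max_iter):
        total_ll = 0.0
        pi_acc = np.zeros(S)
        xi_acc = np.zeros((S, S))
        gamma_den = np.zeros(S)
        r_acc = [np.zeros(len(w)) for w in model.gmm_weights]
        ry_acc = [np.zeros((len(w), D)) for w in model.gmm_weights]
        ryy_acc = [np.zeros((len(w), D)) for w in model.gmm_weights]

        for Z, fl in zip(recordings_features, frame_label_lists):
            B = model.emission_loglik(Z)
            Bc = _clamp_emissions(model, B, fl)
            log_gamma, xi_sum, ll = _forward_backward(model.log_pi, model.log_A, Bc)
            if not np.isfinite(ll):
                raise ParameterError(
                    f"non-finite likelihood at Baum-Welch iteration {iteration}"
                )
            total_ll += ll
            gamma = np.exp(log_gamma)
            pi_acc += gamma[0]
            xi_acc += xi_sum
            gamma_den += gamma.sum(axis=0)
            # component-level responsibilities
            for s in range(S):
                w, mu, var = model.gmm_weights[s], model.gmm_means[s], model.gmm_vars[s]
                quad = np.square(Z[:, None, :] - mu[None, :, :]) / var[None, :, :]
                compll = (
                    -0.5 * (quad.sum(axis=2) + np.log(var).sum(axis=1) + D * np.log(2 * np.pi))
                    + np.log(np.maximum(w, 1e-300))[None, :]
                )
                comp_post = np.exp(compll - logsumexp(compll, axis=1, keepdims=True))
                r = gamma[:, s : s + 1] * comp_post  # (T, K)
                r_acc[s] += r.sum(axis=0)
                ry_acc[s] += r.T @ Z
                ryy_acc[s] += r.T @ np.square(Z)

        ll_history.append(total_ll)
        if len(ll_history) > 1:
            prev = ll_history[-2]
            if abs(total_ll - prev) <= tol * abs(prev):
                break

        # ----- M step -----
        pi = pi_acc / pi_acc.sum()
        A = np.where(model.mask, xi_acc, 0.0)
        row = A.sum(axis=1, keepdims=True)
        old_A = np.exp(model.log_A)
        A = np.where(row > 1e-12, A / np.maximum(row, 1e-12), old_A)
        A /= A.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore"):
            model.log_A = np.where(A > 0, np.log(np.maximum(A, 1e-300)), LOG_ZERO)
            model.log_pi = np.where(pi > 0, np.log(np.maximum(pi, 1e-300)), LOG_ZERO)
        for s in range(S):
            tot = r_acc[s].sum()
            if tot < 1e-8:
                continue  # starved sub-state: keep previous parameters
            keep = r_acc[s] > 1e-10
            w = np.where(keep, r_acc[s], 0.0)
            w = w / w.sum()
            mu = np.where(
                keep[:, None], ry_acc[s] / np.maximum(r_acc[s][:, None], 1e-12),
                model.gmm_means[s],
            )
            var = np.where(
                keep[:, None],
                ryy_acc[s] / np.maximum(r_acc[s][:, None], 1e-12) - np.square(mu),
                model.gmm_vars[s],
            )
            model.gmm_weights[s] = w
            model.gmm_means[s] = mu
            model.gmm_vars[s] = np.maximum(var, model.cov_floor)

    model.trained = True
    model.ll_history_ = ll_history
    return model


@dataclass
class DecodedSequence:
    """Per-frame Viterbi decode plus the frame-to-sample mapping."""

    top_states: list[str]
    substates: np.ndarray
    frame_centers: np.ndarray
    n_samples: int
    sample_rate_hz: float
    loglik: float

    def __len__(self) -> int:
        return len(self.top_states)


def viterbi_decode(
    model: HhmmModel, features: np.ndarray, rec: ImuRecording
) -> DecodedSequence:
    """Globally optimal flat-state path (log domain, unconstrained)."""
    Z = features
    cfg = model.feature_config
    win = cfg.window_samples(rec.sample_rate_hz)
    hop = cfg.hop_samples(rec.sample_rate_hz)
    centers = frame_centers(rec.n_samples, win, hop)[: len(Z)]
    if len(Z) == 0:
        return DecodedSequence([], np.empty(0, int), centers, rec.n_samples,
                               rec.sample_rate_hz, 0.0)
    B = model.emission_loglik(Z)
    T, S = B.shape
    delta = model.log_pi + B[0]
    back = np.zeros((T, S), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + model.log_A
        back[t] = np.argmax(scores, axis=0)
        delta = B[t] + np.max(scores, axis=0)
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    loglik = float(np.max(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    flat = model.flat_states
    tops = [flat[i][0] for i in path]
    subs = np.array([flat[i][1] for i in path], dtype=int)
    return DecodedSequence(tops, subs, centers, rec.n_samples, rec.sample_rate_hz, loglik)


def decode_to_strides(
    decoded: DecodedSequence,
    min_stride_ms: float = MIN_STRIDE_MS,
    max_stride_ms: float = MAX_STRIDE_MS,
) -> StrideDetection:
    """Turn each completed pass through the stride sub-chain into a stride.

    A pass is a maximal run of stride frames without a sub-state reset; a
    reset (sub-state index dropping between consecutive stride frames)
    splits back-to-back strides.  Frame boundaries map to window-center
    samples; a pass touching the first or last frame is extended to the
    signal border, since window centers cannot reach the sequence edges.
    Intervals outside the stride-duration bounds are dropped.
    """
    n_frames = len(decoded)
    fs = decoded.sample_rate_hz
    min_len = ms_to_samples(min_stride_ms, fs)
    max_len = ms_to_samples(max_stride_ms, fs)

    passes: list[tuple[int, int]] = []
    start = None
    for t in range(n_frames):
        is_stride = decoded.top_states[t] == "stride"
        if is_stride and start is None:
            start = t
        elif start is not None:
            if not is_stride:
                passes.append((start, t - 1))
                start = None
            elif decoded.substates[t] < decoded.substates[t - 1]:
                passes.append((start, t - 1))
                start = t
    if start is not None:
        passes.append((start, n_frames - 1))

    def left_border(f: int) -> int:
        return 0 if f == 0 else int(decoded.frame_centers[f])

    def right_border(f: int) -> int:
        if f >= n_frames - 1:
            return decoded.n_samples
        return int(decoded.frame_centers[f + 1])

    intervals = []
    for f0, f1 in passes:
        s, e = left_border(f0), right_border(f1)
        if min_len <= e - s <= max_len:
            intervals.append((s, e))
    return StrideDetection(
        method="hhmm",
        sample_rate_hz=fs,
        intervals=np.asarray(intervals, dtype=int).reshape(-1, 2),
    )


# ---------------------------------------------------------------------------
# Estimator


class HierarchicalHmmSegmenter(BaseSegmenter):
    """Two-level hierarchical HMM segmenter (sklearn-style).

    Defaults are the mid-grid configuration of the search space in
    :data:`DEFAULT_GRID`: 0.3 s Hann windows with 25 % hop, 7 principal
    components, 8 stride / 2 transition / 1 rest sub-states, 10 GMM
    components, at most 20 Baum–Welch iterations.
    """

    method = "hhmm"

    def __init__(
        self,
        window_len_s: float = 0.30,
        hop_frac: float = 0.25,
        n_pca: int = 7,
        n_substates_stride: int = 8,
        n_substates_transition: int = 2,
        n_substates_rest: int = 1,
        n_mix: int = 10,
        max_iter: int = 20,
        tol: float = 1e-4,
        cov_floor: float = 1e-6,
        raw_mode: str = "windowed",
        weight_stats: bool = True,
        random_state: int = 0,
        min_stride_ms: float = MIN_STRIDE_MS,
        max_stride_ms: float = MAX_STRIDE_MS,
    ):
        self.window_len_s = window_len_s
        self.hop_frac = hop_frac
        self.n_pca = n_pca
        self.n_substates_stride = n_substates_stride
        self.n_substates_transition = n_substates_transition
        self.n_substates_rest = n_substates_rest
        self.n_mix = n_mix
        self.max_iter = max_iter
        self.tol = tol
        self.cov_floor = cov_floor
        self.raw_mode = raw_mode
        self.weight_stats = weight_stats
        self.random_state = random_state
        self.min_stride_ms = min_stride_ms
        self.max_stride_ms = max_stride_ms

    def _feature_config(self) -> FeatureConfig:
        return FeatureConfig(
            window_len_s=self.window_len_s,
            hop_frac=self.hop_frac,
            raw_mode=self.raw_mode,
            weight_stats=self.weight_stats,
        )

    def fit(self, X: list[ImuRecording], y: list[SegmentLabelSet]):
        if not X:
            raise ParameterError("training set must not be empty")
        cfg = self._feature_config()
        fs = X[0].sample_rate_hz
        raw_feats = [extract_features(rec, cfg) for rec in X]
        scaler, pca = fit_normalizer_and_pca(np.vstack(raw_feats), self.n_pca)
        feats = [pca.transform(scaler.transform(f)) for f in raw_feats]

        model = init_model(
            feats,
            y,
            fs,
            n_substates={
                "stride": self.n_substates_stride,
                "transition": self.n_substates_transition,
                "rest": self.n_substates_rest,
            },
            n_mix=self.n_mix,
            feature_config=cfg,
            cov_floor=self.cov_floor,
            seed=self.random_state,
        )
        model.scaler, model.pca = scaler, pca

        win = cfg.window_samples(fs)
        hop = cfg.hop_samples(fs)
        fls = [
            frame_labels(lab, frame_centers(rec.n_samples, win, hop)[: len(f)])
            for rec, lab, f in zip(X, y, feats)
        ]
        train_bw(model, feats, fls, max_iter=self.max_iter, tol=self.tol)
        self.model_ = model
        self.ll_history_ = model.ll_history_
        self.fitted_ = True
        return self

    def _predict_one(self, rec: ImuRecording) -> StrideDetection:
        cfg = self.model_.feature_config
        feats = self.model_.transform(extract_features(rec, cfg))
        decoded = viterbi_decode(self.model_, feats, rec)
        return decode_to_strides(decoded, self.min_stride_ms, self.max_stride_ms)


def grid_search(
    cohort,
    estimator: BaseSegmenter,
    param_grid: dict[str, list],
    folds: list[tuple[list[int], list[int]]],
    tol_ms: float = 100.0,
):
    """Exhaustive sweep over a parameter grid, scored by mean validation
    F-score across folds; ties resolved toward the smaller model (fewer
    sub-states × mixtures × components).  Returns (best_params, table).
    """
    from .evaluation import evaluate_detections  # local import: no cycle

    if not param_grid or any(len(v) == 0 for v in param_grid.values()):
        raise ParameterError("parameter grid must be non-empty")
    if len(folds) < 1:
        raise ParameterError("grid search needs at least one fold")

    keys = list(param_grid)
    results = []
    for values in itertools.product(*(param_grid[k] for k in keys)):
        params = dict(zip(keys, values))
        scores = []
        for train_idx, val_idx in folds:
            est = clone_with_params(estimator, params)
            est.fit([cohort[i][0] for i in train_idx], [cohort[i][1] for i in train_idx])
            ms = evaluate_detections(
                est.predict([cohort[i][0] for i in val_idx]),
                [cohort[i][1] for i in val_idx],
                tol_ms=tol_ms,
            )
            scores.append(ms.f_score)
        size = float(np.prod([v for v in values if isinstance(v, (int, np.integer))]) or 1)
        results.append((params, float(np.mean(scores)), size))
    best = max(results, key=lambda r: (r[1], -r[2]))
    return best[0], results


def clone_with_params(estimator: BaseSegmenter, params: dict) -> BaseSegmenter:
    from sklearn.base import clone

    est = clone(estimator)
    est.set_params(**params)
    return est
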