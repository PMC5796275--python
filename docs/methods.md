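# Methods

This note documents the models implemented in `gaitseg`, the choices made
where the design was genuinely open, and what the synthetic benchmark does
and does not demonstrate.

## Problem setting

A foot-worn inertial measurement unit (IMU) records tri-axial acceleration
(±6 g) and angular velocity (±500 °/s) at 102.4 Hz. Gait analysis
pipelines first cut such a recording into individual strides — one full
gait cycle per foot, bounded by the prominent negative troughs of the
sagittal-plane gyroscope channel GZ (the foot-rotation reversals before
swing and at the end of stance). Mid-swing produces the dominant positive
GZ peak. Stride segmentation must cope with inter- and intra-subject
variability in stride duration, amplitude and shape, and — in
heterogeneous protocols such as the Timed Up-and-Go (TUG: rise from a
chair, walk, 180° turn, walk back, sit) — with turning strides and
non-stride movements that must not be segmented as strides.

Four segmenters share one sklearn-style fit/predict surface. All of them
apply the same stride-duration post-filter (600–2500 ms) and are scored
by the same protocol (below). Intervals are half-open `[start, end)` in
0-based samples; consecutive strides share a border sample. Every
millisecond threshold is converted through a single rounding rule
(round half away from zero) to prevent off-by-one drift between modules.

## Peak detection

A sample is a mid-swing event iff GZ exceeds 150 °/s, it is a strict
local maximum (plateaus contribute their first sample), and it is at
least 600 ms — the lower bound on stride duration — away from every other
accepted event. Conflicts inside a refractory window are resolved
greedily by descending amplitude, so only the highest candidate
survives; this greedy order is deterministic and reproduces "keep the
highest peak per window" exactly. The method marks one point per stride
and no borders.

## Subsequence DTW (msDTW)

A stride template X of length M = 200 is matched against the sequence Y
of length T through an M×T distance matrix D, an accumulated cost matrix
C with a free start along the first template row

    C(1,t) = D(1,t),    C(m,1) = Σ_{i≤m} D(i,1),
    C(m,t) = D(m,t) + min{C(m−1,t−1), C(m−1,t), C(m,t−1)},

and the matching function Δ(t) = C(M,t). Local minima of Δ below a match
threshold mark candidate stride end points (minimum strictly attained
within a neighborhood of half the minimum stride duration, ties to the
earlier index); the start point comes from backtracking with ties broken
diagonal → vertical → horizontal. Candidates are filtered by duration
(600–2500 ms) and by pairwise overlap < 200 ms, with lower-Δ matches
taking precedence.

Both the template and the input are normalized to the sensor ranges so
that match thresholds are scale-free; the uninformative axes AZ, GX, GY
are excluded from templates. The Euclidean variant interpolates each
training stride linearly to M samples, averages positionwise, and uses
the per-sample absolute difference per axis, summed over axes
(squared-difference is a config option; the pointwise metric is a design
choice — only the cost-function family is canonical). Default thresholds
are the midpoints of the per-axes grids (GZ alone: 15 of 10–25; 8–15 by
steps of 1, midpoint 11, for the probabilistic cost).

The probabilistic variant models each template position as a diagonal
Gaussian over the axes (variance floored at 1e−4 in normalized units,
which prevents degenerate distributions when training strides are nearly
identical) and uses D(y) = exp(−P(y)). Two likelihood mappings are
implemented:

* `density` (default): P is the raw multivariate Gaussian density. In
  normalized units the per-position densities at the mean are well above
  one, so a sample within a couple of standard deviations costs ≈ 0 and a
  far sample costs ≈ 1 — the accumulated cost then counts poorly matching
  samples along the path, which is the scale on which the 8–15 threshold
  range is meaningful for a 200-row template.
* `rescaled`: P = exp(−½·Mahalanobis²) ∈ (0, 1], the density divided by
  its value at the mean. This makes the "a likelihood is bounded by 1"
  view exact and bounds D in [e^−1, 1], but every path then accumulates
  at least e^−1 per cell regardless of fit, so path costs grow with path
  length and the printed threshold scale becomes unusable; it is kept for
  comparison only.

## Hierarchical HMM

A two-level model: top-level states are movement classes (stride,
transition, rest — or stride alone for homogeneous walks, with a
background class absorbing any unlabeled frames), each expanding into a
left-to-right chain of emitting sub-states with diagonal-covariance GMM
emissions. A sub-state may transition to itself or its successor; the
last sub-state of a chain may exit to the entry sub-state of any
top-level successor, including its own chain — which is what lets
consecutive strides follow back to back.

Observations are sliding-window features: each of the six axes of a
Hann-weighted window contributes the windowed samples themselves ("raw"
feature; a center-sample-only mode exists), mean, variance, energy (sum
of squares) and the three coefficients of a second-order polynomial fit.
Whether the statistics see the Hann weights is a config flag (default:
they do). Features are z-scored and reduced by PCA, both fitted on
training frames only.

Defaults are the mid-grid point of the search space (window 0.10–0.70 s
in steps of 0.20; stride sub-states 4–12 in steps of 2, transition 2–4,
rest 1; GMM components 8–12; principal components 1–15 in steps of 2):
window 0.30 s, 8/2/1 sub-states, 10 components, 7 principal components.
The hop is 25 % of the window. A strict left-to-right pass needs at
least one frame per sub-state, so the frame rate must satisfy
`stride_duration / hop ≥ n_substates`; at 50 % hop a 1.1 s stride spans
only ~7 frames and an 8-sub-state pass is arithmetically impossible,
while 25 % gives ~14 frames per stride and border resolution (half a
hop, ~37 ms) well inside the ±100 ms scoring tolerance.

Training is semi-supervised Baum–Welch, at most 20 iterations with an
additional relative-log-likelihood tolerance of 1e−4: the top level is
supervised by clamping each frame's emission likelihood to −∞ outside
its labeled class, while sub-state alignment within a class is free.
Initialization: top-level transitions from frame-level label bigrams
(with a small smoothing mass), frames assigned to sub-states by uniform
temporal slicing within each labeled segment, per-sub-state GMMs fitted
on the frames so assigned, second-level transitions uniform over the
allowed entries. The structural left-to-right mask survives every update
(zeros stay zero, rows re-normalized); GMM covariances are floored at
1e−6; all recursions run in the log domain. The per-iteration total
log-likelihood of the clamped model is non-decreasing (verified
numerically to 1e−6 relative tolerance — covariance flooring can in
principle nick the EM guarantee, in practice it does not).

Decoding is an unconstrained Viterbi over the flattened model. Each
completed pass through the stride sub-chain (run of stride frames
without a sub-state reset; a reset splits back-to-back strides) yields
one stride. Frame boundaries map to window-center samples; the border
between adjacent passes is the center of the first frame of the later
pass, so back-to-back strides share a border sample exactly. A pass
touching the first or last frame is extended to the signal edge, since
window centers cannot reach it. The duration filter is applied last.

## Evaluation protocol

A detected interval is a true positive iff both borders lie within
±100 ms of an unmatched ground-truth stride; matching is greedy in
temporal order, which coincides with optimal bipartite matching because
strides are ≥ 600 ms and the tolerance is ±100 ms (property-tested
against `linear_sum_assignment`). Peak detections carry no borders; a
peak is a TP iff it falls strictly inside exactly one unmatched
ground-truth stride, extra peaks in the same stride are FPs, unmatched
strides FNs. Precision, recall and F-score use the summed-count closed
forms; with no detections, precision is 1 if there was nothing to find
and 0 otherwise (recall analogously), and F is 0 when P + R = 0.

Cross-validation splits by subject: leave-one-subject-out (both feet of
the held-out subject are the test set) and nested k-fold (seeded
subject-level outer split shared across methods; inner grid search by
mean validation F-score; ties toward the smaller model). Pairwise method
comparison uses the two-sided Wilcoxon signed-rank test on paired
per-fold scores (Pratt zero handling, exact distribution for n ≤ 25, no
multiplicity correction).

## Synthetic gait generator

Stride waveforms are sums of smooth Gaussian bump/trough kernels on a
normalized phase axis — fully parametric, with independent knobs for
duration jitter, shape jitter, additive sensor noise, and subject-level
random effects (duration and amplitude multipliers drawn once per
subject, before stride-level noise, so cohort structure is stable under
noise changes). GZ carries one dominant positive mid-swing bump (default
350 °/s), deep negative border troughs (−180 °/s) and a shallow stance
dip; AZ, GX, GY are nearly flat, mirroring their low information content
in real foot-mounted recordings. The clean preset (5 % duration jitter,
2 °/s / 0.01 g noise) guarantees by construction that the 150 °/s +
600 ms peak rule recovers exactly one mid-swing event per stride.

TUG-like sequences compose rest blocks (noise around gravity),
sit↔stand transitions (low-frequency, high-amplitude accelerometer
excursions plus a narrow foot-adjustment GZ burst of 180 °/s — above the
peak threshold but sub-stride in extent, a deliberate confound for the
event-based method), and straight and turning stride runs. Turning
strides are 1.3× longer, have 0.8× the sagittal swing, a sustained yaw
offset and more shape variability.

What the generator does **not** emulate: pathological phenomena
(freezing, dyskinesia, festination), sensor drift and calibration error,
soft-tissue artifacts, and the long-tailed stride-shape diversity of
real Parkinsonian gait. Perfect scores on the homogeneous synthetic
cohort therefore demonstrate correctness of the implementations and of
the protocol, not clinical performance; the heterogeneous TUG benchmark
shows the expected qualitative ordering (high hierarchical-HMM
precision, high peak-detection recall, template methods in between) but
its difficulty is not calibrated to patient data.

## Benchmark problem sizes

The reference benchmark (also recomputed by `scripts/acceptance.py`)
uses 10 subjects × 2 feet × 20 strides of the clean straight-walk preset
(400 ground-truth strides) under leave-one-subject-out cross-validation;
the TUG ordering report uses 4-subject cohorts over 5 seeds with a
held-out subject per seed. These sizes keep a full run in the minutes
range on one CPU while leaving every per-fold training set large enough
for the 10-component GMMs of the mid-grid hierarchical HMM.

## Known limitations

* The hierarchical HMM's border placement is quantized to the frame hop;
  with very long windows and few sub-states the ±100 ms tolerance can be
  exceeded even on clean data.
* The probabilistic-template cost degrades when training variance is
  unrealistically tight (few training subjects): position Gaussians
  sharpen and in-distribution test strides fall into their tails. This
  mirrors its behavior on real heterogeneous data.
* Grid search is exhaustive and retrains one model per grid point per
  fold; the full Table-style grid is practical only for the compact
  models, not for the windowed-raw-feature configuration with large
  windows.
* The generator's transitions and turns are plausible but unvalidated
  against recorded patient signals; their parameters are difficulty
  knobs, not estimates.
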