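"""Tolerance-based scoring and cross-validation protocols.

A detected stride interval is a true positive iff both of its borders lie
within ±100 ms of the borders of one (not yet matched) ground-truth
stride; matching is greedy in temporal order, one-to-one.  With strides
bounded below by 600 ms and a ±100 ms tolerance, ambiguous multi-matches
are geometrically impossible, so greedy matching coincides with optimal
bipartite matching (property-tested).

The event-based method marks only mid-swing points, no borders; it is
scored by the peak-in-stride rule: a peak is a TP iff it falls strictly
inside exactly one unmatched ground-truth stride; extra peaks inside the
same stride are FPs, unmatched strides FNs.

Metrics follow the summed-count closed forms
    precision = ΣTP/(ΣTP+ΣFP), recall = ΣTP/(ΣTP+ΣFN),
    F = 2·P·R/(P+R),
with documented zero-denominator conventions.  Cross-validation drivers
split by subject: leave-one-subject-out (both feet of the held-out
subject form the test set) and nested k-fold with an inner grid search.
Method comparison uses the two-sided Wilcoxon signed-rank test on paired
per-fold scores (Pratt zero handling, exact distribution for n ≤ 25).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .base import BaseSegmenter
from .core import (
    ParameterError,
    SegmentLabelSet,
    StrideDetection,
    ms_to_samples,
)

DEFAULT_TOL_MS = 100.0


@dataclass
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ParameterError("counts must be non-negative")

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)

    @property
    def n_truth(self) -> int:
        return self.tp + self.fn


@dataclass
class MetricSet:
    precision: float
    recall: float
    f_score: float

    def as_percent(self) -> tuple[float, float, float]:
        return (100 * self.precision, 100 * self.recall, 100 * self.f_score)


def match_strides(
    detected: StrideDetection,
    truth: SegmentLabelSet,
    tol_ms: float = DEFAULT_TOL_MS,
) -> EvalCounts:
    """Count TP/FP/FN for one recording.

    Interval detections use the ±``tol_ms`` border rule; peak-based
    detections use the peak-in-stride rule.  Detection and truth must be
    on the same sample clock.
    """
    if abs(detected.sample_rate_hz - truth.sample_rate_hz) > 1e-9:
        raise ParameterError(
            f"sample-rate mismatch: detection at {detected.sample_rate_hz} Hz, "
            f"truth at {truth.sample_rate_hz} Hz"
        )
    gt = truth.stride_intervals()
    n_truth = len(gt)

    if detected.is_peak_based:
        peaks = detected.peaks if detected.peaks is not None else np.empty(0, int)
        matched = np.zeros(n_truth, dtype=bool)
        tp = fp = 0
        for p in peaks:
            inside = np.where((gt[:, 0] < p) & (p < gt[:, 1]))[0] if n_truth else []
            hit = next((i for i in inside if not matched[i]), None)
            if hit is None:
                fp += 1
            else:
                matched[hit] = True
                tp += 1
        return EvalCounts(tp=tp, fp=fp, fn=int(n_truth - matched.sum()))

    tol = ms_to_samples(tol_ms, truth.sample_rate_hz) if np.isfinite(tol_ms) else None
    matched = np.zeros(n_truth, dtype=bool)
    tp = fp = 0
    for s, e in detected.intervals:
        hit = None
        for i in range(n_truth):
            if matched[i]:
                continue
            if tol is None or (abs(s - gt[i, 0]) <= tol and abs(e - gt[i, 1]) <= tol):
                hit = i
                break
        if hit is None:
            fp += 1
        else:
            matched[hit] = True
            tp += 1
    return EvalCounts(tp=tp, fp=fp, fn=int(n_truth - matched.sum()))


def compute_metrics(counts: EvalCounts) -> MetricSet:
    """Precision/recall/F from summed counts.

    Zero-denominator conventions: with no detections (TP+FP = 0),
    precision is 1 if nothing was there to find (FN = 0) and 0 otherwise;
    recall analogously for TP+FN = 0; F is 0 whenever P+R = 0.
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    if tp + fp == 0:
        precision = 1.0 if fn == 0 else 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall = 1.0 if fp == 0 else 0.0
    else:
        recall = tp / (tp + fn)
    f = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return MetricSet(precision=precision, recall=recall, f_score=f)


def evaluate_detections(
    detections: list[StrideDetection],
    truths: list[SegmentLabelSet],
    tol_ms: float = DEFAULT_TOL_MS,
) -> MetricSet:
    """Metrics from counts summed over several recordings."""
    total = EvalCounts()
    for det, truth in zip(detections, truths):
        total = total + match_strides(det, truth, tol_ms)
    return compute_metrics(total)


# ---------------------------------------------------------------------------
# Cross-validation protocols


def _subject_ids(cohort) -> list[str]:
    seen: list[str] = []
    for rec, _ in cohort:
        if rec.subject_id not in seen:
            seen.append(rec.subject_id)
    return seen


@dataclass
class FoldResult:
    test_subjects: list[str]
    counts: EvalCounts
    metrics: MetricSet
    chosen_params: dict | None = None


def _fit_predict_score(estimator, cohort, train_idx, test_idx, tol_ms) -> tuple[EvalCounts, MetricSet]:
    from .hhmm import clone_with_params

    est = clone_with_params(estimator, {})
    est.fit([cohort[i][0] for i in train_idx], [cohort[i][1] for i in train_idx])
    counts = EvalCounts()
    for i in test_idx:
        det = est.predict(cohort[i][0])
        counts = counts + match_strides(det, cohort[i][1], tol_ms)
    return counts, compute_metrics(counts)


def run_loocv(
    cohort,
    estimator: BaseSegmenter,
    tol_ms: float = DEFAULT_TOL_MS,
) -> list[FoldResult]:
    """Leave-one-subject-out: both feet of one subject form the test set,
    everything else the training set; per-subject metrics from summed
    counts."""
    subjects = _subject_ids(cohort)
    if len(subjects) < 2:
        raise ParameterError("LOOCV requires at least 2 subjects")
    results = []
    for subject in subjects:
        test_idx = [i for i, (r, _) in enumerate(cohort) if r.subject_id == subject]
        train_idx = [i for i in range(len(cohort)) if i not in test_idx]
        counts, metrics = _fit_predict_score(estimator, cohort, train_idx, test_idx, tol_ms)
        results.append(FoldResult([subject], counts, metrics))
    return results


def subject_folds(subjects: list[str], k: int, seed: int) -> list[list[str]]:
    """Seeded subject-level split into k folds (same seed ⇒ same folds for
    every method)."""
    if len(subjects) < k:
        raise ParameterError(f"need at least {k} subjects for {k}-fold CV")
    rng = np.random.default_rng(seed)
    order = list(np.array(subjects)[rng.permutation(len(subjects))])
    return [order[i::k] for i in range(k)]


def run_nested_cv(
    cohort,
    estimator: BaseSegmenter,
    param_grid: dict[str, list] | None = None,
    k_outer: int = 4,
    k_inner: int = 4,
    seed: int = 0,
    tol_ms: float = DEFAULT_TOL_MS,
) -> list[FoldResult]:
    """Nested subject-level cross-validation.

    The outer split is seeded and subject-level; per outer fold, an inner
    k-fold grid search over ``param_grid`` picks the parameters with the
    best mean inner-validation F-score, and the outer test fold is scored
    once with them.  With a single-point grid this reduces to plain
    k-fold CV.
    """
    from .hhmm import clone_with_params

    subjects = _subject_ids(cohort)
    outer = subject_folds(subjects, k_outer, seed)
    by_subject = {
        s: [i for i, (r, _) in enumerate(cohort) if r.subject_id == s] for s in subjects
    }

    def indices(subject_list):
        return [i for s in subject_list for i in by_subject[s]]

    results = []
    for fold_subjects in outer:
        train_subjects = [s for s in subjects if s not in fold_subjects]
        chosen: dict = {}
        if param_grid and any(len(v) > 1 for v in param_grid.values()):
            inner = subject_folds(train_subjects, min(k_inner, len(train_subjects)), seed + 1)
            best_score, best_params = -1.0, {}
            import itertools

            keys = list(param_grid)
            for values in itertools.product(*(param_grid[k] for k in keys)):
                params = dict(zip(keys, values))
                scores = []
                for val_subjects in inner:
                    tr = indices([s for s in train_subjects if s not in val_subjects])
                    va = indices(val_subjects)
                    est = clone_with_params(estimator, params)
                    est.fit([cohort[i][0] for i in tr], [cohort[i][1] for i in tr])
                    ms = evaluate_detections(
                        est.predict([cohort[i][0] for i in va]),
                        [cohort[i][1] for i in va],
                        tol_ms,
                    )
                    scores.append(ms.f_score)
                score = float(np.mean(scores))
                if score > best_score:
                    best_score, best_params = score, params
            chosen = best_params
        elif param_grid:
            chosen = {k: v[0] for k, v in param_grid.items()}

        est = clone_with_params(estimator, chosen)
        tr, te = indices(train_subjects), indices(fold_subjects)
        est.fit([cohort[i][0] for i in tr], [cohort[i][1] for i in tr])
        counts = EvalCounts()
        for i in te:
            counts = counts + match_strides(est.predict(cohort[i][0]), cohort[i][1], tol_ms)
        results.append(FoldResult(list(fold_subjects), counts, compute_metrics(counts), chosen))
    return results


def aggregate(results: list[FoldResult]) -> dict:
    """Mean ± SD of per-fold metrics plus pooled-count metrics."""
    per_fold = np.array(
        [[r.metrics.precision, r.metrics.recall, r.metrics.f_score] for r in results]
    )
    pooled = compute_metrics(sum((r.counts for r in results), EvalCounts()))
    return {
        "mean": per_fold.mean(axis=0),
        "sd": per_fold.std(axis=0, ddof=1) if len(results) > 1 else np.zeros(3),
        "pooled": pooled,
        "n_folds": len(results),
    }


def compare_methods(per_fold_scores: dict[str, list[float]]) -> dict[tuple[str, str], float]:
    """Pairwise two-sided Wilcoxon signed-rank p-values on paired per-fold
    scores (Pratt zero-handling; exact distribution for n ≤ 25; no
    multiplicity correction)."""
    methods = list(per_fold_scores)
    if len(methods) < 2:
        raise ParameterError("need at least two methods to compare")
    n = len(per_fold_scores[methods[0]])
    for m in methods:
        if len(per_fold_scores[m]) != n:
            raise ParameterError("all methods must have the same number of folds")
    out = {}
    for i, a in enumerate(methods):
        for b in methods[i + 1 :]:
            x = np.asarray(per_fold_scores[a], dtype=float)
            y = np.asarray(per_fold_scores[b], dtype=float)
            d = x - y
            if np.allclose(d, 0):
                p = 1.0
            else:
                method = "exact" if n <= 25 and not np.any(d == 0) else "auto"
                p = float(
                    stats.wilcoxon(
                        x, y, zero_method="pratt", alternative="two-sided", method=method
                    ).pvalue
                )
            out[(a, b)] = p
            out[(b, a)] = p
    return out
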