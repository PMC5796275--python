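"""Scikit-learn-style base class shared by all stride segmenters.

A segmenter is fitted on lists of labeled recordings and predicts a
:class:`~gaitseg.core.StrideDetection` per recording:

    seg = EuclideanDtwSegmenter().fit(recordings, labelsets)
    detection = seg.predict(recordings[0])

``get_params`` / ``set_params`` come from :class:`sklearn.base.BaseEstimator`,
so segmenters compose with sklearn model-selection utilities and with the
cross-validation drivers in :mod:`gaitseg.evaluation`.
"""

from __future__ import annotations

from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .core import ImuRecording, SegmentLabelSet, StrideDetection


class BaseSegmenter(BaseEstimator):
    """Common fit/predict surface for the four segmentation methods."""

    #: short method tag used in detections and reports
    method: str = ""

    def fit(self, X: list[ImuRecording], y: list[SegmentLabelSet] | None = None):
        raise NotImplementedError

    def _predict_one(self, rec: ImuRecording) -> StrideDetection:
        raise NotImplementedError

    def predict(self, X):
        """Segment one recording or a list of recordings."""
        self._check_fitted()
        if isinstance(X, ImuRecording):
            return self._predict_one(X)
        return [self._predict_one(rec) for rec in X]

    def _check_fitted(self) -> None:
        if not getattr(self, "fitted_", False):
            raise NotFittedError(
                f"{type(self).__name__} must be fitted before calling predict"
            )
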