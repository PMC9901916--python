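"""Automated hit/miss labelling by thresholding the ORB keypoint count.

The keypoint detector behaves like a cheap peak counter, so a frame is
labelled a *hit* when its keypoint count reaches a threshold tau and a
*miss* otherwise (boundary convention: count == tau is a hit).  Because
the typical Bragg-peak count varies between experiments, tau is data-set
specific and is calibrated by sweeping a grid of candidate thresholds
against reference labels (from a human annotator, a spot finder, or
simulation ground truth) and keeping the smallest tau that maximises the
agreement rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .orb import OrbConfig, OrbFeatureExtractor
from .simulator import HIT, MISS

#: Default calibration grid, centred on the range of thresholds that works
#: for typical experiments (data-set specific values fall around 25-40).
DEFAULT_TAU_GRID = tuple(range(1, 101))


@dataclass(frozen=True)
class LabelConfig:
    """Labelling threshold tau (>= 1) plus the extraction settings."""

    tau: int = 30
    orb_config: OrbConfig = field(default_factory=OrbConfig)

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValueError("tau must be >= 1")


def label_from_count(count: int, tau: int) -> str:
    """'hit' iff keypoint count >= tau."""
    return HIT if count >= tau else MISS


def label_frame(frame, config: LabelConfig, pattern=None) -> str:
    """Label one frame by extracting keypoints and thresholding the count."""
    from . import orb

    kps, _ = orb.extract(frame, config.orb_config, pattern)
    return label_from_count(len(kps), config.tau)


def sweep_threshold(
    counts: np.ndarray,
    reference_labels: list[str] | np.ndarray,
    tau_grid: tuple[int, ...] = DEFAULT_TAU_GRID,
) -> pd.DataFrame:
    """Agreement rate of threshold labelling across a tau grid.

    ``counts`` are precomputed keypoint counts (computed once; reused for
    every tau).  Returns a DataFrame with columns ``tau`` and
    ``success_rate`` (fraction of frames whose threshold label matches the
    reference), plus per-class rates for transparency.
    """
    counts = np.asarray(counts)
    ref = np.asarray(reference_labels)
    if len(counts) != len(ref):
        raise ValueError("counts and reference_labels must have equal length")
    if len(counts) < 2:
        raise ValueError("need at least 2 frames to calibrate")
    classes = set(ref.tolist())
    if len(classes) < 2:
        warnings.warn(
            "reference labels contain a single class; the success rate is "
            "degenerate and tau selection will be uninformative",
            stacklevel=2,
        )
    is_hit_ref = ref == HIT
    rows = []
    for tau in tau_grid:
        pred_hit = counts >= tau
        agree = pred_hit == is_hit_ref
        row = {"tau": int(tau), "success_rate": float(agree.mean())}
        if is_hit_ref.any():
            row["hit_rate"] = float(agree[is_hit_ref].mean())
        if (~is_hit_ref).any():
            row["miss_rate"] = float(agree[~is_hit_ref].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def select_tau(sweep_result: pd.DataFrame) -> int:
    """Smallest tau attaining the maximum success rate.

    The tie-break toward small tau favours sensitivity to weak hits when
    several thresholds lie on the same agreement plateau.
    """
    if len(sweep_result) == 0:
        raise ValueError("sweep result is empty")
    best = sweep_result["success_rate"].max()
    on_plateau = sweep_result[sweep_result["success_rate"] == best]
    return int(on_plateau["tau"].min())


def agreement(reference_labels, predicted_labels) -> pd.DataFrame:
    """Row-normalised 2x2 agreement table in percent.

    Rows are the reference classes (hit, miss), columns the predicted
    classes; each defined row sums to 100.  A reference class with zero
    frames is reported as NaN (undefined), never as 0.
    """
    ref = np.asarray(reference_labels)
    pred = np.asarray(predicted_labels)
    if len(ref) != len(pred):
        raise ValueError("label vectors must have equal length")
    table = pd.DataFrame(index=[HIT, MISS], columns=[HIT, MISS], dtype=float)
    for r in (HIT, MISS):
        sel = ref == r
        n = int(sel.sum())
        for p in (HIT, MISS):
            table.loc[r, p] = 100.0 * float((pred[sel] == p).sum()) / n if n else np.nan
    return table


class ThresholdLabeler(ClassifierMixin, BaseEstimator):
    """Keypoint-count threshold labeller with sweep-based calibration.

    ``fit(frames, reference_labels)`` extracts keypoint counts once,
    sweeps ``tau_grid`` and stores the calibrated ``tau_`` (or uses a
    fixed ``tau`` when given).  ``predict(frames)`` returns hit/miss
    labels.  Both accept precomputed integer counts in place of frames.
    """

    def __init__(
        self,
        tau: int | None = None,
        tau_grid: tuple[int, ...] = DEFAULT_TAU_GRID,
        extractor: OrbFeatureExtractor | None = None,
    ):
        self.tau = tau
        self.tau_grid = tau_grid
        self.extractor = extractor

    def _counts(self, X) -> np.ndarray:
        arr = np.asarray(X, dtype=object)
        if arr.ndim == 1 and all(np.isscalar(x) or isinstance(x, (int, np.integer)) for x in arr):
            return np.asarray(X, dtype=int)
        ext = self.extractor or OrbFeatureExtractor()
        return ext.keypoint_counts(X)

    def fit(self, X, y=None) -> "ThresholdLabeler":
        counts = self._counts(X)
        if self.tau is not None:
            self.tau_ = int(self.tau)
            self.sweep_ = None
        else:
            if y is None:
                raise ValueError("reference labels are required to calibrate tau")
            self.sweep_ = sweep_threshold(counts, y, self.tau_grid)
            self.tau_ = select_tau(self.sweep_)
        self.classes_ = np.array([HIT, MISS])
        return self

    def predict(self, X) -> np.ndarray:
        counts = self._counts(X)
        return np.where(counts >= self.tau_, HIT, MISS)
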