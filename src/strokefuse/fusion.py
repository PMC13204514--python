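"""Voxel-wise logistic fusion of the segmentation probability map with the
selected rs-fMRI feature maps.

The infarct log-odds at each ROI voxel are modelled as

    ln(p / (1 - p)) = b0 + b1 * P_z + b2 * F1_z + ... + bn * Fn_z

where ``P_z`` is the z-scored probability map and ``Fi_z`` the z-scored
(and zero-clipped) feature maps.  The coefficients are found by a coarse
full-grid search maximising the mean training Dice of the binarised
(p > 0.5) prediction; with the default level lists (3 offsets, 4 for the
probability map, 6 for each of two features) the grid enumerates
3*4*6*6 = 432 combinations.  Gradient-based fitting is deliberately absent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

DEFAULT_BETA0_LEVELS = (-2.0, 0.0, 2.0)
DEFAULT_BETA1_LEVELS = (0.5, 1.0, 2.0, 4.0)
DEFAULT_FEATURE_LEVELS = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0)


@dataclass(frozen=True)
class DiceResult:
    """Overlap of a binary prediction with the reference mask."""

    tp: int
    fp: int
    fn: int
    dice: float
    both_empty: bool = False


def dice_index(prediction_mask: np.ndarray, truth_mask: np.ndarray) -> DiceResult:
    """Dice = 2 TP / (2 TP + FP + FN); two empty masks score 1 (flagged)."""
    pred = np.asarray(prediction_mask).astype(bool)
    truth = np.asarray(truth_mask).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.logical_and(pred, truth).sum())
    fp = int(pred.sum()) - tp
    fn = int(truth.sum()) - tp
    denom = 2 * tp + fp + fn
    if denom == 0:
        return DiceResult(tp, fp, fn, 1.0, both_empty=True)
    return DiceResult(tp, fp, fn, 2.0 * tp / denom)


def zero_clip(feature_zmap: np.ndarray, contrast_sign: int,
              threshold: float = 0.1, mode: str = "directional") -> np.ndarray:
    """Suppress z-values that would push the log-odds against the expected
    contrast direction.

    ``mode="directional"`` (default): a positive-contrast feature keeps only
    z >= threshold, a negative-contrast one only z <= -threshold; everything
    else is set to 0.  ``mode="symmetric"`` zeroes |z| < threshold for either
    sign (an alternative reading of the rule, kept as a config switch).
    """
    z = np.asarray(feature_zmap, dtype=float).copy()
    if contrast_sign not in (-1, 1):
        raise ValueError("contrast_sign must be +1 or -1")
    if mode == "directional":
        if contrast_sign > 0:
            z[z < threshold] = 0.0
        else:
            z[z > -threshold] = 0.0
    elif mode == "symmetric":
        z[np.abs(z) < threshold] = 0.0
    else:
        raise ValueError(f"unknown zero-clip mode {mode!r}")
    return z


def logistic_probability(params, probmap_z: np.ndarray,
                         feature_zmaps=(), roi_mask=None) -> np.ndarray:
    """Voxel-wise p_i = sigmoid(b0 + b1*P_z + sum_j b_{j+1}*F_j); 0 outside
    the ROI.  ``params`` = (b0, b1, b2, ...)."""
    params = np.asarray(params, dtype=float)
    maps = [np.asarray(probmap_z, dtype=float)] + \
        [np.asarray(f, dtype=float) for f in feature_zmaps]
    if len(params) != len(maps) + 1:
        raise ValueError("need one coefficient per map plus the offset")
    shape = maps[0].shape
    for m in maps[1:]:
        if m.shape != shape:
            raise ValueError("all maps must share the grid")
    logit = np.full(shape, params[0])
    for b, m in zip(params[1:], maps):
        logit = logit + b * np.nan_to_num(m, nan=0.0)
    p = 1.0 / (1.0 + np.exp(-logit))
    if roi_mask is not None:
        p = np.where(np.asarray(roi_mask).astype(bool), p, 0.0)
    return p


@dataclass
class FusionSubject:
    """Fusion inputs of one subject, flattened over ROI voxels.

    ``feature_zmaps`` are z-scored and zero-clipped columns (one per
    selected biomarker); ``per_run_feature_zmaps`` optionally carries the
    run-wise versions for per-run application.
    """

    subject_id: str
    probmap_z: np.ndarray                      # (n_roi,)
    feature_zmaps: list                        # list of (n_roi,)
    truth: np.ndarray                          # (n_roi,) bool
    probmap_raw: np.ndarray | None = None      # (n_roi,) raw probabilities
    per_run_feature_zmaps: list = field(default_factory=list)  # [run][feat]


class LogisticFusion(BaseEstimator):
    """Coarse full-grid-search logistic fusion model (sklearn-style).

    Parameters are the grid level lists, the number of rs-fMRI features
    (0 = probability-map-only re-optimised contender; at most 2) and the
    decision threshold.  ``fit`` enumerates every coefficient combination,
    scores each by mean training Dice of the thresholded prediction and
    keeps the argmax; ties prefer the smallest-magnitude coefficient vector,
    then enumeration order.
    """

    def __init__(self, n_features: int = 2,
                 beta0_levels=DEFAULT_BETA0_LEVELS,
                 beta1_levels=DEFAULT_BETA1_LEVELS,
                 feature_levels=DEFAULT_FEATURE_LEVELS,
                 threshold: float = 0.5):
        self.n_features = n_features
        self.beta0_levels = beta0_levels
        self.beta1_levels = beta1_levels
        self.feature_levels = feature_levels
        self.threshold = threshold

    def _grid(self) -> np.ndarray:
        if not (0 <= self.n_features <= 2):
            raise ValueError("n_features must be 0, 1 or 2")
        levels = [tuple(self.beta0_levels), tuple(self.beta1_levels)]
        levels += [tuple(self.feature_levels)] * self.n_features
        if any(len(l) == 0 for l in levels):
            raise ValueError("empty grid level list")
        return np.array(list(itertools.product(*levels)))

    def fit(self, subjects: list, y=None):
        subjects = list(subjects)
        if not subjects:
            raise ValueError("no training subjects")
        grid = self._grid()
        cut = np.log(self.threshold / (1.0 - self.threshold))
        dice_sum = np.zeros(len(grid))
        for s in subjects:
            X = np.column_stack(
                [np.nan_to_num(np.asarray(m, dtype=float), nan=0.0)
                 for m in [s.probmap_z, *s.feature_zmaps[:self.n_features]]])
            logits = grid[:, 0][:, None] + grid[:, 1:] @ X.T
            pred = logits > cut
            truth = np.asarray(s.truth, dtype=float)
            tp = pred @ truth
            denom = pred.sum(axis=1) + truth.sum()
            with np.errstate(invalid="ignore"):
                d = np.where(denom > 0, 2.0 * tp / denom, 1.0)
            dice_sum += d
        mean_dice = dice_sum / len(subjects)
        best = mean_dice.max()
        ties = np.flatnonzero(mean_dice >= best - 1e-12)
        mags = (grid[ties] ** 2).sum(axis=1)
        pick = ties[np.lexsort((ties, mags))[0]]
        self.grid_ = grid
        self.grid_dice_ = mean_dice
        self.n_combinations_ = len(grid)
        self.intercept_ = float(grid[pick, 0])
        self.coef_ = grid[pick, 1:].copy()
        self.best_training_dice_ = float(mean_dice[pick])
        return self

    # -- application ------------------------------------------------------

    def _predict_one(self, probmap_z, feature_zmaps) -> np.ndarray:
        params = np.concatenate([[self.intercept_], self.coef_])
        p = logistic_probability(params, probmap_z,
                                 feature_zmaps[:self.n_features])
        return p > self.threshold

    def predict(self, subjects: list) -> list:
        """Binary lesion predictions (one boolean array per subject)."""
        return [self._predict_one(s.probmap_z, s.feature_zmaps)
                for s in subjects]

    def score(self, subjects: list, y=None) -> float:
        """Mean Dice against the subjects' truth masks."""
        return float(np.mean([
            dice_index(pred, s.truth).dice
            for pred, s in zip(self.predict(subjects), subjects)]))


def grid_search_fit(training_subjects, n_features: int = 2,
                    **kwargs) -> LogisticFusion:
    """Fit the fusion model on training subjects (thin wrapper)."""
    return LogisticFusion(n_features=n_features, **kwargs).fit(training_subjects)


def apply_model(model: LogisticFusion, subject: FusionSubject):
    """Predicted lesion mask and Dice for one subject."""
    pred = model._predict_one(subject.probmap_z, subject.feature_zmaps)
    return pred, dice_index(pred, subject.truth)


def original_model_dice(subject: FusionSubject, threshold: float = 0.5) -> DiceResult:
    """The un-re-optimised contender: raw probability map > threshold."""
    if subject.probmap_raw is None:
        raise ValueError("subject carries no raw probability map")
    return dice_index(subject.probmap_raw > threshold, subject.truth)
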