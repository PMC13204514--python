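"""Biomarker screening with the modified Fisher score.

Per scan (one subject, one run) and per feature map the lesion-to-WM
contrast is scored as

    Score = (Mean_Lesion - Mean_WM)^2 / SD_WM^2

with means/SD over valid window voxels of the lesion mask and the entire WM
mask (which includes the lesion territory, as a WM segmentation would).
Ranking averages per-scan scores over all training scans with equal weight
per scan; ties are broken by registry order.  The score uses only the WM
spread in the denominator -- a deliberate asymmetry relative to the
classical two-class Fisher criterion, which sums both class variances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .registry import FEATURE_NAMES
from .roi import FeatureMapSet


@dataclass(frozen=True)
class ScanFeatures:
    """Feature maps of one scan plus its ROI-grid compartment masks."""

    subject_id: str
    visit: str
    run: int
    maps: FeatureMapSet
    lesion_mask: np.ndarray   # ROI grid, bool
    wm_mask: np.ndarray       # ROI grid, bool


@dataclass(frozen=True)
class FisherComponents:
    score: float
    mean_lesion: float
    mean_wm: float
    sd_wm: float


def fisher_score(feature_map: np.ndarray, lesion_mask: np.ndarray,
                 wm_mask: np.ndarray) -> FisherComponents:
    """Modified Fisher score of one 3D feature map (NaN = invalid voxel)."""
    vol = np.asarray(feature_map, dtype=float)
    lesion = np.asarray(lesion_mask).astype(bool)
    wm = np.asarray(wm_mask).astype(bool)
    if vol.shape != lesion.shape or vol.shape != wm.shape:
        raise ValueError("feature map and masks must share the grid")
    lv = vol[lesion & np.isfinite(vol)]
    wv = vol[wm & np.isfinite(vol)]
    if lv.size < 2 or wv.size < 2:
        raise ValueError("need >= 2 valid voxels in each compartment")
    sd_wm = wv.std(ddof=1)
    if sd_wm <= 0:
        raise ValueError("SD_WM is zero, Fisher score undefined")
    ml, mw = lv.mean(), wv.mean()
    return FisherComponents(score=float((ml - mw) ** 2 / sd_wm ** 2),
                            mean_lesion=float(ml), mean_wm=float(mw),
                            sd_wm=float(sd_wm))


def _scan_score_table(scan: ScanFeatures) -> pd.DataFrame:
    """Vectorised per-feature Fisher components for one scan."""
    fms = scan.maps
    lesion_idx = scan.lesion_mask[tuple(fms.coords.T)] & fms.valid
    wm_idx = scan.wm_mask[tuple(fms.coords.T)] & fms.valid
    if lesion_idx.sum() < 2 or wm_idx.sum() < 2:
        raise ValueError(
            f"scan {scan.subject_id}/{scan.visit}/run{scan.run}: "
            "need >= 2 valid voxels in each compartment")
    L = fms.values[lesion_idx]
    W = fms.values[wm_idx]
    ml = L.mean(axis=0)
    mw = W.mean(axis=0)
    sd = W.std(axis=0, ddof=1)
    finite = np.isfinite(ml) & np.isfinite(mw) & np.isfinite(sd)
    degenerate = ~finite | (sd <= 0)
    score = np.zeros(len(FEATURE_NAMES))
    ok = ~degenerate
    score[ok] = (ml[ok] - mw[ok]) ** 2 / sd[ok] ** 2
    return pd.DataFrame({
        "subject_id": scan.subject_id, "visit": scan.visit, "run": scan.run,
        "feature": FEATURE_NAMES, "score": score,
        "mean_lesion": ml, "mean_wm": mw, "sd_wm": sd,
        "degenerate": degenerate,
    })


class FisherScreen(BaseEstimator):
    """Rank the 85 features by mean per-scan Fisher score and keep the top k.

    sklearn-style estimator: ``fit`` takes a sequence of training
    :class:`ScanFeatures`; fitted attributes carry the ranking, the selected
    feature names and their contrast signs (sign of Mean_Lesion - Mean_WM
    pooled over training scans), which drive the zero-clip direction in the
    fusion stage.  Features flagged degenerate (zero WM spread or non-finite
    maps in any scan) are forced to the bottom of the ranking.
    """

    def __init__(self, k: int = 2):
        self.k = k

    def fit(self, scans, y=None):
        if self.k > len(FEATURE_NAMES):
            raise ValueError("k cannot exceed the registry size")
        scans = list(scans)
        if not scans:
            raise ValueError("no training scans")
        per_scan = pd.concat([_scan_score_table(s) for s in scans],
                             ignore_index=True)
        grouped = per_scan.groupby("feature", sort=False)
        mean_score = grouped["score"].mean()
        degenerate = grouped["degenerate"].any()
        contrast = grouped.apply(
            lambda g: (g.mean_lesion - g.mean_wm).mean(), include_groups=False)
        # registry order, then rank
        mean_score = mean_score.reindex(list(FEATURE_NAMES))
        degenerate = degenerate.reindex(list(FEATURE_NAMES))
        contrast = contrast.reindex(list(FEATURE_NAMES))
        sortable = np.where(degenerate.to_numpy(), -np.inf,
                            mean_score.to_numpy())
        # descending score; ties (and degenerates) resolve by registry order
        order = np.lexsort((np.arange(len(FEATURE_NAMES)), -sortable))
        self.per_scan_scores_ = per_scan
        self.mean_scores_ = mean_score
        self.degenerate_ = set(degenerate.index[degenerate])
        self.signs_ = contrast.apply(lambda c: 1 if c >= 0 else -1).to_dict()
        self.ranking_ = [FEATURE_NAMES[i] for i in order]
        self.selected_features_ = self.ranking_[:self.k]
        self.selected_signs_ = [self.signs_[f] for f in self.selected_features_]
        return self

    def transform(self, scans):
        """Top-k feature columns of each scan, (n_scans) list of (n_roi, k)."""
        idx = [FEATURE_NAMES.index(f) for f in self.selected_features_]
        return [np.asarray(s.maps.values[:, idx]) for s in scans]


def rank_features(scans, k: int = len(FEATURE_NAMES)) -> FisherScreen:
    """Fit a :class:`FisherScreen` on training scans (thin wrapper)."""
    return FisherScreen(k=k).fit(scans)


def select_top(screen: FisherScreen, k: int) -> list[tuple[str, int]]:
    """Top-k (feature name, contrast sign) pairs of a fitted screen."""
    return [(f, screen.signs_[f]) for f in screen.ranking_[:k]]
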