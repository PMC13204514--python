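"""ROI construction and sliding-window feature-map extraction.

The analysis region of interest (ROI) is the union of the white-matter and
lesion masks, 2x down-sampled to the 2 mm grid.  Every ROI voxel is probed
with a 3x3x3 sliding window over its in-ROI neighbours; windows with fewer
than 2 in-ROI voxels are invalid (minimum cluster-size rule).  The window's
mean series feeds the univariate features, the individual voxel series feed
the concordance features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .features import DEFAULT_BANDS, BandDefinition, compute_feature_matrix
from .registry import FEATURE_NAMES, N_FEATURES

N_DISCARD_FRAMES = 5  # initial frames dropped for scanner stabilisation


def discard_initial_frames(bold: np.ndarray, n: int = N_DISCARD_FRAMES) -> np.ndarray:
    """Drop the first ``n`` frames of a 4D run (or (n_vox, T) series stack)."""
    if bold.shape[-1] <= n:
        raise ValueError(f"run has {bold.shape[-1]} frames, cannot discard {n}")
    return bold[..., n:]


def downsample_mask(mask: np.ndarray, factor: int = 2, rule: str = "half") -> np.ndarray:
    """Block-downsample a binary mask.

    A coarse voxel is set if >= half of its ``factor``^3 children are set
    (``rule="half"``), or if any child is set (``rule="any"``).  Trailing
    partial blocks are zero-padded.
    """
    mask = np.asarray(mask).astype(bool)
    pads = [(0, (-s) % factor) for s in mask.shape]
    m = np.pad(mask, pads)
    sx, sy, sz = (s // factor for s in m.shape)
    blocks = m.reshape(sx, factor, sy, factor, sz, factor)
    counts = blocks.sum(axis=(1, 3, 5))
    if rule == "half":
        return counts >= (factor ** 3) / 2
    if rule == "any":
        return counts > 0
    raise ValueError(f"unknown downsampling rule {rule!r}")


def build_roi(wm_mask: np.ndarray, lesion_mask: np.ndarray,
              factor: int = 2, rule: str = "half") -> np.ndarray:
    """ROI = union of native-space WM and lesion masks, block-downsampled."""
    wm = np.asarray(wm_mask).astype(bool)
    lesion = np.asarray(lesion_mask).astype(bool)
    if wm.shape != lesion.shape:
        raise ValueError(f"mask shapes differ: {wm.shape} vs {lesion.shape}")
    return downsample_mask(wm | lesion, factor=factor, rule=rule)


_OFFSETS = [(dx, dy, dz)
            for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)]


def window_membership(roi_mask: np.ndarray, min_cluster: int = 2):
    """Window geometry for every ROI voxel.

    Returns ``(coords, valid, membership)``: ROI voxel coordinates (n_roi, 3)
    in C order, a validity flag per ROI voxel (>= ``min_cluster`` in-ROI
    voxels in its 3x3x3 neighbourhood), and a sparse (n_roi, n_roi) 0/1
    matrix mapping each window to its member ROI voxels.  Validity is purely
    geometric.
    """
    roi = np.asarray(roi_mask).astype(bool)
    coords = np.argwhere(roi)
    n = coords.shape[0]
    index = -np.ones(roi.shape, dtype=np.int64)
    index[tuple(coords.T)] = np.arange(n)
    shape = np.array(roi.shape)

    rows, cols = [], []
    for off in _OFFSETS:
        nb = coords + np.array(off)
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        j = index[tuple(nb[ok].T)]
        hit = j >= 0
        rows.append(np.flatnonzero(ok)[hit])
        cols.append(j[hit])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    membership = sp.csr_matrix(
        (np.ones(rows.size, dtype=np.float32), (rows, cols)), shape=(n, n))
    counts = np.asarray(membership.sum(axis=1)).ravel()
    valid = counts >= min_cluster
    return coords, valid, membership


@dataclass
class FeatureMapSet:
    """One run's feature maps on the ROI grid.

    ``values`` is (n_roi, 85) in registry order with NaN at invalid windows;
    ``coords``/``valid`` come from :func:`window_membership`.
    """

    run_id: str
    grid_shape: tuple[int, int, int]
    coords: np.ndarray
    valid: np.ndarray
    values: np.ndarray
    feature_names: tuple[str, ...] = field(default=FEATURE_NAMES)

    def __post_init__(self):
        if self.values.shape != (self.coords.shape[0], len(self.feature_names)):
            raise ValueError("values shape does not match coords/registry")

    def column(self, name: str) -> np.ndarray:
        """Values of one feature over ROI voxels (NaN where invalid)."""
        return self.values[:, self.feature_names.index(name)]

    def volume(self, name: str) -> np.ndarray:
        """One feature as a 3D volume (NaN outside valid windows)."""
        vol = np.full(self.grid_shape, np.nan)
        vol[tuple(self.coords.T)] = self.column(name)
        return vol

    def zscored(self) -> "FeatureMapSet":
        """Per-map z-scoring over valid ROI voxels (mean 0, SD 1)."""
        v = self.values[self.valid]
        mu = v.mean(axis=0)
        sd = v.std(axis=0)
        bad = np.flatnonzero(sd <= 0)
        if bad.size:
            raise ValueError(
                f"zero spread, cannot z-score feature {self.feature_names[bad[0]]}")
        out = np.full_like(self.values, np.nan)
        out[self.valid] = (v - mu) / sd
        return FeatureMapSet(self.run_id, self.grid_shape, self.coords,
                             self.valid.copy(), out, self.feature_names)


def sliding_window_maps(bold_run: np.ndarray, roi_mask: np.ndarray,
                        tr_seconds: float, run_id: str = "run",
                        bands: BandDefinition = DEFAULT_BANDS,
                        min_cluster: int = 2) -> FeatureMapSet:
    """Extract the 85 feature maps of one BOLD run on the ROI grid.

    ``bold_run`` is 4D (x, y, z, t), already resampled to the ROI grid with
    the initial frames discarded.
    """
    roi = np.asarray(roi_mask).astype(bool)
    if bold_run.shape[:3] != roi.shape:
        raise ValueError("BOLD grid does not match the ROI grid")
    if bold_run.shape[-1] < 8:
        raise ValueError("run too short after frame discard (< 8 frames)")
    coords, valid, membership = window_membership(roi, min_cluster=min_cluster)
    voxel_series = np.asarray(bold_run, dtype=float)[tuple(coords.T)]
    return _maps_from_series(voxel_series, coords, valid, membership,
                             roi.shape, tr_seconds, run_id, bands)


def maps_from_roi_series(voxel_series: np.ndarray, roi_mask: np.ndarray,
                         tr_seconds: float, run_id: str = "run",
                         bands: BandDefinition = DEFAULT_BANDS,
                         min_cluster: int = 2,
                         geometry=None) -> FeatureMapSet:
    """Same as :func:`sliding_window_maps` but from (n_roi, T) voxel series.

    ``geometry`` may carry a precomputed ``(coords, valid, membership)``
    triple to avoid recomputing the (purely geometric) window structure for
    every run of the same subject.
    """
    roi = np.asarray(roi_mask).astype(bool)
    if geometry is None:
        geometry = window_membership(roi, min_cluster=min_cluster)
    coords, valid, membership = geometry
    if voxel_series.shape[0] != coords.shape[0]:
        raise ValueError("voxel_series rows must match ROI voxel count")
    return _maps_from_series(np.asarray(voxel_series, dtype=float), coords,
                             valid, membership, roi.shape, tr_seconds,
                             run_id, bands)


def _maps_from_series(voxel_series, coords, valid, membership, grid_shape,
                      tr_seconds, run_id, bands) -> FeatureMapSet:
    counts = np.asarray(membership.sum(axis=1)).ravel()
    vrows = np.flatnonzero(valid)
    memb_v = membership[vrows]
    mean_series = (memb_v @ voxel_series) / counts[vrows, None]
    F = compute_feature_matrix(mean_series, tr_seconds,
                               voxel_series=voxel_series,
                               membership=memb_v, bands=bands)
    values = np.full((coords.shape[0], N_FEATURES), np.nan)
    values[vrows] = F
    return FeatureMapSet(run_id=run_id, grid_shape=tuple(grid_shape),
                         coords=coords, valid=valid.copy(), values=values)


def zscore_map(volume: np.ndarray, roi_mask: np.ndarray,
               name: str = "map") -> np.ndarray:
    """Z-score a 3D map over in-ROI finite voxels; others untouched."""
    vol = np.asarray(volume, dtype=float).copy()
    roi = np.asarray(roi_mask).astype(bool)
    if vol.shape != roi.shape:
        raise ValueError("map/ROI shape mismatch")
    sel = roi & np.isfinite(vol)
    if sel.sum() < 2:
        raise ValueError(f"need >= 2 valid in-ROI values to z-score {name}")
    v = vol[sel]
    sd = v.std()
    if sd <= 0:
        raise ValueError(f"zero spread, cannot z-score {name}")
    vol[sel] = (v - v.mean()) / sd
    return vol


def aggregate_runs(maps: list[FeatureMapSet]) -> FeatureMapSet:
    """Voxel-wise mean over runs; valid where valid in >= 1 run.

    Intended for z-scored per-run maps (the least-assumptive pooling into a
    single per-subject map); permutation-invariant in the run order.
    """
    if not maps:
        raise ValueError("no maps to aggregate")
    first = maps[0]
    for m in maps[1:]:
        if m.grid_shape != first.grid_shape or m.coords.shape != first.coords.shape:
            raise ValueError("feature map grids differ")
    stack = np.stack([m.values for m in maps])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    valid = np.any(np.stack([m.valid for m in maps]), axis=0)
    mean[~valid] = np.nan
    return FeatureMapSet(run_id="mean", grid_shape=first.grid_shape,
                         coords=first.coords, valid=valid, values=mean,
                         feature_names=first.feature_names)
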