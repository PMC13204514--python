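"""Synthetic stroke-cohort generator.

Produces a fully self-contained stand-in for a small longitudinal stroke
cohort: per subject a native-space white-matter (WM) mask and lesion mask, a
continuous lesion-probability map (surrogate for a trained segmentation
model's output), seven resting-state BOLD runs per visit at two visits
(subacute, chronic), and a table of motor / neuropsychological assessment
scores.  Every planted effect is parameterised and seeded:

* the lesion is a connected ellipsoidal blob inside the WM compartment
  (a smoothed ellipsoidal shell around a small ventricle-like hollow);
* BOLD voxels carry a coherent narrow-band oscillation (frequency drawn per
  subject in 0.01-0.10 Hz) whose amplitude in lesion voxels exceeds the WM
  background amplitude by the visit's planted contrast ratio, on top of
  white + weak 1/f noise around a constant baseline;
* the probability map is the lesion mask after Gaussian blur, additive
  noise and a per-subject multiplicative attenuation solved (by bisection)
  so that thresholding at 0.5 yields a target Dice drawn from
  ``probmap_quality_range``;
* assessment-score changes are planted on the per-subject lesion contrast
  (see :func:`generate_assessments`).

The same configuration and seed always reproduce byte-identical volumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

VISITS = ("subacute", "chronic")

_ROI_AFFINE = np.diag([2.0, 2.0, 2.0, 1.0])
_NATIVE_AFFINE = np.diag([1.0, 1.0, 1.0, 1.0])


@dataclass
class CohortConfig:
    """Study conditions of the synthetic cohort (defaults mirror the
    emulated acquisition: 20 subjects, 14 chronic completers, 7 runs per
    visit, 128 frames at TR = 2 s)."""

    n_subjects: int = 20
    n_chronic_completers: int = 14
    n_runs_per_visit: int = 7
    n_frames: int = 128
    tr_seconds: float = 2.0
    grid_shape: tuple[int, int, int] = (16, 16, 16)  # 2 mm ROI grid
    lesion_volume_range: tuple[int, int] = (30, 120)  # ROI voxels
    subacute_peak_contrast: float = 2.0
    chronic_peak_contrast: float = 1.4
    contrast_jitter: float = 0.3    # per-subject uniform +-fraction
    probmap_quality_range: tuple[float, float] = (0.0, 0.85)
    noise_sd: float = 1.0
    wm_oscillation_amplitude: float = 1.0
    baseline: float = 100.0
    pink_fraction: float = 0.3
    physio_sd: float = 1.0            # smooth broadband background scale
    physio_smooth_vox: float = 1.2    # spatial coherence of the background
    physio_heterogeneity: float = 0.4  # smooth +-fractional variance field
    freq_range: tuple[float, float] = (0.01, 0.10)
    probmap_blur_sigma: float = 0.8
    probmap_noise_sd: float = 0.05
    probmap_miss_prob: float = 0.7   # chance of a partial lesion miss
    probmap_fp_prob: float = 0.5     # chance of a false-positive blob
    seed: int = 0

    def __post_init__(self):
        if self.n_runs_per_visit < 1:
            raise ValueError("n_runs_per_visit must be >= 1")
        if self.n_frames <= 5:
            raise ValueError("n_frames must exceed the 5 discarded frames")
        if not self.chronic_peak_contrast < self.subacute_peak_contrast:
            raise ValueError("chronic contrast must be below subacute contrast")
        if not (0 < self.n_chronic_completers <= self.n_subjects):
            raise ValueError("n_chronic_completers must be in (0, n_subjects]")
        if self.lesion_volume_range[0] > self.lesion_volume_range[1]:
            raise ValueError("invalid lesion_volume_range")
        nyq = 0.5 / self.tr_seconds
        if self.freq_range[1] > nyq:
            raise ValueError("injected frequency range exceeds Nyquist")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _ellipsoid(shape, center, radii, rotation=None) -> np.ndarray:
    grid = np.indices(shape).reshape(3, -1).T.astype(float) - np.asarray(center)
    if rotation is not None:
        grid = grid @ rotation.T
    d = (grid / np.asarray(radii)) ** 2
    return (d.sum(axis=1) <= 1.0).reshape(shape)


def wm_compartment(grid_shape) -> np.ndarray:
    """Fixed synthetic WM compartment: smoothed ellipsoid shell around a
    small ventricle-like hollow, proportional to the grid."""
    s = np.asarray(grid_shape, dtype=float)
    center = (s - 1) / 2
    outer = _ellipsoid(grid_shape, center, s * np.array([0.42, 0.36, 0.33]))
    inner = _ellipsoid(grid_shape, center, s * np.array([0.24, 0.15, 0.15]))
    wm = ndimage.gaussian_filter((outer & ~inner).astype(float), 0.5) > 0.5
    return wm


def _random_rotation(rng) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _place_lesion(wm: np.ndarray, volume_range, rng, max_tries: int = 300):
    """Connected ellipsoidal lesion inside the WM compartment."""
    interior = ndimage.distance_transform_edt(wm) >= 1.5
    candidates = np.argwhere(interior if interior.any() else wm)
    if candidates.size == 0:
        raise RuntimeError("WM compartment empty, cannot place lesion")
    lo, hi = volume_range
    for _ in range(max_tries):
        center = candidates[rng.integers(len(candidates))]
        target = rng.uniform(lo, hi)
        p = rng.uniform(0.7, 1.3, size=3)
        r0 = (3.0 * target / (4.0 * np.pi * np.prod(p))) ** (1.0 / 3.0)
        radii = r0 * p
        blob = _ellipsoid(wm.shape, center, radii, _random_rotation(rng)) & wm
        if not blob.any():
            continue
        labels, nlab = ndimage.label(blob)
        if nlab > 1:
            sizes = ndimage.sum(blob, labels, index=range(1, nlab + 1))
            blob = labels == (1 + int(np.argmax(sizes)))
        vol = int(blob.sum())
        if lo <= vol <= hi:
            return blob
    raise RuntimeError(
        f"could not place a connected lesion of {lo}-{hi} voxels inside the "
        f"WM compartment on grid {wm.shape} after {max_tries} attempts")


# ---------------------------------------------------------------------------
# probability map
# ---------------------------------------------------------------------------

def dice_of(pred: np.ndarray, truth: np.ndarray) -> float:
    tp = np.logical_and(pred, truth).sum()
    denom = pred.sum() + truth.sum()
    return 1.0 if denom == 0 else 2.0 * tp / denom


def _make_probmap(lesion: np.ndarray, roi: np.ndarray, cfg: CohortConfig,
                  rng) -> tuple[np.ndarray, float, float]:
    base = ndimage.gaussian_filter(lesion.astype(float), cfg.probmap_blur_sigma)
    base /= max(base.max(), 1e-12)

    # partial miss: strongly attenuate the lesion evidence on one side of a
    # random plane through the lesion centroid -- a failure mode threshold
    # re-optimisation cannot undo
    if rng.random() < cfg.probmap_miss_prob:
        coords = np.indices(base.shape).reshape(3, -1).T.astype(float)
        centroid = np.argwhere(lesion).mean(axis=0)
        normal = rng.normal(size=3)
        normal /= np.linalg.norm(normal)
        side = ((coords - centroid) @ normal).reshape(base.shape) > \
            rng.uniform(-1.0, 1.0)
        base = np.where(side, base * rng.uniform(0.0, 0.4), base)

    # false-positive blob elsewhere in the ROI
    if rng.random() < cfg.probmap_fp_prob:
        cand = np.argwhere(roi & ~lesion)
        center = cand[rng.integers(len(cand))]
        radius = rng.uniform(1.2, 2.4)
        fp = _ellipsoid(base.shape, center, np.full(3, radius))
        fp_base = ndimage.gaussian_filter(fp.astype(float),
                                          cfg.probmap_blur_sigma)
        fp_base /= max(fp_base.max(), 1e-12)
        base = np.maximum(base, rng.uniform(0.6, 1.0) * fp_base)

    noise = rng.normal(0.0, cfg.probmap_noise_sd, size=base.shape)
    target = rng.uniform(*cfg.probmap_quality_range)

    def build(atten: float) -> np.ndarray:
        pm = np.clip(atten * base + noise, 0.0, 1.0)
        pm[~roi] = 0.0
        return pm

    lo_a, hi_a = 0.0, 1.0
    for _ in range(30):
        mid = 0.5 * (lo_a + hi_a)
        if dice_of(build(mid) > 0.5, lesion) < target:
            lo_a = mid
        else:
            hi_a = mid
    atten = hi_a
    pm = build(atten)
    return pm.astype(np.float32), target, dice_of(pm > 0.5, lesion)


# ---------------------------------------------------------------------------
# subject bundle
# ---------------------------------------------------------------------------

def _stream(cfg: CohortConfig, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, *key]))


@dataclass
class SubjectBundle:
    """One subject's volumes and planted parameters.

    Masks are native-space (1 mm, twice the ROI grid); the probability map
    and BOLD runs live on the 2 mm ROI grid.  Full 4D BOLD volumes are
    materialised on demand (:meth:`bold_run`); :meth:`roi_series` yields the
    same ROI voxel series without building the background.
    """

    subject_id: str
    subject_index: int
    config: CohortConfig
    wm_mask: np.ndarray            # native grid, uint8
    lesion_mask: np.ndarray        # native grid, uint8
    wm_mask_roi: np.ndarray        # ROI grid, bool
    lesion_mask_roi: np.ndarray    # ROI grid, bool
    probmap: np.ndarray            # ROI grid, float32 in [0, 1]
    visits: tuple[str, ...]
    frequency_hz: float
    contrast: dict                 # visit -> planted lesion/WM amplitude ratio
    probmap_target_dice: float
    probmap_dice: float
    _roi_coords: np.ndarray = field(repr=False, default=None)

    @property
    def roi_mask(self) -> np.ndarray:
        return self.wm_mask_roi | self.lesion_mask_roi

    @property
    def roi_coords(self) -> np.ndarray:
        if self._roi_coords is None:
            self._roi_coords = np.argwhere(self.roi_mask)
        return self._roi_coords

    def _signal_params(self, visit: str, run: int):
        if visit not in self.visits:
            raise KeyError(f"{self.subject_id} has no {visit} visit")
        if not 0 <= run < self.config.n_runs_per_visit:
            raise IndexError(f"run index {run} out of range")
        vi = VISITS.index(visit)
        return _stream(self.config, self.subject_index, 10 + 100 * vi + run)

    def _physio(self, visit: str, run: int) -> np.ndarray:
        """Spatially smooth broadband background, full grid (x, y, z, t).

        Emulates locally coherent physiological fluctuations (respiration,
        vasculature): white noise smoothed over space, rescaled to unit
        temporal variance and modulated by a smooth spatial amplitude field
        so that background variance varies gently across WM.
        """
        cfg = self.config
        if cfg.physio_sd <= 0:
            return np.zeros((*cfg.grid_shape, cfg.n_frames), dtype=np.float32)
        vi = VISITS.index(visit)
        rng = _stream(cfg, self.subject_index, 3000 + 100 * vi + run)
        white = rng.standard_normal(
            (*cfg.grid_shape, cfg.n_frames)).astype(np.float32)
        s = cfg.physio_smooth_vox
        field = ndimage.gaussian_filter(white, sigma=(s, s, s, 0.0))
        field /= max(field.std(), 1e-12)
        g = ndimage.gaussian_filter(
            rng.standard_normal(cfg.grid_shape).astype(np.float32), 1.5)
        g /= max(g.std(), 1e-12)
        amp = cfg.physio_sd * np.clip(
            1.0 + cfg.physio_heterogeneity * g, 0.2, 2.0)
        return field * amp[..., None]

    def roi_series(self, visit: str, run: int) -> np.ndarray:
        """(n_roi, n_frames) BOLD series of the ROI voxels (frames not yet
        discarded)."""
        cfg = self.config
        rng = self._signal_params(visit, run)
        coords = self.roi_coords
        n_vox, T = coords.shape[0], cfg.n_frames
        noise = rng.standard_normal((n_vox, T))
        if cfg.pink_fraction > 0:
            pink = _pink_noise(rng, n_vox, T)
            noise = noise + cfg.pink_fraction * pink
        phase = rng.uniform(0.0, 2.0 * np.pi)
        t = np.arange(T) * cfg.tr_seconds
        carrier = np.sin(2.0 * np.pi * self.frequency_hz * t + phase)
        lesion_vox = self.lesion_mask_roi[tuple(coords.T)]
        amp = np.where(lesion_vox,
                       cfg.wm_oscillation_amplitude * self.contrast[visit],
                       cfg.wm_oscillation_amplitude)
        physio = self._physio(visit, run)[tuple(coords.T)]
        series = (cfg.baseline + cfg.noise_sd * noise + physio
                  + amp[:, None] * carrier)
        return series.astype(np.float32)

    def bold_run(self, visit: str, run: int) -> np.ndarray:
        """Full 4D BOLD volume on the ROI grid (background = noise only)."""
        cfg = self.config
        vi = VISITS.index(visit)
        bg_rng = _stream(cfg, self.subject_index, 5000 + 100 * vi + run)
        vol = (cfg.baseline
               + cfg.noise_sd * bg_rng.standard_normal(
                   (*cfg.grid_shape, cfg.n_frames))
               + self._physio(visit, run)).astype(np.float32)
        vol[tuple(self.roi_coords.T)] = self.roi_series(visit, run)
        return vol

    @property
    def bold_runs(self) -> dict:
        """visit -> list of 4D runs (materialised on access)."""
        return {v: [self.bold_run(v, r)
                    for r in range(self.config.n_runs_per_visit)]
                for v in self.visits}


def _pink_noise(rng, n_vox: int, T: int) -> np.ndarray:
    """Unit-variance 1/f-shaped noise per voxel."""
    white = rng.standard_normal((n_vox, T))
    F = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(T)
    shape = 1.0 / np.sqrt(np.maximum(f, f[1]))
    shape[0] = 0.0
    pink = np.fft.irfft(F * shape, n=T, axis=1)
    sd = pink.std(axis=1, keepdims=True)
    return pink / np.maximum(sd, 1e-12)


def generate_subject(config: CohortConfig, subject_index: int) -> SubjectBundle:
    """Generate one subject (geometry, probability map, planted parameters).

    BOLD volumes are exposed lazily through the returned bundle and are
    deterministic functions of (config.seed, subject_index, visit, run).
    """
    if not 0 <= subject_index < config.n_subjects:
        raise ValueError("subject_index out of range")
    geo = _stream(config, subject_index, 0)
    compartment = wm_compartment(config.grid_shape)
    lesion_roi = _place_lesion(compartment, config.lesion_volume_range, geo)
    # the WM segmentation excludes the infarcted tissue; WM + lesion = ROI
    wm_roi = compartment & ~lesion_roi

    j = config.contrast_jitter
    contrast = {
        "subacute": config.subacute_peak_contrast * geo.uniform(1 - j, 1 + j),
        "chronic": config.chronic_peak_contrast * geo.uniform(1 - j, 1 + j),
    }
    freq = geo.uniform(*config.freq_range)

    pm_rng = _stream(config, subject_index, 1)
    probmap, target, achieved = _make_probmap(
        lesion_roi, wm_roi | lesion_roi, config, pm_rng)

    completer = subject_index < config.n_chronic_completers
    visits = VISITS if completer else ("subacute",)

    upsample = lambda m: np.kron(m.astype(np.uint8), np.ones((2, 2, 2), np.uint8))
    return SubjectBundle(
        subject_id=f"sub-{subject_index + 1:02d}",
        subject_index=subject_index,
        config=config,
        wm_mask=upsample(wm_roi),
        lesion_mask=upsample(lesion_roi),
        wm_mask_roi=wm_roi,
        lesion_mask_roi=lesion_roi,
        probmap=probmap,
        visits=visits,
        frequency_hz=freq,
        contrast=contrast,
        probmap_target_dice=target,
        probmap_dice=achieved,
    )


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

class SyntheticCohort:
    """Lazy, seeded collection of :class:`SubjectBundle` plus metadata."""

    def __init__(self, config: CohortConfig):
        self.config = config
        self._subjects: dict[int, SubjectBundle] = {}

    def subject(self, index: int) -> SubjectBundle:
        if index not in self._subjects:
            self._subjects[index] = generate_subject(self.config, index)
        return self._subjects[index]

    def __len__(self) -> int:
        return self.config.n_subjects

    def __iter__(self):
        return (self.subject(i) for i in range(len(self)))

    @property
    def subject_ids(self) -> list[str]:
        return [f"sub-{i + 1:02d}" for i in range(len(self))]

    @property
    def metadata(self) -> pd.DataFrame:
        rows = []
        for s in self:
            rows.append({
                "subject_id": s.subject_id,
                "completer": "chronic" in s.visits,
                "frequency_hz": s.frequency_hz,
                "contrast_subacute": s.contrast["subacute"],
                "contrast_chronic": s.contrast["chronic"],
                "lesion_volume_voxels": int(s.lesion_mask_roi.sum()),
                "probmap_target_dice": s.probmap_target_dice,
                "probmap_dice": s.probmap_dice,
            })
        return pd.DataFrame(rows)


def generate_assessments(cohort, effect_slope: float = 5.0,
                         noise_sd: float = 1.2, seed: int | None = None,
                         fim_slope: float = 1.0, fim_noise_sd: float = 1.0,
                         posner_change_sd: float = 80.0) -> pd.DataFrame:
    """Assessment scores with planted recovery associations.

    * change in word comprehension = ``effect_slope`` x (planted subacute
      lesion contrast) + N(0, noise_sd) -- the prognostic association;
    * change in FIM Walk is anti-correlated with the planted amplitude
      change between visits (clipped to the ordinal 1-7 scale);
    * change in Posner cueing reaction time is independent noise.

    ``cohort`` may be a :class:`SyntheticCohort` or a metadata-style
    DataFrame with columns subject_id / completer / contrast_subacute /
    contrast_chronic.  Word-comprehension scores are kept continuous so the
    planted linear effect is exactly recoverable at zero noise.
    """
    meta = cohort.metadata if isinstance(cohort, SyntheticCohort) else cohort
    if seed is None:
        seed = cohort.config.seed if isinstance(cohort, SyntheticCohort) else 0
    rng = np.random.default_rng(np.random.SeedSequence([seed, 999]))
    rows = []
    for _, m in meta.iterrows():
        word_sub = rng.uniform(18.0, 32.0)
        fim_sub = int(rng.integers(2, 6))
        posner_sub = rng.normal(450.0, 60.0)
        rows.append({"subject_id": m.subject_id, "visit": "subacute",
                     "fim_walk": fim_sub, "word_comprehension": word_sub,
                     "posner_ms": posner_sub})
        # draws below are consumed for every subject to keep the stream
        # alignment independent of completer status
        word_change = (effect_slope * m.contrast_subacute
                       + rng.normal(0.0, noise_sd))
        amp_change = m.contrast_chronic - m.contrast_subacute
        fim_change = -fim_slope * amp_change + rng.normal(0.0, fim_noise_sd)
        posner_change = rng.normal(0.0, posner_change_sd)
        if m.completer:
            fim_chr = int(np.clip(round(fim_sub + fim_change), 1, 7))
            rows.append({"subject_id": m.subject_id, "visit": "chronic",
                         "fim_walk": fim_chr,
                         "word_comprehension": word_sub + word_change,
                         "posner_ms": posner_sub + posner_change})
    df = pd.DataFrame(rows)
    if not df.fim_walk.between(1, 7).all():  # pragma: no cover - invariant
        raise AssertionError("FIM Walk out of ordinal range")
    return df


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------

def _save(path: Path, data: np.ndarray, affine: np.ndarray) -> None:
    try:
        nib.save(nib.Nifti1Image(data, affine), str(path))
    except OSError as exc:  # pragma: no cover - I/O failure path
        raise OSError(f"failed writing {path}: {exc}") from exc


def write_cohort(cohort: SyntheticCohort, directory,
                 assessments: pd.DataFrame | None = None,
                 include_bold: bool = True) -> dict:
    """Write the cohort as NIfTI + CSV + JSON manifest; returns the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = cohort.config
    manifest = {"config": cfg.to_dict(), "subjects": []}
    for s in cohort:
        sdir = directory / s.subject_id
        (sdir / "anat").mkdir(parents=True, exist_ok=True)
        entry = {"subject_id": s.subject_id, "visits": list(s.visits),
                 "bold_files": [], "seed": [cfg.seed, s.subject_index]}
        _save(sdir / "anat" / "wm_mask.nii.gz", s.wm_mask, _NATIVE_AFFINE)
        _save(sdir / "anat" / "lesion_mask.nii.gz", s.lesion_mask, _NATIVE_AFFINE)
        _save(sdir / "anat" / "probmap.nii.gz", s.probmap, _ROI_AFFINE)
        if include_bold:
            (sdir / "func").mkdir(exist_ok=True)
            for visit in s.visits:
                for r in range(cfg.n_runs_per_visit):
                    name = f"{s.subject_id}_visit-{visit}_run-{r + 1:02d}_bold.nii.gz"
                    _save(sdir / "func" / name, s.bold_run(visit, r), _ROI_AFFINE)
                    entry["bold_files"].append(f"{s.subject_id}/func/{name}")
        manifest["subjects"].append(entry)
    assess = assessments if assessments is not None else generate_assessments(cohort)
    assess.to_csv(directory / "assessments.csv", index=False)
    cohort.metadata.to_csv(directory / "metadata.csv", index=False)
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_cohort(directory) -> dict:
    """Load a written cohort back into arrays (lossless round trip)."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    out = {"manifest": manifest, "subjects": {},
           "assessments": pd.read_csv(directory / "assessments.csv")}
    for entry in manifest["subjects"]:
        sid = entry["subject_id"]
        sdir = directory / sid
        load = lambda p: np.asarray(nib.load(str(p)).dataobj)
        subj = {
            "wm_mask": load(sdir / "anat" / "wm_mask.nii.gz"),
            "lesion_mask": load(sdir / "anat" / "lesion_mask.nii.gz"),
            "probmap": load(sdir / "anat" / "probmap.nii.gz"),
            "bold": {v: [] for v in entry["visits"]},
        }
        for rel in entry["bold_files"]:
            visit = rel.split("visit-")[1].split("_")[0]
            subj["bold"][visit].append(load(directory / rel))
        out["subjects"][sid] = subj
    return out
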