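"""Evaluation protocol: subject-level 50/50 splits, the swapped split, the
three-contender model comparison, split averaging and paired t-tests.

Contenders: (1) the original probability map thresholded at 0.5, (2) the
re-optimised probability-map-only logistic model, (3) the multivariate
model adding the top-ranked rs-fMRI biomarkers.  All fitting happens on the
training half of a split; the swapped split exchanges the halves; final
numbers average the two splits' test means.  The paired t-test pairs
per-subject test Dice values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sct

from .fusion import (FusionSubject, LogisticFusion, dice_index,
                     original_model_dice, zero_clip)
from .roi import aggregate_runs
from .screening import FisherScreen, ScanFeatures

CONTENDERS = ("original", "reoptimized", "multivariate")


@dataclass(frozen=True)
class CohortSplit:
    train: tuple[str, ...]
    test: tuple[str, ...]
    label: str
    seed: int

    def __post_init__(self):
        if set(self.train) & set(self.test):
            raise ValueError("train and test sets overlap")

    def swapped(self) -> "CohortSplit":
        return CohortSplit(train=self.test, test=self.train,
                           label="swapped", seed=self.seed)


def make_splits(subject_ids, seed: int) -> tuple[CohortSplit, CohortSplit]:
    """Random half/half subject-level partition plus its mirror.

    With odd n the training half receives the extra subject.
    """
    ids = list(subject_ids)
    if len(ids) < 2:
        raise ValueError("need >= 2 subjects to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = (len(ids) + 1) // 2
    train = tuple(ids[i] for i in sorted(perm[:n_train]))
    test = tuple(ids[i] for i in sorted(perm[n_train:]))
    original = CohortSplit(train=train, test=test, label="original", seed=seed)
    return original, original.swapped()


@dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float
    degenerate: bool = False


def paired_t_test(dice_a, dice_b) -> PairedTResult:
    """Two-sided paired t-test on equal-length paired vectors."""
    a = np.asarray(dice_a, dtype=float)
    b = np.asarray(dice_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length paired vectors of size >= 2")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        # zero-variance differences: identical vectors give t=0, p=1
        if np.allclose(diff, 0.0):
            return PairedTResult(t=0.0, p=1.0, degenerate=True)
        return PairedTResult(t=float(np.inf * np.sign(diff.mean())), p=0.0,
                             degenerate=True)
    t, p = sct.ttest_rel(a, b)
    return PairedTResult(t=float(t), p=float(p))


# ---------------------------------------------------------------------------
# subject-level evaluation data
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    """Everything one subject contributes to a visit's evaluation."""

    subject_id: str
    run_maps: list                 # per-run FeatureMapSet
    probmap: np.ndarray            # ROI grid, float in [0, 1]
    lesion_mask: np.ndarray        # ROI grid, bool
    wm_mask: np.ndarray            # ROI grid, bool

    @property
    def roi_mask(self) -> np.ndarray:
        return self.wm_mask | self.lesion_mask


def _zscore_1d(v: np.ndarray) -> np.ndarray:
    sel = np.isfinite(v)
    sd = v[sel].std()
    if sd <= 0:
        raise ValueError("zero spread while z-scoring fusion input")
    out = np.full_like(v, np.nan)
    out[sel] = (v[sel] - v[sel].mean()) / sd
    return out


def build_fusion_subject(data: SubjectData, features, signs,
                         clip_threshold: float = 0.1,
                         clip_mode: str = "directional") -> FusionSubject:
    """Assemble z-scored, zero-clipped fusion inputs for one subject.

    Per-run feature maps are z-scored per run, pooled by voxel-wise mean
    into the model-fitting map, and also kept per run for run-wise
    application; the zero-clip is applied after z-scoring.
    """
    fms0 = data.run_maps[0]
    coords = fms0.coords
    probs_raw = np.asarray(data.probmap, dtype=float)[tuple(coords.T)]
    probs_z = _zscore_1d(probs_raw)
    truth = data.lesion_mask[tuple(coords.T)]

    zruns = [m.zscored() for m in data.run_maps]
    pooled = aggregate_runs(zruns) if len(zruns) > 1 else zruns[0]
    feats, per_run = [], []
    for f, sign in zip(features, signs):
        feats.append(zero_clip(pooled.column(f), sign,
                               threshold=clip_threshold, mode=clip_mode))
    for zm in zruns:
        per_run.append([zero_clip(zm.column(f), sign, threshold=clip_threshold,
                                  mode=clip_mode)
                        for f, sign in zip(features, signs)])
    return FusionSubject(subject_id=data.subject_id, probmap_z=probs_z,
                         feature_zmaps=feats, truth=truth,
                         probmap_raw=probs_raw,
                         per_run_feature_zmaps=per_run)


def compare_models(cohort_data: dict, split: CohortSplit, k: int = 2,
                   clip_threshold: float = 0.1, clip_mode: str = "directional",
                   fusion_kwargs: dict | None = None):
    """Per-subject test Dice of the three contenders on one split.

    ``cohort_data`` maps subject_id -> :class:`SubjectData`.  Returns
    ``(table, info)`` where ``table`` has one row per test subject and
    contender (columns: model, subject_id, dice, dice_sd -- the SD across
    runs for the multivariate model) and ``info`` carries the fitted
    screening and fusion objects.
    """
    fusion_kwargs = fusion_kwargs or {}
    missing = [s for s in (*split.train, *split.test) if s not in cohort_data]
    if missing:
        raise ValueError(f"missing feature maps for subjects: {missing}")

    train_scans = [
        ScanFeatures(sid, "train", r, m, cohort_data[sid].lesion_mask,
                     cohort_data[sid].wm_mask)
        for sid in split.train
        for r, m in enumerate(cohort_data[sid].run_maps)]
    screen = FisherScreen(k=k).fit(train_scans)
    features = screen.selected_features_
    signs = screen.selected_signs_

    fusion_in = {sid: build_fusion_subject(cohort_data[sid], features, signs,
                                           clip_threshold, clip_mode)
                 for sid in (*split.train, *split.test)}
    train_subjects = [fusion_in[sid] for sid in split.train]
    reopt = LogisticFusion(n_features=0, **fusion_kwargs).fit(train_subjects)
    multi = LogisticFusion(n_features=k, **fusion_kwargs).fit(train_subjects)

    rows = []
    for sid in split.test:
        fs = fusion_in[sid]
        rows.append({"model": "original", "subject_id": sid,
                     "dice": original_model_dice(fs).dice, "dice_sd": np.nan})
        pred = reopt._predict_one(fs.probmap_z, [])
        rows.append({"model": "reoptimized", "subject_id": sid,
                     "dice": dice_index(pred, fs.truth).dice,
                     "dice_sd": np.nan})
        run_dice = []
        for run_feats in fs.per_run_feature_zmaps:
            predm = multi._predict_one(fs.probmap_z, run_feats)
            run_dice.append(dice_index(predm, fs.truth).dice)
        rows.append({"model": "multivariate", "subject_id": sid,
                     "dice": float(np.mean(run_dice)),
                     "dice_sd": float(np.std(run_dice, ddof=0))})
    table = pd.DataFrame(rows)
    table["split"] = split.label
    info = {"screen": screen, "reoptimized": reopt, "multivariate": multi,
            "features": features, "signs": signs}
    return table, info


def summarize_dice(values) -> tuple[float, float]:
    """Mean +- SD aggregation used for the per-contender report rows."""
    v = np.asarray(values, dtype=float)
    return float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0


def split_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +- SD of test Dice per contender for one split table."""
    rows = []
    for model, g in table.groupby("model", sort=False):
        mean, sd = summarize_dice(g.dice)
        rows.append({"model": model, "split": g.split.iloc[0],
                     "mean_dice": mean, "sd_dice": sd})
    return pd.DataFrame(rows)


def average_splits(original_table: pd.DataFrame,
                   swapped_table: pd.DataFrame) -> pd.DataFrame:
    """Per-contender mean over the two splits' test means (final report)."""
    s1 = split_summary(original_table).set_index("model")
    s2 = split_summary(swapped_table).set_index("model")
    out = pd.DataFrame({
        "mean_dice_original_split": s1.mean_dice,
        "mean_dice_swapped_split": s2.mean_dice,
    })
    out["mean_dice"] = out.mean(axis=1)
    return out.reset_index()
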