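"""Dice index, zero-clip rule, logistic fusion and the full-grid search."""

import itertools

import numpy as np
import pytest

from strokefuse.fusion import (DEFAULT_BETA0_LEVELS, DEFAULT_BETA1_LEVELS,
                               DEFAULT_FEATURE_LEVELS, FusionSubject,
                               LogisticFusion, apply_model, dice_index,
                               grid_search_fit, logistic_probability,
                               original_model_dice, zero_clip)


# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------

def test_dice_trivial_cases(rng):
    m = rng.random((4, 4, 4)) > 0.5
    m[0, 0, 0] = True
    assert dice_index(m, m).dice == 1.0
    assert dice_index(m, ~m).dice == 0.0
    empty = np.zeros_like(m)
    r = dice_index(empty, empty)
    assert r.dice == 1.0 and r.both_empty
    assert dice_index(empty, m).dice == 0.0


def test_dice_substitution():
    """TP=2, FP=1, FN=1 -> 2*2/(2*2+1+1) = 0.667."""
    pred = np.array([1, 1, 1, 0], dtype=bool)
    truth = np.array([1, 1, 0, 1], dtype=bool)
    r = dice_index(pred, truth)
    assert (r.tp, r.fp, r.fn) == (2, 1, 1)
    assert r.dice == pytest.approx(2 * 2 / (2 * 2 + 1 + 1))


def test_dice_shape_mismatch():
    with pytest.raises(ValueError):
        dice_index(np.ones((2, 2), dtype=bool), np.ones((3, 3), dtype=bool))


# ---------------------------------------------------------------------------
# zero-clip
# ---------------------------------------------------------------------------

def test_zero_clip_cases(rng):
    z = np.full(10, 0.05)
    assert np.all(zero_clip(z, +1) == 0.0)
    z = np.full(10, 0.5)
    assert np.array_equal(zero_clip(z, +1), z)
    mixed = rng.normal(size=1000)
    clipped = zero_clip(mixed, +1)
    # element-wise oracle for the surviving-voxel count
    assert (clipped != 0).sum() == (mixed >= 0.1).sum()
    assert np.array_equal(clipped != 0, mixed >= 0.1)
    neg = zero_clip(mixed, -1)
    assert np.array_equal(neg != 0, mixed <= -0.1)
    sym = zero_clip(mixed, +1, mode="symmetric")
    assert np.array_equal(sym != 0, np.abs(mixed) >= 0.1)


def test_zero_clip_validation(rng):
    with pytest.raises(ValueError):
        zero_clip(np.zeros(3), 0)
    with pytest.raises(ValueError):
        zero_clip(np.zeros(3), 1, mode="bogus")


# ---------------------------------------------------------------------------
# logistic probability
# ---------------------------------------------------------------------------

def test_logistic_closed_forms(rng):
    P = rng.normal(size=(4, 4))
    roi = np.ones((4, 4), dtype=bool)
    assert np.allclose(logistic_probability([0, 0], P, roi_mask=roi), 0.5)
    p = logistic_probability([np.log(3.0), 0.0], P)
    assert np.allclose(p, 0.75)


def test_logistic_matches_independent_sigmoid(rng):
    P = rng.normal(size=50)
    F1, F2 = rng.normal(size=50), rng.normal(size=50)
    params = [0.3, 1.2, -0.7, 2.0]
    got = logistic_probability(params, P, [F1, F2])
    logit = 0.3 + 1.2 * P - 0.7 * F1 + 2.0 * F2
    want = np.exp(logit) / (1.0 + np.exp(logit))
    assert np.allclose(got, want, atol=1e-12)


def test_logistic_masks_outside_roi(rng):
    P = rng.normal(size=(3, 3))
    roi = np.zeros((3, 3), dtype=bool)
    roi[1, 1] = True
    p = logistic_probability([0.0, 1.0], P, roi_mask=roi)
    assert p[0, 0] == 0.0 and p[1, 1] > 0.0


def test_logistic_grid_mismatch(rng):
    with pytest.raises(ValueError):
        logistic_probability([0, 1, 1], rng.normal(size=5),
                             [rng.normal(size=6)])


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

def _subject(rng, n=200, informative=True, seed_truth=None):
    truth = rng.random(n) < 0.25 if seed_truth is None else seed_truth
    probs_z = np.where(truth, 1.0, -0.5) + rng.normal(0, 0.8, n)
    feat = np.where(truth, 1.5, 0.0) + rng.normal(0, 0.5, n) \
        if informative else rng.normal(size=n)
    feat2 = rng.normal(size=n)
    return FusionSubject(subject_id="s", probmap_z=probs_z,
                         feature_zmaps=[feat, feat2], truth=truth,
                         probmap_raw=1 / (1 + np.exp(-probs_z)))


def test_default_grid_enumerates_432_combinations(rng):
    model = LogisticFusion(n_features=2).fit([_subject(rng)])
    assert model.n_combinations_ == 3 * 4 * 6 * 6 == 432
    assert len(DEFAULT_BETA0_LEVELS) == 3
    assert len(DEFAULT_BETA1_LEVELS) == 4
    assert len(DEFAULT_FEATURE_LEVELS) == 6


def test_grid_search_is_exhaustively_optimal(rng):
    """Returned coefficients maximise mean training Dice over every
    enumerated combination (verified by an independent re-computation)."""
    subs = [_subject(rng) for _ in range(3)]
    model = LogisticFusion(n_features=2,
                           beta0_levels=(-1.0, 0.0, 1.0),
                           beta1_levels=(0.5, 1.0),
                           feature_levels=(0.0, 1.0, 2.0)).fit(subs)
    best = -1.0
    for combo in itertools.product((-1.0, 0.0, 1.0), (0.5, 1.0),
                                   (0.0, 1.0, 2.0), (0.0, 1.0, 2.0)):
        dices = []
        for s in subs:
            logit = combo[0] + combo[1] * s.probmap_z + \
                combo[2] * s.feature_zmaps[0] + combo[3] * s.feature_zmaps[1]
            pred = 1 / (1 + np.exp(-logit)) > 0.5
            dices.append(dice_index(pred, s.truth).dice)
        best = max(best, float(np.mean(dices)))
    assert model.best_training_dice_ == pytest.approx(best, abs=1e-12)
    got = np.concatenate([[model.intercept_], model.coef_])
    assert all(got[i] in ((-1.0, 0.0, 1.0), (0.5, 1.0),
                          (0.0, 1.0, 2.0), (0.0, 1.0, 2.0))[i]
               for i in range(4))


def test_tie_break_prefers_smallest_coefficients():
    # a subject where every combination scores identically (empty truth is
    # impossible; use truth = all voxels, any positive logit predicts all)
    n = 20
    s = FusionSubject(subject_id="s", probmap_z=np.full(n, 5.0),
                      feature_zmaps=[np.zeros(n), np.zeros(n)],
                      truth=np.ones(n, dtype=bool))
    model = LogisticFusion(n_features=2, beta0_levels=(0.0, 2.0),
                           beta1_levels=(1.0, 2.0),
                           feature_levels=(0.0, 1.0)).fit([s])
    assert model.intercept_ == 0.0
    assert np.array_equal(model.coef_, [1.0, 0.0, 0.0])


def test_reoptimized_contender_dominates_grid_member(rng):
    """With n_features=0, the fitted training Dice is >= the Dice of any
    single grid member, in particular the default-threshold-equivalent one."""
    subs = [_subject(rng) for _ in range(4)]
    model = LogisticFusion(n_features=0).fit(subs)
    fixed = LogisticFusion(n_features=0, beta0_levels=(0.0,),
                           beta1_levels=(1.0,)).fit(subs)
    assert model.best_training_dice_ >= fixed.best_training_dice_ - 1e-12


def test_informative_biomarker_gets_nonzero_weight(rng):
    subs = [_subject(rng) for _ in range(4)]
    model = grid_search_fit(subs, n_features=1)
    assert model.coef_[1] > 0.0


def test_monotone_in_the_logit(rng):
    s = _subject(rng)
    model = LogisticFusion(n_features=2).fit([s])
    params = np.concatenate([[model.intercept_], model.coef_])
    base = logistic_probability(params, s.probmap_z, s.feature_zmaps)
    bumped = logistic_probability(params, s.probmap_z + 0.5,
                                  s.feature_zmaps)
    if params[1] > 0:
        assert np.all(bumped >= base - 1e-12)


def test_apply_model_limits(rng):
    n = 100
    truth = rng.random(n) < 0.3
    probs_raw = np.where(truth, 0.9, 0.1) + rng.normal(0, 0.01, n)
    probs_z = (probs_raw - probs_raw.mean()) / probs_raw.std()
    s = FusionSubject(subject_id="s", probmap_z=probs_z,
                      feature_zmaps=[rng.normal(size=n)], truth=truth,
                      probmap_raw=probs_raw)
    # beta1 large, feature weight 0 -> prediction equals thresholded probmap
    model = LogisticFusion(n_features=1, beta0_levels=(0.0,),
                           beta1_levels=(50.0,), feature_levels=(0.0,))
    model.fit([s])
    pred, r = apply_model(model, s)
    assert np.array_equal(pred, probs_z > 0)
    assert r.dice == dice_index(probs_z > 0, truth).dice
    # perfect probability map reproduces the truth exactly
    assert original_model_dice(s).dice == 1.0
    # pathological all-zero inputs -> empty prediction, Dice 0
    s0 = FusionSubject(subject_id="z", probmap_z=np.zeros(n),
                       feature_zmaps=[np.zeros(n)], truth=truth)
    m0 = LogisticFusion(n_features=1, beta0_levels=(-2.0,),
                        beta1_levels=(1.0,), feature_levels=(0.0,)).fit([s0])
    pred0, r0 = apply_model(m0, s0)
    assert pred0.sum() == 0 and r0.dice == 0.0


def test_fit_validation(rng):
    with pytest.raises(ValueError):
        LogisticFusion(n_features=3).fit([_subject(rng)])
    with pytest.raises(ValueError):
        LogisticFusion(beta0_levels=()).fit([_subject(rng)])
    with pytest.raises(ValueError):
        LogisticFusion().fit([])
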