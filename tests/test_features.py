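"""Per-window feature extraction against independent brute-force oracles."""

import numpy as np
import pytest
from scipy import stats as sct

from strokefuse.features import (DEFAULT_BANDS, BandDefinition,
                                 TimeseriesWindow, ar_features,
                                 assemble_feature_vector,
                                 compute_feature_matrix, concordance_features,
                                 detrended_variants, envelope_features,
                                 power_spectrum_features, raw_signal_features)
from strokefuse.registry import FEATURE_NAMES, GROUP_SIZES, N_AUTO, N_FEATURES


# ---------------------------------------------------------------------------
# oracles (kept deliberately naive and independent of the implementation)
# ---------------------------------------------------------------------------

def oracle_stats(x):
    x = np.asarray(x, dtype=float)
    n = len(x)
    mean = sum(x) / n
    rms = (sum(v * v for v in x) / n) ** 0.5
    sd = (sum((v - mean) ** 2 for v in x) / (n - 1)) ** 0.5
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    peak = max(abs(v) for v in x)
    mean_abs = sum(abs(v) for v in x) / n
    mean_sqrt = sum(abs(v) ** 0.5 for v in x) / n
    return {
        "mean": mean, "rms": rms, "sd": sd,
        "skewness": m3 / m2 ** 1.5, "kurtosis": m4 / m2 ** 2,
        "peak_value": peak, "minimum": min(x), "maximum": max(x),
        "median": float(np.quantile(x, 0.5)),
        "q1": float(np.quantile(x, 0.25)), "q3": float(np.quantile(x, 0.75)),
        "iqr": float(np.quantile(x, 0.75) - np.quantile(x, 0.25)),
        "crest_factor": peak / rms, "impulse_factor": peak / mean_abs,
        "clearance_factor": peak / mean_sqrt ** 2,
        "shape_factor": rms / mean_abs,
    }


def oracle_amplitude_spectrum(x, tr):
    """Direct O(T^2) DFT of the mean-removed series; one-sided amplitude."""
    x = np.asarray(x, dtype=float)
    T = len(x)
    y = x - x.mean()
    freqs = np.arange(T // 2 + 1) / (T * tr)
    amp = np.empty(freqs.size)
    for k in range(freqs.size):
        c = sum(y[j] * np.exp(-2j * np.pi * k * j / T) for j in range(T))
        scale = 1.0 if k == 0 or (T % 2 == 0 and k == T // 2) else 2.0
        amp[k] = scale * abs(c) / T
    return freqs, amp


def oracle_kendall_w(series):
    """Classical rank-sum formula for Kendall's coefficient of concordance."""
    R = np.array([sct.rankdata(s) for s in series])
    k, T = R.shape
    col = R.sum(axis=0)
    S = ((col - k * (T + 1) / 2.0) ** 2).sum()
    return 12.0 * S / (k ** 2 * (T ** 3 - T))


# ---------------------------------------------------------------------------
# raw signal statistics
# ---------------------------------------------------------------------------

def test_raw_stats_match_direct_formulas(rng):
    x = rng.normal(2.0, 1.5, size=60)
    got = raw_signal_features(x)
    want = oracle_stats(x)
    for key, val in want.items():
        assert got[key] == pytest.approx(val, abs=1e-10), key


def test_constant_series_uses_sentinels():
    got = raw_signal_features([1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
    assert got["mean"] == 1.0
    assert got["sd"] == 0.0
    assert got["crest_factor"] == 1.0
    assert got["skewness"] == 0.0  # sentinel for the 0/0 case


def test_alternating_series():
    got = raw_signal_features([-1.0, 1.0] * 8)
    assert got["mean"] == pytest.approx(0.0)
    assert got["rms"] == pytest.approx(1.0)
    assert got["peak_value"] == 1.0


def test_raw_rejects_short_or_nonfinite():
    with pytest.raises(ValueError):
        raw_signal_features([1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        raw_signal_features([np.nan] + [0.0] * 20)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def test_on_bin_sinusoid_peak_amplitude_and_frequency():
    T, tr, A, k = 123, 2.0, 3.7, 9
    f = k / (T * tr)
    x = 5.0 + A * np.sin(2 * np.pi * f * np.arange(T) * tr + 0.4)
    got = power_spectrum_features(x, tr)
    assert got["peak_amplitude"] == pytest.approx(A, abs=1e-6)
    assert got["peak_frequency"] == pytest.approx(f, abs=1e-12)


def test_sinusoid_strictly_raises_peak_over_matched_noise(rng):
    T, tr = 100, 2.0
    noise = rng.normal(size=T)
    f = 10 / (T * tr)
    with_sin = noise + 2.5 * np.sin(2 * np.pi * f * np.arange(T) * tr)
    a = power_spectrum_features(noise, tr)["peak_amplitude"]
    b = power_spectrum_features(with_sin, tr)["peak_amplitude"]
    assert b > a


def test_highest_admissible_peak_frequency_is_nyquist():
    """TR = 2 s limits the spectrum to 0.25 Hz."""
    tr, T = 2.0, 124  # even length: the last rfft bin is exactly Nyquist
    x = np.sin(2 * np.pi * 0.25 * np.arange(T) * tr + 0.7) + \
        0.01 * np.cos(np.arange(T))
    got = power_spectrum_features(x, tr)
    assert got["peak_frequency"] <= 0.25 + 1e-12
    freqs = np.fft.rfftfreq(T, d=tr)
    assert freqs.max() == pytest.approx(0.25)


def test_spectrum_matches_brute_force_dft(rng):
    x = rng.normal(size=32)
    tr = 2.0
    freqs, amp = oracle_amplitude_spectrum(x, tr)
    got = power_spectrum_features(x, tr)
    k = int(np.argmax(amp[1:]) + 1)
    assert got["peak_amplitude"] == pytest.approx(amp[k], abs=1e-8)
    assert got["peak_frequency"] == pytest.approx(freqs[k], abs=1e-12)


def test_all_zero_series_spectrum():
    got = power_spectrum_features(np.zeros(32), 2.0)
    assert got["power"] == 0.0
    assert got["peak_amplitude"] == 0.0
    assert got["peak_frequency"] == pytest.approx(1 / 64.0)  # lowest bin


# ---------------------------------------------------------------------------
# envelope
# ---------------------------------------------------------------------------

def test_am_modulation_frequency_recovered():
    T, tr = 200, 1.0
    fc, fm = 0.25, 10 / (T * tr)
    t = np.arange(T) * tr
    x = (1.0 + 0.5 * np.cos(2 * np.pi * fm * t)) * np.sin(2 * np.pi * fc * t)
    got = envelope_features(x, sampling_interval=tr)
    assert got["spectrum_peak_frequency"] == pytest.approx(fm, abs=1e-9)


def test_envelope_bounds_detrended_series(rng):
    from strokefuse.features import _detrend, _envelope
    x = rng.normal(size=(1, 64))
    env = _envelope(x)
    assert np.all(env >= np.abs(_detrend(x)) - 1e-9)


def test_constant_series_envelope_is_flat():
    got = envelope_features(np.full(32, 7.0))
    assert got["sd"] == pytest.approx(0.0, abs=1e-10)


# ---------------------------------------------------------------------------
# autoregressive block
# ---------------------------------------------------------------------------

def _ar1(rng, phi, T, noise=1.0):
    x = np.zeros(T)
    for t in range(1, T):
        x[t] = phi * x[t - 1] + noise * rng.normal()
    return x


def test_ar_structure_beats_its_permutation(rng):
    x = _ar1(rng, 0.9, 300)
    aic = ar_features(x)["aic"]
    aic_perm = ar_features(rng.permutation(x))["aic"]
    assert aic < aic_perm


def test_white_noise_first_coefficient_small(rng):
    T = 400
    x = rng.normal(size=T)
    got = ar_features(x)
    assert abs(got["first_coefficient"]) < 3.0 / np.sqrt(T)


def test_low_noise_ar1_residuals_vanish(rng):
    x_hi = _ar1(rng, 0.8, 300, noise=1.0)
    x_lo = _ar1(np.random.default_rng(1), 0.8, 300, noise=1e-4)
    assert ar_features(x_lo)["mse"] < 1e-6 * ar_features(x_hi)["mse"]


def test_ar1_first_coefficient_recovered(rng):
    x = _ar1(rng, 0.7, 2000)
    got = ar_features(x)
    assert got["first_coefficient"] == pytest.approx(0.7, abs=0.08)


# ---------------------------------------------------------------------------
# de-trended variants
# ---------------------------------------------------------------------------

def test_exact_line_detrends_to_zero():
    t = np.arange(40, dtype=float)
    got = detrended_variants(3.0 + 0.5 * t)
    assert got["rms"] == pytest.approx(0.0, abs=1e-9)


def test_detrending_is_idempotent(rng):
    from strokefuse.features import _detrend
    x = rng.normal(size=(1, 50))
    once = _detrend(x)
    assert np.allclose(_detrend(once), once, atol=1e-10)


def test_detrended_features_equal_raw_features_of_residual(rng):
    x = rng.normal(size=64) + 0.3 * np.arange(64)
    t = np.arange(64)
    slope, intercept = np.polyfit(t, x, 1)  # independent line fit
    resid = x - (slope * t + intercept)
    got = detrended_variants(x)
    want = raw_signal_features(resid)
    for key in ("mean", "rms", "sd", "skewness", "kurtosis", "q1", "q3"):
        assert got[key] == pytest.approx(want[key], abs=1e-8), key


# ---------------------------------------------------------------------------
# literature features
# ---------------------------------------------------------------------------

def test_single_band_sinusoid_power_ratios(rng):
    T, tr = 123, 2.0
    t = np.arange(T) * tr
    f = 5 / (T * tr)  # on-bin frequency inside the 0.01-0.04 Hz band
    x = np.sin(2 * np.pi * f * t)
    w = TimeseriesWindow(voxel_series=np.vstack([x, x]), sampling_interval=tr)
    got = assemble_feature_vector(w)
    assert got["literature.power_ratio_low"] == pytest.approx(1.0, abs=1e-6)
    assert got["literature.power_ratio_mid"] == pytest.approx(0.0, abs=1e-6)
    assert got["literature.power_ratio_high"] == pytest.approx(0.0, abs=1e-6)


def test_identical_voxel_series_fully_concordant(rng):
    x = rng.normal(size=50)
    w, tau = concordance_features(np.vstack([x, x, x]))
    assert w[0] == pytest.approx(1.0, abs=1e-12)
    assert tau[0] == pytest.approx(1.0, abs=1e-12)


def test_kendall_w_matches_rank_sum_formula(rng):
    V = rng.normal(size=(27, 123))
    w, _ = concordance_features(V)
    assert w[0] == pytest.approx(oracle_kendall_w(V), abs=1e-12)


def test_mean_pairwise_tau_matches_scipy(rng):
    V = rng.normal(size=(6, 40))
    _, tau = concordance_features(V)
    pairs = [sct.kendalltau(V[i], V[j]).statistic
             for i in range(6) for j in range(i + 1, 6)]
    assert tau[0] == pytest.approx(np.mean(pairs), abs=1e-12)


def test_concordance_requires_two_series(rng):
    with pytest.raises(ValueError):
        TimeseriesWindow(voxel_series=rng.normal(size=(1, 30)),
                         sampling_interval=2.0)


def test_band_definition_validation():
    with pytest.raises(ValueError):
        BandDefinition(low=(0.01, 0.05), mid=(0.04, 0.08))
    with pytest.raises(ValueError):
        DEFAULT_BANDS.validate_nyquist(tr_seconds=10.0)


# ---------------------------------------------------------------------------
# assembled vector and registry
# ---------------------------------------------------------------------------

def test_feature_vector_has_85_unique_named_entries(rng):
    w = TimeseriesWindow(voxel_series=rng.normal(size=(4, 123)),
                         sampling_interval=2.0)
    v = assemble_feature_vector(w)
    assert len(v) == N_FEATURES == 85
    assert list(v) == list(FEATURE_NAMES)
    assert all(np.isfinite(x) for x in v.values())


def test_group_sizes_partition_77_plus_8():
    assert N_AUTO == 77
    assert GROUP_SIZES["literature"] == 8
    assert sum(GROUP_SIZES.values()) == 85


def test_vector_is_deterministic(rng):
    w = TimeseriesWindow(voxel_series=rng.normal(size=(5, 60)),
                         sampling_interval=2.0)
    assert assemble_feature_vector(w) == assemble_feature_vector(w)


def test_batch_engine_agrees_with_per_window_path(rng):
    V = rng.normal(size=(8, 60)) + 100.0
    w = TimeseriesWindow(voxel_series=V, sampling_interval=2.0)
    single = np.array(list(assemble_feature_vector(w).values()))
    import scipy.sparse as sp
    memb = sp.csr_matrix(np.ones((1, 8), dtype=np.float32))
    batch = compute_feature_matrix(V.mean(axis=0)[None, :], 2.0,
                                   voxel_series=V, membership=memb)[0]
    assert np.allclose(single, batch, atol=1e-9, equal_nan=True)


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------

_SCALE_EQUIVARIANT = [
    "raw.mean", "raw.rms", "raw.sd", "raw.peak_value", "raw.q1", "raw.q3",
    "raw.iqr", "spectrum.peak_amplitude", "literature.alff_low",
    "literature.alff_mid", "literature.alff_high",
]
_SCALE_INVARIANT = [
    "raw.crest_factor", "raw.impulse_factor", "raw.clearance_factor",
    "raw.shape_factor", "raw.skewness", "raw.kurtosis",
    "literature.power_ratio_low", "literature.power_ratio_mid",
    "literature.power_ratio_high", "literature.kendall_w",
    "literature.kendall_tau",
]


def test_scale_behaviour_over_20_random_series(rng):
    for _ in range(20):
        V = np.abs(rng.normal(2.0, 1.0, size=(3, 60))) + 0.5
        c = float(rng.uniform(0.5, 4.0))
        w1 = TimeseriesWindow(voxel_series=V, sampling_interval=2.0)
        w2 = TimeseriesWindow(voxel_series=c * V, sampling_interval=2.0)
        v1 = assemble_feature_vector(w1)
        v2 = assemble_feature_vector(w2)
        for name in _SCALE_EQUIVARIANT:
            assert v2[name] == pytest.approx(c * v1[name], rel=1e-8), name
        for name in _SCALE_INVARIANT:
            assert v2[name] == pytest.approx(v1[name], rel=1e-7, abs=1e-9), name


def test_every_feature_finite_on_1000_random_windows(rng):
    X = rng.normal(100.0, 2.0, size=(1000, 59))
    F = compute_feature_matrix(X, 2.0)  # concordance columns NaN by design
    names = np.array(FEATURE_NAMES)
    concord = np.isin(names, ["literature.kendall_w", "literature.kendall_tau"])
    assert np.all(np.isfinite(F[:, ~concord]))
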