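"""Per-window BOLD time-series features.

Everything here operates on the time series of one sliding window: the
window-averaged ("mean") series for univariate metrics and the individual
voxel series for the concordance metrics.  The public per-window operations
(:func:`raw_signal_features` ... :func:`assemble_feature_vector`) are thin
wrappers around a vectorised batch engine (:func:`compute_feature_matrix`)
that evaluates whole stacks of windows at once; there is a single code path.

Numerical conventions (see docs/methods.md):

* spectra are single-taper periodograms of the mean-removed series, no
  zero padding; the amplitude spectrum is scaled so that a sinusoid of
  amplitude A sitting on a DFT bin has peak amplitude exactly A (linear
  de-trending would leak part of an on-bin sinusoid into the fitted line,
  so it is applied only in the de-trended feature groups);
* SNR / SINAD / THD use the largest non-DC periodogram line as the
  fundamental and its integer bin multiples as harmonics, in dB;
* AR models are fitted by Yule-Walker/Levinson-Durbin for orders 1..8 and
  selected by minimum AIC = T*ln(residual variance) + 2*(order+1);
* statistics with a zero denominator on a degenerate (constant) series
  return 0 and the window is flagged so downstream screening can exclude it.
"""

from __future__ import annotations

import warnings
from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy import signal as sps
from scipy import stats as sct

from .registry import FEATURE_NAMES, N_FEATURES

_EPS = 1e-30


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandDefinition:
    """Frequency bands (Hz) for the band-limited literature features.

    Band membership is low <= f <= high for the low band and
    low < f <= high for the mid and high bands, so the shared endpoints are
    counted exactly once.
    """

    low: tuple[float, float] = (0.01, 0.04)
    mid: tuple[float, float] = (0.04, 0.08)
    high: tuple[float, float] = (0.08, 0.10)

    def __post_init__(self):
        if not (self.low[0] < self.low[1] <= self.mid[0] < self.mid[1]
                <= self.high[0] < self.high[1]):
            raise ValueError("bands must be ordered and non-overlapping")

    def validate_nyquist(self, tr_seconds: float) -> None:
        nyq = 0.5 / tr_seconds
        if self.high[1] > nyq:
            raise ValueError(
                f"band edge {self.high[1]} Hz exceeds Nyquist {nyq} Hz")


DEFAULT_BANDS = BandDefinition()


@dataclass
class TimeseriesWindow:
    """The signals of one 3x3x3 sliding window.

    ``voxel_series`` holds the individual in-ROI voxel series (>=2 by the
    minimum cluster-size rule); ``mean_series`` is their average.
    """

    voxel_series: np.ndarray          # (k, T)
    sampling_interval: float          # TR, seconds
    mean_series: np.ndarray = field(default=None)  # (T,)

    def __post_init__(self):
        self.voxel_series = np.asarray(self.voxel_series, dtype=float)
        if self.voxel_series.ndim != 2 or self.voxel_series.shape[0] < 2:
            raise ValueError("a window requires >= 2 voxel series")
        if self.mean_series is None:
            self.mean_series = self.voxel_series.mean(axis=0)
        self.mean_series = np.asarray(self.mean_series, dtype=float)
        if self.mean_series.shape[0] != self.voxel_series.shape[1]:
            raise ValueError("mean_series/voxel_series length mismatch")

    @property
    def n_frames(self) -> int:
        return self.mean_series.shape[0]


# ---------------------------------------------------------------------------
# batch building blocks; every function takes X with shape (n, T)
# ---------------------------------------------------------------------------

def _as_batch(series) -> np.ndarray:
    X = np.atleast_2d(np.asarray(series, dtype=float))
    if X.shape[1] < 8:
        raise ValueError("series must have length >= 8")
    if not np.all(np.isfinite(X)):
        raise ValueError("series must be finite")
    return X


def _safe_div(num, den):
    out = np.zeros(np.broadcast(num, den).shape)
    np.divide(num, den, out=out, where=np.abs(den) > _EPS)
    return out


def _detrend(X: np.ndarray) -> np.ndarray:
    """Remove the least-squares line from each row."""
    return sps.detrend(X, axis=1, type="linear")


def _moment_stats(X: np.ndarray) -> "OrderedDict[str, np.ndarray]":
    absX = np.abs(X)
    peak = absX.max(axis=1)
    rms = np.sqrt((X * X).mean(axis=1))
    mean_abs = absX.mean(axis=1)
    mean_sqrt = np.sqrt(absX).mean(axis=1)
    q1, med, q3 = np.quantile(X, [0.25, 0.5, 0.75], axis=1)
    out = OrderedDict()
    out["mean"] = X.mean(axis=1)
    out["rms"] = rms
    out["sd"] = X.std(axis=1, ddof=1)
    with warnings.catch_warnings():
        # constant rows trip a precision warning; they get the 0 sentinel below
        warnings.simplefilter("ignore", RuntimeWarning)
        out["skewness"] = sct.skew(X, axis=1, bias=True)
        out["kurtosis"] = sct.kurtosis(X, axis=1, fisher=False, bias=True)
    out["peak_value"] = peak
    out["minimum"] = X.min(axis=1)
    out["median"] = med
    out["maximum"] = X.max(axis=1)
    out["q1"] = q1
    out["q3"] = q3
    out["iqr"] = q3 - q1
    out["crest_factor"] = _safe_div(peak, rms)
    out["impulse_factor"] = _safe_div(peak, mean_abs)
    out["clearance_factor"] = _safe_div(peak, mean_sqrt ** 2)
    out["shape_factor"] = _safe_div(rms, mean_abs)
    # constant series produce nan skew/kurtosis; use the 0 sentinel
    for key in ("skewness", "kurtosis"):
        out[key] = np.nan_to_num(out[key], nan=0.0, posinf=0.0, neginf=0.0)
    return out


def _periodogram(X: np.ndarray, tr: float, detrend: bool):
    """One-sided periodogram. Returns (freqs, amplitude, power) per bin.

    ``amplitude`` recovers the amplitude of an on-bin sinusoid; ``power``
    satisfies Parseval: sum over bins (incl. DC) = mean(x^2).
    """
    T = X.shape[1]
    Y = _detrend(X) if detrend else X - X.mean(axis=1, keepdims=True)
    F = np.fft.rfft(Y, axis=1)
    freqs = np.fft.rfftfreq(T, d=tr)
    scale = np.full(freqs.shape, 2.0)
    scale[0] = 1.0
    if T % 2 == 0:
        scale[-1] = 1.0
    amp = scale * np.abs(F) / T
    power = scale * (np.abs(F) ** 2) / T ** 2
    return freqs, amp, power


def _distortion_metrics(power: np.ndarray) -> "OrderedDict[str, np.ndarray]":
    """SNR / SINAD / THD (dB) from a one-sided periodogram (per row)."""
    n, nb = power.shape
    p = power.copy()
    p[:, 0] = 0.0  # DC excluded
    k0 = np.argmax(p, axis=1)
    k0 = np.maximum(k0, 1)
    rows = np.arange(n)
    p_fund = p[rows, k0]
    p_harm = np.zeros(n)
    max_h = int(np.ceil((nb - 1) / 1))
    for h in range(2, max_h + 1):
        kh = h * k0
        inside = kh <= nb - 1
        if not inside.any():
            break
        p_harm[inside] += p[rows[inside], kh[inside]]
    p_total = p.sum(axis=1)
    p_noise = np.maximum(p_total - p_fund - p_harm, 0.0)
    log = lambda x: 10.0 * np.log10(np.maximum(x, _EPS))
    out = OrderedDict()
    out["snr"] = log(p_fund) - log(p_noise)
    out["sinad"] = log(p_fund) - log(p_noise + p_harm)
    out["thd"] = log(p_harm) - log(p_fund)
    # degenerate all-zero spectra -> sentinel 0
    zero = p_total <= _EPS
    for key in out:
        out[key][zero] = 0.0
    return out


def _spectrum_block(X: np.ndarray, tr: float):
    """Peak amplitude / peak frequency / total power (mean-removed series)."""
    freqs, amp, power = _periodogram(X, tr, detrend=False)
    a = amp.copy()
    a[:, 0] = -1.0  # exclude DC from the peak search
    k = np.argmax(a, axis=1)
    k = np.maximum(k, 1)  # all-zero series: report the lowest bin
    rows = np.arange(X.shape[0])
    out = OrderedDict()
    out["peak_amplitude"] = np.maximum(amp[rows, k], 0.0)
    out["peak_frequency"] = freqs[k]
    out["power"] = power[:, 1:].sum(axis=1)
    return out, (freqs, amp, power)


def _band_block(X: np.ndarray, tr: float, bands: BandDefinition):
    bands.validate_nyquist(tr)
    freqs, amp, power = _periodogram(X, tr, detrend=False)
    lo = (freqs >= bands.low[0]) & (freqs <= bands.low[1])
    mi = (freqs > bands.mid[0]) & (freqs <= bands.mid[1])
    hi = (freqs > bands.high[0]) & (freqs <= bands.high[1])
    total = (freqs >= bands.low[0]) & (freqs <= bands.high[1])
    p_tot = power[:, total].sum(axis=1)
    out = OrderedDict()
    out["alff_low"] = amp[:, lo].sum(axis=1)
    out["alff_mid"] = amp[:, mi].sum(axis=1)
    out["alff_high"] = amp[:, hi].sum(axis=1)
    out["power_ratio_low"] = _safe_div(power[:, lo].sum(axis=1), p_tot)
    out["power_ratio_mid"] = _safe_div(power[:, mi].sum(axis=1), p_tot)
    out["power_ratio_high"] = _safe_div(power[:, hi].sum(axis=1), p_tot)
    return out


def _envelope(X: np.ndarray) -> np.ndarray:
    """Analytic-signal magnitude of the linearly de-trended series.

    The trend (and with it the DC offset) is removed first: the envelope
    describes the fluctuation around the baseline, and a raw BOLD baseline of
    ~100 would otherwise dominate the analytic signal.
    """
    return np.abs(sps.hilbert(_detrend(X), axis=1))


def _levinson(r: np.ndarray, max_order: int):
    """Vectorised Levinson-Durbin.

    r: (n, max_order+1) autocovariances.  Returns (coeffs, sigma2) where
    ``coeffs[p]`` is the (n, p) AR coefficient array of order p (model
    x_t = sum_k a_k x_{t-k} + e_t) and ``sigma2[p]`` the (n,) innovation
    variance, for p = 1..max_order.
    """
    n = r.shape[0]
    a = np.zeros((n, max_order + 1))
    E = np.maximum(r[:, 0].copy(), _EPS)
    coeffs, sigma2 = {}, {}
    for p in range(1, max_order + 1):
        acc = r[:, p].copy()
        for j in range(1, p):
            acc -= a[:, j] * r[:, p - j]
        k = _safe_div(acc, E)
        k = np.clip(k, -0.9999, 0.9999)
        prev = a[:, 1:p].copy()
        for j in range(1, p):
            a[:, j] = prev[:, j - 1] - k * prev[:, p - 1 - j]
        a[:, p] = k
        E = np.maximum(E * (1.0 - k * k), _EPS)
        coeffs[p] = a[:, 1:p + 1].copy()
        sigma2[p] = E.copy()
    return coeffs, sigma2


def _dominant_pole(coeffs: np.ndarray) -> np.ndarray:
    """Largest-modulus root of z^p - a1 z^{p-1} - ... - ap, batched."""
    n, p = coeffs.shape
    if p == 1:
        return coeffs[:, 0].astype(complex)
    comp = np.zeros((n, p, p))
    comp[:, 0, :] = coeffs
    idx = np.arange(p - 1)
    comp[:, idx + 1, idx] = 1.0
    roots = np.linalg.eigvals(comp)
    take = np.argmax(np.abs(roots), axis=1)
    return roots[np.arange(n), take]


def _ar_block(X: np.ndarray, tr: float, max_order: int = 8,
              with_damping: bool = False) -> "OrderedDict[str, np.ndarray]":
    n, T = X.shape
    if T <= max_order + 2:
        raise ValueError(f"series length {T} too short for AR order {max_order}")
    Y = X - X.mean(axis=1, keepdims=True)
    # biased autocovariances via FFT
    m = int(2 ** np.ceil(np.log2(2 * T)))
    F = np.fft.rfft(Y, n=m, axis=1)
    acov = np.fft.irfft(np.abs(F) ** 2, n=m, axis=1)[:, :max_order + 1] / T
    degenerate = acov[:, 0] <= _EPS
    acov[degenerate, 0] = 1.0  # placeholder; outputs zeroed below

    coeffs, sigma2 = _levinson(acov, max_order)
    aic = np.stack([T * np.log(np.maximum(sigma2[p], _EPS)) + 2.0 * (p + 1)
                    for p in range(1, max_order + 1)], axis=1)
    order = np.argmin(aic, axis=1) + 1

    out = OrderedDict((k, np.zeros(n)) for k in (
        "first_coefficient", "first_frequency", "mse", "mae", "aic",
        "residual_mean", "residual_variance", "residual_rms",
        "residual_kurtosis"))
    if with_damping:
        out["damping_coefficient"] = np.zeros(n)

    for p in range(1, max_order + 1):
        rows = np.flatnonzero((order == p) & ~degenerate)
        if rows.size == 0:
            continue
        a = coeffs[p][rows]  # (g, p)
        Yg = Y[rows]
        W = np.lib.stride_tricks.sliding_window_view(Yg, p + 1, axis=1)
        # e_t = y_t - sum_j a_j y_{t-j}; W[..., p] is y_t, W[..., p-j] is y_{t-j}
        c = np.concatenate([-a[:, ::-1], np.ones((rows.size, 1))], axis=1)
        e = np.einsum("gtp,gp->gt", W, c)
        out["first_coefficient"][rows] = a[:, 0]
        out["mse"][rows] = (e * e).mean(axis=1)
        out["mae"][rows] = np.abs(e).mean(axis=1)
        out["aic"][rows] = aic[rows, p - 1]
        out["residual_mean"][rows] = e.mean(axis=1)
        out["residual_variance"][rows] = e.var(axis=1)
        out["residual_rms"][rows] = np.sqrt((e * e).mean(axis=1))
        kurt = sct.kurtosis(e, axis=1, fisher=False, bias=True)
        out["residual_kurtosis"][rows] = np.nan_to_num(kurt, nan=0.0)
        pole = _dominant_pole(coeffs[p][rows])
        mod = np.maximum(np.abs(pole), _EPS)
        out["first_frequency"][rows] = np.abs(np.angle(pole)) / (2 * np.pi * tr)
        if with_damping:
            s = np.log(mod) / tr + 1j * np.angle(pole) / tr
            smod = np.abs(s)
            out["damping_coefficient"][rows] = _safe_div(-s.real, smod)
    return out


def _rank(X: np.ndarray) -> np.ndarray:
    """Average ranks along the last axis."""
    return sct.rankdata(X, axis=-1, method="average")


def _pair_signs(X: np.ndarray, dtype=np.float32) -> np.ndarray:
    """(n, C) matrix of sign(x_k - x_j) over all time pairs j < k."""
    n, T = X.shape
    X32 = np.ascontiguousarray(X, dtype=dtype)
    out = np.empty((n, T * (T - 1) // 2), dtype=dtype)
    pos = 0
    for j in range(T - 1):
        w = T - 1 - j
        np.sign(X32[:, j + 1:] - X32[:, j:j + 1], out=out[:, pos:pos + w])
        pos += w
    return out


def concordance_features(voxel_series: np.ndarray,
                         membership: sp.spmatrix | None = None):
    """Kendall W and mean pairwise Kendall tau-a for windows of voxel series.

    ``voxel_series`` is (n_vox, T); ``membership`` a sparse (n_windows, n_vox)
    0/1 matrix selecting each window's voxels (None = one window of all
    voxels).  No tie correction is applied to W (the series are continuous).
    """
    V = np.asarray(voxel_series, dtype=float)
    n_vox, T = V.shape
    if membership is None:
        membership = sp.csr_matrix(np.ones((1, n_vox)))
    k = np.asarray(membership.sum(axis=1)).ravel()
    if np.any(k < 2):
        raise ValueError("concordance requires >= 2 voxel series per window")

    R = _rank(V).astype(np.float32)
    S = membership @ R                              # (n_win, T) rank sums
    dev = S - (k * (T + 1) / 2.0)[:, None]
    w = 12.0 * (dev * dev).sum(axis=1) / (k * k * (T ** 3 - T))

    P = _pair_signs(V)
    C = T * (T - 1) / 2.0
    rowsq = (P != 0).sum(axis=1).astype(np.float64)   # C minus tied pairs
    Ssig = membership @ P
    gross = (Ssig * Ssig).sum(axis=1, dtype=np.float64)
    diag = membership @ rowsq
    tau = (gross - diag) / (k * (k - 1) * C)
    return np.clip(w, 0.0, 1.0), tau


# ---------------------------------------------------------------------------
# the batch engine
# ---------------------------------------------------------------------------

def compute_feature_matrix(mean_series: np.ndarray, tr: float,
                           voxel_series: np.ndarray | None = None,
                           membership: sp.spmatrix | None = None,
                           bands: BandDefinition = DEFAULT_BANDS,
                           max_order: int = 8) -> np.ndarray:
    """All 85 features for a stack of windows.

    mean_series: (n, T); voxel_series: (n_vox, T) with ``membership`` the
    sparse (n, n_vox) window-to-voxel map (needed for the concordance
    features).  Returns (n, 85) in registry order.
    """
    X = _as_batch(mean_series)
    n, T = X.shape
    cols: "OrderedDict[str, np.ndarray]" = OrderedDict()

    raw = _moment_stats(X)
    spec, (_, _, p_raw) = _spectrum_block(X, tr)
    raw.update(_distortion_metrics(p_raw))
    for key, val in raw.items():
        cols[f"raw.{key}"] = val
    for key, val in spec.items():
        cols[f"spectrum.{key}"] = val

    env = _envelope(X)
    est = _moment_stats(env)
    espec, (_, _, p_env) = _spectrum_block(env, tr)
    est.update(_distortion_metrics(p_env))
    for key in (
        "mean", "rms", "sd", "skewness", "kurtosis", "peak_value",
        "crest_factor", "impulse_factor", "clearance_factor", "shape_factor",
        "snr", "sinad", "thd",
    ):
        cols[f"envelope.{key}"] = est[key]
    cols["envelope.power"] = espec["power"]
    cols["envelope_spectrum.peak_amplitude"] = espec["peak_amplitude"]
    cols["envelope_spectrum.peak_frequency"] = espec["peak_frequency"]

    ar = _ar_block(X, tr, max_order=max_order)
    for key, val in ar.items():
        cols[f"ar.{key}"] = val

    D = _detrend(X)
    dt = _moment_stats(D)
    _, _, p_det = _periodogram(D, tr, detrend=False)
    dt.update(_distortion_metrics(p_det))
    for key, val in dt.items():
        cols[f"detrended.{key}"] = val
    cols["detrended.variance"] = D.var(axis=1, ddof=1)

    dtar = _ar_block(D, tr, max_order=max_order, with_damping=True)
    for key, val in dtar.items():
        cols[f"detrended_ar.{key}"] = val

    lit = _band_block(X, tr, bands)
    for key, val in lit.items():
        cols[f"literature.{key}"] = val
    if voxel_series is not None:
        w, tau = concordance_features(voxel_series, membership)
        cols["literature.kendall_w"] = np.broadcast_to(w, (n,)).copy()
        cols["literature.kendall_tau"] = np.broadcast_to(tau, (n,)).copy()
    else:
        cols["literature.kendall_w"] = np.full(n, np.nan)
        cols["literature.kendall_tau"] = np.full(n, np.nan)

    out = np.column_stack([cols[name] for name in FEATURE_NAMES])
    assert out.shape == (n, N_FEATURES)
    return out


# ---------------------------------------------------------------------------
# per-window operations (spec surface); all return OrderedDict name -> float
# ---------------------------------------------------------------------------

def _row(d: "OrderedDict[str, np.ndarray]") -> "OrderedDict[str, float]":
    return OrderedDict((k, float(v[0])) for k, v in d.items())


def raw_signal_features(series) -> "OrderedDict[str, float]":
    """The 19 raw-signal statistics of a single series."""
    X = _as_batch(series)
    out = _moment_stats(X)
    _, _, p = _periodogram(X, 1.0, detrend=False)
    out.update(_distortion_metrics(p))
    return _row(out)


def power_spectrum_features(series, sampling_interval: float) -> "OrderedDict[str, float]":
    """Total power, spectral peak amplitude and peak frequency."""
    X = _as_batch(series)
    out, _ = _spectrum_block(X, sampling_interval)
    return _row(out)


def envelope_features(series, sampling_interval: float = 1.0) -> "OrderedDict[str, float]":
    """Statistics of the analytic-signal envelope plus its spectral peak."""
    X = _as_batch(series)
    env = _envelope(X)
    est = _moment_stats(env)
    espec, (_, _, p_env) = _spectrum_block(env, sampling_interval)
    est.update(_distortion_metrics(p_env))
    out = OrderedDict()
    for key in ("mean", "rms", "sd", "skewness", "kurtosis", "peak_value",
                "crest_factor", "impulse_factor", "clearance_factor",
                "shape_factor", "snr", "sinad", "thd"):
        out[key] = est[key]
    out["power"] = espec["power"]
    out["spectrum_peak_amplitude"] = espec["peak_amplitude"]
    out["spectrum_peak_frequency"] = espec["peak_frequency"]
    return _row(out)


def ar_features(series, max_order: int = 8,
                sampling_interval: float = 1.0) -> "OrderedDict[str, float]":
    """AIC-selected autoregressive diagnostics of a single series."""
    X = _as_batch(series)
    return _row(_ar_block(X, sampling_interval, max_order=max_order,
                          with_damping=True))


def detrended_variants(series, sampling_interval: float = 1.0,
                       max_order: int = 8) -> "OrderedDict[str, float]":
    """Raw-statistic and AR blocks recomputed on the de-trended series."""
    X = _as_batch(series)
    D = _detrend(X)
    out = _moment_stats(D)
    _, _, p = _periodogram(D, sampling_interval, detrend=False)
    out.update(_distortion_metrics(p))
    out["variance"] = D.var(axis=1, ddof=1)
    ar = _ar_block(D, sampling_interval, max_order=max_order, with_damping=True)
    for key, val in ar.items():
        out[f"ar_{key}"] = val
    return _row(out)


def literature_features(window: TimeseriesWindow,
                        bands: BandDefinition = DEFAULT_BANDS) -> "OrderedDict[str, float]":
    """Band amplitudes/power ratios of the mean series + Kendall concordance."""
    X = _as_batch(window.mean_series)
    out = _band_block(X, window.sampling_interval, bands)
    w, tau = concordance_features(window.voxel_series)
    out["kendall_w"] = w
    out["kendall_tau"] = tau
    return _row(out)


def assemble_feature_vector(window: TimeseriesWindow,
                            bands: BandDefinition = DEFAULT_BANDS
                            ) -> "OrderedDict[str, float]":
    """The full 85-entry feature vector of one window, in registry order."""
    F = compute_feature_matrix(window.mean_series[None, :],
                               window.sampling_interval,
                               voxel_series=window.voxel_series,
                               membership=None, bands=bands)
    return OrderedDict(zip(FEATURE_NAMES, (float(v) for v in F[0])))
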