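"""Registry of the 85 per-window rs-fMRI features.

The catalog is partitioned into seven groups of automatically computed
signal-processing metrics (77 in total: raw-signal statistics, power-spectrum
summaries, analytic-envelope statistics, envelope-spectrum summaries,
autoregressive-model diagnostics, and the same statistic/AR blocks after linear
de-trending) plus eight features with an established rs-fMRI literature:
band-limited amplitudes of fluctuation (ALFF-style), band power ratios, and
Kendall concordance measures of local synchrony (ReHo-style).

Feature names are ``<group>.<metric>``; the registry fixes their order, which
is the canonical order of every feature vector and feature-map stack produced
by this package.
"""

from __future__ import annotations

import json
from collections import OrderedDict
from dataclasses import dataclass


@dataclass(frozen=True)
class FeatureInfo:
    name: str
    group: str
    formula: str


_STAT_FORMULAS = {
    "mean": "mean(x)",
    "rms": "sqrt(mean(x^2))",
    "sd": "sample standard deviation of x (ddof=1)",
    "skewness": "m3 / m2^(3/2) (biased moment estimator)",
    "kurtosis": "m4 / m2^2 (Pearson, non-excess, biased moment estimator)",
    "peak_value": "max(|x|)",
    "minimum": "min(x)",
    "median": "median(x)",
    "maximum": "max(x)",
    "q1": "25% quantile (linear interpolation)",
    "q3": "75% quantile (linear interpolation)",
    "iqr": "q3 - q1",
    "crest_factor": "max(|x|) / rms(x)",
    "impulse_factor": "max(|x|) / mean(|x|)",
    "clearance_factor": "max(|x|) / mean(sqrt(|x|))^2",
    "shape_factor": "rms(x) / mean(|x|)",
    "snr": "10*log10(P_fund / P_noise) [dB], fundamental = largest periodogram line",
    "sinad": "10*log10(P_fund / (P_noise + P_harm)) [dB]",
    "thd": "10*log10(P_harm / P_fund) [dB], harmonics = integer multiples of the fundamental bin",
    "variance": "sample variance of x (ddof=1)",
    "power": "total periodogram power excluding DC",
}

_RAW_STATS = [
    "mean", "rms", "sd", "skewness", "kurtosis", "peak_value", "minimum",
    "median", "maximum", "q1", "q3", "iqr", "crest_factor", "impulse_factor",
    "clearance_factor", "shape_factor", "snr", "sinad", "thd",
]

_ENVELOPE_STATS = [
    "mean", "rms", "sd", "skewness", "kurtosis", "peak_value", "crest_factor",
    "impulse_factor", "clearance_factor", "shape_factor", "snr", "sinad",
    "thd", "power",
]

_AR_METRICS = OrderedDict(
    [
        ("first_coefficient", "phi_1 of the AIC-selected AR(p) model"),
        ("first_frequency", "|arg(z*)| / (2*pi*TR) of the dominant AR pole z* [Hz]"),
        ("mse", "mean squared one-step AR residual"),
        ("mae", "mean absolute one-step AR residual"),
        ("aic", "T*ln(residual variance) + 2*(p+1), minimized over p = 1..8"),
        ("residual_mean", "mean of AR residuals"),
        ("residual_variance", "variance of AR residuals (ddof=0)"),
        ("residual_rms", "rms of AR residuals"),
        ("residual_kurtosis", "Pearson kurtosis of AR residuals"),
    ]
)

_DAMPING = ("damping_coefficient",
            "-Re(s)/|s| with s = ln(z*)/TR for the dominant AR pole z*")

_LITERATURE = OrderedDict(
    [
        ("alff_low", "sum of amplitude-spectrum bins with 0.01 <= f <= 0.04 Hz"),
        ("alff_mid", "sum of amplitude-spectrum bins with 0.04 < f <= 0.08 Hz"),
        ("alff_high", "sum of amplitude-spectrum bins with 0.08 < f <= 0.10 Hz"),
        ("power_ratio_low", "band power (low) / total power in 0.01-0.10 Hz"),
        ("power_ratio_mid", "band power (mid) / total power in 0.01-0.10 Hz"),
        ("power_ratio_high", "band power (high) / total power in 0.01-0.10 Hz"),
        ("kendall_w", "Kendall coefficient of concordance of the window's voxel time-series ranks"),
        ("kendall_tau", "mean pairwise Kendall tau-a across the window's voxel series"),
    ]
)


def _build() -> "OrderedDict[str, FeatureInfo]":
    reg: "OrderedDict[str, FeatureInfo]" = OrderedDict()

    def add(group: str, metric: str, formula: str) -> None:
        name = f"{group}.{metric}"
        if name in reg:  # pragma: no cover - registry construction guard
            raise ValueError(f"duplicate feature name {name}")
        reg[name] = FeatureInfo(name=name, group=group, formula=formula)

    for m in _RAW_STATS:
        add("raw", m, _STAT_FORMULAS[m])
    add("spectrum", "peak_amplitude",
        "max of the amplitude spectrum over 0 < f <= Nyquist")
    add("spectrum", "peak_frequency", "frequency of the amplitude-spectrum peak [Hz]")
    add("spectrum", "power", _STAT_FORMULAS["power"])
    for m in _ENVELOPE_STATS:
        add("envelope", m, _STAT_FORMULAS[m] + " applied to the analytic-signal envelope")
    add("envelope_spectrum", "peak_amplitude",
        "max of the envelope amplitude spectrum over 0 < f <= Nyquist")
    add("envelope_spectrum", "peak_frequency",
        "frequency of the envelope amplitude-spectrum peak [Hz]")
    for m, f in _AR_METRICS.items():
        add("ar", m, f)
    for m in _RAW_STATS:
        add("detrended", m, _STAT_FORMULAS[m] + " applied to the linearly de-trended series")
    add("detrended", "variance",
        _STAT_FORMULAS["variance"] + " applied to the linearly de-trended series")
    items = list(_AR_METRICS.items())
    # damping coefficient sits after first_frequency in the de-trended AR block
    for m, f in items[:2]:
        add("detrended_ar", m, f)
    add("detrended_ar", *_DAMPING)
    for m, f in items[2:]:
        add("detrended_ar", m, f)
    for m, f in _LITERATURE.items():
        add("literature", m, f)
    return reg


REGISTRY: "OrderedDict[str, FeatureInfo]" = _build()
FEATURE_NAMES: tuple[str, ...] = tuple(REGISTRY)
N_FEATURES: int = len(FEATURE_NAMES)

GROUP_SIZES = OrderedDict()
for _info in REGISTRY.values():
    GROUP_SIZES[_info.group] = GROUP_SIZES.get(_info.group, 0) + 1

#: number of automatically computed metrics (everything except the literature group)
N_AUTO = N_FEATURES - GROUP_SIZES["literature"]


def feature_index(name: str) -> int:
    """Position of ``name`` in the canonical feature order."""
    return FEATURE_NAMES.index(name)


def export_registry(path) -> None:
    """Write the registry as JSON (name, group, formula)."""
    payload = [vars(info) for info in REGISTRY.values()]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
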