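"""The 51-feature multi-domain description of one EEG epoch.

Per epoch the vector collects, in a fixed canonical order:

* 6 standard deviations, one per characteristic wave (computed literally as
  sqrt(sum of squared deviations), without a 1/n factor; a flag restores the
  conventional estimator),
* 17 auxiliary time-domain features of the denoised epoch (registry below),
* 6 wave energies plus the alpha/theta and delta/theta energy ratios,
* 6 wave powers (sum of the periodogram), the mean frequency of the epoch,
  and the alpha/theta and delta/theta power ratios,
* 6 order-2 Renyi entropies of the wave spectra,
* 5 nonlinear-dynamics features of the denoised full-band epoch:
  Lempel-Ziv complexity (median-binarized, LZ76 parse, normalized),
  multi-scale entropy (sample entropy at coarse-graining scale 11),
  spectral entropy, sample entropy, and fuzzy entropy.

Sample/fuzzy entropy use m = 2 and r = 0.2 x SD of the epoch; multi-scale
entropy keeps the r of the original (pre-coarse-graining) epoch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .preprocessing import (
    WAVE_ORDER,
    extract_characteristic_waves,
    wtd_denoise,
)

__all__ = [
    "FEATURE_NAMES",
    "AUX_TIME_FEATURES",
    "Spectrum",
    "std_features",
    "energy_features",
    "power_spectrum",
    "frequency_features",
    "renyi_entropy",
    "binarize_median",
    "lzc",
    "lz76_phrase_count",
    "coarse_grain",
    "sample_entropy",
    "multiscale_entropy",
    "fuzzy_entropy",
    "spectral_entropy",
    "auxiliary_time_features",
    "extract_feature_vector",
    "extract_feature_table",
]

#: Names (and order) of the 17 auxiliary time-domain features.
AUX_TIME_FEATURES = (
    "mean",
    "median",
    "variance",
    "mean_abs",
    "rms",
    "peak_to_peak",
    "skewness",
    "kurtosis",
    "zero_crossings",
    "hjorth_activity",
    "hjorth_mobility",
    "hjorth_complexity",
    "line_length",
    "iqr",
    "p75",
    "min",
    "max",
)

FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"std_{w}" for w in WAVE_ORDER)
    + AUX_TIME_FEATURES
    + tuple(f"energy_{w}" for w in WAVE_ORDER)
    + ("energy_ratio_alpha_theta", "energy_ratio_delta_theta")
    + tuple(f"power_{w}" for w in WAVE_ORDER)
    + ("mnf",)
    + ("power_ratio_alpha_theta", "power_ratio_delta_theta")
    + tuple(f"renyi_{w}" for w in WAVE_ORDER)
    + ("lzc", "msen", "spectral_entropy", "sample_entropy", "fuzzy_entropy")
)
assert len(FEATURE_NAMES) == 51


@dataclass
class Spectrum:
    """One-sided power spectral density."""

    frequencies: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(self.power < -1e-12):
            raise ValueError("power densities must be non-negative")


# ---------------------------------------------------------------------------
# Time and energy domains
# ---------------------------------------------------------------------------


def std_features(
    waves: dict[str, np.ndarray], normalized: bool = False
) -> dict[str, float]:
    """Per-wave standard deviation.

    Default is the unnormalized form sqrt(sum (w_i - mean)^2);
    ``normalized=True`` divides the sum by n first (conventional estimator).
    """
    out = {}
    for name in WAVE_ORDER:
        w = np.asarray(waves[name], dtype=float)
        if w.size == 0:
            raise ValueError(f"empty wave: {name}")
        ss = float(np.sum((w - w.mean()) ** 2))
        out[f"std_{name}"] = math.sqrt(ss / w.size) if normalized else math.sqrt(ss)
    return out


def energy_features(waves: dict[str, np.ndarray]) -> dict[str, float]:
    """Per-wave total energy sum(w_i^2) and the alpha/theta, delta/theta ratios."""
    out = {}
    for name in WAVE_ORDER:
        w = np.asarray(waves[name], dtype=float)
        out[f"energy_{name}"] = float(np.sum(w**2))
    if out["energy_theta"] <= 0:
        raise ValueError("theta energy is zero; energy ratios undefined")
    out["energy_ratio_alpha_theta"] = out["energy_alpha"] / out["energy_theta"]
    out["energy_ratio_delta_theta"] = out["energy_delta"] / out["energy_theta"]
    return out


# ---------------------------------------------------------------------------
# Frequency domain
# ---------------------------------------------------------------------------


def power_spectrum(samples: np.ndarray, sampling_rate: float) -> Spectrum:
    """One-sided rectangular-window periodogram (no detrending)."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    freqs, pxx = sp_signal.periodogram(
        x, fs=sampling_rate, window="boxcar", detrend=False
    )
    return Spectrum(frequencies=freqs, power=pxx)


def frequency_features(
    waves: dict[str, np.ndarray],
    epoch_samples: np.ndarray,
    sampling_rate: float,
) -> dict[str, float]:
    """Per-wave power (sum of PSD bins), the epoch mean frequency, and ratios."""
    out = {}
    for name in WAVE_ORDER:
        spec = power_spectrum(waves[name], sampling_rate)
        out[f"power_{name}"] = float(np.sum(spec.power))
    spec = power_spectrum(epoch_samples, sampling_rate)
    total = float(np.sum(spec.power))
    if total <= 0:
        raise ValueError("zero total power; mean frequency undefined")
    out["mnf"] = float(np.sum(spec.power * spec.frequencies) / total)
    if out["power_theta"] <= 0:
        raise ValueError("theta power is zero; power ratios undefined")
    out["power_ratio_alpha_theta"] = out["power_alpha"] / out["power_theta"]
    out["power_ratio_delta_theta"] = out["power_delta"] / out["power_theta"]
    return out


def renyi_entropy(spectrum: Spectrum) -> float:
    """Order-2 Renyi entropy -ln(sum p_k^2) of the normalized PSD."""
    total = float(np.sum(spectrum.power))
    if total <= 0:
        raise ValueError("all-zero spectrum")
    p = spectrum.power / total
    return float(-np.log(np.sum(p**2)))


def spectral_entropy(spectrum: Spectrum) -> float:
    """Shannon entropy -sum p_k ln p_k of the normalized PSD (nats)."""
    total = float(np.sum(spectrum.power))
    if total <= 0:
        raise ValueError("all-zero spectrum")
    p = spectrum.power / total
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


# ---------------------------------------------------------------------------
# Nonlinear dynamics
# ---------------------------------------------------------------------------


def binarize_median(samples: np.ndarray) -> np.ndarray:
    """0/1 sequence: 0 where a_i < median, 1 otherwise."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    return (x >= np.median(x)).astype(np.uint8)


@njit(cache=False)
def _lz76_scan(s):  # pragma: no cover - exercised via lz76_phrase_count
    n = s.shape[0]
    c, l, i, k, k_max = 1, 1, 0, 1, 1
    while l + k <= n:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            if k > k_max:
                k_max = k
            i += 1
            if i == l:
                c += 1
                l += k_max
                i, k, k_max = 0, 1, 1
            else:
                k = 1
    return c


def lz76_phrase_count(sequence: np.ndarray) -> int:
    """Number of phrases in the Lempel-Ziv 1976 exhaustive-history parse.

    Kaspar-Schuster scan: the current phrase extends while it can be copied
    from the history; each failure to copy closes a phrase.
    """
    s = np.ascontiguousarray(sequence, dtype=np.uint8)
    if s.size == 0:
        raise ValueError("empty sequence")
    return int(_lz76_scan(s))


def lzc(binary_sequence: np.ndarray, normalized: bool = True) -> float:
    """Lempel-Ziv complexity of a binary sequence.

    Default is the length-normalized form c(n) * log2(n) / n; with
    ``normalized=False`` the raw phrase count c(n) is returned.
    """
    s = np.asarray(binary_sequence)
    if s.size < 2:
        raise ValueError("need at least 2 symbols")
    if not np.all((s == 0) | (s == 1)):
        raise ValueError("sequence must be binary")
    c = lz76_phrase_count(s)
    if not normalized:
        return float(c)
    n = s.size
    return c * math.log2(n) / n


def coarse_grain(samples: np.ndarray, tau: int) -> np.ndarray:
    """Non-overlapping block means of length ``tau``; remainder dropped."""
    x = np.asarray(samples, dtype=float)
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if x.size < tau:
        raise ValueError("series shorter than tau")
    n_blocks = x.size // tau
    return x[: n_blocks * tau].reshape(n_blocks, tau).mean(axis=1)


@njit(cache=False)
def _sampen_counts(x, m, r):  # pragma: no cover - exercised via sample_entropy
    n = x.shape[0]
    nt = n - m
    a = 0
    b = 0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            d = 0.0
            for k in range(m):
                t = abs(x[i + k] - x[j + k])
                if t > d:
                    d = t
                if d >= r:
                    break
            if d < r:
                b += 1
                if abs(x[i + m] - x[j + m]) < r:
                    a += 1
    return a, b


def sample_entropy(samples: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy -ln(A/B), Chebyshev distance < r, self-matches excluded.

    ``r`` defaults to 0.2 x SD of the series.  Raises ``ValueError`` when no
    template pair matches (A or B zero) or when r degenerates to 0.
    """
    x = np.ascontiguousarray(samples, dtype=np.float64)
    if x.size <= m + 1:
        raise ValueError("series too short for the template length")
    if r is None:
        r = 0.2 * float(np.std(x))
    if r <= 0:
        raise ValueError("tolerance r must be positive (constant series?)")
    a, b = _sampen_counts(x, m, float(r))
    if b == 0 or a == 0:
        raise ValueError("sample entropy undefined: no matching templates")
    return float(-math.log(a / b))


def multiscale_entropy(
    samples: np.ndarray,
    m: int = 2,
    r: float | None = None,
    tau: int = 11,
    literal_sum: bool = False,
) -> float:
    """Sample entropy of the coarse-grained series at scale ``tau``.

    ``r`` defaults to 0.2 x SD of the *original* series.  ``literal_sum``
    multiplies by the number of coarse-grained points (the printed
    sum-over-blocks form, a constant multiple at fixed tau).
    """
    x = np.asarray(samples, dtype=float)
    if x.size < tau * (m + 2):
        raise ValueError("series too short for this scale factor")
    if r is None:
        r = 0.2 * float(np.std(x))
    grained = coarse_grain(x, tau)
    value = sample_entropy(grained, m=m, r=r)
    if literal_sum:
        value *= grained.size
    return value


@njit(cache=False)
def _fuzzen_phis(x, m, r, gradient):  # pragma: no cover - via fuzzy_entropy
    n = x.shape[0]
    nt = n - m
    # rolling means of the length-m and length-(m+1) templates
    mu_m = np.empty(nt)
    mu_m1 = np.empty(nt)
    for i in range(nt):
        s = 0.0
        for k in range(m):
            s += x[i + k]
        mu_m[i] = s / m
        mu_m1[i] = (s + x[i + m]) / (m + 1)
    phi_m = 0.0
    phi_m1 = 0.0
    pairs = 0
    squared = gradient == 2.0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            d = 0.0
            for k in range(m):
                t = abs((x[i + k] - mu_m[i]) - (x[j + k] - mu_m[j]))
                if t > d:
                    d = t
            u = d / r
            phi_m += math.exp(-(u * u)) if squared else math.exp(-(u**gradient))
            d = 0.0
            for k in range(m + 1):
                t = abs((x[i + k] - mu_m1[i]) - (x[j + k] - mu_m1[j]))
                if t > d:
                    d = t
            u = d / r
            phi_m1 += math.exp(-(u * u)) if squared else math.exp(-(u**gradient))
            pairs += 1
    return phi_m / pairs, phi_m1 / pairs


def fuzzy_entropy(
    samples: np.ndarray,
    m: int = 2,
    r: float | None = None,
    gradient: float = 2.0,
) -> float:
    """Fuzzy entropy with exponential membership exp(-(d/r)^gradient).

    Templates are mean-subtracted before the Chebyshev distance, which makes
    the measure invariant to a mean shift of the input.
    """
    x = np.ascontiguousarray(samples, dtype=np.float64)
    if x.size <= m + 1:
        raise ValueError("series too short for the template length")
    if r is None:
        r = 0.2 * float(np.std(x))
    if r <= 0:
        raise ValueError("tolerance r must be positive (constant series?)")
    phi_m, phi_m1 = _fuzzen_phis(x, m, float(r), float(gradient))
    return float(math.log(phi_m) - math.log(phi_m1))


# ---------------------------------------------------------------------------
# Auxiliary time-domain registry
# ---------------------------------------------------------------------------


def auxiliary_time_features(
    denoised_epoch: np.ndarray, sampling_rate: float
) -> dict[str, float]:
    """The 17 auxiliary time-domain features of the denoised epoch.

    Hjorth mobility/complexity use the time derivative (first difference
    scaled by the sampling rate), so mobility of a sinusoid at frequency f
    approaches the angular frequency 2*pi*f.
    """
    x = np.asarray(denoised_epoch, dtype=float)
    if x.size == 0:
        raise ValueError("empty epoch")
    dx = np.diff(x) * sampling_rate
    var = float(np.var(x))
    var_d = float(np.var(dx))
    mobility = math.sqrt(var_d / var) if var > 0 else 0.0
    if var_d > 0 and x.size > 2:
        ddx = np.diff(dx) * sampling_rate
        mobility_d = math.sqrt(float(np.var(ddx)) / var_d)
        complexity = mobility_d / mobility if mobility > 0 else 0.0
    else:
        complexity = 0.0
    q25, med, q75 = np.percentile(x, [25, 50, 75])
    return {
        "mean": float(np.mean(x)),
        "median": float(med),
        "variance": var,
        "mean_abs": float(np.mean(np.abs(x))),
        "rms": float(np.sqrt(np.mean(x**2))),
        "peak_to_peak": float(np.ptp(x)),
        "skewness": float(sp_stats.skew(x)) if var > 0 else 0.0,
        "kurtosis": float(sp_stats.kurtosis(x)) if var > 0 else 0.0,
        "zero_crossings": float(np.count_nonzero(np.diff(np.signbit(x)))),
        "hjorth_activity": var,
        "hjorth_mobility": mobility,
        "hjorth_complexity": complexity,
        "line_length": float(np.sum(np.abs(np.diff(x)))),
        "iqr": float(q75 - q25),
        "p75": float(q75),
        "min": float(np.min(x)),
        "max": float(np.max(x)),
    }


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def extract_feature_vector(
    denoised_epoch: np.ndarray,
    sampling_rate: float,
    waves: dict[str, np.ndarray] | None = None,
    mse_tau: int = 11,
) -> dict[str, float]:
    """All 51 features of one (already denoised) epoch, in canonical order.

    ``waves`` may be passed when the characteristic waves were already
    reconstructed for this epoch; otherwise they are computed here.
    """
    x = np.asarray(denoised_epoch, dtype=float)
    if waves is None:
        waves = extract_characteristic_waves(x, sampling_rate)
    values: dict[str, float] = {}
    values.update(std_features(waves))
    values.update(auxiliary_time_features(x, sampling_rate))
    values.update(energy_features(waves))
    values.update(frequency_features(waves, x, sampling_rate))
    for name in WAVE_ORDER:
        values[f"renyi_{name}"] = renyi_entropy(power_spectrum(waves[name], sampling_rate))
    values["lzc"] = lzc(binarize_median(x))
    values["msen"] = multiscale_entropy(x, tau=mse_tau)
    values["spectral_entropy"] = spectral_entropy(power_spectrum(x, sampling_rate))
    values["sample_entropy"] = sample_entropy(x)
    values["fuzzy_entropy"] = fuzzy_entropy(x)
    ordered = {name: values[name] for name in FEATURE_NAMES}
    bad = [k for k, v in ordered.items() if not math.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite features: {bad}")
    return ordered


def extract_feature_table(dataset, denoise: bool = True, mse_tau: int = 11) -> pd.DataFrame:
    """Feature table of a :class:`~sleepcascade.signal_io.LabeledDataset`.

    Rows are epochs in order; columns are the 51 canonical features plus a
    ``stage`` column.  Each epoch is wavelet-denoised first unless
    ``denoise=False`` (pre-denoised input).
    """
    rows = []
    stages = []
    for ep in dataset.epochs:
        x = wtd_denoise(ep.samples) if denoise else np.asarray(ep.samples, float)
        try:
            rows.append(extract_feature_vector(x, dataset.sampling_rate, mse_tau=mse_tau))
        except ValueError as exc:
            raise ValueError(f"feature extraction failed for epoch {ep.index}: {exc}")
        stages.append(ep.stage.value)
    table = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    table["stage"] = stages
    return table
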