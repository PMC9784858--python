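"""Wavelet-threshold denoising and wavelet-packet band reconstruction.

Denoising: 7-level db8 discrete wavelet decomposition with soft-threshold
shrinkage of the detail coefficients (universal threshold, per-level noise
estimate), approximation untouched.

Band extraction: a full 7-level wavelet packet decomposition splits
[0, Nyquist) into 2^7 = 128 uniform tiles (0.390625 Hz wide at 100 Hz).
Terminal nodes are taken in frequency (sequency) order — the natural tree
order does not map monotonically to frequency — and a characteristic wave is
reconstructed by inverse-transforming only the nodes whose tile intersects
the wave's band.  Six waves are extracted per epoch: alpha, beta, theta,
delta, sleep spindle, and sawtooth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

__all__ = [
    "Band",
    "CANONICAL_BANDS",
    "WAVE_ORDER",
    "WaveletPacketTree",
    "wtd_denoise",
    "node_frequency_band",
    "wpt_decompose",
    "reconstruct_band",
    "extract_characteristic_waves",
]

DEFAULT_WTD_WAVELET = "db8"
DEFAULT_WTD_LEVELS = 7
# db8 packet filters leak too much across tile edges at level 7 (a pure
# 10 Hz tone keeps only ~89% of its energy in the alpha band); db20 keeps
# >97% while staying in the same family, so it is the packet default.
DEFAULT_WPT_WAVELET = "db20"
DEFAULT_WPT_LEVELS = 7
DEFAULT_MODE = "symmetric"


@dataclass(frozen=True)
class Band:
    """A frequency band in Hz, half-open [low, high)."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 <= self.low < self.high:
            raise ValueError(f"invalid band limits for {self.name}")


#: The six characteristic waves, in canonical order.
WAVE_ORDER = ("alpha", "beta", "theta", "delta", "spindle", "sawtooth")

CANONICAL_BANDS: dict[str, Band] = {
    "alpha": Band("alpha", 8.0, 13.0),
    "beta": Band("beta", 12.0, 30.0),
    "theta": Band("theta", 4.0, 8.0),
    "delta": Band("delta", 0.5, 2.0),
    "spindle": Band("spindle", 12.0, 14.0),
    "sawtooth": Band("sawtooth", 2.0, 6.0),
}


# ---------------------------------------------------------------------------
# Wavelet threshold denoising
# ---------------------------------------------------------------------------


def _sure_threshold(detail: np.ndarray, sigma: float) -> float:
    """SURE-optimal soft threshold (SureShrink), capped by the universal one.

    Minimizes Stein's unbiased risk estimate over candidate thresholds equal
    to the (noise-normalized) coefficient magnitudes.
    """
    s = np.sort(np.abs(detail) / sigma)
    n = s.size
    k = np.arange(n)
    risk = n - 2.0 * (k + 1) + np.cumsum(s**2) + (n - k - 1) * s**2
    t_sure = s[int(np.argmin(risk))]
    t_univ = np.sqrt(2.0 * np.log(max(n, 2)))
    return sigma * min(t_sure, t_univ)


def wtd_denoise(
    samples: np.ndarray,
    wavelet: str = DEFAULT_WTD_WAVELET,
    levels: int = DEFAULT_WTD_LEVELS,
    mode: str = DEFAULT_MODE,
    threshold_rule: str = "sure",
) -> np.ndarray:
    """Soft-threshold wavelet denoising, returned at the input length.

    The noise scale sigma is the robust MAD estimate median(|d1|)/0.6745
    from the finest detail level, where oscillatory EEG content is weakest.
    Rules for the per-level threshold:

    * ``'sure'`` (default) - SureShrink: the SURE-optimal soft threshold per
      detail level, capped by the universal threshold.  Levels carrying
      strong rhythms get a small threshold, so the waves survive shrinkage.
    * ``'universal'`` - sigma * sqrt(2 ln N) on every detail level.
    * ``'none'`` - no shrinkage (round-trip checks).

    Approximation coefficients are never touched.
    """
    x = np.asarray(samples, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")
    if x.size < 2**levels:
        raise ValueError(f"need at least {2**levels} samples for {levels} levels")
    coeffs = pywt.wavedec(x, wavelet, mode=mode, level=levels)
    if threshold_rule in ("sure", "universal"):
        n = x.size
        sigma = float(np.median(np.abs(coeffs[-1])) / 0.6745)
        out = [coeffs[0]]
        if sigma <= 0:
            out = coeffs
        else:
            for d in coeffs[1:]:
                if threshold_rule == "sure":
                    thr = _sure_threshold(d, sigma)
                else:
                    thr = sigma * np.sqrt(2.0 * np.log(n))
                out.append(pywt.threshold(d, thr, mode="soft"))
        coeffs = out
    elif threshold_rule != "none":
        raise ValueError(f"unknown threshold rule: {threshold_rule!r}")
    rec = pywt.waverec(coeffs, wavelet, mode=mode)
    return rec[: x.size]


# ---------------------------------------------------------------------------
# Wavelet packet transform
# ---------------------------------------------------------------------------


@dataclass
class WaveletPacketTree:
    """A full wavelet-packet decomposition of one epoch.

    ``nodes`` holds the terminal-level coefficient arrays in frequency
    (sequency) order; ``paths`` the matching pywt node paths, so selected
    nodes can be re-inserted for inverse transformation.
    """

    nodes: list[np.ndarray]
    paths: list[str]
    n_samples: int
    sampling_rate: float
    levels: int
    wavelet: str
    mode: str

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def node_frequency_band(
    level: int, node_index: int, sampling_rate: float
) -> tuple[float, float]:
    """Frequency interval [low, high) of a frequency-ordered packet node.

    ``node_index`` is 1-based within ``level``; each of the 2^level nodes
    covers Nyquist / 2^level Hz.
    """
    n_nodes = 2**level
    if not 1 <= node_index <= n_nodes:
        raise ValueError(f"node_index must be in [1, {n_nodes}]")
    width = (sampling_rate / 2.0) / n_nodes
    return ((node_index - 1) * width, node_index * width)


def wpt_decompose(
    samples: np.ndarray,
    sampling_rate: float,
    levels: int = DEFAULT_WPT_LEVELS,
    wavelet: str = DEFAULT_WPT_WAVELET,
    mode: str = DEFAULT_MODE,
) -> WaveletPacketTree:
    """Decompose an epoch into its frequency-ordered terminal packet nodes."""
    x = np.asarray(samples, dtype=float)
    wp = pywt.WaveletPacket(x, wavelet, mode=mode, maxlevel=levels)
    ordered = wp.get_level(levels, order="freq")
    return WaveletPacketTree(
        nodes=[np.asarray(nd.data, dtype=float) for nd in ordered],
        paths=[nd.path for nd in ordered],
        n_samples=x.size,
        sampling_rate=sampling_rate,
        levels=levels,
        wavelet=wavelet,
        mode=mode,
    )


def _band_node_indices(tree: WaveletPacketTree, band: Band) -> list[int]:
    width = (tree.sampling_rate / 2.0) / tree.n_nodes
    sel = [
        k
        for k in range(tree.n_nodes)
        if k * width < band.high and (k + 1) * width > band.low
    ]
    return sel


def reconstruct_band(tree: WaveletPacketTree, band: Band) -> np.ndarray:
    """Inverse-transform only the packet nodes overlapping ``band``.

    A node is kept when its half-open tile [k·w, (k+1)·w) overlaps (low, high)
    with positive measure; a band edge falling exactly on a tile edge assigns
    the tile to the band containing it half-open from below.
    """
    if band.high > tree.sampling_rate / 2.0 + 1e-9:
        raise ValueError("band exceeds the Nyquist frequency")
    sel = _band_node_indices(tree, band)
    wp = pywt.WaveletPacket(
        None, tree.wavelet, mode=tree.mode, maxlevel=tree.levels
    )
    for k in sel:
        wp[tree.paths[k]] = tree.nodes[k]
    rec = wp.reconstruct(update=False)
    return np.asarray(rec[: tree.n_samples], dtype=float)


def extract_characteristic_waves(
    epoch_samples: np.ndarray,
    sampling_rate: float,
    bands: dict[str, Band] | None = None,
    levels: int = DEFAULT_WPT_LEVELS,
    wavelet: str = DEFAULT_WPT_WAVELET,
    mode: str = DEFAULT_MODE,
) -> dict[str, np.ndarray]:
    """Decompose once and reconstruct each characteristic wave.

    Returns a mapping wave name -> band-limited series of epoch length, in
    :data:`WAVE_ORDER`.
    """
    bands = CANONICAL_BANDS if bands is None else bands
    tree = wpt_decompose(
        epoch_samples, sampling_rate, levels=levels, wavelet=wavelet, mode=mode
    )
    return {name: reconstruct_band(tree, bands[name]) for name in WAVE_ORDER}
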