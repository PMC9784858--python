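"""Stage-conditioned synthetic EEG for testing the pipeline end to end.

Each stage is emulated as a sum of band-limited oscillations over a 1/f
background, following the classical stage-to-rhythm mapping:

* W  - prominent alpha (10 Hz) with some beta (20 Hz),
* N1 - low-amplitude theta (6 Hz) with residual sleep-onset alpha,
* N2 - sleep-spindle bursts (13 Hz, 0.5-1 s, amplitude-modulated) and
  sparse K-complex-like 1 Hz transients over light theta,
* N3 - high-amplitude delta (1 Hz),
* R  - mixed theta, 4 Hz sawtooth-shaped waves and weak alpha/beta.

Amplitudes are in microvolts, in the range scalp EEG shows for these
rhythms.  This emulates the spectral structure the feature system targets,
not physiologically realistic EEG; a single ``separation`` knob scales
oscillation amplitude against the noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sp_signal

from .signal_io import (
    EPOCH_SECONDS,
    LabeledDataset,
    LabeledEpoch,
    SleepStage,
    write_edf,
)

__all__ = [
    "Component",
    "StageSynthesisParams",
    "DEFAULT_STAGE_PROPORTIONS",
    "default_counts",
    "synth_epoch",
    "synth_dataset",
]

#: Stage mix of a full night (fractions of all scored epochs).
DEFAULT_STAGE_PROPORTIONS = {
    SleepStage.W: 0.2697,
    SleepStage.N1: 0.0710,
    SleepStage.N2: 0.3947,
    SleepStage.N3: 0.1103,
    SleepStage.R: 0.1543,
}


@dataclass(frozen=True)
class Component:
    """One oscillatory ingredient of a stage.

    ``kind`` is 'sine', 'sawtooth' (asymmetric triangular shape), 'burst'
    (amplitude-modulated events, e.g. spindles) or 'transient' (sparse
    high-amplitude monocycles, e.g. K-complex-like waves).  ``amplitude`` is
    the peak amplitude in microvolts.

    When ``amplitude_end`` is set the stage is a transition continuum: a
    per-epoch depth u ~ U(0,1), shared by all the stage's components,
    interpolates each amplitude from ``amplitude`` (u=0) to
    ``amplitude_end`` (u=1).  This models sleep onset (N1), whose shallow
    epochs resemble wake and whose deep epochs resemble light/REM sleep.
    """

    band: str
    frequency: float
    amplitude: float
    kind: str = "sine"
    amplitude_end: float | None = None


@dataclass(frozen=True)
class StageSynthesisParams:
    """Generator settings: per-stage components plus the noise background."""

    components: dict[SleepStage, tuple[Component, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_COMPONENTS)
    )
    noise_exponent: float = 1.0  # 1/f^exponent background
    noise_sigma: float = 10.0  # microvolts RMS
    burst_rate: float = 0.25  # spindle bursts per second (N2)
    freq_jitter: float = 0.05  # relative frequency jitter per epoch
    amp_jitter: float = 0.5  # sigma of per-epoch lognormal amplitude scaling
    separation: float = 1.0  # oscillation-vs-noise difficulty knob
    sampling_rate: float = 100.0


_DEFAULT_COMPONENTS: dict[SleepStage, tuple[Component, ...]] = {
    SleepStage.W: (
        Component("alpha", 10.0, 45.0),
        Component("beta", 20.0, 18.0),
    ),
    SleepStage.N1: (
        # wake-like onset (attenuating alpha/beta) -> drowsy theta/slow mix
        Component("alpha", 9.75, 40.0, amplitude_end=8.0),
        Component("beta", 20.0, 15.0, amplitude_end=5.0),
        Component("theta", 6.5, 8.0, amplitude_end=22.0),
        Component("sawtooth", 3.0, 0.0, kind="sawtooth", amplitude_end=12.0),
    ),
    SleepStage.N2: (
        Component("spindle", 13.0, 35.0, kind="burst"),
        Component("kcomplex", 1.0, 60.0, kind="transient"),
        Component("theta", 6.5, 15.0),
    ),
    SleepStage.N3: (
        Component("delta", 1.0, 100.0),
        Component("theta", 6.5, 10.0),
    ),
    SleepStage.R: (
        Component("theta", 6.5, 22.0),
        Component("sawtooth", 3.0, 25.0, kind="sawtooth"),
        Component("alpha", 10.0, 8.0),
        Component("beta", 20.0, 6.0),
    ),
}


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian 1/f^exponent noise with unit standard deviation."""
    freqs = np.fft.rfftfreq(n, d=1.0)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    phases = rng.uniform(0, 2 * np.pi, freqs.size)
    spectrum = amp * np.exp(1j * phases)
    x = np.fft.irfft(spectrum, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _render(comp: Component, t: np.ndarray, params: StageSynthesisParams,
            rng: np.random.Generator, depth: float | None = None) -> np.ndarray:
    freq = comp.frequency * (1 + params.freq_jitter * rng.uniform(-1, 1))
    phase = rng.uniform(0, 2 * np.pi)
    base = comp.amplitude
    if comp.amplitude_end is not None and depth is not None:
        base = (1 - depth) * comp.amplitude + depth * comp.amplitude_end
    amp = base * params.separation
    if params.amp_jitter > 0:
        amp *= rng.lognormal(0.0, params.amp_jitter)
    if amp == 0:
        return np.zeros_like(t)
    if comp.kind == "sine":
        return amp * np.sin(2 * np.pi * freq * t + phase)
    if comp.kind == "sawtooth":
        return amp * sp_signal.sawtooth(2 * np.pi * freq * t + phase, width=0.9)
    if comp.kind == "burst":
        carrier = np.sin(2 * np.pi * freq * t + phase)
        envelope = np.zeros_like(t)
        n_events = rng.poisson(params.burst_rate * t[-1])
        for _ in range(max(n_events, 1)):
            center = rng.uniform(0, t[-1])
            width = rng.uniform(0.25, 0.5)  # SD of the Gaussian envelope, s
            envelope += np.exp(-0.5 * ((t - center) / width) ** 2)
        return amp * np.clip(envelope, 0, 1) * carrier
    if comp.kind == "transient":
        out = np.zeros_like(t)
        for _ in range(rng.integers(1, 4)):
            center = rng.uniform(1, t[-1] - 1)
            width = 0.5 / freq  # half a cycle each way
            mask = np.abs(t - center) < 2 * width
            out[mask] += amp * np.sin(np.pi * (t[mask] - center) / width) * np.exp(
                -0.5 * ((t[mask] - center) / width) ** 2
            )
        return out
    raise ValueError(f"unknown component kind: {comp.kind!r}")


def synth_epoch(
    stage: SleepStage,
    params: StageSynthesisParams | None = None,
    seed: int | np.random.Generator = 0,
    index: int = 0,
) -> LabeledEpoch:
    """One 30-s synthetic epoch of the given stage; deterministic per seed."""
    params = params or StageSynthesisParams()
    stage = SleepStage(stage)
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    fs = params.sampling_rate
    n = int(round(EPOCH_SECONDS * fs))
    t = np.arange(n) / fs
    x = params.noise_sigma * _pink_noise(n, params.noise_exponent, rng)
    comps = params.components[stage]
    depth = rng.uniform() if any(c.amplitude_end is not None for c in comps) else None
    for comp in comps:
        x = x + _render(comp, t, params, rng, depth=depth)
    return LabeledEpoch(samples=x, stage=stage, index=index)


def default_counts(n_total: int) -> dict[SleepStage, int]:
    """Per-stage counts following the default full-night stage mix."""
    counts = {
        s: int(round(p * n_total)) for s, p in DEFAULT_STAGE_PROPORTIONS.items()
    }
    # rounding drift goes to the most common stage
    drift = n_total - sum(counts.values())
    counts[SleepStage.N2] += drift
    return counts


def synth_dataset(
    counts: dict[SleepStage, int] | None = None,
    params: StageSynthesisParams | None = None,
    seed: int = 0,
    n_total: int | None = None,
    out_edf: str | Path | None = None,
    out_labels: str | Path | None = None,
    channel_name: str = "EEG Fpz-Cz",
) -> LabeledDataset:
    """Generate a shuffled labeled dataset; optionally write EDF + labels CSV.

    Either pass explicit per-stage ``counts`` or ``n_total`` to use the
    default stage mix.  The EDF write-out concatenates the (shuffled) epochs
    into one continuous channel so the file round-trips through the reader
    and segmenter.
    """
    params = params or StageSynthesisParams()
    if counts is None:
        counts = default_counts(n_total if n_total is not None else 1000)
    counts = {SleepStage(s): int(c) for s, c in counts.items()}
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be non-negative")
    if sum(counts.values()) == 0:
        raise ValueError("all-zero counts")
    rng = np.random.default_rng(seed)
    stages: list[SleepStage] = []
    for s in SleepStage.order():
        stages.extend([s] * counts.get(s, 0))
    order = rng.permutation(len(stages))
    epochs = [
        synth_epoch(stages[k], params=params, seed=rng, index=i)
        for i, k in enumerate(order)
    ]
    dataset = LabeledDataset(epochs=epochs, sampling_rate=params.sampling_rate)
    if out_edf is not None:
        continuous = np.concatenate([ep.samples for ep in dataset.epochs])
        write_edf(out_edf, [continuous], params.sampling_rate, [channel_name])
    if out_labels is not None:
        dataset.write_labels_csv(out_labels)
    return dataset
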