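"""EDF input/output, hypnogram label mapping, and epoch segmentation.

Recordings are single-channel EEG sampled at (typically) 100 Hz.  Sleep is
scored in 30-second epochs; each epoch carries one of the five AASM stages
W, N1, N2, N3, R.  Legacy R&K hypnograms (Sleep-EDF style) use stages 1-4
plus movement/unknown tokens; stages 3 and 4 are merged into N3 and
movement/unknown epochs are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SleepStage",
    "Recording",
    "LabeledEpoch",
    "LabeledDataset",
    "EPOCH_SECONDS",
    "read_edf_signal",
    "write_edf",
    "map_legacy_stage",
    "segment_epochs",
]

#: AASM scoring window length in seconds.
EPOCH_SECONDS = 30.0


class SleepStage(str, Enum):
    """The five AASM sleep stages."""

    W = "W"
    N1 = "N1"
    N2 = "N2"
    N3 = "N3"
    R = "R"

    @classmethod
    def order(cls) -> list["SleepStage"]:
        """Canonical stage order used for confusion matrices and tie-breaks."""
        return [cls.W, cls.N1, cls.N2, cls.N3, cls.R]


@dataclass
class Recording:
    """A continuous single-channel signal with its sampling rate.

    Amplitudes are in microvolts (the EDF physical unit for EEG).
    """

    samples: np.ndarray
    sampling_rate: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.size == 0:
            raise ValueError("recording has no samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass
class LabeledEpoch:
    """One 30-s scoring window with its stage label."""

    samples: np.ndarray
    stage: SleepStage
    index: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)


@dataclass
class LabeledDataset:
    """Ordered labeled epochs plus the sampling rate they share."""

    epochs: list[LabeledEpoch]
    sampling_rate: float

    def __len__(self) -> int:
        return len(self.epochs)

    def stage_counts(self) -> dict[SleepStage, int]:
        counts = {s: 0 for s in SleepStage.order()}
        for ep in self.epochs:
            counts[ep.stage] += 1
        return counts

    def stages(self) -> list[SleepStage]:
        return [ep.stage for ep in self.epochs]

    def to_labels_frame(self) -> pd.DataFrame:
        """Interchange table: ``epoch_index,start_s,stage``."""
        return pd.DataFrame(
            {
                "epoch_index": [ep.index for ep in self.epochs],
                "start_s": [ep.index * EPOCH_SECONDS for ep in self.epochs],
                "stage": [ep.stage.value for ep in self.epochs],
            }
        )

    def write_labels_csv(self, path: str | Path) -> None:
        self.to_labels_frame().to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> pd.DataFrame:
    """Read a labeled-epoch CSV and validate its stage column."""
    frame = pd.read_csv(path)
    if "epoch_index" not in frame.columns or "stage" not in frame.columns:
        raise ValueError("labels CSV needs 'epoch_index' and 'stage' columns")
    bad = set(frame["stage"]) - {s.value for s in SleepStage}
    if bad:
        raise ValueError(f"unknown stage labels in CSV: {sorted(bad)}")
    return frame


# ---------------------------------------------------------------------------
# EDF reading (mne) and a minimal EDF writer for fixtures/interchange
# ---------------------------------------------------------------------------


def read_edf_signal(path: str | Path, channel_name: str) -> Recording:
    """Read one channel of an EDF/EDF+ file as a :class:`Recording`.

    Amplitudes are returned in microvolts; the sampling rate comes from the
    file header.  Raises ``FileNotFoundError`` for a missing file and
    ``ValueError`` (naming the available channels) when the channel is absent.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(str(path), preload=False, verbose="error")
    if channel_name not in raw.ch_names:
        raise ValueError(
            f"channel {channel_name!r} not in file; available: {raw.ch_names}"
        )
    raw = raw.pick([channel_name]).load_data(verbose="error")
    data = raw.get_data(picks=[channel_name])[0] * 1e6  # mne returns volts
    return Recording(
        samples=data, sampling_rate=float(raw.info["sfreq"]), channel_name=channel_name
    )


def _pad_ascii(text: str, width: int) -> bytes:
    raw = text.encode("ascii")[:width]
    return raw.ljust(width)


def write_edf(
    path: str | Path,
    signals: Sequence[np.ndarray],
    sampling_rate: float,
    channel_names: Sequence[str],
    physical_range: tuple[float, float] = (-3276.8, 3276.7),
) -> None:
    """Write channels to a minimal EDF file (16-bit, 1-second data records).

    All channels share one sampling rate and the microvolt physical range.
    Samples are quantized to the 16-bit digital grid; with the default range
    the quantization step is 0.1 µV.  The total length must be a whole number
    of seconds.
    """
    signals = [np.asarray(s, dtype=float) for s in signals]
    if len(signals) != len(channel_names):
        raise ValueError("one channel name per signal required")
    n = signals[0].size
    if any(s.size != n for s in signals):
        raise ValueError("all channels must have equal length")
    rec_samples = int(round(sampling_rate))
    if abs(rec_samples - sampling_rate) > 1e-9:
        raise ValueError("writer supports integer sampling rates only")
    if n % rec_samples != 0:
        raise ValueError("signal length must be a whole number of seconds")
    n_records = n // rec_samples
    n_sig = len(signals)
    pmin, pmax = physical_range
    dmin, dmax = -32768, 32767

    header = b"".join(
        [
            _pad_ascii("0", 8),  # version
            _pad_ascii("X X X X", 80),  # patient id
            _pad_ascii("Startdate X X X X", 80),  # recording id
            _pad_ascii("01.01.00", 8),
            _pad_ascii("23.00.00", 8),
            _pad_ascii(str(256 * (n_sig + 1)), 8),
            _pad_ascii("", 44),
            _pad_ascii(str(n_records), 8),
            _pad_ascii("1", 8),  # record duration, seconds
            _pad_ascii(str(n_sig), 4),
        ]
    )
    per_signal = [
        (channel_names, 16),  # label
        (["" for _ in signals], 80),  # transducer
        (["uV" for _ in signals], 8),
        ([f"{pmin:g}" for _ in signals], 8),
        ([f"{pmax:g}" for _ in signals], 8),
        ([str(dmin) for _ in signals], 8),
        ([str(dmax) for _ in signals], 8),
        (["" for _ in signals], 80),  # prefiltering
        ([str(rec_samples) for _ in signals], 8),
        (["" for _ in signals], 32),  # reserved
    ]
    for values, width in per_signal:
        header += b"".join(_pad_ascii(str(v), width) for v in values)

    scale = (dmax - dmin) / (pmax - pmin)
    digital = [
        np.clip(np.round((s - pmin) * scale + dmin), dmin, dmax).astype("<i2")
        for s in signals
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            lo = rec * rec_samples
            for d in digital:
                fh.write(d[lo : lo + rec_samples].tobytes())


def quantize_edf(samples: np.ndarray, physical_range=(-3276.8, 3276.7)) -> np.ndarray:
    """Snap samples to the 16-bit grid :func:`write_edf` stores them on."""
    pmin, pmax = physical_range
    scale = 65535 / (pmax - pmin)
    dig = np.clip(np.round((np.asarray(samples, float) - pmin) * scale - 32768),
                  -32768, 32767)
    return (dig + 32768) / scale + pmin


# ---------------------------------------------------------------------------
# Hypnogram label mapping and segmentation
# ---------------------------------------------------------------------------

_DROPPED_TOKENS = {"movement time", "sleep stage ?", "?", "movement", "unknown"}

_STAGE_TOKENS = {
    "w": SleepStage.W,
    "1": SleepStage.N1,
    "2": SleepStage.N2,
    "3": SleepStage.N3,
    "4": SleepStage.N3,  # R&K S3/S4 merge to AASM N3
    "r": SleepStage.R,
    "n1": SleepStage.N1,
    "n2": SleepStage.N2,
    "n3": SleepStage.N3,
    "rem": SleepStage.R,
    "wake": SleepStage.W,
}


def map_legacy_stage(raw_label: str) -> Optional[SleepStage]:
    """Map a Sleep-EDF hypnogram token to an AASM stage.

    Returns ``None`` for movement/unknown epochs (these are dropped) and
    raises ``ValueError`` for tokens that are not hypnogram labels at all.
    """
    token = raw_label.strip().lower()
    if token in _DROPPED_TOKENS:
        return None
    if token.startswith("sleep stage "):
        token = token[len("sleep stage "):]
    if token in _DROPPED_TOKENS:
        return None
    if token in _STAGE_TOKENS:
        return _STAGE_TOKENS[token]
    raise ValueError(f"unrecognized hypnogram label: {raw_label!r}")


def segment_epochs(
    recording: Recording,
    hypnogram: Sequence[tuple[float, float, str]],
    window: Optional[tuple[float, float]] = None,
) -> LabeledDataset:
    """Cut a recording into labeled, contiguous, non-overlapping 30-s epochs.

    ``hypnogram`` holds ``(onset_s, duration_s, raw_label)`` spans relative to
    the recording start.  ``window`` is ``(start_s, end_s)`` from recording
    start, aligned to the 30-s grid; by default the whole recording is used.
    Epochs whose label maps to ``None`` are excluded; a gap in hypnogram
    coverage inside the window is an error.
    """
    fs = recording.sampling_rate
    total_s = recording.samples.size / fs
    if window is None:
        window = (0.0, np.floor(total_s / EPOCH_SECONDS) * EPOCH_SECONDS)
    start_s, end_s = window
    if start_s % EPOCH_SECONDS or end_s % EPOCH_SECONDS:
        raise ValueError("window must be aligned to the 30-s epoch grid")
    if start_s < 0 or end_s > total_s + 1e-9:
        raise ValueError("window lies outside the recording")
    if end_s <= start_s:
        raise ValueError("empty window")

    spans = sorted(hypnogram, key=lambda t: t[0])

    def label_at(t: float) -> str:
        for onset, dur, lab in spans:
            if onset - 1e-9 <= t < onset + dur - 1e-9:
                return lab
        raise ValueError(f"hypnogram gap: no label covers t={t:.1f} s")

    samples_per_epoch = int(round(EPOCH_SECONDS * fs))
    epochs: list[LabeledEpoch] = []
    n_windows = int(round((end_s - start_s) / EPOCH_SECONDS))
    for k in range(n_windows):
        t0 = start_s + k * EPOCH_SECONDS
        stage = map_legacy_stage(label_at(t0))
        if stage is None:
            continue
        i0 = int(round(t0 * fs))
        seg = recording.samples[i0 : i0 + samples_per_epoch]
        if seg.size != samples_per_epoch:
            raise ValueError(f"epoch at t={t0:.0f}s truncated by recording end")
        epochs.append(LabeledEpoch(samples=seg, stage=stage, index=k))
    return LabeledDataset(epochs=epochs, sampling_rate=fs)
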