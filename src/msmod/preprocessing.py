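"""Continuous-EEG containers and reduction to clean 2-s epochs.

The preprocessing chain mirrors standard microstate practice: band-pass
filter to 2-20 Hz (zero phase), re-reference to the common average, cut
into contiguous non-overlapping epochs, and drop any epoch whose
absolute amplitude exceeds +/- 80 μV. Artifact rejection is a purely
programmatic amplitude threshold; no ICA or ocular correction is
performed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

__all__ = [
    "Recording",
    "EpochedEEG",
    "bandpass_filter",
    "average_reference",
    "epoch_and_reject",
    "read_recording",
    "write_recording_fif",
]


@dataclass
class Recording:
    """A continuous multichannel recording in μV.

    ``data`` is ``(n_channels, n_samples)``; ``reference`` records the
    referencing scheme ("average" once re-referenced).
    """

    data: np.ndarray
    channel_labels: list[str]
    sampling_rate: float
    reference: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError("data must be (n_channels >= 2, n_samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match data rows")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochedEEG:
    """Fixed-length epochs that survived amplitude rejection.

    ``data`` is ``(n_epochs, n_channels, n_samples_per_epoch)`` and
    ``kept_epoch_indices`` maps back to positions in the original
    continuous segmentation.
    """

    data: np.ndarray
    epoch_length_ms: float
    kept_epoch_indices: np.ndarray
    rejection_threshold: float
    sampling_rate: float
    channel_labels: list[str] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def concatenated(self) -> np.ndarray:
        """Kept epochs joined along time, ``(n_channels, n_kept*samples)``."""
        return np.concatenate(list(self.data), axis=1) if self.n_epochs else np.empty((self.n_channels, 0))


def bandpass_filter(
    rec: Recording, low: float, high: float, order: int = 4
) -> Recording:
    """Zero-phase Butterworth band-pass (applied forward and backward).

    The default 4th-order design gives essentially unit gain mid-band and
    removes DC entirely; `filtfilt` application doubles the effective
    order without phase distortion, which matters because microstate
    labeling is sample-by-sample.
    """
    nyq = rec.sampling_rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band ({low}, {high}) Hz must lie inside (0, {nyq}) Hz")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.sampling_rate, output="sos")
    out = sps.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=out)


def average_reference(rec: Recording) -> Recording:
    """Subtract the instantaneous spatial mean from every sample."""
    out = rec.data - rec.data.mean(axis=0, keepdims=True)
    return replace(rec, data=out, reference="average")


def epoch_and_reject(
    rec: Recording, epoch_ms: float = 2000.0, threshold_uv: float = 80.0
) -> EpochedEEG:
    """Cut contiguous non-overlapping epochs and drop high-amplitude ones.

    An epoch is rejected when any sample on any channel exceeds
    ``threshold_uv`` in absolute value. The trailing partial epoch is
    discarded.
    """
    n_per = epoch_ms * rec.sampling_rate / 1000.0
    if abs(n_per - round(n_per)) > 1e-9 or round(n_per) < 2:
        raise ValueError("epoch_ms must map to an integer sample count >= 2")
    n_per = int(round(n_per))
    n_epochs = rec.n_samples // n_per
    if n_epochs == 0:
        raise ValueError("recording shorter than one epoch")
    cut = rec.data[:, : n_epochs * n_per]
    epochs = cut.reshape(rec.n_channels, n_epochs, n_per).transpose(1, 0, 2)
    keep = np.abs(epochs).max(axis=(1, 2)) <= threshold_uv
    return EpochedEEG(
        data=epochs[keep].copy(),
        epoch_length_ms=float(epoch_ms),
        kept_epoch_indices=np.flatnonzero(keep),
        rejection_threshold=float(threshold_uv),
        sampling_rate=rec.sampling_rate,
        channel_labels=list(rec.channel_labels),
    )


def read_recording(path: str | Path, channels: list[str] | None = None) -> Recording:
    """Load EDF, BrainVision (.vhdr) or FIF through MNE, in μV.

    ``channels`` optionally restricts to a labeled subset (order taken
    from the argument).
    """
    import mne

    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif suffix == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    elif suffix == ".fif":
        raw = mne.io.read_raw_fif(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported EEG format: {path.name}")
    if channels is not None:
        raw = raw.pick(channels)
        raw = raw.reorder_channels(channels)
    data = raw.get_data() * 1e6  # volts -> μV
    return Recording(data, list(raw.ch_names), float(raw.info["sfreq"]))


def write_recording_fif(rec: Recording, path: str | Path) -> None:
    """Persist a recording as FIF (μV converted back to volts)."""
    import mne

    info = mne.create_info(rec.channel_labels, rec.sampling_rate, ch_types="eeg")
    raw = mne.io.RawArray(rec.data * 1e-6, info, verbose="error")
    raw.save(path, overwrite=True, verbose="error")
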