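"""Window containers and EEG preprocessing.

The pipeline operates on fixed-length multichannel windows (by default 1-s
segments of 21-channel scalp EEG sampled at 250 Hz).  Preprocessing follows
standard clinical-EEG practice: zero-phase Butterworth band-pass filtering
between 1 and 40 Hz, followed by amplitude normalization that divides the
data by a high percentile (default 99th) of the absolute amplitude of the
training set, so that values mostly lie in [-1, 1].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

#: The 21 standard 10-20 electrodes, in the channel order used throughout.
STANDARD_CHANNELS: tuple[str, ...] = (
    "Fp1", "F7", "T3", "T5", "Fp2", "F8", "T4", "T6",
    "F3", "C3", "P3", "O1", "F4", "C4", "P4", "O2",
    "Fz", "Cz", "Pz", "A1", "A2",
)


class InvalidSpecError(ValueError):
    """Raised when a preprocessing specification is inconsistent."""


@dataclass
class WindowSet:
    """A batch of fixed-length multichannel signal windows.

    Parameters
    ----------
    data : ndarray, shape (n_windows, n_channels, n_samples)
        Window samples (volts, microvolts, or normalized units).
    fs : float
        Sampling rate in Hz.
    labels : ndarray of int, optional
        One category label per window.
    subjects : ndarray, optional
        One subject identifier per window.
    channel_names : sequence of str, optional
        Ordered channel labels; defaults to the standard 21-channel list
        when the channel count matches.
    """

    data: np.ndarray
    fs: float
    labels: np.ndarray | None = None
    subjects: np.ndarray | None = None
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (n_windows, n_channels, n_samples), got shape {self.data.shape}"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.n_windows:
                raise ValueError("labels length must equal n_windows")
        if self.subjects is not None:
            self.subjects = np.asarray(self.subjects)
            if len(self.subjects) != self.n_windows:
                raise ValueError("subjects length must equal n_windows")
        if self.channel_names is None and self.data.shape[1] == len(STANDARD_CHANNELS):
            self.channel_names = STANDARD_CHANNELS
        elif self.channel_names is not None:
            self.channel_names = tuple(self.channel_names)
            if len(self.channel_names) != self.n_channels:
                raise ValueError("channel_names length must equal n_channels")

    @property
    def n_windows(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def subset(self, idx: np.ndarray) -> "WindowSet":
        """Return a new WindowSet containing the windows selected by ``idx``."""
        idx = np.asarray(idx)
        return WindowSet(
            data=self.data[idx],
            fs=self.fs,
            labels=None if self.labels is None else self.labels[idx],
            subjects=None if self.subjects is None else self.subjects[idx],
            channel_names=self.channel_names,
        )

    def save(self, path: str | Path) -> None:
        """Persist as a compressed .npz archive with a JSON sidecar."""
        path = Path(path)
        arrays = {"data": self.data}
        if self.labels is not None:
            arrays["labels"] = self.labels
        if self.subjects is not None:
            arrays["subjects"] = np.asarray(self.subjects, dtype="U32")
        np.savez_compressed(path.with_suffix(".npz"), **arrays)
        meta = {
            "fs": self.fs,
            "channel_names": list(self.channel_names) if self.channel_names else None,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "WindowSet":
        path = Path(path)
        with np.load(path.with_suffix(".npz")) as arc:
            data = arc["data"]
            labels = arc["labels"] if "labels" in arc else None
            subjects = arc["subjects"] if "subjects" in arc else None
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            data=data,
            fs=meta["fs"],
            labels=labels,
            subjects=subjects,
            channel_names=meta["channel_names"],
        )


@dataclass
class PreprocessSpec:
    """Band-pass and normalization settings.

    ``norm_scale`` is learned from training data by :func:`fit_normalizer`
    and then divides all data (train and test alike), so the preprocessing
    is fully determined by the training split.
    """

    low_hz: float = 1.0
    high_hz: float = 40.0
    filter_order: int = 4
    norm_percentile: float = 99.0
    norm_scale: float | None = None

    def validate(self, fs: float) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise InvalidSpecError("require 0 < low_hz < high_hz")
        if self.high_hz >= fs / 2:
            raise InvalidSpecError(
                f"high cutoff {self.high_hz} Hz must be below Nyquist ({fs / 2} Hz)"
            )
        if not (0 < self.norm_percentile <= 100):
            raise InvalidSpecError("norm_percentile must be in (0, 100]")
        if self.norm_scale is not None and self.norm_scale <= 0:
            raise InvalidSpecError("norm_scale must be positive once fitted")


def bandpass_filter(
    signals: np.ndarray, spec: PreprocessSpec, fs: float
) -> np.ndarray:
    """Zero-phase Butterworth band-pass filter along the last axis.

    The filter is applied forward and backward (``filtfilt``), so the
    effective magnitude response is the squared Butterworth response and the
    phase response is identically zero.
    """
    spec.validate(fs)
    signals = np.asarray(signals, dtype=np.float64)
    sos = sps.butter(
        spec.filter_order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=fs, output="sos"
    )
    # sosfiltfilt pads internally; a too-short signal raises a clear error.
    return sps.sosfiltfilt(sos, signals, axis=-1)


def fit_normalizer(train: WindowSet, spec: PreprocessSpec) -> PreprocessSpec:
    """Learn ``norm_scale`` as a percentile of |amplitude| over the training set.

    The percentile pools every sample of every channel of every training
    window and uses linear interpolation between order statistics.
    """
    if train.n_windows == 0:
        raise ValueError("cannot fit a normalizer on an empty WindowSet")
    scale = float(np.percentile(np.abs(train.data), spec.norm_percentile))
    if scale <= 0:
        raise ValueError("training data percentile is zero; cannot normalize")
    return replace(spec, norm_scale=scale)


def apply_normalizer(windows: WindowSet, spec: PreprocessSpec) -> WindowSet:
    """Divide all window data by the fitted ``norm_scale``."""
    if spec.norm_scale is None:
        raise InvalidSpecError("normalizer not fitted; call fit_normalizer first")
    return WindowSet(
        data=windows.data / spec.norm_scale,
        fs=windows.fs,
        labels=windows.labels,
        subjects=windows.subjects,
        channel_names=windows.channel_names,
    )


def preprocess(
    windows: WindowSet, spec: PreprocessSpec, *, fit: bool = False
) -> tuple[WindowSet, PreprocessSpec]:
    """Filter every window and normalize; optionally fit the normalizer first.

    Returns the preprocessed windows and the (possibly updated) spec.
    """
    filtered = WindowSet(
        data=bandpass_filter(windows.data, spec, windows.fs),
        fs=windows.fs,
        labels=windows.labels,
        subjects=windows.subjects,
        channel_names=windows.channel_names,
    )
    if fit:
        spec = fit_normalizer(filtered, spec)
    return apply_normalizer(filtered, spec), spec


def segment(
    recording: np.ndarray,
    fs: float,
    duration_s: float,
    stride_s: float | None = None,
    *,
    channel_names: tuple[str, ...] | None = None,
) -> WindowSet:
    """Cut a (channels x time) recording into fixed-length windows.

    Windows are half-open sample ranges [start, start + duration*fs), laid
    left to right with the given stride (stride == duration means
    non-overlapping tiling).  A trailing remainder shorter than one window
    is dropped.
    """
    recording = np.atleast_2d(np.asarray(recording, dtype=np.float64))
    if stride_s is None:
        stride_s = duration_s
    if stride_s <= 0:
        raise ValueError("stride_s must be positive")
    win = duration_s * fs
    hop = stride_s * fs
    if abs(win - round(win)) > 1e-9:
        raise ValueError("duration_s * fs must be an integer number of samples")
    win = int(round(win))
    hop_exact = hop
    hop = int(round(hop))
    if abs(hop_exact - hop) > 1e-9:
        raise ValueError("stride_s * fs must be an integer number of samples")
    n_ch, T = recording.shape
    if T < win:
        warnings.warn("recording shorter than one window; returning empty WindowSet")
        return WindowSet(
            data=np.empty((0, n_ch, win)), fs=fs, channel_names=channel_names
        )
    n_windows = (T - win) // hop + 1
    starts = np.arange(n_windows) * hop
    data = np.stack([recording[:, s : s + win] for s in starts])
    return WindowSet(data=data, fs=fs, channel_names=channel_names)
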