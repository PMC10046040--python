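"""Time-frequency feature representations for the baseline encoders.

Two alternatives are implemented, both computed per channel of a 1-s window
and concatenated across the 21 channels:

* STFT: the magnitude spectrum of the (Hann-tapered) 1-s frame at the 30
  integer frequencies 1..30 Hz — a 1-s frame has exactly 1 Hz bin spacing —
  giving 21 x 30 = 630 values per window.
* Ricker (Mexican-hat) CWT: convolution with 29 wavelets whose peak response
  frequencies are log-spaced from 1 to 30 Hz; for each scale the mean,
  standard deviation, minimum and maximum of the coefficient series are
  kept, giving 21 x 29 x 4 = 2436 values per window.

Features are z-scored column-wise with training-set statistics (see
:class:`FeatureScaler`) before encoder training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve
from scipy.signal.windows import hann

from .windows import WindowSet

N_STFT_BANDS = 30
N_CWT_SCALES = 29
CWT_STATS = ("mean", "std", "min", "max")


@dataclass
class FeatureMatrix:
    """Per-window feature vectors with column labels."""

    values: np.ndarray  # (n_windows, n_features)
    kind: str  # "stft" or "cwt"
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match the number of columns")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def stft_features(windows: WindowSet, taper: str = "hann") -> FeatureMatrix:
    """Single-frame magnitude-spectrum features at 1..30 Hz per channel."""
    if abs(windows.duration_s - 1.0) > 1e-9:
        raise ValueError(
            f"STFT features expect 1-s windows (one frame per window); "
            f"got {windows.duration_s:.3g} s — re-segment the recording"
        )
    if windows.fs < 2 * N_STFT_BANDS:
        raise ValueError("sampling rate too low to resolve 30 Hz")
    x = windows.data  # (n, C, T)
    n, C, T = x.shape
    if taper == "hann":
        x = x * hann(T, sym=False)
    elif taper != "rectangular":
        raise ValueError("taper must be 'hann' or 'rectangular'")
    spec = np.abs(np.fft.rfft(x, axis=-1))
    # 1-s frame: rfft bin k is exactly k Hz
    bands = spec[:, :, 1 : N_STFT_BANDS + 1]
    values = bands.reshape(n, C * N_STFT_BANDS)
    ch_names = windows.channel_names or [f"ch{i}" for i in range(C)]
    names = [f"{ch}_stft_{f}Hz" for ch in ch_names for f in range(1, N_STFT_BANDS + 1)]
    return FeatureMatrix(values, "stft", names)


def ricker_wavelet(width: float, n_points: int) -> np.ndarray:
    """Sampled Ricker (Mexican-hat) wavelet of width ``a`` (in samples).

    psi_a(t) = 2 / (sqrt(3a) * pi**0.25) * (1 - t**2/a**2) * exp(-t**2 / (2 a**2))
    """
    t = np.arange(n_points) - (n_points - 1) / 2.0
    amp = 2.0 / (np.sqrt(3.0 * width) * np.pi**0.25)
    return amp * (1.0 - (t / width) ** 2) * np.exp(-(t**2) / (2.0 * width**2))


def ricker_scales(fs: float, n_scales: int = N_CWT_SCALES,
                  f_min: float = 1.0, f_max: float = 30.0) -> np.ndarray:
    """Wavelet widths (samples) whose peak frequencies are log-spaced f_min..f_max.

    The Ricker spectrum peaks at f = sqrt(2) / (2 pi a / fs), i.e.
    a = fs * sqrt(2) / (2 pi f).
    """
    freqs = np.geomspace(f_min, f_max, n_scales)
    return fs * np.sqrt(2.0) / (2.0 * np.pi * freqs)


def cwt_features(windows: WindowSet) -> FeatureMatrix:
    """Ricker-CWT band statistics: (channel, scale, statistic) ordering."""
    x = windows.data
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input windows")
    n, C, T = x.shape
    widths = ricker_scales(windows.fs)
    flat = x.reshape(n * C, T)
    stats = np.empty((n * C, N_CWT_SCALES, 4))
    for si, a in enumerate(widths):
        m = min(int(10 * a) | 1, 2 * T - 1)  # odd support, truncated near window length
        w = ricker_wavelet(a, m)
        coef = fftconvolve(flat, w[None, :], mode="same", axes=1)
        stats[:, si, 0] = coef.mean(axis=1)
        stats[:, si, 1] = coef.std(axis=1)
        stats[:, si, 2] = coef.min(axis=1)
        stats[:, si, 3] = coef.max(axis=1)
    values = stats.reshape(n, C * N_CWT_SCALES * 4)
    ch_names = windows.channel_names or [f"ch{i}" for i in range(C)]
    names = [
        f"{ch}_cwt_s{si}_{stat}"
        for ch in ch_names
        for si in range(N_CWT_SCALES)
        for stat in CWT_STATS
    ]
    return FeatureMatrix(values, "cwt", names)


@dataclass
class FeatureScaler:
    """Column-wise z-scoring with statistics frozen from the training split."""

    mean: np.ndarray | None = None
    std: np.ndarray | None = None

    def fit(self, features: FeatureMatrix) -> "FeatureScaler":
        self.mean = features.values.mean(axis=0)
        std = features.values.std(axis=0)
        self.std = np.where(std > 0, std, 1.0)  # constant columns pass through
        return self

    def transform(self, features: FeatureMatrix) -> FeatureMatrix:
        if self.mean is None:
            raise RuntimeError("scaler not fitted")
        return FeatureMatrix(
            (features.values - self.mean) / self.std,
            features.kind,
            features.feature_names,
        )
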