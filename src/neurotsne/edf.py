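"""EDF input/output.

Reading goes through MNE-Python, which handles the many EDF/EDF+ dialects in
the wild.  Writing is provided by a deliberately minimal EDF writer (16-bit,
one-second data records) sufficient for exporting simulated recordings and
for round-trip testing of the reader.
"""

from __future__ import annotations

from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal as sps


class ChannelMatchError(KeyError):
    """Raised when requested channel labels cannot be resolved in an EDF file."""


def _normalize_label(label: str) -> str:
    """Canonicalize an EDF channel label for matching.

    Tolerates the common 'EEG Fp1-REF' / 'EEG FP1-LE' decorations: the 'EEG'
    prefix and a '-<reference>' suffix are stripped and case is ignored.
    """
    lab = label.strip().upper()
    if lab.startswith("EEG "):
        lab = lab[4:]
    if "-" in lab:
        lab = lab.split("-", 1)[0]
    return lab.strip()


def read_edf(
    path: str | Path,
    channel_names: list[str] | tuple[str, ...],
    target_fs: float = 250.0,
) -> np.ndarray:
    """Read selected channels from an EDF file.

    Channels are returned in the requested order, in microvolts, resampled to
    ``target_fs`` (polyphase filtering) and converted to average reference
    over the returned channels.

    Raises :class:`ChannelMatchError` listing any label that cannot be
    resolved.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    available = {_normalize_label(name): i for i, name in enumerate(raw.ch_names)}
    picks, missing = [], []
    for name in channel_names:
        key = _normalize_label(name)
        if key in available:
            picks.append(available[key])
        else:
            missing.append(name)
    if missing:
        raise ChannelMatchError(
            f"channels not found in {path}: {missing}; file has {raw.ch_names}"
        )
    data = raw.get_data(picks=picks) * 1e6  # MNE returns SI volts
    fs = raw.info["sfreq"]
    if abs(fs - target_fs) > 1e-9:
        frac = Fraction(target_fs / fs).limit_denominator(1000)
        data = sps.resample_poly(data, frac.numerator, frac.denominator, axis=-1)
    data = data - data.mean(axis=0, keepdims=True)
    return data


def write_edf(
    path: str | Path,
    data: np.ndarray,
    fs: float,
    channel_names: list[str] | tuple[str, ...],
    physical_dim: str = "uV",
) -> None:
    """Write a (channels x time) array as a 16-bit EDF file.

    Each data record spans one second; a trailing partial second is
    zero-padded.  Physical scaling per channel is symmetric about zero so the
    quantization error is below 2**-15 of the channel's peak amplitude.
    """
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    n_ch, n_samp = data.shape
    if len(channel_names) != n_ch:
        raise ValueError("channel_names length must match data rows")
    fs_int = int(round(fs))
    if abs(fs - fs_int) > 1e-9:
        raise ValueError("the minimal writer supports integer sampling rates only")
    n_records = int(np.ceil(n_samp / fs_int))
    padded = np.zeros((n_ch, n_records * fs_int))
    padded[:, :n_samp] = data

    phys_max = np.maximum(np.abs(padded).max(axis=1), 1e-6)
    dig_max = 32767
    scaled = np.clip(
        np.round(padded / phys_max[:, None] * dig_max), -dig_max - 1, dig_max
    ).astype("<i2")

    def f(text: str, width: int) -> bytes:
        return f"{text:<{width}.{width}}".encode("ascii")

    header = b"".join(
        [
            f("0", 8),
            f("X X X X", 80),  # patient id
            f("Startdate X X X X", 80),  # recording id
            f("01.01.00", 8),
            f("00.00.00", 8),
            f(str(256 * (n_ch + 1)), 8),
            f("", 44),
            f(str(n_records), 8),
            f("1", 8),  # record duration, seconds
            f(str(n_ch), 4),
        ]
    )
    header += b"".join(f(name, 16) for name in channel_names)
    header += b"".join(f("", 80) for _ in range(n_ch))  # transducer
    header += b"".join(f(physical_dim, 8) for _ in range(n_ch))
    header += b"".join(f(f"{-pm:.6g}"[:8], 8) for pm in phys_max)
    header += b"".join(f(f"{pm:.6g}"[:8], 8) for pm in phys_max)
    header += b"".join(f(str(-dig_max - 1), 8) for _ in range(n_ch))
    header += b"".join(f(str(dig_max), 8) for _ in range(n_ch))
    header += b"".join(f("", 80) for _ in range(n_ch))  # prefiltering
    header += b"".join(f(str(fs_int), 8) for _ in range(n_ch))
    header += b"".join(f("", 32) for _ in range(n_ch))

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            block = scaled[:, rec * fs_int : (rec + 1) * fs_int]
            fh.write(block.tobytes())
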