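"""Seedable generator of labelled multichannel EEG-like windows.

Three two-class contrasts, mirroring the kinds of categories a clinical
reader separates, are emulated on top of 1/f-shaped Gaussian background
activity:

* ``sleep_wake`` — class 0 (wake) adds an 8-12 Hz posterior-dominant
  rhythm; class 1 (sleep) adds high-amplitude 1-3 Hz slow waves with
  occasional 12-14 Hz spindle bursts over central channels.
* ``ied`` — class 1 adds a single interictal spike-and-slow-wave transient
  (~70 ms spike followed by a ~300 ms wave) at a random time on a random
  contiguous channel subset; class 0 is background only.
* ``seizure`` — class 1 adds rhythmic 3-5 Hz activity whose frequency
  drifts linearly and whose amplitude grows across the window, over most
  channels; class 0 is background only.

The morphologies are parametric caricatures with controllable class
structure, not biophysical simulations.  Subject-level random effects
(amplitude and frequency jitter) let tests reproduce the
train-on-some-subjects / test-on-others setting.  The per-window generative
parameters are returned for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .windows import STANDARD_CHANNELS, WindowSet

POSTERIOR = ("O1", "O2", "T5", "T6", "P3", "P4")
CENTRAL = ("C3", "C4", "Cz", "F3", "F4")

CONTRASTS = ("sleep_wake", "ied", "seizure")


@dataclass
class SyntheticSpec:
    contrast: str = "sleep_wake"
    n_per_class: int = 100
    n_channels: int = 21
    fs: float = 250.0
    duration_s: float = 1.0
    snr: float = 2.0  # amplitude of the class signature relative to background sd
    n_subjects: int = 3
    background_exponent: float = 1.0  # power-spectrum slope of the background
    seed: int = 0

    def validate(self) -> None:
        if self.contrast not in CONTRASTS:
            raise ValueError(f"contrast must be one of {CONTRASTS}")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


def one_over_f_noise(
    rng: np.random.Generator, shape: tuple[int, ...], n_samples: int, exponent: float
) -> np.ndarray:
    """Gaussian noise whose power spectrum falls as 1/f**exponent, unit sd."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = amp * (
        rng.standard_normal((*shape, len(freqs)))
        + 1j * rng.standard_normal((*shape, len(freqs)))
    )
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def _channel_indices(names: tuple[str, ...], wanted: tuple[str, ...]) -> np.ndarray:
    return np.array([i for i, n in enumerate(names) if n in wanted])


def generate(spec: SyntheticSpec) -> tuple[WindowSet, pd.DataFrame]:
    """Generate a labelled WindowSet plus a table of generative parameters."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    T = int(round(spec.duration_s * spec.fs))
    C = spec.n_channels
    n = 2 * spec.n_per_class
    names = (
        STANDARD_CHANNELS
        if C == len(STANDARD_CHANNELS)
        else tuple(f"ch{i}" for i in range(C))
    )
    t = np.arange(T) / spec.fs

    subj_amp = np.exp(rng.normal(0.0, 0.2, size=spec.n_subjects))
    subj_freq_jitter = rng.normal(0.0, 0.3, size=spec.n_subjects)

    labels = np.repeat([0, 1], spec.n_per_class)
    subjects = np.array([f"s{i % spec.n_subjects}" for i in range(n)])
    subj_idx = np.array([int(s[1:]) for s in subjects])

    data = one_over_f_noise(rng, (n, C), T, spec.background_exponent)
    data *= subj_amp[subj_idx, None, None]

    posterior = _channel_indices(names, POSTERIOR)
    central = _channel_indices(names, CENTRAL)
    records: list[dict] = []

    for i in range(n):
        amp = spec.snr * subj_amp[subj_idx[i]]
        rec: dict = {
            "window": i,
            "label": int(labels[i]),
            "subject": subjects[i],
            "subject_amp": subj_amp[subj_idx[i]],
        }
        if spec.contrast == "sleep_wake":
            if labels[i] == 0:  # wake: posterior-dominant alpha
                f = rng.uniform(8.0, 12.0) + subj_freq_jitter[subj_idx[i]]
                phase = rng.uniform(0, 2 * np.pi)
                osc = np.sin(2 * np.pi * f * t + phase)
                weights = np.full(C, 0.2)
                if len(posterior):
                    weights[posterior] = 1.0
                data[i] += amp * weights[:, None] * osc
                rec.update(signature="alpha", freq_hz=f)
            else:  # sleep: slow waves, occasional spindles
                f = rng.uniform(1.0, 3.0)
                phase = rng.uniform(0, 2 * np.pi)
                data[i] += 1.5 * amp * np.sin(2 * np.pi * f * t + phase)
                rec.update(signature="slow_wave", freq_hz=f, spindle=False)
                if rng.uniform() < 0.3 and len(central):
                    fs_sp = rng.uniform(12.0, 14.0)
                    dur = int(0.5 * spec.fs)
                    onset = rng.integers(0, T - dur + 1)
                    env = np.sin(np.pi * np.arange(dur) / dur) ** 2
                    burst = env * np.sin(2 * np.pi * fs_sp * t[:dur])
                    data[i, central[:, None], np.arange(onset, onset + dur)] += (
                        0.8 * amp * burst
                    )
                    rec.update(spindle=True, spindle_freq_hz=fs_sp)
        elif spec.contrast == "ied" and labels[i] == 1:
            # spike (~70 ms) followed by a slow wave (~300 ms)
            spike_sd = 0.070 / 6.0
            wave_dur = int(0.300 * spec.fs)
            margin = int(0.050 * spec.fs)
            t0 = rng.uniform(0.05, spec.duration_s - 0.35)
            spike = np.exp(-((t - t0) ** 2) / (2 * spike_sd**2))
            wave = np.zeros(T)
            w_start = int(t0 * spec.fs) + margin
            w_len = min(wave_dur, T - w_start)
            wave[w_start : w_start + w_len] = np.sin(
                np.pi * np.arange(w_len) / wave_dur
            )
            n_ch = int(rng.integers(3, min(9, C + 1)))
            start_ch = int(rng.integers(0, C - n_ch + 1))
            transient = 3.0 * amp * spike + 1.5 * amp * wave
            data[i, start_ch : start_ch + n_ch] += transient
            rec.update(
                signature="spike_wave", onset_s=t0, first_channel=start_ch, n_ch=n_ch
            )
        elif spec.contrast == "seizure" and labels[i] == 1:
            f0 = rng.uniform(3.0, 5.0) + subj_freq_jitter[subj_idx[i]]
            drift = rng.uniform(-1.5, -0.5)  # Hz per second, rhythmic slowing
            f_inst = np.maximum(f0 + drift * t, 0.5)
            phase = 2 * np.pi * np.cumsum(f_inst) / spec.fs
            ramp = 0.5 + 1.0 * t / spec.duration_s  # amplitude growth
            ch_w = rng.uniform(0.5, 1.0, size=C)
            data[i] += 1.5 * amp * ch_w[:, None] * (ramp * np.sin(phase))[None, :]
            rec.update(signature="rhythmic", f0_hz=f0, drift_hz_per_s=drift)
        else:
            rec.update(signature="background")
        records.append(rec)

    ws = WindowSet(
        data=data, fs=spec.fs, labels=labels, subjects=subjects, channel_names=names
    )
    return ws, pd.DataFrame.from_records(records)
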