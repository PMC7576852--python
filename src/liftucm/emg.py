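"""EMG conditioning.

The conditioning chain follows standard surface-EMG practice for lifting
studies: cardiac-artifact removal by zeroing all spectral components below
40 Hz (FFT high-pass), full-wave rectification, a zero-lag 4th-order
Butterworth low-pass at 5 Hz to obtain the linear envelope, and amplitude
normalization of each muscle by the within-set mean of its per-repetition
envelope maxima.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .datatypes import EmgRecording

__all__ = [
    "fft_highpass",
    "envelope",
    "normalize_amplitude",
    "exclude_channels",
    "notch_filter",
    "EnvelopeSet",
]

#: Minimum record length accepted by the zero-phase IIR filters; below this
#: the forward-backward pad dominates the output.
_MIN_FILTER_SAMPLES = 30


@dataclass
class EnvelopeSet:
    """Normalized EMG envelopes plus the per-channel normalizing factors."""

    envelopes: np.ndarray  # (n_samples, n_channels), nonnegative, unitless
    normalizers: np.ndarray  # (n_channels,), > 0
    labels: list[str]

    def __post_init__(self) -> None:
        self.envelopes = np.asarray(self.envelopes, dtype=float)
        self.normalizers = np.asarray(self.normalizers, dtype=float)
        if np.any(self.normalizers <= 0):
            raise ValueError("normalizers must be positive")
        if np.any(self.envelopes < 0):
            raise ValueError("envelope values must be nonnegative")


def fft_highpass(signal: np.ndarray, fs: float, cutoff: float = 40.0) -> np.ndarray:
    """Zero all spectral components strictly below ``cutoff``.

    The signal is transformed with the FFT, every bin whose frequency
    magnitude is below the cutoff (including DC) is set to zero on both
    sides of the spectrum, and the result is transformed back.  The
    operation is an orthogonal projection, so applying it twice equals
    applying it once.

    Parameters
    ----------
    signal
        1-D array, or 2-D array filtered along axis 0.
    fs
        Sampling rate in Hz.
    cutoff
        High-pass edge in Hz; bins at exactly ``cutoff`` are retained.
    """
    x = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    if cutoff >= fs / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    n = x.shape[0]
    spec = np.fft.rfft(x, axis=0)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = freqs < cutoff
    if x.ndim == 1:
        spec[mask] = 0.0
    else:
        spec[mask, ...] = 0.0
    # irfft enforces conjugate symmetry, i.e. the symmetric zeroing of the
    # negative-frequency bins, and returns a real signal of original length.
    return np.fft.irfft(spec, n=n, axis=0)


def envelope(
    signal: np.ndarray, fs: float, cutoff: float = 5.0, order: int = 4
) -> np.ndarray:
    """Linear envelope: full-wave rectification, then a zero-lag (forward-
    backward) Butterworth low-pass.

    Negative undershoot produced by the low-pass is clipped to zero so the
    result is a valid nonnegative input for NMF.
    """
    x = np.asarray(signal, dtype=float)
    if x.shape[0] < _MIN_FILTER_SAMPLES:
        raise ValueError("signal too short for zero-lag envelope filtering")
    if cutoff >= fs / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    env = sps.sosfiltfilt(sos, np.abs(x), axis=0)
    return np.clip(env, 0.0, None)


def normalize_amplitude(
    envelopes: np.ndarray,
    rep_bounds: Sequence[tuple[int, int]],
    labels: Sequence[str] | None = None,
) -> EnvelopeSet:
    """Normalize each channel by the mean of its per-repetition envelope maxima.

    Parameters
    ----------
    envelopes
        Array of shape ``(n_samples, n_channels)``, nonnegative.
    rep_bounds
        ``(onset, offset)`` sample index pairs (inclusive) delimiting each
        repetition of the set.
    """
    env = np.atleast_2d(np.asarray(envelopes, dtype=float))
    if env.ndim != 2:
        raise ValueError("envelopes must be 2-D (time x channels)")
    if np.any(env < 0):
        raise ValueError("envelopes must be nonnegative")
    if not rep_bounds:
        raise ValueError("at least one repetition is required")
    for on, off in rep_bounds:
        if not (0 <= on < off <= env.shape[0] - 1):
            raise ValueError(f"repetition bounds ({on}, {off}) out of range")
    maxima = np.stack([env[on : off + 1].max(axis=0) for on, off in rep_bounds])
    normalizers = maxima.mean(axis=0)
    silent = np.flatnonzero(normalizers <= 0)
    if silent.size:
        names = (
            [labels[i] for i in silent] if labels is not None else silent.tolist()
        )
        raise ValueError(f"silent channel: {names}")
    out_labels = list(labels) if labels is not None else [
        f"ch{i}" for i in range(env.shape[1])
    ]
    return EnvelopeSet(env / normalizers, normalizers, out_labels)


def exclude_channels(rec: EmgRecording, labels_to_drop: Sequence[str]) -> EmgRecording:
    """Drop channels by label (e.g. rectus abdominis when contaminated by
    movement artifacts)."""
    unknown = [lab for lab in labels_to_drop if lab not in rec.labels]
    if unknown:
        raise KeyError(f"unknown EMG channel(s): {unknown}")
    keep = [i for i, lab in enumerate(rec.labels) if lab not in set(labels_to_drop)]
    return EmgRecording(
        samples=rec.samples[:, keep],
        fs=rec.fs,
        labels=[rec.labels[i] for i in keep],
    )


def notch_filter(
    signal: np.ndarray, fs: float, freq: float = 50.0, q: float = 30.0
) -> np.ndarray:
    """Optional zero-lag IIR notch for power-line interference (off by
    default in the standard chain)."""
    x = np.asarray(signal, dtype=float)
    if x.shape[0] < _MIN_FILTER_SAMPLES:
        raise ValueError("signal too short for notch filtering")
    b, a = sps.iirnotch(freq, q, fs=fs)
    return sps.filtfilt(b, a, x, axis=0)
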