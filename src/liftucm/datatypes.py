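"""Core in-memory containers shared across the pipeline stages.

Conventions
-----------
* Time series are stored time-major: ``samples[i, c]`` is channel ``c`` at
  sample ``i``.
* Marker positions are metres in the laboratory frame with the floor at
  ``z = 0`` and the laboratory vertical along ``+z``.
* Normalized movement cycles have exactly ``n_points`` (default 100)
  samples per repetition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EmgRecording",
    "MarkerRecording",
    "SegmentDisplacement",
    "PhaseSegmentation",
    "CycleSet",
]


def _check_finite(name: str, arr: np.ndarray) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")


@dataclass
class EmgRecording:
    """Raw multichannel surface EMG.

    Parameters
    ----------
    samples
        Array of shape ``(n_samples, n_channels)``, arbitrary amplitude units.
    fs
        Sampling rate in Hz.
    labels
        Muscle name per channel.
    """

    samples: np.ndarray
    fs: float
    labels: list[str]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("EMG samples must be 2-D (time x channels)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.labels) != self.samples.shape[1]:
            raise ValueError("label count does not match channel count")
        _check_finite("EMG samples", self.samples)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown EMG channel {label!r}") from None
        return self.samples[:, idx]


@dataclass
class MarkerRecording:
    """Motion-capture marker trajectories.

    ``positions`` has shape ``(n_samples, n_markers, 3)`` in metres.
    """

    positions: np.ndarray
    fs: float
    labels: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("marker positions must have shape (time, markers, 3)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.labels) != self.positions.shape[1]:
            raise ValueError("label count does not match marker count")
        _check_finite("marker positions", self.positions)

    @property
    def n_samples(self) -> int:
        return self.positions.shape[0]

    def has(self, label: str) -> bool:
        return label in self.labels

    def get(self, label: str) -> np.ndarray:
        try:
            idx = self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown marker {label!r}") from None
        return self.positions[:, idx, :]


@dataclass
class SegmentDisplacement:
    """Anterior-posterior and vertical displacement of one body segment,
    expressed in the task-aligned virtual coordinate frame."""

    ap: np.ndarray
    v: np.ndarray
    segment: str

    def __post_init__(self) -> None:
        self.ap = np.asarray(self.ap, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.ap.shape != self.v.shape:
            raise ValueError("ap and v must have equal length")
        if self.segment not in ("pelvis", "trunk"):
            raise ValueError("segment must be 'pelvis' or 'trunk'")


@dataclass
class PhaseSegmentation:
    """Per-repetition onset/offset sample indices of one movement phase."""

    phase: str  # "lift" or "lower"
    onsets: np.ndarray
    offsets: np.ndarray
    peak_velocity: float

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=int)
        self.offsets = np.asarray(self.offsets, dtype=int)
        if self.phase not in ("lift", "lower"):
            raise ValueError("phase must be 'lift' or 'lower'")
        if self.onsets.shape != self.offsets.shape:
            raise ValueError("onsets and offsets must align")
        if np.any(self.onsets >= self.offsets):
            raise ValueError("each onset must precede its offset")
        if np.any(self.onsets[1:] <= self.offsets[:-1]):
            raise ValueError("repetitions must be ordered and non-overlapping")

    @property
    def n_reps(self) -> int:
        return len(self.onsets)


@dataclass
class CycleSet:
    """Phase-labelled, time-normalized cycles.

    ``curves`` has shape ``(n_channels, n_reps, n_points)``.
    """

    curves: np.ndarray
    labels: list[str]
    phase: str
    n_points: int = field(default=100)

    def __post_init__(self) -> None:
        self.curves = np.asarray(self.curves, dtype=float)
        if self.curves.ndim != 3:
            raise ValueError("curves must have shape (channels, reps, points)")
        if self.curves.shape[2] != self.n_points:
            raise ValueError(
                f"curves have {self.curves.shape[2]} points, expected {self.n_points}"
            )
        if len(self.labels) != self.curves.shape[0]:
            raise ValueError("label count does not match channel count")
        _check_finite("cycle curves", self.curves)

    @property
    def n_channels(self) -> int:
        return self.curves.shape[0]

    @property
    def n_reps(self) -> int:
        return self.curves.shape[1]
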