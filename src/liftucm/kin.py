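"""Kinematics: marker filtering, virtual coordinate frame, segment
displacements, velocity-threshold phase segmentation and time
normalization.

The task-aligned virtual frame is anchored to the feet: its origin is the
mid-point of the bilateral calcaneus markers projected onto the floor, the
anterior axis points towards the floor projection of the mid-point of the
bilateral first metatarsophalangeal markers, and the vertical axis is the
laboratory vertical.  Pelvis and trunk displacements are the anterior-
posterior and vertical coordinates of a pelvis landmark and of the right
acromion marker in that frame.

A lifting (lowering) phase is the contiguous region where the acromion's
positive (negative) vertical velocity stays at or above 10% of the set's
peak positive (negative) velocity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .datatypes import MarkerRecording, PhaseSegmentation, SegmentDisplacement

__all__ = [
    "VirtualFrame",
    "filter_markers",
    "build_virtual_frame",
    "compute_displacements",
    "vertical_velocity",
    "segment_phases",
    "pair_repetitions",
    "time_normalize",
]

DEFAULT_CALCANEI = ("LCAL", "RCAL")
DEFAULT_MTP = ("LMTP1", "RMTP1")
DEFAULT_TRUNK_MARKER = "RACR"
DEFAULT_PELVIS_MARKER = "PEL"
#: Fallback pelvis landmark: centroid of the four pelvis markers.
PELVIS_CLUSTER = ("LASI", "RASI", "LPSI", "RPSI")

_MIN_FILTER_SAMPLES = 30


@dataclass
class VirtualFrame:
    """Right-handed orthonormal frame: rows of ``axes`` are the lateral,
    anterior and vertical unit vectors in laboratory coordinates."""

    origin: np.ndarray
    axes: np.ndarray  # (3, 3)

    def to_local(self, points: np.ndarray) -> np.ndarray:
        """Express laboratory-frame points (…, 3) in frame coordinates."""
        return (np.asarray(points) - self.origin) @ self.axes.T

    @property
    def lateral(self) -> np.ndarray:
        return self.axes[0]

    @property
    def anterior(self) -> np.ndarray:
        return self.axes[1]

    @property
    def vertical(self) -> np.ndarray:
        return self.axes[2]


def filter_markers(
    rec: MarkerRecording, cutoff: float = 6.0, order: int = 4
) -> MarkerRecording:
    """Zero-lag low-pass of every marker coordinate.

    The design order applies to the underlying Butterworth; the forward-
    backward application doubles the effective attenuation and cancels the
    phase lag.
    """
    if rec.n_samples < _MIN_FILTER_SAMPLES:
        raise ValueError("marker recording too short to filter")
    if cutoff >= rec.fs / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    sos = sps.butter(order, cutoff, btype="low", fs=rec.fs, output="sos")
    flat = rec.positions.reshape(rec.n_samples, -1)
    out = sps.sosfiltfilt(sos, flat, axis=0).reshape(rec.positions.shape)
    return MarkerRecording(out, rec.fs, list(rec.labels))


def build_virtual_frame(
    rec: MarkerRecording,
    calcanei: tuple[str, str] = DEFAULT_CALCANEI,
    mtp: tuple[str, str] = DEFAULT_MTP,
) -> VirtualFrame:
    """Construct the foot-anchored virtual frame from the (static) foot
    markers, using their time-averaged positions."""
    for lab in (*calcanei, *mtp):
        if not rec.has(lab):
            raise KeyError(f"missing marker {lab!r} for virtual frame")
    mid_cal = np.mean([rec.get(lab).mean(axis=0) for lab in calcanei], axis=0)
    mid_mtp = np.mean([rec.get(lab).mean(axis=0) for lab in mtp], axis=0)
    origin = np.array([mid_cal[0], mid_cal[1], 0.0])
    vertical = np.array([0.0, 0.0, 1.0])
    anterior = np.array([mid_mtp[0], mid_mtp[1], 0.0]) - origin
    norm = np.linalg.norm(anterior)
    if norm < 1e-9:
        raise ValueError("degenerate landmark geometry: calcanei and MTP "
                         "mid-points coincide on the floor")
    anterior = anterior / norm
    lateral = np.cross(anterior, vertical)
    axes = np.vstack([lateral, anterior, vertical])
    return VirtualFrame(origin=origin, axes=axes)


def compute_displacements(
    rec: MarkerRecording,
    frame: VirtualFrame,
    trunk_label: str = DEFAULT_TRUNK_MARKER,
    pelvis_label: str = DEFAULT_PELVIS_MARKER,
) -> tuple[SegmentDisplacement, SegmentDisplacement]:
    """Pelvis and trunk AP/vertical displacements in the virtual frame.

    The pelvis landmark is either a dedicated (precomputed) marker channel
    or, when absent, the centroid of the four pelvis markers.
    """
    if not rec.has(trunk_label):
        raise KeyError(f"missing trunk landmark {trunk_label!r}")
    trunk = rec.get(trunk_label)
    if rec.has(pelvis_label):
        pelvis = rec.get(pelvis_label)
    elif all(rec.has(lab) for lab in PELVIS_CLUSTER):
        pelvis = np.mean([rec.get(lab) for lab in PELVIS_CLUSTER], axis=0)
    else:
        raise KeyError(
            f"missing pelvis landmark {pelvis_label!r} (and no "
            f"{'/'.join(PELVIS_CLUSTER)} cluster to derive it from)"
        )
    t_loc = frame.to_local(trunk)
    p_loc = frame.to_local(pelvis)
    return (
        SegmentDisplacement(ap=p_loc[:, 1], v=p_loc[:, 2], segment="pelvis"),
        SegmentDisplacement(ap=t_loc[:, 1], v=t_loc[:, 2], segment="trunk"),
    )


def vertical_velocity(displacement: np.ndarray, fs: float) -> np.ndarray:
    """Central-difference vertical velocity of a displacement series (m/s)."""
    return np.gradient(np.asarray(displacement, dtype=float)) * fs


def _threshold_regions(
    above: np.ndarray, merge_gap: int, min_duration: int
) -> list[tuple[int, int]]:
    """Contiguous runs of True, with short gaps merged and short runs
    dropped.  Gap merging guards against single-sample dips created by
    measurement noise near the threshold crossing."""
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    regions = list(zip(starts.tolist(), ends.tolist()))
    merged: list[tuple[int, int]] = []
    for on, off in regions:
        if merged and on - merged[-1][1] - 1 <= merge_gap:
            merged[-1] = (merged[-1][0], off)
        else:
            merged.append((on, off))
    return [(on, off) for on, off in merged if off - on + 1 >= min_duration]


def segment_phases(
    velocity: np.ndarray,
    fs: float,
    threshold_frac: float = 0.10,
    min_duration_s: float = 0.2,
    merge_gap_s: float = 0.04,
) -> list[PhaseSegmentation]:
    """Detect lifting and lowering phases from the acromion vertical velocity.

    The lift (lower) phase of each repetition is the contiguous region where
    the positive (negative) vertical velocity is at or above
    ``threshold_frac`` of the set's peak positive (negative) velocity.
    Returns the lift and lower :class:`PhaseSegmentation`, in that order,
    with equal repetition counts and each lift preceding its lower.
    """
    v = np.asarray(velocity, dtype=float)
    if v.ndim != 1:
        raise ValueError("velocity must be a 1-D series")
    merge_gap = max(int(round(merge_gap_s * fs)), 0)
    min_dur = max(int(round(min_duration_s * fs)), 1)
    segs: dict[str, list[tuple[int, int]]] = {}
    peaks: dict[str, float] = {}
    for phase, signed in (("lift", v), ("lower", -v)):
        peak = signed.max(initial=-np.inf)
        if peak <= 0:
            raise ValueError(f"no repetition detected: no {phase} excursion")
        regions = _threshold_regions(
            signed >= threshold_frac * peak, merge_gap, min_dur
        )
        if not regions:
            raise ValueError(f"no repetition detected in {phase} phase")
        segs[phase] = regions
        peaks[phase] = float(peak)
    lifts, lowers = segs["lift"], segs["lower"]
    if len(lifts) != len(lowers):
        raise ValueError(
            f"unpaired phases: {len(lifts)} lift vs {len(lowers)} lower regions"
        )
    for (lon, loff), (won, woff) in zip(lifts, lowers):
        if not (lon < loff < won < woff):
            raise ValueError("overlapping or mis-ordered lift/lower phases")
    return [
        PhaseSegmentation(
            "lift",
            np.array([r[0] for r in lifts]),
            np.array([r[1] for r in lifts]),
            peaks["lift"],
        ),
        PhaseSegmentation(
            "lower",
            np.array([r[0] for r in lowers]),
            np.array([r[1] for r in lowers]),
            peaks["lower"],
        ),
    ]


def pair_repetitions(
    segmentation: list[PhaseSegmentation],
) -> list[tuple[int, int]]:
    """Full-repetition bounds (lift onset to lower offset), one per rep."""
    lift = next(s for s in segmentation if s.phase == "lift")
    lower = next(s for s in segmentation if s.phase == "lower")
    return list(zip(lift.onsets.tolist(), lower.offsets.tolist()))


def time_normalize(curve: np.ndarray, n_points: int = 100) -> np.ndarray:
    """Resample a curve onto ``n_points`` equally spaced abscissae spanning
    the phase, by piecewise-linear interpolation.  Endpoints are preserved.

    1-D input gives a 1-D output; 2-D input ``(samples, channels)`` is
    normalized per column.
    """
    c = np.asarray(curve, dtype=float)
    if c.shape[0] < 2:
        raise ValueError("curve must have at least 2 samples")
    x_old = np.arange(c.shape[0], dtype=float)
    x_new = np.linspace(0.0, c.shape[0] - 1.0, n_points)
    if c.ndim == 1:
        return np.interp(x_new, x_old, c)
    if c.ndim == 2:
        return np.column_stack(
            [np.interp(x_new, x_old, c[:, j]) for j in range(c.shape[1])]
        )
    raise ValueError("curve must be 1-D or 2-D")
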