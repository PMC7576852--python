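"""Synthetic lifting datasets with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
participant repeatedly lifts and lowers a load; 14 muscles are driven by 3
latent modes (``EMG = W_true @ H``); each repetition's mode activations
fluctuate around phase-specific templates with a planted covariance whose
goal-equivalent and non-goal-equivalent components (with respect to a
planted Jacobian) are controlled exactly; pelvis/trunk displacement
fluctuations are linearly driven by the same mode fluctuations.

Design choices that make every processing stage verifiable:

* The cardiac artifact is a periodic pulse train whose harmonics all lie
  below 40 Hz, so the spectral high-pass removes it by construction.
* The EMG carrier is envelope-modulated band-limited (40-450 Hz) noise, so
  rectification plus low-pass recovers the planted envelope up to a gain.
  The carrier repeats exactly once per repetition, so its rectification
  ripple is identical across repetitions and cancels from the mean-free
  inter-repetition fluctuations that the UCM stage analyses.
* Muscle weights and activation templates are rescaled (once, from a
  noiseless probe) so that each channel's per-repetition envelope maximum
  is one; the pipeline's amplitude normalization is then a near-identity
  and the planted ``W_true`` / covariance live in the same coordinates the
  pipeline measures.
* The acromion's vertical velocity is a smooth per-phase bump; the stored
  cycle bounds are obtained by applying the same 10%-of-peak threshold
  rule the segmentation stage uses, on the generated velocity itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from . import kin
from .datatypes import EmgRecording, MarkerRecording
from .ucm import null_row_bases

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "SynthDataset",
    "GroupEffects",
    "CohortMember",
    "plant_covariance",
    "generate_dataset",
    "generate_cohort",
    "generate_h_table",
    "generate_epoch_table",
    "DEFAULT_MUSCLES",
]

#: 14 retained muscles (rectus abdominis already excluded).
DEFAULT_MUSCLES = [
    "TA", "SOL", "GL", "VL", "RF", "BicepsF", "ST", "GMax",
    "EO", "Longis", "Ileoc", "LatsD", "BicepsB", "AntDelt",
]

MARKER_LABELS = ["LCAL", "RCAL", "LMTP1", "RMTP1", "RACR", "PEL"]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of one synthetic participant.

    Defaults mirror the lifting protocol the analysis targets: 20
    repetitions per phase, 14 muscles driven by 3 modes, 100-point
    normalized cycles, EMG at 1000 Hz and motion capture at 250 Hz, with
    lift/lower durations near the group means of the task (1.1 / 1.2 s).
    """

    n_muscles: int = 14
    n_modes: int = 3
    n_reps: int = 20
    n_points: int = 100
    fs_emg: float = 1000.0
    fs_mocap: float = 250.0
    lift_duration: float = 1.1  # seconds
    lower_duration: float = 1.2  # seconds
    pause_duration: float = 0.3  # seconds between phases / repetitions
    lift_height: float = 0.55  # metres of acromion rise per repetition
    noise_cv: float = 0.05  # multiplicative EMG noise coefficient of variation
    ecg_amplitude: float = 0.5  # cardiac artifact scale, relative to mean envelope
    ecg_rate: float = 1.2  # Hz
    gev_level: float = 4e-3  # planted goal-equivalent variance per DOF
    ngev_level: float = 2e-3  # planted non-goal-equivalent variance per DOF
    delta_bandwidth_hz: float | None = 4.5  # bandwidth of inter-rep fluctuations
    jacobian_scale: float = 0.002  # metres of displacement per unit mode fluctuation
    disp_noise: float = 2e-5  # metres of residual displacement noise per cycle point
    h_offset: np.ndarray | float | None = None  # additive offset on H templates
    seed: int = 0

    def validate(self) -> None:
        counts = dict(n_muscles=self.n_muscles, n_modes=self.n_modes,
                      n_reps=self.n_reps, n_points=self.n_points)
        for name, val in counts.items():
            if val < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_modes >= self.n_muscles:
            raise ValueError("n_modes must be smaller than n_muscles")
        if self.n_reps < 3:
            raise ValueError("n_reps must be >= 3 for covariance estimation")
        if self.fs_emg <= 2 * 5.0:
            raise ValueError("fs_emg must exceed twice the envelope cutoff")
        ratio = self.fs_emg / self.fs_mocap
        if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
            raise ValueError("fs_emg must be an integer multiple of fs_mocap")
        if self.noise_cv < 0 or self.ecg_amplitude < 0:
            raise ValueError("noise levels must be nonnegative")
        if self.gev_level <= 0 or self.ngev_level <= 0:
            raise ValueError("variance levels must be positive")


@dataclass
class SynthTruth:
    """Ground truth planted in a synthetic dataset."""

    W_true: np.ndarray  # (n_muscles, n_modes), columns sum to 1
    H_templates: dict[str, np.ndarray]  # phase -> (n_modes, n_points)
    H_reps: dict[str, np.ndarray]  # phase -> (n_reps, n_modes, n_points)
    J_true: dict[str, np.ndarray]  # segment -> (2, n_modes)
    C_true: np.ndarray  # (n_modes, n_modes)
    gev_true: float
    ngev_true: float
    ima_true: float
    cycle_bounds: dict[str, tuple[np.ndarray, np.ndarray]]  # phase -> (onsets, offsets), mocap samples
    acromion_velocity: np.ndarray  # backward-difference vertical velocity, mocap rate
    clip_fraction: float = 0.0


@dataclass
class SynthDataset:
    emg: EmgRecording
    markers: MarkerRecording
    truth: SynthTruth
    config: SynthConfig = field(default=None)  # type: ignore[assignment]


@dataclass(frozen=True)
class GroupEffects:
    """Planted group-level effect: additive on the H activation templates,
    multiplicative on the planted variance levels."""

    h_offset: np.ndarray | float | None = None
    gev_scale: float = 1.0
    ngev_scale: float = 1.0


@dataclass
class CohortMember:
    subject: str
    group: str
    dataset: SynthDataset


def plant_covariance(
    J: np.ndarray,
    gev_level: float,
    ngev_level: float,
    seed: int | None = None,
) -> np.ndarray:
    """Construct an ``n x n`` covariance with exactly the requested
    goal-equivalent and non-goal-equivalent variance per DOF.

    The covariance is ``Q diag(v) Q'`` where ``Q`` stacks orthonormal bases
    of null(J) and of range(J'); the eigenvalues within each subspace are
    spread randomly (seeded) but constrained so the subspace traces hit the
    requested levels exactly.
    """
    j = np.atleast_2d(np.asarray(J, dtype=float))
    d, n = j.shape
    if n < 3:
        raise ValueError("need at least 3 DOFs")
    if gev_level <= 0 or ngev_level <= 0:
        raise ValueError("variance levels must be positive")
    N, R = null_row_bases(j, d)  # raises "degenerate Jacobian" on rank loss
    rng = np.random.default_rng(seed)
    if seed is None:
        v_null = np.full(n - d, gev_level)
        v_row = np.full(d, ngev_level)
    else:
        v_null = rng.uniform(0.5, 1.5, n - d)
        v_null *= (n - d) * gev_level / v_null.sum()
        v_row = rng.uniform(0.5, 1.5, d)
        v_row *= d * ngev_level / v_row.sum()
    Q = np.hstack([N, R])
    C = Q @ np.diag(np.concatenate([v_null, v_row])) @ Q.T
    return (C + C.T) / 2


# ---------------------------------------------------------------------------
# building blocks of the synthetic participant


def _mode_templates(cfg: SynthConfig) -> dict[str, np.ndarray]:
    """Smooth per-phase activation templates: one Gaussian burst per mode,
    bursts staggered across the cycle over a small tonic baseline.

    The baseline is kept low so that each mode's activation nearly
    vanishes where the others peak; this makes the planted factorization
    essentially unique, which is what allows NMF to recover the planted
    coordinates (rather than an equally good obliquely mixed solution).
    """
    t = np.linspace(0.0, 1.0, cfg.n_points)
    out = {}
    for phase, (centers0, width) in (
        ("lift", (0.20, 0.10)),
        ("lower", (0.26, 0.12)),
    ):
        centers = centers0 + np.arange(cfg.n_modes) * (
            (0.82 - centers0) / max(cfg.n_modes - 1, 1)
        )
        rows = [0.04 + 0.96 * np.exp(-((t - c) ** 2) / (2 * width**2)) for c in centers]
        out[phase] = np.vstack(rows)
    return out


def _muscle_weights(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Block-structured nonnegative weights: each muscle is dominated by
    one mode (round-robin assignment, seeded jitter) with small seeded
    cross-mode loadings, so every mode has several near-exclusive anchor
    muscles and the factorization stays identifiable."""
    w = np.abs(rng.normal(0.0, 0.02, size=(cfg.n_muscles, cfg.n_modes)))
    for m in range(cfg.n_muscles):
        w[m, m % cfg.n_modes] = 0.7 + 0.6 * rng.random()
    return w


def _draw_jacobian(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Random full-row-rank 2 x n_modes Jacobian at the configured scale."""
    for _ in range(100):
        j = rng.normal(0.0, cfg.jacobian_scale, size=(2, cfg.n_modes))
        s = np.linalg.svd(j, compute_uv=False)
        if s[-1] > 0.2 * s[0]:
            return j
    raise RuntimeError("could not draw a well-conditioned Jacobian")


def _phase_velocity_profile(n: int, peak: float) -> np.ndarray:
    """Velocity bump: a smooth sin^2 hump riding on a 20%-of-peak shoulder.

    The shoulder makes the 10%-of-peak threshold crossing a step edge at
    the phase boundary, so the small velocity wiggle contributed by the
    planted displacement fluctuations cannot shift the detected onsets
    between repetitions: rep-to-rep window jitter would alias the steep
    base trajectory into the mean-free fluctuation signals.  Low-pass
    marker filtering smears the edge into a constant few-sample widening
    of the detected windows — identical in every repetition, hence
    harmless to the repetition-wise analysis."""
    i = np.arange(n)
    return peak * (0.35 + 0.65 * np.sin(np.pi * i / (n - 1)) ** 2)


def _interp_track(
    knot_pos: np.ndarray, knot_val: np.ndarray, n_total: int
) -> np.ndarray:
    """Piecewise-linear track through (position, value) knots, held flat
    before the first and after the last knot."""
    return np.interp(np.arange(n_total, dtype=float), knot_pos, knot_val)


def _band_limited_carrier(
    rng: np.random.Generator, n_period: int, fs: float,
    band: tuple[float, float] = (40.0, 450.0),
) -> np.ndarray:
    """One period of zero-mean band-limited noise with mean absolute value
    one.  FFT-based band-limiting makes the period seamless when tiled."""
    white = rng.standard_normal(n_period)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_period, d=1.0 / fs)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    x = np.fft.irfft(spec, n=n_period)
    return x / np.mean(np.abs(x))


def _ecg_waveform(
    rng: np.random.Generator, n: int, fs: float, rate: float, cutoff: float = 40.0
) -> np.ndarray:
    """Periodic pulse-train-like artifact: harmonics of ``rate`` strictly
    below ``cutoff`` with 1/h amplitudes and random phases, unit peak."""
    t = np.arange(n) / fs
    wave = np.zeros(n)
    h = 1
    while h * rate < cutoff:
        wave += np.sin(2 * np.pi * h * rate * t + rng.uniform(0, 2 * np.pi)) / h
        h += 1
    peak = np.max(np.abs(wave))
    return wave / peak if peak > 0 else wave


def generate_dataset(config: SynthConfig) -> SynthDataset:
    """Generate one synthetic participant (EMG + markers + ground truth).

    Deterministic for a fixed config: the same seed yields byte-identical
    arrays.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    fsm, fse = cfg.fs_mocap, cfg.fs_emg
    ratio = int(round(fse / fsm))
    phases = ("lift", "lower")

    # --- latent structure -------------------------------------------------
    H0 = _mode_templates(cfg)  # raw templates, peak ~1
    W0 = _muscle_weights(cfg, rng)
    # Noiseless probe: rescale so every channel's envelope maximum over a
    # full repetition equals one, then renormalize W columns to sum to one.
    # The planted truth then lives in the coordinates the pipeline measures
    # after its per-channel amplitude normalization.
    probe = W0 @ np.hstack([H0[p] for p in phases])
    chan_max = probe.max(axis=1)
    SW = W0 / chan_max[:, None]
    d1 = SW.sum(axis=0)
    W_true = SW / d1
    H_eff = {p: d1[:, None] * H0[p] for p in phases}
    if cfg.h_offset is not None:
        off = np.asarray(cfg.h_offset, dtype=float)
        H_eff = {p: np.clip(H_eff[p] + off, 0.05, None) for p in phases}

    J = _draw_jacobian(cfg, rng)
    J_true = {"pelvis": J, "trunk": J.copy()}
    C_true = plant_covariance(
        J, cfg.gev_level, cfg.ngev_level, seed=int(rng.integers(2**31 - 1))
    )
    chol = np.linalg.cholesky(C_true)

    # Per-repetition activations: template + mode fluctuations with
    # per-cycle-point covariance C_true.  The fluctuations are band-limited
    # below the envelope cutoff (exactly rescaled so the per-point
    # covariance is still C_true): variability the envelope stage cannot
    # transmit would be planted but unrecoverable by construction.
    durations = {"lift": cfg.lift_duration, "lower": cfg.lower_duration}
    delta: dict[str, np.ndarray] = {}
    H_reps: dict[str, np.ndarray] = {}
    clipped = 0
    total = 0
    for p in phases:
        z = rng.standard_normal((cfg.n_reps, cfg.n_points, cfg.n_modes))
        if cfg.delta_bandwidth_hz is not None:
            # keep cycle-axis Fourier components up to F cycles per phase
            F = max(1, int(round(cfg.delta_bandwidth_hz * durations[p])))
            spec = np.fft.rfft(z, axis=1)
            spec[:, F + 1 :, :] = 0.0
            z = np.fft.irfft(spec, n=cfg.n_points, axis=1)
            z *= np.sqrt(cfg.n_points / (2 * F + 1))
        dlt = z @ chol.T  # (reps, points, modes)
        h = H_eff[p].T[None, :, :] + dlt  # (reps, points, modes)
        clipped += int(np.sum(h < 0))
        total += h.size
        delta[p] = dlt
        H_reps[p] = np.clip(h, 0.0, None).transpose(0, 2, 1)  # (reps, modes, points)

    # --- timeline (mocap samples; EMG = ratio x) ---------------------------
    n_lift = int(round(cfg.lift_duration * fsm))
    n_lower = int(round(cfg.lower_duration * fsm))
    n_gap = int(round(cfg.pause_duration * fsm))
    period = n_lift + n_gap + n_lower + n_gap
    lead = n_gap
    n_mocap = lead + cfg.n_reps * period + n_gap
    n_emg = n_mocap * ratio

    spans: dict[str, list[tuple[int, int]]] = {"lift": [], "lower": []}
    for r in range(cfg.n_reps):
        s = lead + r * period
        spans["lift"].append((s, s + n_lift - 1))
        s2 = s + n_lift + n_gap
        spans["lower"].append((s2, s2 + n_lower - 1))

    def knots(values_per_phase: dict[str, np.ndarray], scale: int) -> tuple[np.ndarray, np.ndarray]:
        """Collect (position, value) knots in time order across all phase
        occurrences; values_per_phase[p] has shape (n_reps, n_points)."""
        pos_list, val_list = [], []
        for r in range(cfg.n_reps):
            for p in phases:
                on, off = spans[p][r]
                pos = (on + (off - on) * np.arange(cfg.n_points) / (cfg.n_points - 1))
                pos_list.append(pos * scale)
                val_list.append(values_per_phase[p][r])
        return np.concatenate(pos_list), np.concatenate(val_list)

    # --- EMG ---------------------------------------------------------------
    env = np.empty((cfg.n_muscles, n_emg))
    h_tracks = np.empty((cfg.n_modes, n_emg))
    for k in range(cfg.n_modes):
        pos, val = knots({p: H_reps[p][:, k, :] for p in phases}, ratio)
        h_tracks[k] = _interp_track(pos, val, n_emg)
    env[:] = W_true @ h_tracks

    # Carrier and multiplicative amplitude noise both repeat exactly once
    # per repetition, so the inter-repetition variability of the envelopes
    # comes solely from the planted mode fluctuations (the generator's
    # contract is a controlled GEV:NGEV ratio of that variability).
    emg = np.empty_like(env)
    n_period_emg = period * ratio
    n_tiles = n_emg // n_period_emg + 1
    for m in range(cfg.n_muscles):
        carrier = _band_limited_carrier(rng, n_period_emg, fse)
        tiled = np.tile(carrier, n_tiles)[:n_emg]
        emg[m] = env[m] * tiled
    if cfg.noise_cv > 0:
        for m in range(cfg.n_muscles):
            gain = 1.0 + cfg.noise_cv * rng.standard_normal(n_period_emg)
            emg[m] *= np.tile(gain, n_tiles)[:n_emg]
    if cfg.ecg_amplitude > 0:
        ecg = _ecg_waveform(rng, n_emg, fse, cfg.ecg_rate)
        emg += cfg.ecg_amplitude * float(env.mean()) * ecg[None, :]

    # --- markers -----------------------------------------------------------
    peak_lift = cfg.lift_height * fsm / _phase_velocity_profile(n_lift, 1.0).sum()
    peak_lower = cfg.lift_height * fsm / _phase_velocity_profile(n_lower, 1.0).sum()
    v_base = np.zeros(n_mocap)
    for on, off in spans["lift"]:
        v_base[on : off + 1] = _phase_velocity_profile(n_lift, peak_lift)
    for on, off in spans["lower"]:
        v_base[on : off + 1] = -_phase_velocity_profile(n_lower, peak_lower)
    z_base = 1.0 + np.cumsum(v_base) / fsm

    # Smooth taper to zero around every phase edge.  The vertical
    # acromion fluctuation is masked there so the velocity-threshold
    # crossings are identical in every repetition: any rep-to-rep window
    # jitter would alias the steep base trajectory into the mean-free
    # displacement fluctuations and swamp the planted J.delta signal.
    edge_mask = np.ones(n_mocap)
    w_edge = 20  # samples of half-width around each phase edge
    for p in phases:
        for span in spans[p]:
            for e in span:
                idx = np.arange(max(e - w_edge, 0), min(e + w_edge + 1, n_mocap))
                u = np.clip(np.abs(idx - e) / w_edge, 0.0, 1.0)
                notch = 0.5 - 0.5 * np.cos(np.pi * u)  # 0 at the edge -> 1
                edge_mask[idx] = np.minimum(edge_mask[idx], notch)

    def fluct_tracks(j: np.ndarray, mask_vertical: bool) -> tuple[np.ndarray, np.ndarray]:
        """AP and vertical displacement fluctuation tracks J.delta (+
        residual noise)."""
        out = []
        for row in range(2):
            per_phase = {}
            for p in phases:
                vals = delta[p] @ j[row]  # (reps, points)
                if cfg.disp_noise > 0:
                    vals = vals + cfg.disp_noise * rng.standard_normal(vals.shape)
                per_phase[p] = vals
            pos, val = knots(per_phase, 1)
            track = _interp_track(pos, val, n_mocap)
            track = gaussian_filter1d(track, sigma=0.02 * fsm)
            if row == 1 and mask_vertical:
                track = track * edge_mask
            out.append(track)
        return out[0], out[1]

    trunk_ap_f, trunk_v_f = fluct_tracks(J_true["trunk"], mask_vertical=True)
    pelvis_ap_f, pelvis_v_f = fluct_tracks(J_true["pelvis"], mask_vertical=False)

    racr = np.column_stack([
        np.full(n_mocap, 0.05),                      # lateral
        0.25 + 0.15 * (z_base - z_base.min()) / max(np.ptp(z_base), 1e-9) + trunk_ap_f,
        z_base + trunk_v_f,                          # vertical
    ])
    pel_z = 0.9 + 0.45 * (z_base - z_base.min())
    pel = np.column_stack([
        np.zeros(n_mocap),
        0.18 + 0.08 * (z_base - z_base.min()) / max(np.ptp(z_base), 1e-9) + pelvis_ap_f,
        pel_z + pelvis_v_f,
    ])
    static = {
        "LCAL": (-0.05, -0.15, 0.03),
        "RCAL": (0.05, -0.15, 0.03),
        "LMTP1": (-0.06, 0.07, 0.02),
        "RMTP1": (0.06, 0.07, 0.02),
    }
    positions = np.empty((n_mocap, len(MARKER_LABELS), 3))
    for i, lab in enumerate(MARKER_LABELS):
        if lab in static:
            positions[:, i, :] = static[lab]
        elif lab == "RACR":
            positions[:, i, :] = racr
        else:  # PEL
            positions[:, i, :] = pel

    # --- stored cycle bounds: the 10%-of-peak rule applied to the actual
    # generated velocity (backward difference of the final RACR height) ----
    racr_z = positions[:, MARKER_LABELS.index("RACR"), 2]
    v_actual = np.empty(n_mocap)
    v_actual[0] = 0.0
    v_actual[1:] = np.diff(racr_z) * fsm
    segs = kin.segment_phases(v_actual, fsm)
    bounds = {
        s.phase: (s.onsets.copy(), s.offsets.copy()) for s in segs
    }
    for p in phases:
        if len(bounds[p][0]) != cfg.n_reps:
            raise RuntimeError(
                f"synthetic velocity produced {len(bounds[p][0])} {p} phases, "
                f"expected {cfg.n_reps}"
            )

    labels = (
        list(DEFAULT_MUSCLES)
        if cfg.n_muscles == len(DEFAULT_MUSCLES)
        else [f"m{i + 1:02d}" for i in range(cfg.n_muscles)]
    )
    truth = SynthTruth(
        W_true=W_true,
        H_templates=H_eff,
        H_reps=H_reps,
        J_true=J_true,
        C_true=C_true,
        gev_true=cfg.gev_level,
        ngev_true=cfg.ngev_level,
        ima_true=float(np.log(cfg.gev_level / cfg.ngev_level)),
        cycle_bounds=bounds,
        acromion_velocity=v_actual,
        clip_fraction=clipped / max(total, 1),
    )
    return SynthDataset(
        emg=EmgRecording(emg.T, fse, labels),
        markers=MarkerRecording(positions, fsm, list(MARKER_LABELS)),
        truth=truth,
        config=cfg,
    )


def generate_cohort(
    config: SynthConfig,
    n_per_group: int = 16,
    group_effects: dict[str, GroupEffects] | None = None,
    groups: tuple[str, ...] = ("con", "rLBP", "cLBP"),
) -> list[CohortMember]:
    """Generate a labelled cohort; each subject gets an independent seed
    derived from the config seed, and its group's planted effects."""
    group_effects = group_effects or {}
    rng = np.random.default_rng(config.seed)
    members = []
    for g in groups:
        eff = group_effects.get(g, GroupEffects())
        for i in range(n_per_group):
            sub_cfg = replace(
                config,
                seed=int(rng.integers(2**31 - 1)),
                gev_level=config.gev_level * eff.gev_scale,
                ngev_level=config.ngev_level * eff.ngev_scale,
                h_offset=eff.h_offset,
            )
            members.append(
                CohortMember(
                    subject=f"{g}{i + 1:02d}", group=g,
                    dataset=generate_dataset(sub_cfg),
                )
            )
    return members


def generate_h_table(
    n_per_group: int = 16,
    seed: int = 0,
    groups: tuple[str, ...] = ("con", "rLBP", "cLBP"),
    phases: tuple[str, ...] = ("lift", "lower"),
    n_points: int = 100,
    group_offsets: dict[str, np.ndarray | float] | None = None,
    sd_subject: float = 0.15,
    sd_noise: float = 0.2,
) -> pd.DataFrame:
    """Light-weight cohort of per-subject mode-activation curves for
    exercising the curve-level inference directly (no EMG synthesis).

    The generating model matches the inference model's assumptions: a
    smooth phase-specific population curve, optional planted group offset
    curves, a subject-specific intercept and i.i.d. point noise.
    """
    rng = np.random.default_rng(seed)
    group_offsets = group_offsets or {}
    t = np.linspace(0.0, 1.0, n_points)
    base = {
        "lift": 0.5 + 0.35 * np.exp(-((t - 0.35) ** 2) / (2 * 0.15**2)),
        "lower": 0.45 + 0.3 * np.exp(-((t - 0.6) ** 2) / (2 * 0.18**2)),
    }
    rows = []
    for g in groups:
        off = np.broadcast_to(
            np.asarray(group_offsets.get(g, 0.0), dtype=float), (n_points,)
        )
        for i in range(n_per_group):
            subj = f"{g}{i + 1:02d}"
            b = rng.normal(0.0, sd_subject)
            for p in phases:
                curve = base.get(p, base["lift"])
                vals = curve + off + b + rng.normal(0.0, sd_noise, n_points)
                rows.append(
                    pd.DataFrame(
                        {
                            "subject": subj,
                            "group": g,
                            "phase": p,
                            "cycle": np.arange(1, n_points + 1),
                            "value": vals,
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)


def generate_epoch_table(
    n_per_group: int = 16,
    seed: int = 0,
    groups: tuple[str, ...] = ("con", "rLBP", "cLBP"),
    segments: tuple[str, ...] = ("pelvis", "trunk"),
    baseline_log_gev: float = -5.1,
    baseline_log_ngev: float = -5.8,
    ima_effects: dict[str, float] | None = None,
    sd_subject: float = 0.15,
    sd_noise: float = 0.15,
) -> pd.DataFrame:
    """Epoch-level summaries drawn directly from the mixed-model data
    generating process (for exercising the epoch inference).

    ``ima_effects`` maps ``"factor:level"`` keys (e.g. ``"phase:lower"``,
    ``"epoch:late"``, ``"group:cLBP"``) to additive IMA shifts, applied on
    the log-GEV side.
    """
    rng = np.random.default_rng(seed)
    ima_effects = ima_effects or {}
    rows = []
    for g in groups:
        for i in range(n_per_group):
            subj = f"{g}{i + 1:02d}"
            b = rng.normal(0.0, sd_subject)
            for seg in segments:
                for phase in ("lift", "lower"):
                    for epoch in ("early", "late"):
                        shift = (
                            ima_effects.get(f"group:{g}", 0.0)
                            + ima_effects.get(f"phase:{phase}", 0.0)
                            + ima_effects.get(f"epoch:{epoch}", 0.0)
                        )
                        lg = baseline_log_gev + shift + b + rng.normal(0, sd_noise)
                        ln = baseline_log_ngev + b + rng.normal(0, sd_noise)
                        rows.append(
                            dict(
                                subject=subj, group=g, segment=seg,
                                phase=phase, epoch=epoch,
                                ima=lg - ln, log_gev=lg, log_ngev=ln,
                            )
                        )
    return pd.DataFrame(rows)
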