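"""Uncontrolled-manifold (UCM) variance decomposition.

At each 1% of the normalized movement cycle, the mean-free mode
activations across repetitions (``dH``, reps x n) are linearly related to
the mean-free segment displacements (``dDisp``, reps x d) through a
Jacobian ``J`` (d x n) estimated by no-intercept least squares.  The
covariance ``C`` of ``dH`` is then projected onto the null space of ``J``
(fluctuations that leave the displacement goal invariant) and the row
space of ``J`` (fluctuations that perturb it):

    GEV  = trace(N' C N) / (n - d),   N an orthonormal basis of null(J)
    NGEV = trace(R' C R) / d,         R an orthonormal basis of range(J')
    IMA  = log(GEV / NGEV)

Both variances are normalized per subspace dimension; the index of motor
abundance (IMA) is positive when goal-equivalent variability dominates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CycleFluctuations",
    "JacobianAtCycle",
    "UcmSeries",
    "EpochSummary",
    "mean_free",
    "null_row_bases",
    "estimate_jacobian",
    "gev",
    "ngev",
    "ima",
    "ucm_series",
    "epoch_average",
]

#: Relative singular-value tolerance for rank decisions.
_RANK_RTOL = 1e-10


@dataclass
class CycleFluctuations:
    """Mean-free activations and displacements at one cycle point."""

    dH: np.ndarray  # (reps, n_modes)
    dDisp: np.ndarray  # (reps, d)


@dataclass
class JacobianAtCycle:
    J: np.ndarray  # (d, n_modes)
    adj_r2: np.ndarray  # per outcome row
    rmse: np.ndarray  # per outcome row, same units as dDisp


@dataclass
class UcmSeries:
    """Per-cycle-point UCM quantities for one participant/phase/outcome."""

    C: np.ndarray  # (n_points, n, n)
    gev: np.ndarray  # (n_points,)
    ngev: np.ndarray  # (n_points,)
    ima: np.ndarray  # (n_points,), NaN where undefined
    n_modes: int
    d: int
    phase: str = "lift"
    segment: str = "pelvis"
    jacobians: np.ndarray | None = None  # (n_points, d, n)
    adj_r2: np.ndarray | None = None  # (n_points, d)
    rmse: np.ndarray | None = None  # (n_points, d)

    @property
    def n_points(self) -> int:
        return len(self.gev)


@dataclass
class EpochSummary:
    phase: str
    epoch: str  # "early" (points 1-50) or "late" (points 51-100)
    mean_ima: float
    mean_log_gev: float
    mean_log_ngev: float
    segment: str = "pelvis"
    n_excluded: int = 0
    exclusion_warning: bool = False


def mean_free(values: np.ndarray) -> np.ndarray:
    """Subtract the across-repetition mean of each column."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 2:
        raise ValueError("values must be 2-D (reps x m)")
    if v.shape[0] < 3:
        raise ValueError("insufficient repetitions (need >= 3)")
    return v - v.mean(axis=0, keepdims=True)


def null_row_bases(J: np.ndarray, d: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal bases of null(J) and of the column space of J',
    via singular value decomposition.

    Returns ``(N, R)`` with shapes ``(n, n - d)`` and ``(n, d)``.
    """
    j = np.atleast_2d(np.asarray(J, dtype=float))
    d_req = j.shape[0] if d is None else d
    _, s, vt = np.linalg.svd(j, full_matrices=True)
    rank = int(np.sum(s > s[0] * _RANK_RTOL)) if s.size and s[0] > 0 else 0
    if rank < d_req:
        raise ValueError("degenerate Jacobian: rank below the outcome dimension")
    return vt[rank:].T, vt[:rank].T


def estimate_jacobian(fluct: CycleFluctuations) -> JacobianAtCycle:
    """No-intercept least-squares fit of each displacement component on the
    mode fluctuations; coefficients arranged as the d x n Jacobian.

    Both inputs are mean-free, so an intercept would be estimated near zero
    and is omitted.  A rank-deficient ``dH`` raises instead of silently
    falling back to a pseudo-inverse.
    """
    dh = np.asarray(fluct.dH, dtype=float)
    dd = np.atleast_2d(np.asarray(fluct.dDisp, dtype=float))
    if dd.shape[0] != dh.shape[0]:
        raise ValueError("dH and dDisp must have equal repetition counts")
    reps, n = dh.shape
    if np.linalg.matrix_rank(dh, tol=None) < n:
        raise ValueError("degenerate fluctuations: dH is rank deficient")
    coef, _, _, _ = np.linalg.lstsq(dh, dd, rcond=None)
    J = coef.T  # (d, n)
    pred = dh @ coef
    resid = dd - pred
    sse = (resid**2).sum(axis=0)
    sst = (dd**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - sse / sst
        adj = 1.0 - (1.0 - r2) * (reps - 1) / max(reps - n - 1, 1)
    rmse = np.sqrt(sse / reps)
    return JacobianAtCycle(J=J, adj_r2=adj, rmse=rmse)


def _check_cov(C: np.ndarray, n: int) -> np.ndarray:
    c = np.asarray(C, dtype=float)
    if c.shape != (n, n):
        raise ValueError(f"C must be {n}x{n}")
    if not np.allclose(c, c.T, atol=1e-8 * max(1.0, np.abs(c).max())):
        raise ValueError("C must be symmetric")
    return c


def gev(J: np.ndarray, C: np.ndarray, n: int | None = None, d: int | None = None) -> float:
    """Goal-equivalent variance per null-space dimension:
    ``trace(N' C N) / (n - d)``."""
    j = np.atleast_2d(np.asarray(J, dtype=float))
    d = j.shape[0] if d is None else d
    n = j.shape[1] if n is None else n
    c = _check_cov(C, n)
    N, _ = null_row_bases(j, d)
    return float(np.trace(N.T @ c @ N) / (n - d))


def ngev(J: np.ndarray, C: np.ndarray, d: int | None = None) -> float:
    """Non-goal-equivalent variance per row-space dimension:
    ``trace(R' C R) / d``."""
    j = np.atleast_2d(np.asarray(J, dtype=float))
    d = j.shape[0] if d is None else d
    c = _check_cov(C, j.shape[1])
    _, R = null_row_bases(j, d)
    return float(np.trace(R.T @ c @ R) / d)


def ima(gev_val: float, ngev_val: float) -> float:
    """Index of motor abundance: natural log of GEV/NGEV.

    Nonpositive or undefined inputs propagate as NaN rather than +/-inf so
    downstream epoch averages can exclude (and count) them explicitly.
    """
    if not np.isfinite(gev_val) or not np.isfinite(ngev_val):
        return float("nan")
    if gev_val <= 0 or ngev_val <= 0:
        return float("nan")
    return float(np.log(gev_val / ngev_val))


def ucm_series(
    H_cycles: np.ndarray,
    disp_cycles: np.ndarray,
    phase: str = "lift",
    segment: str = "pelvis",
) -> UcmSeries:
    """Run the per-cycle-point UCM decomposition.

    Parameters
    ----------
    H_cycles
        Mode activations, shape ``(reps, n_modes, n_points)``.
    disp_cycles
        Segment displacements, shape ``(reps, d, n_points)``.
    """
    h = np.asarray(H_cycles, dtype=float)
    dsp = np.asarray(disp_cycles, dtype=float)
    if h.ndim != 3 or dsp.ndim != 3:
        raise ValueError("H_cycles and disp_cycles must be 3-D")
    if h.shape[0] != dsp.shape[0] or h.shape[2] != dsp.shape[2]:
        raise ValueError("repetition/point counts of H and displacements differ")
    reps, n, pts = h.shape
    d = dsp.shape[1]
    C = np.empty((pts, n, n))
    g = np.empty(pts)
    ng = np.empty(pts)
    im = np.empty(pts)
    Js = np.empty((pts, d, n))
    r2 = np.empty((pts, d))
    rmse = np.empty((pts, d))
    for p in range(pts):
        try:
            dh = mean_free(h[:, :, p])
            dd = mean_free(dsp[:, :, p])
            C[p] = np.cov(dh.T, ddof=1)
            jac = estimate_jacobian(CycleFluctuations(dH=dh, dDisp=dd))
            g[p] = gev(jac.J, C[p], n=n, d=d)
            ng[p] = ngev(jac.J, C[p], d=d)
            im[p] = ima(g[p], ng[p])
            Js[p] = jac.J
            r2[p] = jac.adj_r2
            rmse[p] = jac.rmse
        except ValueError as exc:
            raise ValueError(f"cycle point {p + 1}: {exc}") from exc
    return UcmSeries(
        C=C, gev=g, ngev=ng, ima=im, n_modes=n, d=d, phase=phase,
        segment=segment, jacobians=Js, adj_r2=r2, rmse=rmse,
    )


def _nan_log_mean(x: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(x > 0, np.log(np.where(x > 0, x, 1.0)), np.nan)
    return float(np.nanmean(logs)) if np.any(np.isfinite(logs)) else float("nan")


def epoch_average(series: UcmSeries, phase: str | None = None) -> tuple[EpochSummary, EpochSummary]:
    """Average IMA (and log GEV / log NGEV) over the early (points 1-50)
    and late (points 51-100) halves of the cycle.

    Undefined points are excluded with a count; if more than 20% of an
    epoch is excluded the summary carries a warning flag.
    """
    if series.n_points % 2 != 0:
        raise ValueError("epoch averaging requires an even number of points")
    phase = series.phase if phase is None else phase
    half = series.n_points // 2
    out = []
    for name, sl in (("early", slice(0, half)), ("late", slice(half, None))):
        im = series.ima[sl]
        n_excl = int(np.sum(~np.isfinite(im)))
        out.append(
            EpochSummary(
                phase=phase,
                epoch=name,
                mean_ima=float(np.nanmean(im)) if n_excl < half else float("nan"),
                mean_log_gev=_nan_log_mean(series.gev[sl]),
                mean_log_ngev=_nan_log_mean(series.ngev[sl]),
                segment=series.segment,
                n_excluded=n_excl,
                exclusion_warning=n_excl > 0.2 * half,
            )
        )
    return out[0], out[1]
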