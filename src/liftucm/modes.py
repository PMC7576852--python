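"""Muscle-mode (synergy) extraction by non-negative matrix factorization.

A participant's phase-specific envelope cycles are concatenated into an
``n_muscles x (n_points * n_reps)`` matrix and factorized as ``X ~ W H``:
``W`` holds the relative contribution of each muscle to each mode (columns
rescaled to sum to one, with the inverse scale absorbed into ``H``) and
``H`` the temporal activation of each mode.  The retained mode number is
the smallest k whose variance-accounted-for (VAF) exceeds 90% while the
gain from one further mode is at most 3 percentage points.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning
import warnings

from .datatypes import CycleSet

__all__ = [
    "ModeDecomposition",
    "ModeMatching",
    "concatenate_cycles",
    "split_cycles",
    "run_nmf",
    "vaf_curve",
    "select_mode_number",
    "select_modes",
    "match_modes",
    "flag_contributing_muscles",
]


@dataclass
class ModeDecomposition:
    """NMF result for one participant and phase."""

    W: np.ndarray  # (n_muscles, k), columns sum to 1
    H: np.ndarray  # (k, n_points * n_reps)
    vaf_curve: np.ndarray  # VAF(%) for k = 1..len(vaf_curve)
    k_retained: int
    phase: str = "lift"
    labels: list[str] = field(default_factory=list)


@dataclass
class ModeMatching:
    """Bijection mapping subject modes onto reference modes."""

    permutation: np.ndarray  # permutation[subject_mode] = reference_mode
    correlations: np.ndarray  # Pearson r of the matched pairs

    def reorder(self, arr: np.ndarray, axis: int = 0) -> np.ndarray:
        """Reorder an array indexed by subject mode so that position j holds
        the subject mode matched to reference mode j."""
        inverse = np.argsort(self.permutation)
        return np.take(arr, inverse, axis=axis)


def concatenate_cycles(cycle_set: CycleSet) -> np.ndarray:
    """Concatenate time-normalized cycles rep-major into an
    ``n_channels x (n_points * n_reps)`` matrix (rep 1 points 1..n, then
    rep 2, ...), the NMF input layout."""
    if np.any(cycle_set.curves < 0):
        raise ValueError("cycle curves must be nonnegative for NMF input")
    ch, reps, pts = cycle_set.curves.shape
    return cycle_set.curves.reshape(ch, reps * pts)


def split_cycles(matrix: np.ndarray, n_reps: int, n_points: int) -> np.ndarray:
    """Inverse of :func:`concatenate_cycles`: reshape to
    ``(n_channels, n_reps, n_points)``."""
    m = np.asarray(matrix)
    if m.shape[1] != n_reps * n_points:
        raise ValueError("matrix width does not equal n_reps * n_points")
    return m.reshape(m.shape[0], n_reps, n_points)


def _vaf(x: np.ndarray, w: np.ndarray, h: np.ndarray) -> float:
    resid = x - w @ h
    return 100.0 * (1.0 - (resid**2).sum() / (x**2).sum())


def run_nmf(
    matrix: np.ndarray,
    k: int,
    seed: int | None = None,
    n_restarts: int = 20,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of-restarts NMF with squared Frobenius loss.

    Returns ``(W, H, vaf)`` with the columns of ``W`` rescaled to sum to
    one and the inverse scale absorbed into the rows of ``H``, leaving the
    reconstruction ``W @ H`` unchanged.
    """
    x = np.asarray(matrix, dtype=float)
    if np.any(x < 0):
        raise ValueError("NMF input must be nonnegative")
    if not np.any(x > 0):
        raise ValueError("NMF input is all zero")
    if not 1 <= k <= x.shape[0]:
        raise ValueError("k must lie in 1..n_muscles")
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for _ in range(max(n_restarts, 1)):
            model = NMF(
                n_components=k,
                init="random",
                solver="cd",
                beta_loss="frobenius",
                tol=tol,
                max_iter=max_iter,
                random_state=int(rng.integers(2**31 - 1)),
            )
            w = model.fit_transform(x)
            h = model.components_
            err = float(np.linalg.norm(x - w @ h))
            if best is None or err < best[0]:
                best = (err, w, h)
    assert best is not None
    _, w, h = best
    colsum = w.sum(axis=0)
    # a vanished component keeps scale 1 so the reconstruction is unchanged
    scale = np.where(colsum > 0, colsum, 1.0)
    w = w / scale
    h = h * scale[:, None]
    return w, h, _vaf(x, w, h)


def vaf_curve(
    matrix: np.ndarray,
    k_max: int | None = None,
    seed: int | None = None,
    n_restarts: int = 20,
    **nmf_kwargs,
) -> np.ndarray:
    """VAF(%) for k = 1..k_max (default: the muscle count)."""
    x = np.asarray(matrix, dtype=float)
    k_max = x.shape[0] if k_max is None else k_max
    rng = np.random.default_rng(seed)
    return np.array(
        [
            run_nmf(x, k, seed=int(rng.integers(2**31 - 1)),
                    n_restarts=n_restarts, **nmf_kwargs)[2]
            for k in range(1, k_max + 1)
        ]
    )


def select_mode_number(
    vaf: np.ndarray, vaf_min: float = 90.0, delta_max: float = 3.0
) -> int:
    """Smallest k with VAF(k) > ``vaf_min`` whose increment to k+1 is at
    most ``delta_max`` percentage points.  For the last entry of a
    full-length curve the increment condition is vacuously true."""
    v = np.asarray(vaf, dtype=float)
    for i, val in enumerate(v):
        if val <= vaf_min:
            continue
        if i == len(v) - 1 or v[i + 1] - val <= delta_max:
            return i + 1
    raise ValueError(
        f"no mode number satisfies VAF > {vaf_min} with increment <= "
        f"{delta_max}; VAF curve: {np.round(v, 2).tolist()}"
    )


def select_modes(
    matrix: np.ndarray,
    vaf_min: float = 90.0,
    delta_max: float = 3.0,
    seed: int | None = None,
    n_restarts: int = 20,
    **nmf_kwargs,
) -> tuple[int, np.ndarray]:
    """Apply the VAF rule, growing the curve incrementally so no more
    factorizations are run than the rule needs.  Returns ``(k, vaf_curve)``
    where the curve covers k = 1..k_selected+1 (or the full range if the
    rule is only satisfied at the muscle count)."""
    x = np.asarray(matrix, dtype=float)
    rng = np.random.default_rng(seed)
    vafs: list[float] = []
    for k in range(1, x.shape[0] + 1):
        vafs.append(
            run_nmf(x, k, seed=int(rng.integers(2**31 - 1)),
                    n_restarts=n_restarts, **nmf_kwargs)[2]
        )
        if len(vafs) >= 2 and vafs[-2] > vaf_min and vafs[-1] - vafs[-2] <= delta_max:
            return len(vafs) - 1, np.array(vafs)
    if vafs[-1] > vaf_min:
        return len(vafs), np.array(vafs)
    raise ValueError(
        f"no mode number satisfies VAF > {vaf_min} with increment <= "
        f"{delta_max}; VAF curve: {np.round(vafs, 2).tolist()}"
    )


def match_modes(W_subject: np.ndarray, W_reference: np.ndarray) -> ModeMatching:
    """Greedy assignment of subject modes to reference modes by descending
    Pearson correlation of the W columns, without replacement; ties break
    towards the lowest reference index, then the lowest subject index."""
    ws = np.asarray(W_subject, dtype=float)
    wr = np.asarray(W_reference, dtype=float)
    if ws.shape != wr.shape:
        raise ValueError("subject and reference W must have equal shape")
    k = ws.shape[1]
    if np.any(ws.std(axis=0) == 0) or np.any(wr.std(axis=0) == 0):
        raise ValueError("zero-variance W column: correlation undefined")
    corr = np.corrcoef(ws.T, wr.T)[:k, k:]
    perm = np.full(k, -1, dtype=int)
    rvals = np.zeros(k)
    free_s, free_r = set(range(k)), set(range(k))
    for _ in range(k):
        best = max(
            ((corr[s, r], -r, -s, s, r) for s in free_s for r in free_r),
        )
        _, _, _, s, r = best
        perm[s] = r
        rvals[s] = corr[s, r]
        free_s.remove(s)
        free_r.remove(r)
    return ModeMatching(permutation=perm, correlations=rvals)


def exhaustive_match(W_subject: np.ndarray, W_reference: np.ndarray) -> np.ndarray:
    """Assignment maximizing the summed correlation over all permutations
    (reference oracle for small k; O(k!))."""
    ws = np.asarray(W_subject, dtype=float)
    wr = np.asarray(W_reference, dtype=float)
    k = ws.shape[1]
    corr = np.corrcoef(ws.T, wr.T)[:k, k:]
    best_perm, best_val = None, -np.inf
    for perm in itertools.permutations(range(k)):
        val = sum(corr[s, perm[s]] for s in range(k))
        if val > best_val:
            best_val, best_perm = val, perm
    return np.array(best_perm)


def flag_contributing_muscles(
    W: np.ndarray, threshold: float | None = None
) -> np.ndarray:
    """Boolean mask of muscles contributing to each mode: a muscle is
    flagged when its W weight strictly exceeds the uniform share
    ``1 / n_muscles`` (0.071 for 14 muscles)."""
    w = np.asarray(W, dtype=float)
    if threshold is None:
        threshold = 1.0 / w.shape[0]
    return w > threshold
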