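"""Group-level statistical inference.

Two branches mirror the two questions the pipeline answers:

* **Activation curves.** Per-subject mode-activation (H) curves are
  modelled additively: group x phase cell means, a penalized smooth cycle
  effect per cell built from 15 cubic regression splines (second-order
  difference penalty, smoothing parameter chosen by generalized
  cross-validation), and subject intercepts.  Pairwise group differences
  are summarized by the contrast-cycle-difference (CCD): the predicted
  difference curve with a Bonferroni-adjusted confidence band
  ``delta_hat +/- t_{1 - alpha/(2 g)} * sqrt(var(delta_hat))`` over the
  ``g`` pairwise comparisons; a cycle point is flagged when the band
  excludes zero.

* **Epoch summaries.** IMA, log GEV and log NGEV per subject, phase and
  epoch are analyzed with a linear mixed model (fixed effects: group,
  phase, epoch and their two-way interactions; random subject intercept),
  Wald chi-square tests per effect, Benjamini-Hochberg-Yekutieli
  adjustment of the six effect p-values, and estimated-marginal-means
  pairwise contrasts for significant effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import interpolate, linalg, stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "CurveModelFit",
    "ContrastResult",
    "EpochModelResult",
    "fit_cycle_curves",
    "ccd_contrast",
    "fit_epoch_model",
    "adjust_pvalues_bhy",
    "emm_contrasts",
]

EPOCH_EFFECTS = ("group", "phase", "epoch", "group:phase", "group:epoch", "phase:epoch")


# ---------------------------------------------------------------------------
# penalized spline curves + CCD


def _bspline_basis(x: np.ndarray, xmin: float, xmax: float, size: int) -> np.ndarray:
    """Cubic B-spline design matrix with ``size`` basis functions on
    [xmin, xmax] (evenly spaced interior knots)."""
    degree = 3
    n_interior = size - degree - 1
    if n_interior < 0:
        raise ValueError("basis size must be at least 4 for cubic splines")
    interior = np.linspace(xmin, xmax, n_interior + 2)[1:-1]
    knots = np.concatenate(
        [np.repeat(xmin, degree + 1), interior, np.repeat(xmax, degree + 1)]
    )
    return interpolate.BSpline.design_matrix(
        np.clip(x, xmin, xmax), knots, degree
    ).toarray()


@dataclass
class CurveModelFit:
    """Penalized additive fit of activation curves over the cycle."""

    groups: list[str]
    phases: list[str]
    cells: list[tuple[str, str]]
    cycle_grid: np.ndarray
    beta: np.ndarray
    Vb: np.ndarray  # Bayesian posterior covariance of beta
    lam: float
    edf: float
    sigma2: float
    n_subjects: int
    n_obs: int
    _basis_grid: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    _n_cells: int = 0
    _p_spline: int = 0

    def cell_design(self, group: str, phase: str) -> np.ndarray:
        """Design rows predicting the cell's mean curve on the cycle grid
        (average subject)."""
        if (group, phase) not in self.cells:
            raise KeyError(f"unknown cell {(group, phase)!r}")
        c = self.cells.index((group, phase))
        n_grid = len(self.cycle_grid)
        p = len(self.beta)
        X = np.zeros((n_grid, p))
        X[:, c] = 1.0
        start = self._n_cells + c * self._p_spline
        X[:, start : start + self._p_spline] = self._basis_grid
        return X

    def predict(self, group: str, phase: str) -> np.ndarray:
        return self.cell_design(group, phase) @ self.beta


def fit_cycle_curves(
    h_table: pd.DataFrame,
    basis_size: int = 15,
    lam: float | None = None,
    lam_grid: np.ndarray | None = None,
) -> CurveModelFit:
    """Fit the additive curve model to a long table with columns
    ``subject, group, phase, cycle, value``.

    The design has one unpenalized intercept per group x phase cell, a
    penalized 15-function cubic regression spline per cell (constrained to
    be orthogonal to the cell intercept), and subject intercepts treated as
    ridge-penalized random effects whose variance is estimated by a moment
    (within/between) decomposition — so contrast variances include the
    between-subject component.  ``lam=None`` selects the spline smoothing
    parameter by generalized cross-validation on a log-spaced grid.
    """
    required = {"subject", "group", "phase", "cycle", "value"}
    missing = required - set(h_table.columns)
    if missing:
        raise ValueError(f"h_table is missing columns {sorted(missing)}")
    df = h_table
    groups = sorted(df["group"].unique())
    phases = sorted(df["phase"].unique())
    cells = [(g, p) for g in groups for p in phases]
    for g, p in cells:
        sub = df[(df["group"] == g) & (df["phase"] == p)]
        if sub["subject"].nunique() < 2:
            raise ValueError(f"singular design: fewer than 2 subjects in cell {(g, p)}")
    cycle = df["cycle"].to_numpy(dtype=float)
    cycle_grid = np.unique(cycle)
    y = df["value"].to_numpy(dtype=float)
    n = len(y)

    # spline basis, constrained orthogonal to the intercept over the grid
    B_grid = _bspline_basis(cycle_grid, cycle_grid.min(), cycle_grid.max(), basis_size)
    c_vec = B_grid.mean(axis=0)
    Z = linalg.null_space(c_vec[None, :])  # (size, size-1)
    basis_grid = B_grid @ Z
    p_spline = basis_grid.shape[1]
    B_obs = _bspline_basis(cycle, cycle_grid.min(), cycle_grid.max(), basis_size) @ Z

    # penalty: second-order differences on the raw spline coefficients
    D2 = np.diff(np.eye(basis_size), n=2, axis=0)
    S_spline = Z.T @ D2.T @ D2 @ Z

    # subject intercept columns (one dummy per subject, ridge-penalized)
    subj_of = df["subject"].to_numpy()
    grp_of = df["group"].to_numpy()
    subjects = sorted(df["subject"].unique())
    n_subjects = len(subjects)
    n_cells = len(cells)
    p = n_cells + n_cells * p_spline + n_subjects
    X = np.zeros((n, p))
    cell_idx = {cp: i for i, cp in enumerate(cells)}
    rows_cell = np.array([cell_idx[(g, ph)] for g, ph in zip(grp_of, df["phase"])])
    X[np.arange(n), rows_cell] = 1.0
    for c in range(n_cells):
        mask = rows_cell == c
        start = n_cells + c * p_spline
        X[mask, start : start + p_spline] = B_obs[mask]
    subj_idx = {s: i for i, s in enumerate(subjects)}
    subj_start = n_cells + n_cells * p_spline
    X[np.arange(n), subj_start + np.array([subj_idx[s] for s in subj_of])] = 1.0

    S = np.zeros((p, p))
    for c in range(n_cells):
        start = n_cells + c * p_spline
        S[start : start + p_spline, start : start + p_spline] = S_spline

    # moment estimates of the within- and between-subject variance, used to
    # set the random-intercept ridge (kappa = sigma_e^2 / sigma_b^2)
    cellpoint_mean = (
        df.assign(_cp=list(zip(grp_of, df["phase"], cycle)))
        .groupby("_cp")["value"]
        .transform("mean")
        .to_numpy()
    )
    resid0 = y - cellpoint_mean
    subj_means = pd.Series(resid0).groupby(pd.Series(subj_of)).mean()
    n_per_subj = n / n_subjects
    sigma_e2 = float(np.var(resid0 - subj_means[subj_of].to_numpy(), ddof=1))
    sigma_b2 = max(
        float(subj_means.var(ddof=1)) - sigma_e2 / n_per_subj, 1e-10
    )
    # small absolute floor keeps the system positive definite even for
    # degenerate (noise-free) inputs where the moment estimates vanish
    kappa = max(sigma_e2 / sigma_b2, 1e-8)
    R = np.zeros((p, p))
    R[subj_start:, subj_start:] = kappa * np.eye(n_subjects)

    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def solve(l: float) -> tuple[np.ndarray, float, float]:
        A = XtX + l * S + R
        cho = linalg.cho_factor(A, lower=True)
        beta = linalg.cho_solve(cho, Xty)
        edf = float(np.trace(linalg.cho_solve(cho, XtX)))
        rss = yty - 2 * beta @ Xty + beta @ XtX @ beta
        return beta, edf, max(rss, 1e-12)

    if lam is not None:
        lam_sel = float(lam)
    else:
        grid = (
            np.logspace(-2, 7, 25) if lam_grid is None else np.asarray(lam_grid)
        )
        scores = []
        for l in grid:
            _, edf, rss = solve(l)
            scores.append(n * rss / (n - edf) ** 2)
        lam_sel = float(grid[int(np.argmin(scores))])
    beta, edf, rss = solve(lam_sel)
    sigma2 = rss / max(n - edf, 1.0)
    A = XtX + lam_sel * S + R
    Vb = sigma2 * linalg.cho_solve(linalg.cho_factor(A, lower=True), np.eye(p))
    fit = CurveModelFit(
        groups=groups, phases=phases, cells=cells, cycle_grid=cycle_grid,
        beta=beta, Vb=Vb, lam=lam_sel, edf=edf, sigma2=sigma2,
        n_subjects=n_subjects, n_obs=n,
    )
    fit._basis_grid = basis_grid
    fit._n_cells = n_cells
    fit._p_spline = p_spline
    return fit


@dataclass
class ContrastResult:
    """Pairwise group-difference curve with adjusted confidence band."""

    delta: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    significant: np.ndarray
    alpha: float
    g: int
    df: float
    critical_value: float
    group_a: str = ""
    group_b: str = ""
    phase: str = ""


def ccd_critical_value(alpha: float, g: int, df: float) -> float:
    """Bonferroni-adjusted two-sided t critical value over g comparisons."""
    return float(stats.t.ppf(1.0 - alpha / (2.0 * g), df))


def ccd_contrast(
    fit: CurveModelFit,
    group_a: str,
    group_b: str,
    phase: str,
    alpha: float = 0.05,
    g: int = 6,
    df: float | None = None,
) -> ContrastResult:
    """Contrast-cycle-difference between two groups in one phase.

    The reference distribution is t with ``df`` degrees of freedom
    (default: number of subjects minus one); the band is Bonferroni
    adjusted over the ``g`` pairwise group comparisons, pointwise in the
    cycle.
    """
    for grp in (group_a, group_b):
        if grp not in fit.groups:
            raise KeyError(f"unknown group {grp!r}")
    if phase not in fit.phases:
        raise KeyError(f"unknown phase {phase!r}")
    df_eff = float(fit.n_subjects - 1) if df is None else float(df)
    Xd = fit.cell_design(group_a, phase) - fit.cell_design(group_b, phase)
    delta = Xd @ fit.beta
    var = np.einsum("ij,jk,ik->i", Xd, fit.Vb, Xd)
    crit = ccd_critical_value(alpha, g, df_eff)
    half = crit * np.sqrt(np.clip(var, 0.0, None))
    low, high = delta - half, delta + half
    return ContrastResult(
        delta=delta, ci_low=low, ci_high=high,
        significant=(low > 0) | (high < 0),
        alpha=alpha, g=g, df=df_eff, critical_value=crit,
        group_a=group_a, group_b=group_b, phase=phase,
    )


# ---------------------------------------------------------------------------
# epoch-level mixed models


def _effect_design(
    df: pd.DataFrame,
) -> tuple[np.ndarray, list[str], dict[str, list[int]], dict[str, dict[str, np.ndarray]]]:
    """Sum-to-zero (effect) coded fixed-effects design with all two-way
    interactions of group, phase and epoch."""
    codes: dict[str, dict[str, np.ndarray]] = {}
    for factor in ("group", "phase", "epoch"):
        levels = sorted(df[factor].unique())
        k = len(levels)
        mapping = {}
        for i, lev in enumerate(levels):
            if i < k - 1:
                row = np.zeros(k - 1)
                row[i] = 1.0
            else:
                row = -np.ones(k - 1)
            mapping[lev] = row
        codes[factor] = mapping
    cols: list[np.ndarray] = [np.ones(len(df))]
    names: list[str] = ["Intercept"]
    term_cols: dict[str, list[int]] = {}

    def add(term: str, block: np.ndarray, labels: list[str]) -> None:
        start = len(names)
        for j in range(block.shape[1]):
            cols.append(block[:, j])
            names.append(labels[j])
        term_cols[term] = list(range(start, len(names)))

    mats = {
        f: np.vstack([codes[f][v] for v in df[f]]) for f in ("group", "phase", "epoch")
    }
    for f in ("group", "phase", "epoch"):
        add(f, mats[f], [f"{f}[{j}]" for j in range(mats[f].shape[1])])
    for f1, f2 in (("group", "phase"), ("group", "epoch"), ("phase", "epoch")):
        a, b = mats[f1], mats[f2]
        block = np.concatenate(
            [a[:, i : i + 1] * b for i in range(a.shape[1])], axis=1
        )
        add(
            f"{f1}:{f2}", block,
            [f"{f1}:{f2}[{j}]" for j in range(block.shape[1])],
        )
    return np.column_stack(cols), names, term_cols, codes


@dataclass
class EpochModelResult:
    """Mixed-model effect tests for one response (and segment)."""

    response: str
    segment: str | None
    effects: pd.DataFrame  # columns: effect, df, chi2, p, p_adjusted
    params: np.ndarray
    cov_params: np.ndarray
    param_names: list[str]
    term_cols: dict[str, list[int]]
    codes: dict[str, dict[str, np.ndarray]]
    levels: dict[str, list[str]]
    converged: bool

    def significant_effects(self, alpha: float = 0.05) -> list[str]:
        eff = self.effects
        return eff.loc[eff["p_adjusted"] < alpha, "effect"].tolist()


def fit_epoch_model(
    epoch_table: pd.DataFrame,
    response: str,
    segment: str | None = None,
    adjust: bool = True,
) -> EpochModelResult:
    """Fit the epoch-level linear mixed model for one response.

    Fixed effects: group, phase, epoch and their two-way interactions
    (sum-to-zero coding); random subject intercept; REML.  Wald chi-square
    tests per effect; the six effect p-values are adjusted with the
    Benjamini-Hochberg-Yekutieli procedure.
    """
    df = epoch_table
    if segment is not None:
        if "segment" not in df.columns:
            raise ValueError("epoch_table has no 'segment' column")
        df = df[df["segment"] == segment]
    required = {"subject", "group", "phase", "epoch", response}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"epoch_table is missing columns {sorted(missing)}")
    df = df.dropna(subset=[response]).reset_index(drop=True)
    cell_counts = df.groupby(["group", "phase", "epoch"]).size()
    expected_cells = (
        df["group"].nunique() * df["phase"].nunique() * df["epoch"].nunique()
    )
    if len(cell_counts) < expected_cells:
        raise ValueError("unbalanced design: empty group x phase x epoch cells")

    X, names, term_cols, codes = _effect_design(df)
    y = df[response].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = MixedLM(y, X, groups=df["subject"].to_numpy())
        res = model.fit(reml=True)
    k_fe = X.shape[1]
    params = np.asarray(res.fe_params)
    cov = np.asarray(res.cov_params())[:k_fe, :k_fe]
    rows = []
    for term in EPOCH_EFFECTS:
        idx = term_cols[term]
        b = params[idx]
        V = cov[np.ix_(idx, idx)]
        try:
            w = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            w = float("nan")
        p = float(stats.chi2.sf(w, len(idx)))
        rows.append(dict(effect=term, df=len(idx), chi2=w, p=p))
    eff = pd.DataFrame(rows)
    eff["p_adjusted"] = (
        adjust_pvalues_bhy(eff["p"].to_numpy()) if adjust else eff["p"].to_numpy()
    )
    levels = {f: sorted(df[f].unique()) for f in ("group", "phase", "epoch")}
    return EpochModelResult(
        response=response, segment=segment, effects=eff,
        params=params, cov_params=cov, param_names=names,
        term_cols=term_cols, codes=codes, levels=levels,
        converged=bool(res.converged),
    )


def adjust_pvalues_bhy(p_values: np.ndarray, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg-Yekutieli step-up adjustment under arbitrary
    dependence: adjusted p = step-up minimum of ``m c(m) p_(i) / i`` with
    ``c(m) = sum_{i=1}^m 1/i``, capped at one."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if m is None:
        m = n
    if m < n:
        raise ValueError("m must be at least the number of p-values")
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    raw = m * c_m * ranked / np.arange(1, n + 1)
    stepped = np.minimum.accumulate(raw[::-1])[::-1]
    adjusted = np.minimum(stepped, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


def _cell_row(
    result: EpochModelResult, group: str, phase: str, epoch: str
) -> np.ndarray:
    """Fixed-effect design row for one cell mean (random intercept at its
    mean of zero)."""
    row = np.zeros(len(result.params))
    row[0] = 1.0
    vals = dict(group=group, phase=phase, epoch=epoch)
    mats = {f: result.codes[f][vals[f]] for f in ("group", "phase", "epoch")}
    for f in ("group", "phase", "epoch"):
        row[result.term_cols[f]] = mats[f]
    for f1, f2 in (("group", "phase"), ("group", "epoch"), ("phase", "epoch")):
        inter = np.concatenate(
            [mats[f1][i] * mats[f2] for i in range(len(mats[f1]))]
        )
        row[result.term_cols[f"{f1}:{f2}"]] = inter
    return row


def emm_contrasts(
    result: EpochModelResult,
    factor: str,
    alpha: float = 0.05,
    force: bool = False,
) -> pd.DataFrame:
    """Pairwise contrasts of estimated marginal means for one factor.

    Marginal means are model-implied cell means averaged over the levels
    of the other factors.  Following the gating rule, contrasts are only
    computed when the factor's main effect or an interaction involving it
    is significant after adjustment (override with ``force=True``).
    """
    if factor not in ("group", "phase", "epoch"):
        raise KeyError(f"factor {factor!r} not in the epoch model")
    if not force:
        sig = result.significant_effects(alpha)
        if not any(factor in eff.split(":") for eff in sig):
            raise ValueError(
                f"no significant effect involving {factor!r}; "
                "pass force=True to compute contrasts anyway"
            )
    others = [f for f in ("group", "phase", "epoch") if f != factor]
    level_rows: dict[str, np.ndarray] = {}
    for lev in result.levels[factor]:
        rows = []
        for o1 in result.levels[others[0]]:
            for o2 in result.levels[others[1]]:
                vals = {factor: lev, others[0]: o1, others[1]: o2}
                rows.append(
                    _cell_row(result, vals["group"], vals["phase"], vals["epoch"])
                )
        level_rows[lev] = np.mean(rows, axis=0)
    records = []
    for a, b in combinations(result.levels[factor], 2):
        L = level_rows[a] - level_rows[b]
        est = float(L @ result.params)
        se = float(np.sqrt(L @ result.cov_params @ L))
        z = est / se if se > 0 else np.nan
        records.append(
            dict(
                contrast=f"{a} - {b}", estimate=est, se=se, z=z,
                p=float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
            )
        )
    return pd.DataFrame(records)


def estimated_marginal_means(
    result: EpochModelResult, factor: str
) -> pd.DataFrame:
    """Model-implied marginal means per level of one factor."""
    others = [f for f in ("group", "phase", "epoch") if f != factor]
    records = []
    for lev in result.levels[factor]:
        rows = []
        for o1 in result.levels[others[0]]:
            for o2 in result.levels[others[1]]:
                vals = {factor: lev, others[0]: o1, others[1]: o2}
                rows.append(
                    _cell_row(result, vals["group"], vals["phase"], vals["epoch"])
                )
        L = np.mean(rows, axis=0)
        records.append(
            dict(
                level=lev,
                emmean=float(L @ result.params),
                se=float(np.sqrt(L @ result.cov_params @ L)),
            )
        )
    return pd.DataFrame(records)
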