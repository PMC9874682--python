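"""Segmented-linear dynamics of lexical-property / gaze-measure relations.

After an interaction between a skill and a lexical property is identified,
participants are median-split on the skill and, per group, the gaze measure
is related to the lexical property three ways: a loess baseline, a simple
linear (or logistic) fit, and a segmented (broken-line) fit whose breakpoint
is estimated by iterative linearization.  Candidates are compared on AIC and
on the mean squared error of Equation-style predictions (squared error of
predicted probabilities for binary measures); the parametric winner is the
one with the smaller AIC, with any AIC/MSE disagreement flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GroupSplit",
    "SegmentedFit",
    "LinearFit",
    "LoessFit",
    "ModelComparison",
    "median_split",
    "mse",
    "fit_linear",
    "fit_segmented",
    "fit_loess",
    "compare_and_select",
    "dynamics_report",
]


# --------------------------------------------------------------------------
# group split

@dataclass(frozen=True)
class GroupSplit:
    skill: str
    threshold: float
    low_ids: tuple
    high_ids: tuple


def median_split(scores: pd.Series | dict, skill: str = "skill") -> GroupSplit:
    """Split participants at the median: at-or-below goes low, above high.

    With an even number of distinct scores the halves are equal; with odd n
    the low group holds the extra participant (the median itself).
    """
    s = pd.Series(scores, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least 2 participants")
    if s.nunique() == 1:
        raise ValueError("all scores equal; no split possible")
    thr = float(s.median())
    low = tuple(s.index[s <= thr])
    high = tuple(s.index[s > thr])
    return GroupSplit(skill=skill, threshold=thr, low_ids=low, high_ids=high)


# --------------------------------------------------------------------------
# error and candidate fits

def mse(obs, pre) -> float:
    """Mean squared error (1/n) * sum (obs_i - pre_i)^2."""
    obs = np.asarray(obs, dtype=float)
    pre = np.asarray(pre, dtype=float)
    if obs.shape != pre.shape:
        raise ValueError("obs and pre must have equal length")
    if obs.size == 0:
        raise ValueError("need at least one observation")
    return float(np.mean((obs - pre) ** 2))


def _gaussian_loglik(resid: np.ndarray) -> float:
    n = resid.size
    sse = float(resid @ resid)
    if sse <= 0:
        return np.inf
    return -0.5 * n * (np.log(2 * np.pi * sse / n) + 1.0)


def _binom_loglik(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _aic(loglik: float, k: int) -> float:
    return 2.0 * k - 2.0 * loglik


def _ols(Xd: np.ndarray, y: np.ndarray):
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    fitted = Xd @ beta
    resid = y - fitted
    n, p = Xd.shape
    sigma2 = float(resid @ resid) / max(n - p, 1)
    XtX_inv = np.linalg.pinv(Xd.T @ Xd)
    cov = sigma2 * XtX_inv
    return beta, fitted, resid, cov


def _logit_irls(Xd: np.ndarray, y: np.ndarray, maxiter: int = 100):
    n, p = Xd.shape
    beta = np.zeros(p)
    for _ in range(maxiter):
        eta = Xd @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = Xd.T @ (y - mu)
        H = (Xd * w[:, None]).T @ Xd
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        beta = beta + step
        if np.abs(step).max() < 1e-10:
            break
    eta = Xd @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1 - mu), 1e-10, None)
    cov = np.linalg.pinv((Xd * w[:, None]).T @ Xd)
    separated = bool(np.abs(beta).max() > 30)
    return beta, mu, cov, separated


@dataclass
class LinearFit:
    family: str
    intercept: float
    slope: float
    slope_ci: tuple[float, float]
    aic: float
    mse: float
    separated: bool = False
    coef: np.ndarray = field(default=None, repr=False)

    def predict(self, x) -> np.ndarray:
        eta = self.intercept + self.slope * np.asarray(x, dtype=float)
        if self.family == "binomial":
            return 1.0 / (1.0 + np.exp(-eta))
        return eta


def fit_linear(x, y, family: str = "gaussian") -> LinearFit:
    """Simple linear (Gaussian) or logistic (binomial) fit of y on x.

    Gaussian AIC counts the error variance as a parameter (k = 3), the
    convention of likelihood-based AIC for a fitted normal linear model;
    binomial k = 2.  MSE is squared error of predictions (probabilities for
    the binomial family) against the observations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    Xd = np.column_stack([np.ones_like(x), x])
    if family == "gaussian":
        beta, fitted, resid, cov = _ols(Xd, y)
        ll = _gaussian_loglik(resid)
        aic = _aic(ll, 3)
        err = mse(y, fitted)
        se = np.sqrt(cov[1, 1])
        ci = (beta[1] - 1.96 * se, beta[1] + 1.96 * se)
        return LinearFit("gaussian", float(beta[0]), float(beta[1]), ci,
                         aic, err, coef=beta)
    elif family == "binomial":
        beta, mu, cov, sep = _logit_irls(Xd, y)
        ll = _binom_loglik(y, mu)
        aic = _aic(ll, 2)
        err = mse(y, mu)
        se = np.sqrt(max(cov[1, 1], 0))
        ci = (beta[1] - 1.96 * se, beta[1] + 1.96 * se)
        return LinearFit("binomial", float(beta[0]), float(beta[1]), ci,
                         aic, err, separated=sep, coef=beta)
    raise ValueError("family must be 'gaussian' or 'binomial'")


# --------------------------------------------------------------------------
# segmented fit

@dataclass
class SegmentedFit:
    family: str
    psi: float
    intercept: float
    slope_below: float
    slope_above: float
    gamma: float
    slope_below_ci: tuple[float, float]
    slope_above_ci: tuple[float, float]
    converged: bool
    n_iter: int
    aic: float
    mse: float

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        eta = (self.intercept + self.slope_below * x
               + self.gamma * np.clip(x - self.psi, 0.0, None))
        if self.family == "binomial":
            return 1.0 / (1.0 + np.exp(-eta))
        return eta


def _segmented_design(x: np.ndarray, psi: float) -> np.ndarray:
    U = np.clip(x - psi, 0.0, None)
    V = -(x > psi).astype(float)
    return np.column_stack([np.ones_like(x), x, U, V])


def _final_segmented(x, y, psi, family, n_iter, converged) -> SegmentedFit:
    Xd = np.column_stack([np.ones_like(x), x, np.clip(x - psi, 0.0, None)])
    if family == "gaussian":
        beta, fitted, resid, cov = _ols(Xd, y)
        ll = _gaussian_loglik(resid)
        aic = _aic(ll, 5)  # 4 mean parameters + error variance
        err = mse(y, fitted)
    else:
        beta, mu, cov, _ = _logit_irls(Xd, y)
        ll = _binom_loglik(y, mu)
        aic = _aic(ll, 4)
        err = mse(y, mu)
    b_lo = float(beta[1])
    gamma = float(beta[2])
    var_lo = cov[1, 1]
    var_hi = cov[1, 1] + cov[2, 2] + 2 * cov[1, 2]
    se_lo = np.sqrt(max(var_lo, 0))
    se_hi = np.sqrt(max(var_hi, 0))
    return SegmentedFit(
        family=family, psi=float(psi), intercept=float(beta[0]),
        slope_below=b_lo, slope_above=b_lo + gamma, gamma=gamma,
        slope_below_ci=(b_lo - 1.96 * se_lo, b_lo + 1.96 * se_lo),
        slope_above_ci=(b_lo + gamma - 1.96 * se_hi,
                        b_lo + gamma + 1.96 * se_hi),
        converged=converged, n_iter=n_iter, aic=aic, mse=err)


def fit_segmented(
    x, y, family: str = "gaussian",
    psi_init: float | None = None,
    tol: float = 1e-5,
    max_iter: int = 50,
) -> SegmentedFit:
    """Broken-line fit with breakpoint estimated by iterative linearization.

    At each step the model ``y ~ 1 + x + (x - psi)_+ + V`` is fit under the
    family's likelihood, where ``V = -1[x > psi]`` carries the first-order
    breakpoint correction; psi is updated by ``psi + gamma_V / beta_U`` until
    |delta psi| < tol.  Iterations run from the median of the distinct x
    values and restarts over their quantiles (an iterate leaving the data
    range aborts that start); among converged starts the solution with the
    best in-sample fit is kept, guarding against local optima of the
    breakpoint criterion.  If no start converges, the best last iterate is
    returned with ``converged=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 6:
        raise ValueError("need at least 6 points")
    if np.unique(x).size < 4:
        raise ValueError("need at least 4 distinct x values")
    xmin, xmax = x.min(), x.max()
    span = xmax - xmin

    def score(psi: float) -> float:
        # in-sample badness of the refit at psi (SSE or binomial deviance)
        Xd = np.column_stack([np.ones_like(x), x,
                              np.clip(x - psi, 0.0, None)])
        if family == "gaussian":
            beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
            r = y - Xd @ beta
            return float(r @ r)
        beta, mu, _, _ = _logit_irls(Xd, y)
        return -2.0 * _binom_loglik(y, mu)

    starts: list[float] = []
    if psi_init is not None:
        starts.append(float(psi_init))
    distinct = np.unique(x)
    starts.append(float(np.median(distinct)))
    # coarse pre-scan of the profile criterion: the best grid candidates
    # seed the iteration so it starts near the global optimum
    scan = np.unique(np.quantile(distinct, np.linspace(0.05, 0.95, 19)))
    scan = scan[(scan > xmin) & (scan < xmax)]
    if scan.size:
        order = np.argsort([score(c) for c in scan])
        starts.extend(float(scan[i]) for i in order[:4])
    starts.extend(float(np.quantile(distinct, q)) for q in (0.3, 0.7))

    best_conv: tuple[float, float, int] | None = None   # (score, psi, iters)
    best_any: tuple[float, float, int] | None = None
    for psi0 in starts:
        psi = float(np.clip(psi0, xmin + 1e-9 * max(span, 1),
                            xmax - 1e-9 * max(span, 1)))
        for it in range(1, max_iter + 1):
            Xd = _segmented_design(x, psi)
            if family == "gaussian":
                beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
            else:
                beta, _, _, _ = _logit_irls(Xd, y)
            b_u, g_v = float(beta[2]), float(beta[3])
            if abs(b_u) < 1e-10:
                # no slope change detectable: segmented collapses to linear
                return _final_segmented(x, y, psi, family, it, True)
            delta = g_v / b_u
            psi_new = psi + delta
            if not (xmin < psi_new < xmax):
                cand = (score(psi), psi, it)
                if best_any is None or cand[0] < best_any[0]:
                    best_any = cand
                break
            psi = psi_new
            if abs(delta) < tol:
                cand = (score(psi), psi, it)
                if best_conv is None or cand[0] < best_conv[0]:
                    best_conv = cand
                break
        else:
            cand = (score(psi), psi, max_iter)
            if best_any is None or cand[0] < best_any[0]:
                best_any = cand
    if best_conv is not None:
        _, psi, it = best_conv
        return _final_segmented(x, y, psi, family, it, True)
    _, psi, it = best_any if best_any is not None else (
        0.0, float(np.median(x)), 0)
    return _final_segmented(x, y, float(np.clip(psi, xmin, xmax)),
                            family, it, False)


# --------------------------------------------------------------------------
# loess baseline

@dataclass
class LoessFit:
    x_grid: np.ndarray
    fitted: np.ndarray
    se: np.ndarray
    span: float
    degree: int
    mse: float
    _x: np.ndarray = field(repr=False, default=None)
    _y: np.ndarray = field(repr=False, default=None)

    def predict(self, x0) -> np.ndarray:
        return _loess_eval(self._x, self._y, np.atleast_1d(
            np.asarray(x0, dtype=float)), self.span, self.degree)[0]


def _loess_eval(x, y, grid, span, degree):
    n = x.size
    k = max(int(np.ceil(span * n)), degree + 2)
    k = min(k, n)
    fitted = np.empty(grid.size)
    l2 = np.empty(grid.size)  # squared norm of the equivalent kernel
    for i, x0 in enumerate(grid):
        d = np.abs(x - x0)
        idx = np.argsort(d, kind="stable")[:k]
        dmax = d[idx].max()
        if dmax == 0:
            w = np.ones(idx.size)
        else:
            w = (1.0 - (d[idx] / dmax) ** 3) ** 3
            w = np.clip(w, 1e-12, None)
        B = np.vander(x[idx] - x0, degree + 1, increasing=True)
        WB = B * w[:, None]
        G = B.T @ WB
        try:
            coef_row = np.linalg.solve(G, WB.T)
        except np.linalg.LinAlgError:
            coef_row = np.linalg.pinv(G) @ WB.T
        lvec = coef_row[0]  # weights giving the fit at x0
        fitted[i] = float(lvec @ y[idx])
        l2[i] = float(lvec @ lvec)
    return fitted, l2


def fit_loess(x, y, span: float = 0.75, degree: int = 2,
              grid: np.ndarray | None = None) -> LoessFit:
    """Local polynomial regression with tricube weights.

    At each evaluation point the nearest ``ceil(span * n)`` observations are
    weighted by the tricube kernel and a degree-``degree`` polynomial is fit
    by weighted least squares.  The pointwise standard error uses the
    equivalent-kernel norm with a global residual variance estimate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 points for loess")
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    n = x.size
    if int(np.ceil(span * n)) < degree + 2:
        raise ValueError("span too small for the local fits")
    if n <= 1000:
        fitted_at_data, _ = _loess_eval(x, y, x, span, degree)
    else:
        # large samples: evaluate on a fine grid and interpolate for the
        # residual pass (the smooth is far smoother than the grid spacing)
        fine = np.linspace(x.min(), x.max(), 201)
        fvals, _ = _loess_eval(x, y, fine, span, degree)
        fitted_at_data = np.interp(x, fine, fvals)
    resid = y - fitted_at_data
    sigma2 = float(resid @ resid) / max(n - (degree + 1), 1)
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 101)
    fitted, l2 = _loess_eval(x, y, np.asarray(grid, dtype=float), span, degree)
    return LoessFit(x_grid=np.asarray(grid, dtype=float), fitted=fitted,
                    se=np.sqrt(sigma2 * l2), span=span, degree=degree,
                    mse=mse(y, fitted_at_data), _x=x, _y=y)


# --------------------------------------------------------------------------
# comparison and per-interaction report

@dataclass
class ModelComparison:
    candidates: dict          # name -> {"aic": float | None, "mse": float}
    best: str
    agreement: bool           # AIC and MSE pick the same parametric winner


def compare_and_select(fits: dict) -> ModelComparison:
    """Select the best parametric candidate by AIC; flag MSE disagreement.

    ``fits`` maps candidate names to fit objects with ``aic``/``mse``
    attributes; a loess entry (no AIC) is carried for reference only.
    """
    cand = {}
    parametric = {}
    for name, f in fits.items():
        aic = getattr(f, "aic", None)
        cand[name] = {"aic": aic, "mse": f.mse}
        if aic is not None:
            parametric[name] = (aic, f.mse)
    if len(parametric) < 2:
        raise ValueError("need at least 2 parametric candidates")
    by_aic = min(parametric, key=lambda k: parametric[k][0])
    by_mse = min(parametric, key=lambda k: parametric[k][1])
    return ModelComparison(candidates=cand, best=by_aic,
                           agreement=(by_aic == by_mse))


def dynamics_report(
    split: GroupSplit,
    table: pd.DataFrame,
    predictor: str,
    response: str,
    family: str = "gaussian",
    span: float = 0.75,
    degree: int = 2,
    tol: float = 1e-5,
    max_iter: int = 50,
    min_points: int = 6,
) -> dict:
    """Per-group loess / linear / segmented fits for one interaction.

    Returns ``{"low": {...}, "high": {...}}`` where each group dict carries
    n, the three fits, and the :class:`ModelComparison`; groups with fewer
    than ``min_points`` usable rows are reported as unfittable.
    """
    out = {}
    for name, ids in (("low", split.low_ids), ("high", split.high_ids)):
        sub = table[table["participant_id"].isin(ids)].dropna(
            subset=[predictor, response])
        x = sub[predictor].to_numpy(dtype=float)
        y = sub[response].to_numpy(dtype=float)
        if x.size < max(min_points, 10) or np.unique(x).size < 4:
            out[name] = {"fittable": False, "n": int(x.size)}
            continue
        linear = fit_linear(x, y, family)
        seg = fit_segmented(x, y, family, tol=tol, max_iter=max_iter)
        lo = fit_loess(x, y, span=span, degree=degree)
        comp = compare_and_select(
            {"linear": linear, "segmented": seg, "loess": lo})
        out[name] = {"fittable": True, "n": int(x.size), "linear": linear,
                     "segmented": seg, "loess": lo, "comparison": comp}
    return out


def report_rows(report: dict, skill: str, predictor: str,
                response: str) -> list[dict]:
    """Flatten a dynamics report into machine-readable rows (one per group)."""
    rows = []
    for group, r in report.items():
        row = {"skill": skill, "predictor": predictor, "response": response,
               "group": group, "n": r["n"], "fittable": r["fittable"]}
        if r["fittable"]:
            lin, seg, comp = r["linear"], r["segmented"], r["comparison"]
            row.update({
                "lm_intercept": lin.intercept, "lm_slope": lin.slope,
                "lm_slope_lo": lin.slope_ci[0], "lm_slope_hi": lin.slope_ci[1],
                "lm_aic": lin.aic, "lm_mse": lin.mse,
                "seg_point": seg.psi,
                "seg_slope_below": seg.slope_below,
                "seg_slope_above": seg.slope_above,
                "seg_slope_below_lo": seg.slope_below_ci[0],
                "seg_slope_below_hi": seg.slope_below_ci[1],
                "seg_slope_above_lo": seg.slope_above_ci[0],
                "seg_slope_above_hi": seg.slope_above_ci[1],
                "seg_converged": seg.converged,
                "seg_aic": seg.aic, "seg_mse": seg.mse,
                "loess_mse": r["loess"].mse,
                "best": comp.best, "aic_mse_agree": comp.agreement,
            })
        rows.append(row)
    return rows
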