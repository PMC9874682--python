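"""Score and lexical-covariate preparation.

Skill side: examine raw score distributions, Box-Cox transform the highly
skewed ones (|skew| > 0.5), standardize everything to Z-scores, and build
composite constructs (oral comprehension + vocabulary, decoding, reading
comprehension) as re-standardized means of component Z-scores.

Lexical side: mean-center word position and lengths, standardize log
frequencies, and residualize each frequency against the length of the same
word so the length/frequency collinearity does not enter the models twice.

Also provides the collinearity diagnostics (condition number kappa, VIF)
reported alongside every mixed model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import COMPOSITE_COMPONENTS

__all__ = [
    "moments",
    "box_cox",
    "fit_box_cox_lambda",
    "standardize",
    "center",
    "make_composite",
    "residualize",
    "correlation_table",
    "collinearity",
    "prepare_skills",
    "prepare_lexical",
    "simple_regression_r2",
]

SKEW_THRESHOLD = 0.5  # |skew| above which a score is Box-Cox transformed


def moments(values) -> dict[str, float]:
    """Sample mean, SD (n-1), adjusted Fisher-Pearson skewness, excess kurtosis."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        return {"mean": float(x.mean()), "sd": 0.0,
                "skewness": float("nan"), "kurtosis": float("nan")}
    return {
        "mean": float(x.mean()),
        "sd": float(sd),
        "skewness": float(stats.skew(x, bias=False)),
        "kurtosis": float(stats.kurtosis(x, bias=False)),  # excess
    }


def box_cox(values, lam: float) -> np.ndarray:
    """Box-Cox power transform: (x^lam - 1)/lam, or log(x) at lam = 0."""
    x = np.asarray(values, dtype=float)
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive values; "
                         "shift the data before transforming")
    if lam == 0.0:
        return np.log(x)
    return (x ** lam - 1.0) / lam


def fit_box_cox_lambda(values, grid: np.ndarray | None = None) -> float:
    """Profile-likelihood Box-Cox lambda over a grid (default [-3, 3], step 0.01)."""
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    if grid is None:
        grid = np.arange(-3.0, 3.0 + 1e-12, 0.01)
    grid = np.asarray(grid, dtype=float)
    n = x.size
    logx = np.log(x)
    # vectorized profile log-likelihood over the whole grid
    lam = grid[:, None]
    with np.errstate(over="ignore", invalid="ignore"):
        y = np.where(lam == 0.0, logx[None, :],
                     (np.exp(lam * logx[None, :]) - 1.0)
                     / np.where(lam == 0.0, 1.0, lam))
    var = y.var(axis=1)
    ll = -0.5 * n * np.log(var) + (grid - 1.0) * logx.sum()
    ll[~np.isfinite(ll)] = -np.inf
    return float(grid[np.argmax(ll)])


def standardize(values) -> np.ndarray:
    """Convert to Z-scores (mean 0, SD 1 with the n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a zero-variance vector")
    return (x - x.mean()) / sd


def center(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    return x - x.mean()


def make_composite(components: list) -> np.ndarray:
    """Row-wise mean of standardized component vectors, re-standardized."""
    arrs = [np.asarray(c, dtype=float) for c in components]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("component vectors must have equal length")
    return standardize(np.mean(arrs, axis=0))


def residualize(y, x) -> np.ndarray:
    """Residuals of the least-squares regression of y on x (and an intercept)."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0:
        raise ValueError("regressor has zero variance")
    b, a = np.polyfit(x, y, 1)
    return y - (a + b * x)


def correlation_table(columns: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of the numeric columns."""
    return columns.corr(method="pearson")


def collinearity(design: np.ndarray | pd.DataFrame,
                 names: list[str] | None = None) -> dict:
    """Condition number kappa and per-column VIFs of a design matrix.

    kappa is the ratio of the largest to smallest singular value of the
    column-standardized design (intercept excluded).  VIF_j = 1/(1 - R2_j)
    from regressing column j on the remaining columns (with intercept);
    exact collinearity yields ``inf``.
    """
    X = np.asarray(design, dtype=float)
    if isinstance(design, pd.DataFrame) and names is None:
        names = list(design.columns)
    n, p = X.shape
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        raise ValueError("constant column in design; remove the intercept")
    Z = (X - X.mean(axis=0)) / sds
    sv = np.linalg.svd(Z, compute_uv=False)
    kappa = float(sv[0] / sv[-1]) if sv[-1] > 0 else float("inf")

    vifs = []
    ones = np.ones((n, 1))
    for j in range(p):
        others = np.hstack([ones, np.delete(X, j, axis=1)])
        yj = X[:, j]
        beta, res, rank, _ = np.linalg.lstsq(others, yj, rcond=None)
        fitted = others @ beta
        sst = float(((yj - yj.mean()) ** 2).sum())
        sse = float(((yj - fitted) ** 2).sum())
        r2 = 1.0 - sse / sst if sst > 0 else 0.0
        vifs.append(float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2))
    named = dict(zip(names, vifs)) if names else dict(enumerate(vifs))
    return {"kappa": kappa, "vif": named, "max_vif": max(vifs)}


def prepare_skills(skills: pd.DataFrame,
                   skew_threshold: float = SKEW_THRESHOLD) -> dict:
    """Transform, standardize and composite a raw skill-score table.

    Measures whose |sample skewness| exceeds ``skew_threshold`` receive a
    profile-likelihood Box-Cox transform (scores are shifted positive first
    if needed); all measures are then Z-scored and the composite constructs
    of ``COMPOSITE_COMPONENTS`` are built as re-standardized means.

    Returns ``{"profiles": DataFrame, "lambdas": {measure: lambda or None},
    "shifts": {measure: shift}}`` where ``profiles`` holds participant_id,
    per-measure Z-scores (``z_<measure>``) and composite columns.
    """
    measures = [c for c in skills.columns if c != "participant_id"]
    out = pd.DataFrame({"participant_id": skills["participant_id"]})
    lambdas: dict[str, float | None] = {}
    shifts: dict[str, float] = {}
    for m in measures:
        x = skills[m].to_numpy(dtype=float)
        sk = moments(x)["skewness"]
        if abs(sk) > skew_threshold:
            shift = 0.0
            if x.min() <= 0:
                shift = 1.0 - x.min()
            lam = fit_box_cox_lambda(x + shift)
            x = box_cox(x + shift, lam)
            lambdas[m] = lam
            shifts[m] = shift
        else:
            lambdas[m] = None
            shifts[m] = 0.0
        out[f"z_{m}"] = standardize(x)
    for comp, parts in COMPOSITE_COMPONENTS.items():
        out[comp] = make_composite([out[f"z_{p}"] for p in parts])
    return {"profiles": out, "lambdas": lambdas, "shifts": shifts}


def prepare_lexical(table: pd.DataFrame,
                    center_position_per_sentence: bool = False) -> pd.DataFrame:
    """Add centered/standardized/residualized lexical covariates to a table.

    Centering and standardization statistics are computed over the unique
    retained word tokens (one weight per token, however many participants
    fixated it), then broadcast back to the per-participant rows.  Each
    standardized log frequency is residualized against the centered length
    of the same word, making the pair exactly orthogonal over tokens.
    """
    tok = (table[["sentence_id", "word_index", "position", "len_w",
                  "len_prev", "len_next", "freq_w", "freq_prev", "freq_next"]]
           .drop_duplicates(["sentence_id", "word_index"])
           .sort_values(["sentence_id", "word_index"])
           .reset_index(drop=True))

    if center_position_per_sentence:
        tok["position_c"] = (tok["position"]
                             - tok.groupby("sentence_id")["position"]
                                  .transform("mean"))
    else:
        tok["position_c"] = center(tok["position"])
    for side in ("w", "prev", "next"):
        len_col = "len_w" if side == "w" else f"len_{side}"
        tok[f"{len_col}_c"] = center(tok[len_col])
        freq_col = "freq_w" if side == "w" else f"freq_{side}"
        z = standardize(tok[freq_col])
        tok[f"{freq_col}_z"] = z
        tok[f"freq_resid_{side}"] = residualize(z, tok[f"{len_col}_c"])

    derived = ["position_c", "len_w_c", "len_prev_c", "len_next_c",
               "freq_w_z", "freq_prev_z", "freq_next_z",
               "freq_resid_w", "freq_resid_prev", "freq_resid_next"]
    return table.merge(tok[["sentence_id", "word_index"] + derived],
                       on=["sentence_id", "word_index"], how="left")


def simple_regression_r2(r: float, n: int = 44) -> float:
    """R-squared of a standardized simple regression with sample correlation r.

    Builds two exactly Z-scored vectors of length ``n`` whose sample
    correlation equals ``r``, fits the least-squares line, and returns the
    proportion of variance explained.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    if n < 3:
        raise ValueError("need n >= 3")
    rng = np.random.default_rng(12345)
    x = standardize(rng.standard_normal(n))
    e = rng.standard_normal(n)
    e = standardize(residualize(e, x))  # exactly orthogonal to x, unit SD
    y = r * x + np.sqrt(1.0 - r * r) * e  # sample corr(x, y) == r exactly
    resid = residualize(y, x)
    sst = float(((y - y.mean()) ** 2).sum())
    return 1.0 - float((resid ** 2).sum()) / sst
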