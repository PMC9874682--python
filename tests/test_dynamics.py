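"""Segmented dynamics: splits, candidate fits, breakpoint recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gazedyn.dynamics import (compare_and_select, dynamics_report, fit_linear,
                              fit_loess, fit_segmented, median_split, mse)


def piecewise(x, psi, b_lo, b_hi, intercept=0.0):
    return intercept + np.where(x <= psi, b_lo * (x - psi),
                                b_hi * (x - psi))


def grid_search_sse(x, y, candidates):
    """Independent breakpoint oracle: exhaustive OLS over candidate psi."""
    best = (None, np.inf)
    for psi in candidates:
        X = np.column_stack([np.ones_like(x), x, np.clip(x - psi, 0, None)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(((y - X @ beta) ** 2).sum())
        if sse < best[1]:
            best = (psi, sse)
    return best


# --------------------------------------------------------------------------
# median split

def test_even_split_is_equal_halves():
    rng = np.random.default_rng(0)
    s = pd.Series(rng.normal(size=44), index=[f"p{i}" for i in range(44)])
    sp = median_split(s, "sspan_corr")
    assert len(sp.low_ids) == len(sp.high_ids) == 22
    assert set(sp.low_ids).isdisjoint(sp.high_ids)
    assert set(sp.low_ids) | set(sp.high_ids) == set(s.index)


def test_small_and_odd_splits():
    sp = median_split(pd.Series({"a": 1.0, "b": 2.0}))
    assert sp.low_ids == ("a",) and sp.high_ids == ("b",)
    sp5 = median_split(pd.Series(dict(zip("abcde", [1., 2., 3., 4., 5.]))))
    assert len(sp5.low_ids) == 3 and len(sp5.high_ids) == 2
    with pytest.raises(ValueError):
        median_split(pd.Series({"a": 1.0, "b": 1.0, "c": 1.0}))


# --------------------------------------------------------------------------
# mse and linear fits

def test_mse_closed_forms():
    assert mse([1, 2, 3], [1, 1, 4]) == pytest.approx(2 / 3)
    assert mse([2, 2], [2, 2]) == 0.0
    assert mse([0.0], [3.0]) == 9.0
    with pytest.raises(ValueError):
        mse([1, 2], [1])


def test_linear_fit_exact_line_and_aic_formula():
    x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    y = 2 * x + 1
    f = fit_linear(x, y)
    assert f.slope == pytest.approx(2.0) and f.intercept == pytest.approx(1.0)
    assert f.mse == pytest.approx(0.0, abs=1e-20)

    rng = np.random.default_rng(1)
    y2 = y + rng.normal(0, 0.5, 5)
    f2 = fit_linear(x, y2)
    sse = float(((y2 - f2.predict(x)) ** 2).sum())
    n, k = 5, 3  # intercept, slope, error variance
    aic_hand = n * np.log(2 * np.pi * sse / n) + n + 2 * k
    assert f2.aic == pytest.approx(aic_hand)


def test_logistic_flat_outcomes_give_zero_slope():
    rng = np.random.default_rng(2)
    x = rng.normal(size=400)
    y = (rng.random(400) < 0.5).astype(float)
    f = fit_linear(x, y, family="binomial")
    assert abs(f.slope) < 0.25
    assert not f.separated


# --------------------------------------------------------------------------
# segmented fits

def test_noiseless_breakpoint_recovery_vs_grid_oracle():
    x = np.arange(-5, 5.01, 0.5)
    y = piecewise(x, 0.0, 1.0, 3.0)
    f = fit_segmented(x, y)
    assert f.converged
    assert abs(f.psi - 0.0) <= 0.25
    assert f.slope_below == pytest.approx(1.0, abs=0.05)
    assert f.slope_above == pytest.approx(3.0, abs=0.05)
    psi_star, sse_star = grid_search_sse(x, y, np.arange(-4.5, 4.51, 0.05))
    assert abs(f.psi - psi_star) <= 0.25
    assert len(x) * f.mse <= sse_star + 1e-9


def test_pure_line_collapses_to_linear():
    x = np.arange(-5, 5.01, 0.5)
    y = 2 * x
    f = fit_segmented(x, y)
    lin = fit_linear(x, y)
    assert np.allclose(f.predict(x), lin.predict(x), atol=1e-6)
    assert abs(f.gamma) < 1e-6


def test_segmented_nesting_beats_linear_on_random_data():
    rng = np.random.default_rng(3)
    for _ in range(25):
        x = rng.uniform(-3, 3, 80)
        y = piecewise(x, rng.uniform(-1, 1), rng.uniform(-2, 2),
                      rng.uniform(-2, 2)) + rng.normal(0, 0.5, 80)
        f = fit_segmented(x, y)
        lin = fit_linear(x, y)
        assert f.mse <= lin.mse + 1e-9
        if f.converged:
            psi_star, sse_star = grid_search_sse(
                x, y, np.linspace(x.min() + 0.05, x.max() - 0.05, 150))
            assert len(x) * f.mse <= sse_star * 1.02 + 1e-9


def test_noisy_breakpoint_recovery_median_error():
    rng = np.random.default_rng(4)
    errs = []
    for s in range(100):
        x = rng.uniform(-5, 5, 500)
        y = piecewise(x, 1.0, 0.5, 3.0) + rng.normal(0, 0.2 * 10, 500)
        f = fit_segmented(x, y)
        errs.append(abs(f.psi - 1.0))
    assert np.median(errs) <= 1.0  # 10% of the predictor range


def test_binomial_breakpoint_recovery():
    rng = np.random.default_rng(5)
    x = rng.uniform(-2, 6, 5000)
    eta = 0.1 + 0.5 * np.clip(x - 2.0, 0, None)
    y = (rng.random(5000) < 1 / (1 + np.exp(-eta))).astype(float)
    f = fit_segmented(x, y, family="binomial")
    assert abs(f.psi - 2.0) <= 0.5


def test_shift_equivariance():
    rng = np.random.default_rng(6)
    x = rng.uniform(-3, 3, 120)
    y = piecewise(x, 0.5, 1.0, 2.5) + rng.normal(0, 0.3, 120)
    f = fit_segmented(x, y)
    g = fit_segmented(x + 10.0, y)
    assert g.psi - f.psi == pytest.approx(10.0, abs=1e-6)
    assert g.slope_below == pytest.approx(f.slope_below, abs=1e-8)
    assert g.slope_above == pytest.approx(f.slope_above, abs=1e-8)


@settings(max_examples=20, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_segmented_never_beats_itself_outside_range(seed):
    """psi stays strictly inside the observed x range."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(-4, 4, 60)
    y = rng.normal(0, 1, 60) + 0.5 * x
    f = fit_segmented(x, y)
    assert x.min() <= f.psi <= x.max()


# --------------------------------------------------------------------------
# loess

def test_loess_constant_and_linear_limits():
    x = np.linspace(0, 10, 60)
    f = fit_loess(x, np.full(60, 3.0))
    assert np.allclose(f.fitted, 3.0, atol=1e-8)

    rng = np.random.default_rng(7)
    y = 2 * x + rng.normal(0, 1e-6, 60)
    f2 = fit_loess(x, y)
    inner = (f2.x_grid > 1) & (f2.x_grid < 9)
    assert np.allclose(f2.fitted[inner], 2 * f2.x_grid[inner], atol=1e-3)


def test_loess_pointwise_weighted_least_squares_oracle():
    rng = np.random.default_rng(8)
    x = np.sort(rng.uniform(0, 5, 40))
    y = np.sin(x) + rng.normal(0, 0.1, 40)
    span, degree = 0.75, 2
    f = fit_loess(x, y, span=span, degree=degree, grid=x[5:35:5])
    k = int(np.ceil(span * 40))
    for x0, got in zip(f.x_grid, f.fitted):
        d = np.abs(x - x0)
        idx = np.argsort(d, kind="stable")[:k]
        w = (1 - (d[idx] / d[idx].max()) ** 3) ** 3
        coefs = np.polynomial.polynomial.polyfit(
            x[idx] - x0, y[idx], degree, w=np.sqrt(np.clip(w, 1e-12, None)))
        assert got == pytest.approx(coefs[0], abs=1e-8)


def test_loess_span_too_small_rejected():
    x = np.linspace(0, 1, 20)
    with pytest.raises(ValueError):
        fit_loess(x, x, span=0.05)


# --------------------------------------------------------------------------
# selection and reporting

def test_selection_under_segmented_truth():
    rng = np.random.default_rng(9)
    x = rng.uniform(-4, 4, 300)
    y = piecewise(x, 0.5, 0.5, 4.0) + rng.normal(0, 1.0, 300)
    fits = {"linear": fit_linear(x, y), "segmented": fit_segmented(x, y),
            "loess": fit_loess(x, y)}
    comp = compare_and_select(fits)
    assert comp.best == "segmented"
    assert comp.agreement  # AIC and MSE pick the same winner


def test_selection_under_linear_truth():
    rng = np.random.default_rng(10)
    x = rng.uniform(-4, 4, 300)
    y = 1.0 + 0.8 * x + rng.normal(0, 1.0, 300)
    comp = compare_and_select(
        {"linear": fit_linear(x, y), "segmented": fit_segmented(x, y)})
    assert comp.best == "linear"  # fewer parameters win AIC


def test_identical_predictions_prefer_fewer_parameters():
    x = np.arange(-5, 5.01, 0.5)
    y = 2 * x
    comp = compare_and_select(
        {"linear": fit_linear(x, y), "segmented": fit_segmented(x, y)})
    assert comp.best == "linear"
    assert comp.candidates["segmented"]["mse"] == pytest.approx(
        comp.candidates["linear"]["mse"], abs=1e-12)


def _group_table(rng, ids, psi, n_per=120):
    rows = []
    for pid in ids:
        x = rng.uniform(-4, 4, n_per)
        y = piecewise(x, psi, 0.5, 4.0) + rng.normal(0, 1.0, n_per)
        rows.append(pd.DataFrame({"participant_id": pid, "x": x, "y": y}))
    return pd.concat(rows, ignore_index=True)


def test_dynamics_report_recovers_group_breakpoints():
    rng = np.random.default_rng(11)
    low_ids = [f"L{i}" for i in range(5)]
    high_ids = [f"H{i}" for i in range(5)]
    table = pd.concat([_group_table(rng, low_ids, psi=-1.0),
                       _group_table(rng, high_ids, psi=1.5)],
                      ignore_index=True)
    scores = pd.Series({**{i: -1.0 - k for k, i in enumerate(low_ids)},
                        **{i: 1.0 + k for k, i in enumerate(high_ids)}})
    split = median_split(scores, "skill")
    rep = dynamics_report(split, table, predictor="x", response="y")
    assert rep["low"]["fittable"] and rep["high"]["fittable"]
    assert rep["low"]["segmented"].psi < rep["high"]["segmented"].psi
    assert rep["low"]["comparison"].best == "segmented"


def test_dynamics_report_unfittable_group():
    rng = np.random.default_rng(12)
    table = pd.concat([
        _group_table(rng, ["a"], psi=0.0, n_per=50),
        pd.DataFrame({"participant_id": "b", "x": [0.0, 1.0],
                      "y": [1.0, 2.0]})], ignore_index=True)
    split = median_split(pd.Series({"b": 0.0, "a": 1.0}), "skill")
    rep = dynamics_report(split, table, predictor="x", response="y")
    assert not rep["low"]["fittable"]
    assert rep["high"]["fittable"]
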