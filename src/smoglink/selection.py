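"""Specification tests for the spatial panel regression.

The battery a practitioner runs before committing to a spatial Durbin
specification:

* Lagrange-multiplier tests from pooled OLS residuals — LM-lag, LM-error
  and their robust variants (each chi-squared with 1 df) — to detect
  spatial dependence and to discriminate lag from error dependence.  The
  cross-section formulas are applied to two-way within-transformed pooled
  data with a block-diagonal I_T (x) W weight structure.
* Likelihood-ratio and Wald tests for whether the SDM reduces to SAR or
  SEM (theta restrictions).
* A classical Hausman test of fixed vs random effects on the non-spatial
  panel regression (Swamy-Arora random effects vs the within estimator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .panel import COVARIATES, PanelData
from .sdm import ComparisonFit, TwoRegimeSDMFit, _param_lookup, within_transform
from .weights import SpatialWeights, row_standardize

__all__ = ["TestResult", "lm_tests", "lr_test", "wald_test", "hausman_test"]


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    df: int
    p: float
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "note": self.note,
        }


def _chi2_result(name: str, stat: float, df: int, note: str = "") -> TestResult:
    return TestResult(
        name=name,
        statistic=float(stat),
        df=df,
        p=float(stats.chi2.sf(stat, df)) if np.isfinite(stat) else np.nan,
        note=note,
    )


def lm_tests(
    panel: PanelData,
    w: SpatialWeights,
    effects: str = "two_way",
    log_transform: bool = False,
) -> dict[str, TestResult]:
    """Anselin LM-lag / LM-error and their robust variants from OLS residuals.

    Returns a dict with keys ``lm_lag``, ``lm_error``, ``robust_lm_lag``,
    ``robust_lm_error``.  All four are chi-squared(1).
    """
    ws = w if w.standardized else row_standardize(w)
    W = ws.w
    n, T = panel.n, panel.T
    N = n * T
    Y = panel.outcome
    X = panel.covariate_stack()
    if log_transform:
        X = X.copy()
        for j, name in enumerate(COVARIATES):
            if name in ("HC", "PG", "PD", "ES"):
                X[:, :, j] = np.log(X[:, :, j])
    tw = lambda M: within_transform(M, effects)
    y = tw(Y).ravel()
    Xb = np.column_stack([tw(X[:, :, j]).ravel() for j in range(X.shape[2])])
    XtX = Xb.T @ Xb
    if np.linalg.cond(XtX) > 1e12:
        raise np.linalg.LinAlgError("singular regressor cross-product in LM tests")
    b = np.linalg.solve(XtX, Xb.T @ y)
    e = y - Xb @ b

    def lagged(v: np.ndarray) -> np.ndarray:
        # block-diagonal (I_T kron W) applied to an (nT,) stack
        return (W @ v.reshape(n, T)).ravel()

    # Moments under the demeaned null.  The within transform makes the
    # demeaned weight operator W* = M (I_T kron W) M non-trace-free
    # (tr W* = -(1'W1/n)(T-1) for two-way demeaning), so the score terms
    # must be centred at their null means and the trace term computed from
    # W*; with no demeaning this reduces to the classic cross-section
    # formulas (tr W = 0, T1 = T tr(W'W + W^2)).
    Qn = np.eye(n) - np.ones((n, n)) / n
    if effects == "two_way":
        Wq, t_factor = Qn @ W @ Qn, T - 1
    elif effects == "time":
        Wq, t_factor = Qn @ W @ Qn, T
    elif effects == "unit":
        Wq, t_factor = W, T - 1
    else:
        Wq, t_factor = W, T
    trWs = float(np.trace(Wq)) * t_factor
    T1 = t_factor * float(np.trace(Wq.T @ Wq) + np.trace(Wq @ Wq))
    df = {"two_way": (n - 1) * (T - 1), "unit": n * (T - 1), "time": (n - 1) * T, "none": N}[
        effects
    ] - Xb.shape[1]
    sigma2 = float(e @ e) / df  # unbiased under the demeaned null

    WXb_cols = np.column_stack([lagged(Xb[:, j]) for j in range(Xb.shape[1])])
    d_lag = float(e @ lagged(y)) / sigma2
    d_err = float(e @ lagged(e)) / sigma2
    # common null mean of both scores: tr(P W* P) = tr W* - tr((X'X)^-1 X'WX)
    center = trWs - float(np.trace(np.linalg.solve(XtX, Xb.T @ WXb_cols)))
    c_lag = c_err = center
    yhat = Xb @ b
    Wyhat = lagged(yhat)
    M_Wyhat = Wyhat - Xb @ np.linalg.solve(XtX, Xb.T @ Wyhat)
    D = float(Wyhat @ M_Wyhat) / sigma2  # (W X b)' M (W X b) / sigma^2

    g_lag = d_lag - c_lag
    g_err = d_err - c_err
    lm_lag = g_lag**2 / (D + T1)
    lm_err = g_err**2 / T1
    rlm_lag = (g_lag - g_err) ** 2 / D if D > 0 else np.nan
    denom = T1 - T1**2 / (D + T1)
    rlm_err = (g_err - T1 / (D + T1) * g_lag) ** 2 / denom if denom > 0 else np.nan

    return {
        "lm_lag": _chi2_result("LM spatial lag", lm_lag, 1),
        "lm_error": _chi2_result("LM spatial error", lm_err, 1),
        "robust_lm_lag": _chi2_result("Robust LM lag", rlm_lag, 1),
        "robust_lm_error": _chi2_result("Robust LM error", rlm_err, 1),
    }


def lr_test(full, restricted, df: int | None = None) -> TestResult:
    """Likelihood-ratio test of a restricted model nested in a full one.

    ``df`` defaults to the difference in free-parameter counts inferred
    from the fits' parameter names.  A statistic below -1e-6 signals a
    convergence failure in one of the fits and raises.
    """
    ll_f, ll_r = full.loglik, restricted.loglik
    stat = 2.0 * (ll_f - ll_r)
    if stat < -1e-6:
        raise ValueError(
            f"negative LR statistic ({stat:.3g}): restricted model has higher "
            "likelihood; check nesting/convergence"
        )
    stat = max(stat, 0.0)
    if df is None:
        if not (full.param_names and restricted.param_names):
            raise ValueError("cannot infer df; pass df explicitly")
        df = len(full.param_names) - len(restricted.param_names)
    if df <= 0:
        raise ValueError(f"non-nested models: df={df}")
    return _chi2_result(
        f"LR {getattr(full, 'model', 'full')} vs {getattr(restricted, 'model', 'restricted')}",
        stat,
        df,
    )


def _estimate_vector(fit) -> np.ndarray:
    if isinstance(fit, TwoRegimeSDMFit):
        return np.array([_param_lookup(fit, nm) for nm in fit.param_names])
    if isinstance(fit, ComparisonFit):
        return np.array([fit.params[nm] for nm in fit.param_names])
    raise TypeError(f"unsupported fit type: {type(fit).__name__}")


def wald_test(fit, R: np.ndarray, r: np.ndarray | None = None, name: str = "Wald") -> TestResult:
    """Wald test of the linear restrictions R @ params = r.

    ``R`` has one row per restriction over ``fit.param_names``; ``r``
    defaults to zero.  Statistic (R b - r)' (R V R')^-1 (R b - r) is
    chi-squared with rank(R) df.
    """
    if fit.cov is None:
        raise ValueError("fit carries no covariance matrix")
    R = np.atleast_2d(np.asarray(R, dtype=float))
    b = _estimate_vector(fit)
    if R.shape[1] != len(b):
        raise ValueError(f"R has {R.shape[1]} columns for {len(b)} parameters")
    r = np.zeros(R.shape[0]) if r is None else np.asarray(r, dtype=float)
    diff = R @ b - r
    V = R @ fit.cov @ R.T
    rank = np.linalg.matrix_rank(V)
    if rank < R.shape[0]:
        raise np.linalg.LinAlgError("rank-deficient restriction covariance")
    stat = float(diff @ np.linalg.solve(V, diff))
    return _chi2_result(name, stat, R.shape[0])


def wald_restriction(fit, param_names: list[str]) -> TestResult:
    """Convenience Wald test that the named parameters are jointly zero."""
    R = np.zeros((len(param_names), len(fit.param_names)))
    for i, nm in enumerate(param_names):
        R[i, fit.param_names.index(nm)] = 1.0
    return wald_test(fit, R, name=f"Wald {'+'.join(param_names)}=0")


def hausman_test(
    panel: PanelData, x_names: tuple[str, ...] = COVARIATES
) -> TestResult:
    """Classical Hausman test, fixed vs random effects, non-spatial model.

    Compares the within (FE) estimator with the Swamy-Arora feasible-GLS
    random-effects estimator of Y on the named covariates with one-way
    unit effects.  H = d' (V_FE - V_RE)^-1 d ~ chi-squared(k).  If the
    variance difference is not positive definite the Moore-Penrose
    pseudoinverse is used and the result is flagged in ``note``.
    """
    n, T = panel.n, panel.T
    if T < 2:
        raise ValueError("Hausman test needs T >= 2 (within estimator undefined)")
    k = len(x_names)
    y = panel.outcome
    X = np.stack([panel.covariates[nm] for nm in x_names], axis=-1)  # (n,T,k)

    # within (FE)
    yw = (y - y.mean(axis=1, keepdims=True)).ravel()
    Xw = np.column_stack(
        [(X[:, :, j] - X[:, :, j].mean(axis=1, keepdims=True)).ravel() for j in range(k)]
    )
    XtXw = Xw.T @ Xw
    b_fe = np.linalg.solve(XtXw, Xw.T @ yw)
    e_w = yw - Xw @ b_fe
    s2_eps = float(e_w @ e_w) / (n * (T - 1) - k)
    V_fe = s2_eps * np.linalg.inv(XtXw)

    # between regression on group means (with intercept)
    yb = y.mean(axis=1)
    Xb = np.column_stack([np.ones(n)] + [X[:, :, j].mean(axis=1) for j in range(k)])
    bb, *_ = np.linalg.lstsq(Xb, yb, rcond=None)
    e_b = yb - Xb @ bb
    dof_b = n - (k + 1)
    if dof_b <= 0:
        raise ValueError("too few units for the between regression")
    s2_between = float(e_b @ e_b) / dof_b  # estimates sigma_mu^2 + sigma_eps^2 / T
    s2_mu = max(0.0, s2_between - s2_eps / T)

    # Swamy-Arora quasi-demeaning
    theta = 1.0 - np.sqrt(s2_eps / (s2_eps + T * s2_mu))
    y_star = (y - theta * y.mean(axis=1, keepdims=True)).ravel()
    cols = [np.full(n * T, 1.0 - theta)]
    cols += [
        (X[:, :, j] - theta * X[:, :, j].mean(axis=1, keepdims=True)).ravel()
        for j in range(k)
    ]
    Xs = np.column_stack(cols)
    XtXs = Xs.T @ Xs
    b_re_full = np.linalg.solve(XtXs, Xs.T @ y_star)
    V_re_full = s2_eps * np.linalg.inv(XtXs)
    b_re = b_re_full[1:]
    V_re = V_re_full[1:, 1:]

    d = b_fe - b_re
    Vd = V_fe - V_re
    note = ""
    try:
        L = np.linalg.cholesky(Vd)
        sol = np.linalg.solve(Vd, d)
    except np.linalg.LinAlgError:
        sol = np.linalg.pinv(Vd) @ d
        note = "variance difference not positive definite; Moore-Penrose used"
    stat = float(d @ sol)
    if stat < 0:
        sol = np.linalg.pinv(Vd) @ d
        stat = abs(float(d @ sol))
        note = note or "negative quadratic form; Moore-Penrose used"
    # small-sample reference: the contrast variance is driven by the
    # between regression's n-k-1 df, so H/k is F(k, n-k-1) rather than
    # chi2(k)/k; the chi2 form over-rejects noticeably at n ~ 30
    df2 = n - k - 1
    p = float(stats.f.sf(stat / k, k, df2))
    note = (note + "; " if note else "") + f"p from F({k}, {df2}) small-sample reference"
    return TestResult(name="Hausman FE vs RE", statistic=float(stat), df=k, p=p, note=note)
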