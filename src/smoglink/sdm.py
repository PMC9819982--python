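"""Two-regime spatial Durbin model (SDM) with two-way fixed effects.

The model lets the strength of spatial interaction in the outcome depend
on a unit's position relative to its neighbours.  For regulation strength
Y_it of region i in period t:

    Y_it = rho1 * d_it * (W Y_.t)_i + rho2 * (1 - d_it) * (W Y_.t)_i
           + X_it' beta + (W X_.t)_i' theta + mu_i + lambda_t + eps_it

    d_it = 1  iff  Y_it > (W Y_.t)_i   (strict inequality)

so rho1 measures how strongly a region responds to neighbours when it
already regulates harder than they do, and rho2 when it regulates less.
rho1 > rho2 is the signature of a "race to the bottom" (regions imitate
neighbours' relaxation more strongly); rho1 < rho2 of a "race to the top".

Estimation is maximum likelihood with the regime indicator held fixed at
its observed value.  Unit and time effects are removed by the two-way
within transformation of Y, the regime-split lags d∘WY and (1-d)∘WY, X and
WX; (beta, theta, sigma^2) are concentrated out by least squares for each
(rho1, rho2); the pair (rho1, rho2) maximizes the concentrated
log-likelihood

    L_c(rho1, rho2) = -(nT/2) (log(2 pi sigma_hat^2) + 1)
                      + sum_t log|I - rho1 D_t W - rho2 (I - D_t) W|

over a coarse grid followed by a derivative-free polish (deterministic: no
random starts).  Standard errors come from the numerical Hessian of the
full log-likelihood in (rho1, rho2, beta, theta, sigma^2).  No small-T
bias correction is applied.

Single-regime comparison models (pooled OLS, SAR, SEM, SDM) share the
same within-transformed data and the same log-determinant machinery, so
their log-likelihoods are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .panel import COVARIATES, PanelData
from .weights import SpatialWeights, row_standardize

__all__ = [
    "RegimePanel",
    "TwoRegimeSDMFit",
    "StrategyVerdict",
    "build_regime_indicator",
    "fit_two_regime_sdm",
    "fit_comparison",
    "classify_strategy",
    "staged_fit",
    "within_transform",
    "TwoRegimeLikelihood",
]

RHO_BOUND = 0.99  # admissible |rho| for row-standardized W
GRID_POINTS = 21


class SDMError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# regime indicator


@dataclass(frozen=True)
class RegimePanel:
    """0/1 indicator d_it: 1 iff Y_it strictly exceeds its spatial lag."""

    d: np.ndarray  # (n, T) of {0, 1}
    source: str = "observed"

    def __post_init__(self) -> None:
        d = np.asarray(self.d)
        if not np.isin(d, (0, 1)).all():
            raise SDMError("regime indicator must be 0/1")
        object.__setattr__(self, "d", d.astype(float))

    @property
    def counts(self) -> np.ndarray:
        """Number of regime-1 units per period."""
        return self.d.sum(axis=0).astype(int)

    def to_dict(self) -> dict:
        return {"source": self.source, "d": self.d.astype(int).tolist()}


def build_regime_indicator(Y: np.ndarray, w: SpatialWeights) -> RegimePanel:
    """d_it = 1 iff Y_it > (W Y_.t)_i, with W row-standardized."""
    Y = np.asarray(Y, dtype=float)
    ws = w if w.standardized else row_standardize(w)
    if Y.ndim != 2 or Y.shape[0] != ws.n:
        raise SDMError(f"Y must be (n={ws.n}, T); got {Y.shape}")
    lag = ws.w @ Y
    return RegimePanel(d=(Y > lag).astype(float), source="observed")


# ---------------------------------------------------------------------------
# within transformation


def within_transform(M: np.ndarray, effects: str = "two_way") -> np.ndarray:
    """Demean an (n, T) matrix by unit and/or time means.

    ``two_way`` removes unit means, time means and adds back the grand
    mean; ``unit``/``time`` remove one margin; ``none`` is the identity.
    """
    M = np.asarray(M, dtype=float)
    if effects == "two_way":
        return M - M.mean(axis=1, keepdims=True) - M.mean(axis=0, keepdims=True) + M.mean()
    if effects == "unit":
        return M - M.mean(axis=1, keepdims=True)
    if effects == "time":
        return M - M.mean(axis=0, keepdims=True)
    if effects == "none":
        return M
    raise SDMError(f"unknown effects spec: {effects!r}")


# ---------------------------------------------------------------------------
# likelihood


class TwoRegimeLikelihood:
    """Concentrated and full log-likelihood of the two-regime SDM.

    Built once per fit from the within-transformed data; evaluating the
    concentrated likelihood at any (rho1, rho2) costs one batched
    log-determinant plus a closed-form quadratic.
    """

    def __init__(
        self,
        Y: np.ndarray,
        X: np.ndarray,  # (n, T, k)
        w: SpatialWeights,
        d: np.ndarray,  # (n, T)
        effects: str = "two_way",
        durbin: bool = True,
    ) -> None:
        Y = np.asarray(Y, dtype=float)
        X = np.asarray(X, dtype=float)
        d = np.asarray(d, dtype=float)
        ws = w if w.standardized else row_standardize(w)
        W = ws.w
        n, T = Y.shape
        if d.shape != (n, T):
            raise SDMError("regime indicator shape mismatch")
        self.n, self.T, self.W, self.d = n, T, W, d
        self.N = n * T

        WY = W @ Y
        Z1 = d * WY
        Z2 = (1.0 - d) * WY
        blocks = [X[:, :, j] for j in range(X.shape[2])]
        if durbin:
            blocks += [W @ X[:, :, j] for j in range(X.shape[2])]
        tw = lambda M: within_transform(M, effects)
        self.y = tw(Y).ravel()
        self.z1 = tw(Z1).ravel()
        self.z2 = tw(Z2).ravel()
        self.Xmat = np.column_stack([tw(B).ravel() for B in blocks]) if blocks else np.empty((self.N, 0))
        self.k = self.Xmat.shape[1]

        # regime-split Jacobian factors: A_t = I - rho1 D_t W - rho2 (I-D_t) W
        eye = np.eye(n)
        self._M1 = d.T[:, :, None] * W[None, :, :]  # (T, n, n)
        self._M2 = (1.0 - d.T)[:, :, None] * W[None, :, :]
        self._eye = eye

        # residuals of [y, z1, z2] on X columns -> quadratic form in rho
        if self.k:
            Q, _ = np.linalg.qr(self.Xmat)
            proj = lambda v: v - Q @ (Q.T @ v)
            self._XtX = self.Xmat.T @ self.Xmat
        else:
            proj = lambda v: v
            self._XtX = np.empty((0, 0))
        E = np.column_stack([proj(self.y), proj(self.z1), proj(self.z2)])
        self._C = E.T @ E  # 3x3 cross-products of residualized [y, z1, z2]

        self.regime1_cells = int(d.sum())
        self.regime0_cells = int(self.N - d.sum())
        self.rho1_identified = self.regime1_cells > 0
        self.rho2_identified = self.regime0_cells > 0

        # effective observations left by the demeaning (two-way demeaning
        # spans an (n-1)(T-1)-dimensional space); used only to put the
        # reported covariance on a finite-sample footing
        self.N_eff = {
            "two_way": (n - 1) * (T - 1),
            "unit": n * (T - 1),
            "time": (n - 1) * T,
            "none": n * T,
        }[effects]

    # -- pieces -------------------------------------------------------------

    def log_jacobian(self, rho1: float, rho2: float) -> float:
        """sum_t log|I - rho1 D_t W - rho2 (I - D_t) W|; -inf if singular."""
        A = self._eye[None, :, :] - rho1 * self._M1 - rho2 * self._M2
        sign, logdet = np.linalg.slogdet(A)
        if (sign <= 0).any():
            return -np.inf
        return float(logdet.sum())

    def sse(self, rho1: float, rho2: float) -> float:
        C = self._C
        r = np.array([1.0, -rho1, -rho2])
        return float(r @ C @ r)

    def coefficients(self, rho1: float, rho2: float) -> np.ndarray:
        """(beta, theta) by least squares at fixed (rho1, rho2)."""
        if self.k == 0:
            return np.empty(0)
        rhs = self.Xmat.T @ (self.y - rho1 * self.z1 - rho2 * self.z2)
        return np.linalg.solve(self._XtX, rhs)

    def concentrated(self, rho1: float, rho2: float) -> float:
        """Profile log-likelihood with (beta, theta, sigma^2) maximized out."""
        if max(abs(rho1), abs(rho2)) >= RHO_BOUND:
            return -np.inf
        lj = self.log_jacobian(rho1, rho2)
        if not np.isfinite(lj):
            return -np.inf
        sigma2 = self.sse(rho1, rho2) / self.N
        if sigma2 <= 0:
            return -np.inf
        return -(self.N / 2.0) * (np.log(2 * np.pi * sigma2) + 1.0) + lj

    def full(self, params: np.ndarray) -> float:
        """Log-likelihood at (rho1, rho2, beta/theta..., sigma2)."""
        rho1, rho2 = params[0], params[1]
        coefs = params[2 : 2 + self.k]
        sigma2 = params[-1]
        if sigma2 <= 0:
            return -np.inf
        lj = self.log_jacobian(rho1, rho2)
        if not np.isfinite(lj):
            return -np.inf
        e = self.y - rho1 * self.z1 - rho2 * self.z2
        if self.k:
            e = e - self.Xmat @ coefs
        return (
            -(self.N / 2.0) * np.log(2 * np.pi * sigma2)
            + lj
            - e @ e / (2.0 * sigma2)
        )

    def spectral_ok(self, rho1: float, rho2: float, tol: float = 1e-8) -> bool:
        """Spectral radius of rho1 D_t W + rho2 (I-D_t) W below 1 for all t."""
        B = rho1 * self._M1 + rho2 * self._M2
        for t in range(self.T):
            if np.abs(np.linalg.eigvals(B[t])).max() >= 1 + tol:
                return False
        return True


def _numerical_hessian(f: Callable[[np.ndarray], float], x0: np.ndarray) -> np.ndarray:
    p = len(x0)
    h = 1e-5 * np.maximum(np.abs(x0), 1.0)
    H = np.empty((p, p))
    f0 = f(x0)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        H[i, i] = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej) + f(x0 - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


# ---------------------------------------------------------------------------
# fits


@dataclass(frozen=True)
class TwoRegimeSDMFit:
    """Estimates and inference for the two-regime SDM."""

    rho1: float
    rho2: float
    beta: dict[str, float]
    theta: dict[str, float]
    sigma2: float
    se: dict[str, float]
    z: dict[str, float]
    p: dict[str, float]
    loglik: float
    adj_r2: float
    n: int
    T: int
    converged: bool
    regime_panel: RegimePanel
    rho1_identified: bool = True
    rho2_identified: bool = True
    cov: np.ndarray | None = field(default=None, repr=False)
    param_names: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "rho1": self.rho1,
            "rho2": self.rho2,
            "beta": self.beta,
            "theta": self.theta,
            "sigma2": self.sigma2,
            "se": self.se,
            "z": self.z,
            "p": self.p,
            "loglik": self.loglik,
            "adj_r2": self.adj_r2,
            "n": self.n,
            "T": self.T,
            "converged": self.converged,
            "rho1_identified": self.rho1_identified,
            "rho2_identified": self.rho2_identified,
            "regime1_counts": self.regime_panel.counts.tolist(),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.param_names:
            rows.append(
                {
                    "parameter": name,
                    "estimate": _param_lookup(self, name),
                    "se": self.se.get(name, np.nan),
                    "z": self.z.get(name, np.nan),
                    "p": self.p.get(name, np.nan),
                }
            )
        return pd.DataFrame(rows)


def _param_lookup(fit: TwoRegimeSDMFit, name: str) -> float:
    if name == "rho1":
        return fit.rho1
    if name == "rho2":
        return fit.rho2
    if name == "sigma2":
        return fit.sigma2
    if name.startswith("W*"):
        return fit.theta[name[2:]]
    return fit.beta[name]


def _panel_arrays(panel: PanelData, log_transform: bool = False) -> tuple[np.ndarray, np.ndarray]:
    Y = panel.outcome
    X = panel.covariate_stack()
    if log_transform:
        X = X.copy()
        for j, name in enumerate(COVARIATES):
            if name in ("HC", "PG", "PD", "ES"):
                X[:, :, j] = np.log(X[:, :, j])
    return Y, X


def _maximize_rho(
    lik: TwoRegimeLikelihood, profile_dims: int, tol: float = 1e-8
) -> tuple[np.ndarray, float]:
    """Coarse grid then Nelder-Mead polish of the concentrated likelihood."""
    grid = np.linspace(-0.95 * RHO_BOUND, 0.95 * RHO_BOUND, GRID_POINTS)
    if profile_dims == 2:
        best, best_ll = None, -np.inf
        for r1 in grid:
            for r2 in grid:
                ll = lik.concentrated(r1, r2)
                if ll > best_ll:
                    best, best_ll = (r1, r2), ll
        obj = lambda r: -lik.concentrated(r[0], r[1])
        x0 = np.array(best)
    else:
        which = 0 if lik.rho1_identified else 1
        lls = [
            lik.concentrated(r, 0.0) if which == 0 else lik.concentrated(0.0, r)
            for r in grid
        ]
        x0 = np.array([grid[int(np.argmax(lls))]])
        if which == 0:
            obj = lambda r: -lik.concentrated(r[0], 0.0)
        else:
            obj = lambda r: -lik.concentrated(0.0, r[0])
    # explicit initial simplex at the grid spacing: scipy's default simplex
    # collapses to ~2.5e-4 steps around zero coordinates and stalls
    step = grid[1] - grid[0]
    simplex = [x0]
    for i in range(len(x0)):
        v = x0.copy()
        v[i] = v[i] + step if v[i] + step < RHO_BOUND else v[i] - step
        simplex.append(v)
    res = optimize.minimize(
        obj,
        x0,
        method="Nelder-Mead",
        options={
            "xatol": tol,
            "fatol": tol,
            "maxiter": 2000,
            "initial_simplex": np.array(simplex),
        },
    )
    if profile_dims == 2:
        return res.x, -res.fun
    full = np.array([res.x[0], 0.0]) if lik.rho1_identified else np.array([0.0, res.x[0]])
    return full, -res.fun


def fit_two_regime_sdm(
    panel: PanelData,
    w: SpatialWeights,
    effects: str = "two_way",
    regime: RegimePanel | None = None,
    log_transform: bool = False,
    tol: float = 1e-8,
) -> TwoRegimeSDMFit:
    """ML fit of the two-regime SDM with the observed regime indicator.

    If a regime has no cells (d identically 0 or 1) the corresponding rho
    is unidentified: it is fixed at 0, its standard error reported as NaN
    and the matching ``rho*_identified`` flag cleared.
    """
    ws = w if w.standardized else row_standardize(w)
    Y, X = _panel_arrays(panel, log_transform)
    if regime is None:
        regime = build_regime_indicator(Y, ws)
    lik = TwoRegimeLikelihood(Y, X, ws, regime.d, effects=effects)

    both = lik.rho1_identified and lik.rho2_identified
    rho, ll = _maximize_rho(lik, profile_dims=2 if both else 1, tol=tol)
    rho1, rho2 = float(rho[0]), float(rho[1])
    if not lik.spectral_ok(rho1, rho2):
        raise ConvergenceError(
            f"optimum (rho1={rho1:.4f}, rho2={rho2:.4f}) violates the spectral-radius bound"
        )
    coefs = lik.coefficients(rho1, rho2)
    sigma2 = lik.sse(rho1, rho2) / lik.N

    k = X.shape[2]
    coef_names = list(COVARIATES[:k]) + [f"W*{c}" for c in COVARIATES[:k]]
    param_names = ["rho1", "rho2", *coef_names, "sigma2"]
    theta_full = np.concatenate([[rho1, rho2], coefs, [sigma2]])

    # covariance from the full-likelihood Hessian over identified parameters
    free = [i for i, nm in enumerate(param_names) if not (
        (nm == "rho1" and not lik.rho1_identified)
        or (nm == "rho2" and not lik.rho2_identified)
    )]
    def restricted(v: np.ndarray) -> float:
        full = theta_full.copy()
        full[free] = v
        return lik.full(full)

    H = _numerical_hessian(restricted, theta_full[free])
    cov_free = np.full((len(free), len(free)), np.nan)
    try:
        cov_free = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        pass
    # finite-sample df correction: the ML sigma^2 divides by nT although the
    # within transform leaves N_eff dimensions and 2+2k slopes are estimated
    n_slopes = 2 + lik.k
    df = max(lik.N_eff - n_slopes, 1)
    cov_free = cov_free * (lik.N / df)
    cov = np.full((len(param_names), len(param_names)), np.nan)
    cov[np.ix_(free, free)] = cov_free

    se_vec = np.sqrt(np.where(np.diag(cov) > 0, np.diag(cov), np.nan))
    z_vec = theta_full / se_vec
    p_vec = 2 * stats.norm.sf(np.abs(z_vec))
    se = dict(zip(param_names, se_vec))
    zd = dict(zip(param_names, z_vec))
    pd_ = dict(zip(param_names, p_vec))

    # fit statistics on the within-transformed data
    e = lik.y - rho1 * lik.z1 - rho2 * lik.z2 - (lik.Xmat @ coefs if lik.k else 0.0)
    sst = float(lik.y @ lik.y)
    n_par = 2 + lik.k
    adj_r2 = 1.0 - (e @ e / (lik.N - n_par)) / (sst / (lik.N - 1))

    beta = dict(zip(coef_names[:k], coefs[:k]))
    theta = dict(zip(COVARIATES[:k], coefs[k:]))
    return TwoRegimeSDMFit(
        rho1=rho1,
        rho2=rho2,
        beta=beta,
        theta=theta,
        sigma2=float(sigma2),
        se=se,
        z=zd,
        p=pd_,
        loglik=float(ll),
        adj_r2=float(adj_r2),
        n=panel.n,
        T=panel.T,
        converged=True,
        regime_panel=regime,
        rho1_identified=lik.rho1_identified,
        rho2_identified=lik.rho2_identified,
        cov=cov,
        param_names=tuple(param_names),
    )


# ---------------------------------------------------------------------------
# single-regime comparison models


@dataclass(frozen=True)
class ComparisonFit:
    """A single-regime benchmark fit (OLS / SAR / SEM / SDM)."""

    model: str
    params: dict[str, float]
    se: dict[str, float]
    z: dict[str, float]
    p: dict[str, float]
    sigma2: float
    loglik: float
    adj_r2: float
    n: int
    T: int
    cov: np.ndarray | None = field(default=None, repr=False)
    param_names: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.params,
            "se": self.se,
            "z": self.z,
            "p": self.p,
            "sigma2": self.sigma2,
            "loglik": self.loglik,
            "adj_r2": self.adj_r2,
        }


def _gaussian_ll(N: int, sse: float) -> float:
    sigma2 = sse / N
    return -(N / 2.0) * (np.log(2 * np.pi * sigma2) + 1.0)


def fit_comparison(
    panel: PanelData,
    w: SpatialWeights,
    model: str,
    effects: str = "two_way",
    log_transform: bool = False,
    tol: float = 1e-8,
) -> ComparisonFit:
    """Fit one of the benchmark models on the same within-transformed data.

    ``ols``: pooled least squares, no spatial terms.  ``sar``: spatial lag
    of Y.  ``sem``: spatial error.  ``sdm``: spatial lags of Y and X.
    """
    model = model.lower()
    if model not in ("ols", "sar", "sem", "sdm"):
        raise SDMError(f"unknown model: {model!r}")
    ws = w if w.standardized else row_standardize(w)
    Y, X = _panel_arrays(panel, log_transform)
    n, T = Y.shape
    k = X.shape[2]
    N = n * T
    W = ws.w
    tw = lambda M: within_transform(M, effects)
    y = tw(Y).ravel()
    Xb = np.column_stack([tw(X[:, :, j]).ravel() for j in range(k)])
    WXb = np.column_stack([tw(W @ X[:, :, j]).ravel() for j in range(k)])
    names_x = list(COVARIATES[:k])
    names_wx = [f"W*{c}" for c in names_x]
    N_eff = {"two_way": (n - 1) * (T - 1), "unit": n * (T - 1), "time": (n - 1) * T, "none": N}[effects]

    # eigenvalues of W give T * sum log(1 - rho * eig) for the Jacobian
    eigs = np.linalg.eigvals(W)

    def logdet(rho: float) -> float:
        vals = 1.0 - rho * eigs
        if np.any(vals.real <= 0) and np.all(np.abs(vals.imag) < 1e-12):
            return -np.inf
        return float(T * np.log(vals).sum().real)

    if model == "ols":
        coefs, *_ = np.linalg.lstsq(Xb, y, rcond=None)
        e = y - Xb @ coefs
        sse = float(e @ e)
        ll = _gaussian_ll(N, sse)
        sigma2 = sse / N
        cov_b = (sse / max(N_eff - k, 1)) * np.linalg.inv(Xb.T @ Xb)
        names = names_x
        est = dict(zip(names, coefs))
        se = dict(zip(names, np.sqrt(np.diag(cov_b))))
        rho_name = None
        adj_par = k
        cov = cov_b
    elif model in ("sar", "sdm"):
        Z = Xb if model == "sar" else np.column_stack([Xb, WXb])
        d_ones = np.ones((n, T))
        lik = TwoRegimeLikelihood(Y, X, ws, d_ones, effects=effects, durbin=(model == "sdm"))
        rho_vec, ll = _maximize_rho(lik, profile_dims=1, tol=tol)
        rho = float(rho_vec[0])
        coefs = lik.coefficients(rho, 0.0)
        sse = lik.sse(rho, 0.0)
        sigma2 = sse / N
        names = names_x + (names_wx if model == "sdm" else [])
        param_names_full = ["rho", *names, "sigma2"]
        vec = np.concatenate([[rho], coefs, [sigma2]])

        def full_rho(v: np.ndarray) -> float:
            return lik.full(np.array([v[0], 0.0, *v[1:]]))

        H = _numerical_hessian(full_rho, vec)
        try:
            cov = np.linalg.inv(-H) * (N / max(N_eff - 1 - len(names), 1))
        except np.linalg.LinAlgError:
            cov = np.full((len(vec), len(vec)), np.nan)
        se_all = np.sqrt(np.where(np.diag(cov) > 0, np.diag(cov), np.nan))
        est = dict(zip(param_names_full, vec))
        se = dict(zip(param_names_full, se_all))
        e = lik.y - rho * lik.z1 - Z @ coefs
        rho_name = "rho"
        adj_par = 1 + len(names)
    else:  # sem
        def sem_pieces(lam: float):
            # (I - lam W) applied to the n-vector of each period
            Ym = y.reshape(n, T)
            ys = (Ym - lam * (W @ Ym)).ravel()
            Xs = np.column_stack(
                [(Xb[:, j].reshape(n, T) - lam * (W @ Xb[:, j].reshape(n, T))).ravel() for j in range(k)]
            )
            coefs, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
            e = ys - Xs @ coefs
            return coefs, float(e @ e)

        def conc(lam: float) -> float:
            if abs(lam) >= RHO_BOUND:
                return -np.inf
            lj = logdet(lam)
            if not np.isfinite(lj):
                return -np.inf
            _, sse = sem_pieces(lam)
            return _gaussian_ll(N, sse) + lj

        grid = np.linspace(-0.95 * RHO_BOUND, 0.95 * RHO_BOUND, GRID_POINTS)
        lam0 = grid[int(np.argmax([conc(g) for g in grid]))]
        res = optimize.minimize_scalar(
            lambda g: -conc(g),
            bracket=(lam0 - 0.05, lam0, lam0 + 0.05) if abs(lam0) < 0.9 else None,
            bounds=(-RHO_BOUND + 1e-6, RHO_BOUND - 1e-6),
            method="bounded",
            options={"xatol": tol},
        )
        lam = float(res.x)
        ll = conc(lam)
        coefs, sse = sem_pieces(lam)
        sigma2 = sse / N
        names = names_x
        param_names_full = ["lambda", *names, "sigma2"]
        vec = np.concatenate([[lam], coefs, [sigma2]])

        def full_sem(v: np.ndarray) -> float:
            lam_v, cf, s2 = v[0], v[1 : 1 + k], v[-1]
            if s2 <= 0 or abs(lam_v) >= RHO_BOUND:
                return -np.inf
            lj = logdet(lam_v)
            if not np.isfinite(lj):
                return -np.inf
            Ym = y.reshape(n, T)
            ys = (Ym - lam_v * (W @ Ym)).ravel()
            Xs = np.column_stack(
                [(Xb[:, j].reshape(n, T) - lam_v * (W @ Xb[:, j].reshape(n, T))).ravel() for j in range(k)]
            )
            e = ys - Xs @ cf
            return -(N / 2.0) * np.log(2 * np.pi * s2) + lj - e @ e / (2 * s2)

        H = _numerical_hessian(full_sem, vec)
        try:
            cov = np.linalg.inv(-H) * (N / max(N_eff - 1 - k, 1))
        except np.linalg.LinAlgError:
            cov = np.full((len(vec), len(vec)), np.nan)
        se_all = np.sqrt(np.where(np.diag(cov) > 0, np.diag(cov), np.nan))
        est = dict(zip(param_names_full, vec))
        se = dict(zip(param_names_full, se_all))
        e = y - Xb @ coefs
        rho_name = "lambda"
        adj_par = 1 + k

    sst = float(y @ y)
    adj_r2 = 1.0 - (float(e @ e) / (N - adj_par)) / (sst / (N - 1))
    zd = {kk: est[kk] / se[kk] if se.get(kk) and np.isfinite(se[kk]) and se[kk] > 0 else np.nan for kk in est}
    pv = {kk: 2 * stats.norm.sf(abs(zz)) if np.isfinite(zz) else np.nan for kk, zz in zd.items()}
    return ComparisonFit(
        model=model,
        params={kk: float(v) for kk, v in est.items()},
        se={kk: float(v) for kk, v in se.items()},
        z={kk: float(v) for kk, v in zd.items()},
        p={kk: float(v) for kk, v in pv.items()},
        sigma2=float(sigma2),
        loglik=float(ll),
        adj_r2=float(adj_r2),
        n=n,
        T=T,
        cov=cov,
        param_names=tuple(est.keys()),
    )


# ---------------------------------------------------------------------------
# strategy classification and staged analysis


@dataclass(frozen=True)
class StrategyVerdict:
    """Race-to-the-bottom / race-to-the-top verdict from (rho1, rho2).

    The label follows the point comparison rho1 vs rho2; ``wald_equal_p``
    (the test of rho1 = rho2, when a covariance is available) is attached
    as a caveat statistic and never changes the label.
    """

    label: str  # race_to_bottom | race_to_top | indeterminate
    rho_ratio: float
    wald_equal_p: float | None = None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "rho_ratio": self.rho_ratio,
            "wald_equal_p": self.wald_equal_p,
        }


def classify_strategy(
    fit_or_rho1: "TwoRegimeSDMFit | float", rho2: float | None = None
) -> StrategyVerdict:
    """Classify the competition strategy from the fitted (rho1, rho2).

    Accepts either a :class:`TwoRegimeSDMFit` or the two coefficients
    directly.  rho1 > rho2 -> race_to_bottom; rho1 < rho2 -> race_to_top;
    exact tie or a non-finite coefficient -> indeterminate.
    """
    wald_p = None
    if isinstance(fit_or_rho1, TwoRegimeSDMFit):
        fit = fit_or_rho1
        r1, r2 = fit.rho1, fit.rho2
        if fit.cov is not None and fit.param_names:
            i1 = fit.param_names.index("rho1")
            i2 = fit.param_names.index("rho2")
            var = fit.cov[i1, i1] + fit.cov[i2, i2] - 2 * fit.cov[i1, i2]
            if np.isfinite(var) and var > 0:
                stat = (r1 - r2) ** 2 / var
                wald_p = float(stats.chi2.sf(stat, df=1))
    else:
        if rho2 is None:
            raise SDMError("classify_strategy needs (rho1, rho2) or a fit")
        r1, r2 = float(fit_or_rho1), float(rho2)

    if not (np.isfinite(r1) and np.isfinite(r2)) or r1 == r2:
        label = "indeterminate"
    elif r1 > r2:
        label = "race_to_bottom"
    else:
        label = "race_to_top"
    ratio = r1 / r2 if r2 != 0 else np.nan
    return StrategyVerdict(label=label, rho_ratio=float(ratio), wald_equal_p=wald_p)


@dataclass(frozen=True)
class StagedFits:
    """Per-period-split fits plus their strategy verdicts."""

    stages: tuple[tuple[int, int], ...]
    fits: tuple[TwoRegimeSDMFit, ...]
    verdicts: tuple[StrategyVerdict, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (a, b), fit, verdict in zip(self.stages, self.fits, self.verdicts):
            row = {"stage": f"{a}-{b}", "rho1": fit.rho1, "rho2": fit.rho2}
            row.update({f"z_{p}": fit.z.get(p, np.nan) for p in ("rho1", "rho2")})
            row.update(fit.beta)
            row.update({f"W*{kk}": vv for kk, vv in fit.theta.items()})
            row["adj_r2"] = fit.adj_r2
            row["loglik"] = fit.loglik
            row["verdict"] = verdict.label
            row["rho_ratio"] = verdict.rho_ratio
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "stages": [list(s) for s in self.stages],
            "fits": [f.to_dict() for f in self.fits],
            "verdicts": [v.to_dict() for v in self.verdicts],
        }


def staged_fit(
    panel: PanelData,
    w: SpatialWeights,
    splits: Sequence[tuple[int, int]],
    effects: str = "two_way",
    log_transform: bool = False,
) -> StagedFits:
    """Independent two-regime fits on consecutive year ranges.

    The splits must partition the panel's years and each stage needs at
    least two periods (the within transformation is otherwise degenerate).
    """
    covered: list[int] = []
    for a, b in splits:
        if b - a + 1 < 2:
            raise SDMError(f"stage ({a}, {b}) has fewer than 2 periods")
        covered.extend(range(a, b + 1))
    if sorted(covered) != sorted(panel.years):
        raise SDMError("splits do not partition the panel years")
    fits, verdicts = [], []
    for a, b in splits:
        sub = panel.subset_years(range(a, b + 1))
        fit = fit_two_regime_sdm(sub, w, effects=effects, log_transform=log_transform)
        fits.append(fit)
        verdicts.append(classify_strategy(fit))
    return StagedFits(
        stages=tuple((int(a), int(b)) for a, b in splits),
        fits=tuple(fits),
        verdicts=tuple(verdicts),
    )
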