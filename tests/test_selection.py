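import numpy as np
import pytest
from scipy import stats

import smoglink as sl
from smoglink.sdm import within_transform
from smoglink.selection import wald_restriction


def lm_dense_oracle(panel, w):
    """LM statistics from dense NT x NT kron matrices (literal formulas)."""
    W = w.w
    n, T = panel.n, panel.T
    N = n * T
    # stacking: region-major ravel of an (n, T) matrix -> W_full = W kron I_T
    W_full = np.kron(W, np.eye(T))
    y = within_transform(panel.outcome).ravel()
    X = panel.covariate_stack()
    Xb = np.column_stack([within_transform(X[:, :, j]).ravel() for j in range(6)])
    b = np.linalg.lstsq(Xb, y, rcond=None)[0]
    e = y - Xb @ b
    df = (n - 1) * (T - 1) - 6
    sigma2 = e @ e / df
    # demeaned operator W* = M W_full M via dense projectors
    Qn = np.eye(n) - np.ones((n, n)) / n
    Qt = np.eye(T) - np.ones((T, T)) / T
    M = np.kron(Qn, Qt)
    Ws = M @ W_full @ M
    trWs = np.trace(Ws)
    T1 = np.trace(Ws.T @ Ws) + np.trace(Ws @ Ws)
    center = trWs - np.trace(np.linalg.solve(Xb.T @ Xb, Xb.T @ W_full @ Xb))
    d_lag = e @ W_full @ y / sigma2 - center
    d_err = e @ W_full @ e / sigma2 - center
    Wyhat = W_full @ (Xb @ b)
    MW = Wyhat - Xb @ np.linalg.lstsq(Xb, Wyhat, rcond=None)[0]
    D = Wyhat @ MW / sigma2
    return {
        "lm_lag": d_lag**2 / (D + T1),
        "lm_error": d_err**2 / T1,
        "robust_lm_lag": (d_lag - d_err) ** 2 / D,
        "robust_lm_error": (d_err - T1 / (D + T1) * d_lag) ** 2 / (T1 - T1**2 / (D + T1)),
    }


def test_lm_statistics_match_dense_oracle():
    """Structured trace computations equal literal dense-matrix formulas."""
    for seed in (0, 1, 2):
        sim = sl.simulate_panel(sl.DGPSpec(n=10, T=5, seed=seed))
        got = sl.lm_tests(sim.panel, sim.weights)
        want = lm_dense_oracle(sim.panel, sim.weights)
        for key, val in want.items():
            assert got[key].statistic == pytest.approx(val, abs=1e-10)


def test_lm_type_one_error_calibrated():
    """No spatial dependence: rejection at 5% within [0.035, 0.065]."""
    spec = sl.DGPSpec(rho1=0.0, rho2=0.0, theta=(0.0,) * 6)
    ss = np.random.SeedSequence(3)
    rej_lag = rej_err = 0
    n_rep = 500
    for child in ss.spawn(n_rep):
        sim = sl.simulate_panel(spec, np.random.default_rng(child))
        res = sl.lm_tests(sim.panel, sim.weights)
        rej_lag += res["lm_lag"].p < 0.05
        rej_err += res["lm_error"].p < 0.05
    assert 0.035 <= rej_lag / n_rep <= 0.065
    assert 0.035 <= rej_err / n_rep <= 0.065


def test_lm_lag_dominates_on_sar_data():
    """Strong spatial-lag dependence: LM-lag exceeds LM-error most of the time."""
    spec = sl.DGPSpec(rho1=0.5, rho2=0.5, theta=(0.0,) * 6)
    ss = np.random.SeedSequence(4)
    wins = 0
    n_rep = 50
    for child in ss.spawn(n_rep):
        sim = sl.simulate_panel(spec, np.random.default_rng(child))
        res = sl.lm_tests(sim.panel, sim.weights)
        wins += res["lm_lag"].statistic > res["lm_error"].statistic
        assert res["lm_lag"].p < 0.05  # strong dependence always detected
    assert wins >= 0.8 * n_rep


def test_lr_identical_models_is_zero(sim_small):
    fit = sl.fit_comparison(sim_small.panel, sim_small.weights, "sar")
    res = sl.lr_test(fit, fit, df=1)
    assert res.statistic == 0.0
    assert res.p == pytest.approx(1.0)


def test_lr_power_and_null():
    """SDM vs SAR: rejects when theta != 0, calibrated when theta = 0."""
    power = null_rej = 0
    n_rep = 40
    for rep in range(n_rep):
        sim_alt = sl.simulate_panel(sl.DGPSpec(rho1=0.2, rho2=0.2, seed=200 + rep))
        sdm = sl.fit_comparison(sim_alt.panel, sim_alt.weights, "sdm")
        sar = sl.fit_comparison(sim_alt.panel, sim_alt.weights, "sar")
        power += sl.lr_test(sdm, sar).p < 0.05
        sim_null = sl.simulate_panel(
            sl.DGPSpec(rho1=0.2, rho2=0.2, theta=(0.0,) * 6, seed=600 + rep)
        )
        sdm0 = sl.fit_comparison(sim_null.panel, sim_null.weights, "sdm")
        sar0 = sl.fit_comparison(sim_null.panel, sim_null.weights, "sar")
        null_rej += sl.lr_test(sdm0, sar0).p < 0.05
    assert power >= 0.9 * n_rep
    assert null_rej / n_rep <= 0.15  # near nominal within MC error


def test_lr_rejects_non_nested():
    class Fake:
        loglik = 1.0
        param_names = ("a",)
        model = "fake"

    with pytest.raises(ValueError, match="df"):
        sl.lr_test(Fake(), Fake())


def test_wald_single_constraint_is_z_squared(sim_small):
    fit = sl.fit_comparison(sim_small.panel, sim_small.weights, "sdm")
    name = "W*HC"
    res = wald_restriction(fit, [name])
    z = fit.params[name] / fit.se[name]
    assert res.statistic == pytest.approx(z**2, abs=1e-8)


def test_wald_satisfied_constraint_is_zero(sim_small):
    fit = sl.fit_comparison(sim_small.panel, sim_small.weights, "sar")
    k = len(fit.param_names)
    R = np.zeros((1, k))
    R[0, 0] = 1.0
    res = sl.wald_test(fit, R, r=np.array([fit.params[fit.param_names[0]]]))
    assert res.statistic == pytest.approx(0.0, abs=1e-12)


def test_wald_and_lr_agree_under_true_restriction():
    """Wald and LR are asymptotically equivalent near the null: on data
    where the restriction holds (theta = 0) the two statistics stay within
    20% of each other (they diverge under fixed alternatives)."""
    for rep in range(20):
        sim = sl.simulate_panel(
            sl.DGPSpec(rho1=0.2, rho2=0.2, theta=(0.0,) * 6, seed=900 + rep)
        )
        sdm = sl.fit_comparison(sim.panel, sim.weights, "sdm")
        sar = sl.fit_comparison(sim.panel, sim.weights, "sar")
        lr = sl.lr_test(sdm, sar)
        wald = wald_restriction(sdm, [f"W*{c}" for c in sl.COVARIATES])
        assert abs(wald.statistic - lr.statistic) <= 0.2 * max(lr.statistic, wald.statistic)


def test_hausman_null_calibrated():
    """Effects independent of X: rejection near nominal 5%."""
    spec = sl.DGPSpec(rho1=0.0, rho2=0.0, theta=(0.0,) * 6, sigma_lambda=0.0)
    ss = np.random.SeedSequence(5)
    rej = 0
    n_rep = 500
    for child in ss.spawn(n_rep):
        sim = sl.simulate_panel(spec, np.random.default_rng(child))
        rej += sl.hausman_test(sim.panel).p < 0.05
    assert 0.035 <= rej / n_rep <= 0.065


def test_hausman_power_on_correlated_effects():
    """Unit effects built from unit-mean covariates: FE and RE diverge."""
    spec = sl.DGPSpec(rho1=0.0, rho2=0.0, theta=(0.0,) * 6, sigma_lambda=0.0)
    rej = 0
    n_rep = 50
    for child in np.random.SeedSequence(6).spawn(n_rep):
        rng = np.random.default_rng(child)
        sim = sl.simulate_panel(spec, rng)
        p = sim.panel
        shift = p.covariates["HC"].mean(axis=1) - p.covariates["HC"].mean()
        biased = sl.PanelData(
            region_ids=p.region_ids,
            years=p.years,
            outcome=p.outcome + 3.0 * shift[:, None],
            covariates=p.covariates,
        )
        rej += sl.hausman_test(biased).p < 0.05
    assert rej >= 0.9 * n_rep


def test_hausman_needs_multiple_periods(sim_small):
    p = sim_small.panel
    one_period = sl.PanelData(
        region_ids=p.region_ids,
        years=(p.years[0],),
        outcome=p.outcome[:, :1],
        covariates={k: v[:, :1] for k, v in p.covariates.items()},
    )
    with pytest.raises(ValueError, match="T >= 2"):
        sl.hausman_test(one_period)


def test_p_values_monotone_in_statistic():
    """Larger LR gaps at fixed df always mean smaller p-values."""

    class Fit:
        param_names = ("a", "b")
        model = "full"

        def __init__(self, ll):
            self.loglik = ll

    class Restricted(Fit):
        param_names = ("a",)
        model = "restricted"

    base = Restricted(0.0)
    ps = [sl.lr_test(Fit(gap), base).p for gap in (0.25, 0.5, 1.0, 2.5)]
    assert ps == sorted(ps, reverse=True)
    res = sl.hausman_test(sl.simulate_panel(sl.DGPSpec(seed=0)).panel)
    assert 0.0 <= res.p <= 1.0 and res.statistic >= 0
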