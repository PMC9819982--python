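import numpy as np
import pytest

import smoglink as sl
from smoglink.sdm import SDMError, TwoRegimeLikelihood, within_transform

from conftest import random_weights


def naive_loglik(Y, X, W, d, rho1, rho2, beta, sigma2, effects="two_way"):
    """Per-period determinant / explicit-residual evaluation."""
    n, T = Y.shape
    tw = lambda M: within_transform(M, effects)
    blocks = [X[:, :, j] for j in range(X.shape[2])] + [
        W @ X[:, :, j] for j in range(X.shape[2])
    ]
    y = tw(Y)
    WY = W @ Y
    z1 = tw(d * WY)
    z2 = tw((1 - d) * WY)
    ll = -(n * T / 2) * np.log(2 * np.pi * sigma2)
    for t in range(T):
        A = np.eye(n) - (rho1 * d[:, t] + rho2 * (1 - d[:, t]))[:, None] * W
        ll += np.linalg.slogdet(A)[1]
    e = y - rho1 * z1 - rho2 * z2 - sum(b * tw(B) for b, B in zip(beta, blocks))
    return ll - (e * e).sum() / (2 * sigma2)


# ---------------------------------------------------------------------------
# regime indicator


def test_constant_column_gives_all_zero(ring4):
    Y = np.full((4, 3), 2.5)
    d = sl.build_regime_indicator(Y, ring4)
    assert np.all(d.d == 0)  # strict inequality: lag equals Y


def test_alternating_ring(ring4):
    Y = np.array([[1.0], [-1.0], [1.0], [-1.0]])
    d = sl.build_regime_indicator(Y, ring4)
    np.testing.assert_array_equal(d.d[:, 0], [1, 0, 1, 0])


def test_regime_indicator_matches_per_cell_loop():
    rng = np.random.default_rng(8)
    w = sl.row_standardize(random_weights(rng, 9))
    Y = rng.standard_normal((9, 5))
    d = sl.build_regime_indicator(Y, w).d
    for t in range(5):
        for i in range(9):
            lag = sum(w.w[i, j] * Y[j, t] for j in range(9))
            assert d[i, t] == (1.0 if Y[i, t] > lag else 0.0)


def test_regime_counts(sim_small):
    counts = sim_small.regime.counts
    assert counts.shape == (sim_small.panel.T,)
    assert np.all(counts >= 0) and np.all(counts <= sim_small.panel.n)


# ---------------------------------------------------------------------------
# likelihood


def test_likelihood_matches_naive_evaluation(sim_small):
    """Structured evaluation equals the per-period naive one at random points."""
    p, w, d = sim_small.panel, sim_small.weights, sim_small.regime.d
    X = p.covariate_stack()
    lik = TwoRegimeLikelihood(p.outcome, X, w, d)
    rng = np.random.default_rng(0)
    for _ in range(20):
        rho1, rho2 = rng.uniform(-0.6, 0.6, size=2)
        beta = rng.standard_normal(12)
        sigma2 = float(rng.uniform(0.2, 2.0))
        full = lik.full(np.array([rho1, rho2, *beta, sigma2]))
        naive = naive_loglik(p.outcome, X, w.w, d, rho1, rho2, beta, sigma2)
        assert full == pytest.approx(naive, abs=1e-8)


def test_outcome_shift_single_regime_exactly_invariant(sim_small):
    """Adding a constant to Y moves only the effects in the single-regime
    models: with row-standardized W, rho*W*c = rho*c is absorbed by the
    within transformation, so rho/beta/theta are unchanged."""
    p, w = sim_small.panel, sim_small.weights
    fit0 = sl.fit_comparison(p, w, "sdm")
    shifted = sl.PanelData(
        region_ids=p.region_ids,
        years=p.years,
        outcome=p.outcome + 7.5,
        covariates=p.covariates,
    )
    fit1 = sl.fit_comparison(shifted, w, "sdm")
    for name in fit0.param_names:
        if name != "sigma2":
            assert fit1.params[name] == pytest.approx(fit0.params[name], abs=1e-7)


def test_outcome_shift_two_regime_drift_is_second_order(sim_small):
    """The two-regime model is not exactly shift-invariant (the lag of a
    constant becomes c*(rho1*d + rho2*(1-d)), which is regime-dependent),
    but the regime indicator is invariant and the estimate drift is on the
    order of c*|rho1 - rho2|, far below the estimates themselves."""
    p, w = sim_small.panel, sim_small.weights
    d0 = sl.build_regime_indicator(p.outcome, w)
    fit0 = sl.fit_two_regime_sdm(p, w, regime=sim_small.regime)
    shifted = sl.PanelData(
        region_ids=p.region_ids,
        years=p.years,
        outcome=p.outcome + 7.5,
        covariates=p.covariates,
    )
    d1 = sl.build_regime_indicator(shifted.outcome, w)
    np.testing.assert_array_equal(d0.d, d1.d)
    fit1 = sl.fit_two_regime_sdm(shifted, w, regime=sim_small.regime)
    scale = 7.5 * max(abs(fit0.rho1 - fit0.rho2), 1e-3)
    assert abs(fit1.rho1 - fit0.rho1) <= scale
    assert abs(fit1.rho2 - fit0.rho2) <= scale


def test_degenerate_regime_profile_matches_single_regime(sim_small):
    """With d == 1 the two-regime profile equals the single-regime SDM profile."""
    p, w = sim_small.panel, sim_small.weights
    X = p.covariate_stack()
    ones = np.ones_like(p.outcome)
    two = TwoRegimeLikelihood(p.outcome, X, w, ones)
    one = TwoRegimeLikelihood(p.outcome, X, w, ones, durbin=True)
    for rho in np.linspace(-0.8, 0.8, 17):
        assert two.concentrated(rho, 0.3) == pytest.approx(
            two.concentrated(rho, -0.5), abs=1e-10
        )  # rho2 drops out entirely
        assert two.concentrated(rho, 0.0) == pytest.approx(one.concentrated(rho, 0.0), abs=1e-6)
    fit = sl.fit_two_regime_sdm(p, w, regime=sl.RegimePanel(d=ones))
    sdm = sl.fit_comparison(p, w, "sdm")
    assert fit.loglik == pytest.approx(sdm.loglik, abs=1e-6)
    assert not fit.rho2_identified
    assert np.isnan(fit.se["rho2"])


def test_spectral_radius_constraint_holds_at_optimum(sim_small):
    fit = sl.fit_two_regime_sdm(sim_small.panel, sim_small.weights, regime=sim_small.regime)
    lik = TwoRegimeLikelihood(
        sim_small.panel.outcome,
        sim_small.panel.covariate_stack(),
        sim_small.weights,
        sim_small.regime.d,
    )
    assert lik.spectral_ok(fit.rho1, fit.rho2)
    assert fit.sigma2 > 0 and np.isfinite(fit.loglik)


# ---------------------------------------------------------------------------
# estimation behaviour


def test_null_spatial_dependence_recovered():
    """DGP with rho1 = rho2 = 0: both estimates within 2 SE of zero."""
    sim = sl.simulate_panel(sl.DGPSpec(rho1=0.0, rho2=0.0, seed=1))
    fit = sl.fit_two_regime_sdm(sim.panel, sim.weights, regime=sim.regime)
    assert abs(fit.rho1) <= 2 * fit.se["rho1"]
    assert abs(fit.rho2) <= 2 * fit.se["rho2"]


def test_ols_matches_closed_form(sim_small):
    """Pooled OLS equals the textbook least-squares solution."""
    p, w = sim_small.panel, sim_small.weights
    fit = sl.fit_comparison(p, w, "ols")
    y = within_transform(p.outcome).ravel()
    X = p.covariate_stack()
    Xb = np.column_stack([within_transform(X[:, :, j]).ravel() for j in range(6)])
    b = np.linalg.solve(Xb.T @ Xb, Xb.T @ y)
    for j, name in enumerate(sl.COVARIATES):
        assert fit.params[name] == pytest.approx(b[j], abs=1e-10)


def test_sdm_with_zero_theta_reproduces_sar():
    """SAR loglik equals the SDM profile when the WX terms are dropped."""
    sim = sl.simulate_panel(sl.DGPSpec(rho1=0.2, rho2=0.2, theta=(0,) * 6, seed=3))
    sar = sl.fit_comparison(sim.panel, sim.weights, "sar")
    # direct check: SAR is the durbin=False profile of the same machinery
    lik = TwoRegimeLikelihood(
        sim.panel.outcome,
        sim.panel.covariate_stack(),
        sim.weights,
        np.ones_like(sim.panel.outcome),
        durbin=False,
    )
    assert lik.concentrated(sar.params["rho"], 0.0) == pytest.approx(sar.loglik, abs=1e-8)


# ---------------------------------------------------------------------------
# strategy classification


@pytest.mark.parametrize(
    "rho1, rho2, label",
    [
        (0.163, 0.151, "race_to_bottom"),
        (0.160, 0.170, "race_to_top"),
        (0.075, 0.117, "race_to_top"),
        (0.1, 0.1, "indeterminate"),
    ],
)
def test_classify_strategy_point_rule(rho1, rho2, label):
    verdict = sl.classify_strategy(rho1, rho2)
    assert verdict.label == label


def test_classify_strategy_ratio():
    assert sl.classify_strategy(0.075, 0.117).rho_ratio == pytest.approx(0.641, abs=5e-4)
    assert np.isnan(sl.classify_strategy(0.1, 0.0).rho_ratio)
    assert sl.classify_strategy(0.1, 0.0).label == "race_to_bottom"


def test_classify_strategy_from_fit_attaches_wald(sim_small):
    fit = sl.fit_two_regime_sdm(sim_small.panel, sim_small.weights, regime=sim_small.regime)
    verdict = sl.classify_strategy(fit)
    assert verdict.wald_equal_p is not None
    assert 0.0 <= verdict.wald_equal_p <= 1.0


# ---------------------------------------------------------------------------
# staged fits


def test_staged_fit_partition_errors(sim_small):
    with pytest.raises(SDMError, match="partition"):
        sl.staged_fit(sim_small.panel, sim_small.weights, [(2005, 2008)])
    with pytest.raises(SDMError, match="fewer than 2"):
        sl.staged_fit(sim_small.panel, sim_small.weights, [(2005, 2005), (2006, 2010)])


def test_single_stage_equals_full_fit(sim_small):
    p, w = sim_small.panel, sim_small.weights
    staged = sl.staged_fit(p, w, [(p.years[0], p.years[-1])])
    full = sl.fit_two_regime_sdm(p, w)
    # agreement to optimizer tolerance (copy alignment perturbs means by ulps)
    assert staged.fits[0].rho1 == pytest.approx(full.rho1, abs=1e-6)
    assert staged.fits[0].loglik == pytest.approx(full.loglik, abs=1e-6)
    frame = staged.to_frame()
    assert list(frame["verdict"]) == [staged.verdicts[0].label]


def test_staged_regime_flip_recovered():
    """A mid-series flip of the true rho ordering shows up in the verdicts."""
    hits = 0
    n_rep = 20
    for rep in range(n_rep):
        spec = sl.DGPSpec(
            T=12,
            start_year=2005,
            rho1=(0.25,) * 6 + (0.10,) * 6,
            rho2=(0.10,) * 6 + (0.25,) * 6,
            center_outcome=True,  # race-to-top stages need levels near zero
            seed=100 + rep,
        )
        sim = sl.simulate_panel(spec)
        staged = sl.staged_fit(sim.panel, sim.weights, [(2005, 2010), (2011, 2016)])
        labels = [v.label for v in staged.verdicts]
        hits += labels == ["race_to_bottom", "race_to_top"]
    assert hits >= 0.8 * n_rep
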