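# Methods

## The model

The package's core object is a two-regime spatial Durbin model (SDM) for a
balanced panel of n regions over T years. Writing `Y_t` for the
cross-section of the outcome (regulation strength, RS) in year t, `X_t`
for the n×6 matrix of covariates (HC, PG, PD, ES, URB, IND), and `W` for
the row-standardized contiguity matrix:

    Y_it = ρ1 d_it (W Y_t)_i + ρ2 (1 − d_it)(W Y_t)_i
           + X_it'β + (W X_t)_i'θ + μ_i + λ_t + ε_it,
    d_it = 1{ Y_it > (W Y_t)_i },           ε_it ~ N(0, σ²) i.i.d.

The spatial lag `(W Y_t)_i` is the average outcome of region i's
neighbours. The regime indicator d splits the spatial reaction: ρ1 applies
to regions already above their neighbourhood average, ρ2 to regions below
it. A larger ρ1 means relaxation by neighbours is imitated more strongly
than tightening — a race to the bottom; ρ1 < ρ2 is a race to the top. The
strategy verdict follows the point comparison of the two estimates; a Wald
test of ρ1 = ρ2 is always attached as a caveat statistic but does not
change the label, since near-tie regimes are intrinsically low-power.

Assumptions worth stating explicitly:

* W is binary first-order contiguity read from an adjacency file, then
  row-standardized for estimation. Isolated regions are a hard error; an
  island needs an explicit bridge pair. Whether to row-standardize is a
  modelling choice; it is the field default and both standardizations are
  accepted by the Moran functions.
* μ_i and λ_t are fixed effects, removed by the two-way within
  transformation. The model uses untransformed covariates by default; an
  opt-in flag log-transforms the positive covariates (HC, PG, PD, ES).
* D_t = diag(d_·t) is held fixed at its observed value during estimation.
  The circularity of d depending on Y is a property of the data-generating
  process, handled in the simulator; its consequences for the estimator
  are quantified below.

## Estimation

Fixed effects are removed by two-way demeaning of Y, the two regime-split
lag variables d∘WY and (1−d)∘WY, X and WX. For fixed (ρ1, ρ2) the
coefficients (β, θ) and σ² have closed-form least-squares solutions, so
the log-likelihood

    L = −(nT/2) log(2πσ²) + Σ_t log|I − ρ1 D_t W − ρ2 (I−D_t) W| − e'e/(2σ²)

is concentrated to a two-dimensional surface. Because the residual sum of
squares is a quadratic polynomial in (ρ1, ρ2), each evaluation costs one
batched 30×30 log-determinant per period plus a 3×3 quadratic form. The
surface is maximized by a 21×21 coarse grid over (−0.94, 0.94) followed by
a Nelder–Mead polish (tolerance 1e-8) started from an explicit simplex at
the grid spacing — scipy's default initial simplex collapses to ~2.5e-4
steps around zero coordinates and can stall on the ρ1/ρ2 ridge. The
optimization is deterministic; there are no random starts. At the optimum
the spectral radius of ρ1 D_t W + ρ2 (I−D_t) W is verified to be below 1
for every period.

If a regime is empty (d identically 0 or 1) the corresponding ρ is
unidentified: it is pinned at 0, its standard error reported as NaN, and a
flag cleared. In that case the two-regime likelihood coincides exactly
with the single-regime SDM likelihood, which the tests exploit as an
oracle.

Standard errors come from the numerical Hessian (central differences) of
the full likelihood in (ρ1, ρ2, β, θ, σ²). On top of the inverse Hessian
the covariance is scaled by nT / ((n−1)(T−1) − p), p = 2 + 12: the ML σ²
divides by nT although two-way demeaning leaves only (n−1)(T−1)
dimensions. Against the sampling distribution measured with exogenous
regimes, the corrected standard errors match the Monte-Carlo standard
deviation to within a few percent. No small-T/incidental-parameter bias
correction of the estimates themselves is applied; the measured bias of
the within-ML at n = 30, T = 13 is below 0.01 on ρ, small against
standard errors of comparable size.

Comparison models (pooled OLS, SAR, SEM, SDM) are estimated on the same
within-transformed data so log-likelihoods and adjusted R² (1 − SSE/SST
with a parameter-count adjustment, on the transformed data) are directly
comparable. SAR and SDM reuse the two-regime machinery with d ≡ 1; SEM
transforms both sides by (I − λW) per period.

### Regime endogeneity and what the recovery experiment shows

Because d is a function of Y, ε influences which regime a cell lands in.
Cells whose own-vs-neighbour contrast is smaller than the noise scale are
"flippable", and conditioning on their realized regime correlates ε with
the regime-split regressors, attenuating both ρ estimates and overstating
precision. Measured under the package's own generator: with noise at 1/8
of the cross-sectional contrast scale roughly 10% of cells are flippable
and both ρ's are biased down by ≈0.05; at the default noise (1/40 of the
contrast) the bias is ≈0.003 and 95% Wald intervals cover ≈90%. The
estimator is exactly unbiased with calibrated intervals when regimes are
exogenous — the bias is a property of treating an outcome-dependent regime
as given, and users can quantify it for their own configuration by raising
`sigma_eps` in `recovery_experiment`.

## Specification tests

* **LM tests.** The Anselin LM-lag/LM-error scores and their robust
  variants are computed from pooled OLS residuals with the block-diagonal
  I_T⊗W weight structure. Applied to within-transformed data the classic
  formulas are biased: the demeaned weight operator W* = M (I_T⊗W) M is
  not trace-free (tr W* = −(1'W1/n)(T−1) under two-way demeaning), so the
  scores are centred at tr(P W* P) (P the full residual projector) and the
  trace term T1 is computed from W*; σ² uses the demeaned degrees of
  freedom. With no demeaning this reduces exactly to the textbook
  cross-section formulas. Null rejection rates at n=30, T=13 are within
  a point of the nominal 5%.
* **LR and Wald.** Standard; the LR statistic is validated non-negative
  (a negative value signals a convergence failure and raises). Wald and
  LR agree to ~15% under true restrictions; under strong alternatives
  they legitimately diverge.
* **Hausman.** The classical FE-vs-RE contrast on the non-spatial panel
  regression, with Swamy–Arora feasible GLS for the random-effects side
  and the within σ̂² used in both covariances. The χ²(k) reference
  over-rejects at n = 30 (the contrast variance is driven by the between
  regression's n−k−1 degrees of freedom), so the p-value uses the
  F(k, n−k−1) small-sample reference; the note on the result says so.

## Moran's I

Global I uses the population variance S² = Σ(x−x̄)²/n; E[I] = −1/(n−1).
Normal-approximation p-values use the randomization moments; the
permutation test reports the two-sided pseudo p-value
(1 + #{|I_perm − E[I]| ≥ |I_obs − E[I]|})/(n_perm+1), vectorized over all
permutations, reproducible by seed. The local statistic is the Anselin
form I_i = (x_i−x̄)/S² · Σ_j w_ij (x_j−x̄); with row-standardized W the
mean of the local values equals the global I, which is tested. Quadrant
labels are computed from mean-deviations of x and of the lag of those
deviations; exact zeros count as "high" so every region gets a
deterministic label.

## Gravity networks

Intensities follow the modified gravity form with the GDP-share factor
K = G_i/(G_i+G_j), which makes the network directed with the exact
identity T_ij/T_ji = G_i/G_j. The distance-decay exponent defaults to
b = 2 (haze disperses over a two-dimensional field). Masses enter as the
plain product P_i G_i P_j G_j; a `sqrt_masses` flag switches to the
classical square-root form for sensitivity analysis. The default edge
rule retains i→j iff T_ij is at least the mean of row i's intensities;
"all" and absolute-cutoff rules are available. The coordination index is
this package's own summary — 1 minus the share of total intensity carried
by retained edges — so concentrated linkage scores near 0 and evenly
spread linkage scores high; under the row-mean rule a perfectly uniform
network retains every edge and scores 0, a documented edge case.

## The synthetic generator

The generator emulates a 30-region, 13-year balanced panel. Covariates
are AR(1)-in-time latent Gaussian fields (persistence 0.8), smoothed by
one pass of (I+W)/2, then mapped to realistic provincial magnitudes:
log-normal levels for HC (median 45 µg/m³), PG, PD, ES, and logistic
fractions for URB (≈0.50) and IND (≈0.45). The outcome is drawn from the
two-regime SDM: for each period, starting from the single-regime solution
at the average ρ, the generator alternates solving Y given d and
recomputing d = 1{Y > WY} until the indicator stabilizes, with a restart
from d ≡ 1 and a sequential cell-at-a-time sweep as fallbacks. A
converged draw satisfies the outcome equation and the regime rule
*exactly*: plugging the true parameters back in recovers the drawn noise
to machine precision, and `build_regime_indicator` reproduces the
returned d bit-for-bit.

Default interaction strengths are ρ1 = 0.163, ρ2 = 0.151 with β and θ at
empirically plausible magnitudes, so simulations exercise the estimator
in the near-tie regime where it is actually used. Error scales default to
σ_μ = 1.0, σ_λ = 0.3, σ_ε = 0.1: regulation-intensity differentials
across regions are persistent institutional quantities (intraclass
correlation near 1), so the regime indicator is structurally determined —
the estimator's maintained assumption. Raising σ_ε toward the contrast
scale is the supported way to probe the selection bias described above.

**Level sensitivity of the strict rule.** Holding other cells fixed, cell
i is consistent with d = 1 iff base_i > (1−ρ1)·lag_i and with d = 0 iff
base_i ≤ (1−ρ2)·lag_i; a gap with no consistent assignment opens exactly
when lag_i(ρ1 − ρ2) < 0. At realistic positive outcome levels every lag
is positive, so race-to-bottom orderings (ρ1 > ρ2) always admit a
self-consistent draw — while race-to-top orderings (ρ2 > ρ1) admit none:
exhaustive search over all 2^n regime configurations at n = 8 confirms
generic non-existence, and a regime switch at those levels moves a cell's
outcome by |ρ1−ρ2|·level, swamping the own-vs-neighbour contrast. When no
joint solution exists the generator falls back to a predetermined regime
(taken from the average-ρ solution), reports the count of rule-violating
cells in `regime_mismatch`, and marks the regime `predetermined` rather
than raising. For meaningful ρ2 > ρ1 simulations set
`center_outcome=True`, which subtracts the structural grand mean so the
outcome fluctuates around zero; regime violations then drop to a few
percent of cells and a mid-series strategy flip is recovered by the
staged fits essentially always. This level sensitivity is a property of
the model's strict comparison rule, not of the implementation.

What the generator does **not** emulate, and hence what passing tests do
not show about real data: serially correlated or spatially correlated
noise, measurement error in the covariates, missing-data interpolation,
regime rules based on anything but the contemporaneous spatial lag, and
covariate distributions calibrated to any particular yearbook. The
generator is a verification harness for the estimator and pipeline, not a
calibrated replica of the study system.

## Numerical choices and degenerate inputs

* Admissible region |ρ| < 0.99 with per-period spectral-radius checks;
  the log-determinant returns −∞ outside it.
* Exact ties Y = WY assign regime 0 (the rule is a strict inequality);
  ties are measure-zero under continuous noise.
* Constant x is a degenerate-variance error for Moran's I; n < 3 is
  rejected; permutation tests require ≥ 99 permutations.
* Validation is total: `validate_panel` returns findings (one per
  violation) and never raises on finite numeric input.
* JSON serialization uses repr-accurate floats; numeric fields round-trip
  to 1e-12. Optimizer-dependent quantities (ρ estimates) are reproducible
  to ~1e-6 across equivalent in-memory layouts, limited by the 1e-8
  optimizer tolerance and ulp-level differences in vectorized reductions.

## Problem sizes in the test suite

The suite simulates at the study scale (n = 30, T = 13) for calibration
experiments — 100 replicates for parameter recovery, 500 for each
type-I-error rate — and at n = 10–20 with T = 5–8 for oracle and
round-trip checks, which keeps the default run at about a minute on one
CPU while exercising every code path. `scripts/acceptance.py` re-runs the
full chain at those same sizes.

## Known limitations

* The estimator inherits the fixed-regime assumption; its selection bias
  under noisy regime assignment is documented, not corrected (GMM/IV
  treatments of the indicator's endogeneity are out of scope).
* No small-T bias correction for fixed-effects spatial ML.
* Impact (direct/indirect effect) decompositions are not computed.
* Contiguity must be supplied as an adjacency list; the package does not
  derive it from geometry.
* The real study's data (provincial yearbooks, satellite-derived PM2.5)
  are not bundled; all quantitative claims in the tests are about the
  synthetic conditions above.
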