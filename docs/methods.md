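# Methods

## Model

`itsarima` estimates the impact of one or more interventions on an
equally spaced univariate series by interrupted time series (ITS)
analysis with a seasonal ARIMA error structure:

    phi(B) Phi(B^s) (1-B)^d (1-B^s)^D [ Y_t - sum_j f_j(B) X_jt ]
        = c + theta(B) Theta(B^s) eps_t,    eps_t ~ iid N(0, sigma^2)

* `Y_t` — the outcome (a rate, mean, or large count; Gaussian errors are
  assumed, so small Poisson-like counts are out of scope);
* `X_jt` — intervention inputs: step (sustained level shift), pulse
  (one-period disturbance) or ramp (slope change), each optionally
  delayed by whole periods;
* `f_j(B) = omega_j(B)/delta_j(B)` — rational transfer functions; with
  h = 0, r = 0 the impact is `omega_0 * X_t` (abrupt); with r = 1 it
  builds up or decays geometrically at rate `delta_1`, `|delta_1| < 1`.
  h = 0 and r in {0, 1} are the supported surface; higher orders are
  accepted but flagged experimental;
* differencing orders d (trend) and D (seasonality, lag s) induce
  stationarity; d + D > 3 is rejected.

The regression-with-ARIMA-errors form above (regressors differenced
identically to the outcome) keeps `omega` interpretable in outcome units
on the level scale.

## Estimation

Exact Gaussian maximum likelihood:

1. The outcome and every regressor column are differenced d regular and
   D seasonal times (n_effective = n - d - D*s observations remain).
2. For given ARMA coefficients the likelihood is evaluated by the
   innovations decomposition: a Harvey companion-form state space with
   the *stationary* initial covariance (solved as a discrete Lyapunov
   equation).  The covariance recursion is data-independent, so the
   gains are computed once per parameter value and applied jointly to
   the outcome and all regressor columns; the regression coefficients
   then drop out by exact GLS on the whitened columns and sigma^2 by its
   closed form.  Pure-AR models bypass the filter via Cholesky whitening
   of the first p observations plus the AR recursion (same likelihood,
   much faster inside simulation loops; the equivalence is property-
   tested).
3. The remaining low-dimensional optimisation over (phi, theta, Phi,
   Theta, delta) runs in an unconstrained space mapped to the
   stationary/invertible region through partial autocorrelations
   (tanh-transformed), so every iterate is a valid model.  L-BFGS-B with
   relative function tolerance 1e-12; up to 5 restarts from perturbed
   starts (fixed internal seed 0) if the optimiser reports failure.
   Estimates with any partial correlation beyond 0.998 in magnitude
   trigger a boundary warning (SEs there are unreliable).
4. Standard errors: inverse numerical Hessian (central differences,
   adaptive steps that shrink rather than cross the stationarity
   boundary) of the non-concentrated negative log-likelihood over all
   natural coefficients and log sigma^2.  95% CIs are estimate
   +- 1.96 SE (Wald).
5. The constant is included only when d = D = 0 (a constant under
   differencing would imply a deterministic polynomial trend);
   user-overridable.  Internally the constant is the process mean mu;
   the recursion constant c = mu * phi_full(1) is also reported.
6. Parameter count for the information criteria includes every free
   coefficient plus sigma^2: AIC = -2l + 2k, BIC = -2l + k log(n_eff),
   AICc = AIC + 2k(k+1)/(n_eff - k - 1).

Forecasts iterate the difference-equation form of the fitted model with
innovations from the Kalman pass; prediction variances come from the
psi-weights of the integrated process, so interval width is
non-decreasing in horizon.  Forecast intervals ignore parameter
uncertainty (the standard textbook convention).

## Differencing recommendation

`choose_differencing` is advisory (explicit d/D always win):

* **D** in {0, 1}: the series is detrended by one regular difference and
  the lag-s autocorrelation compared with the +-1.96/sqrt(n) band.
  Difference-detrending rather than OLS-detrending is used because a
  stochastic trend survives OLS detrending and masks the seasonal spike.
  Requires n >= 2s + 10; otherwise D = 0 with a warning.
* **d** in {0, 1, 2} by repeated augmented Dickey-Fuller testing
  (constant-only regression, AIC-chosen augmentation lags) on the
  (seasonally differenced) series.  The first difference is taken at the
  conventional alpha = 0.05.  Escalating to d = 2 requires the ADF on
  the once-differenced series to show essentially *no* evidence of
  stationarity (p > 0.5): in series of a few dozen points the ADF has
  very low power, and over-differencing is the costlier error — it
  plants a near-non-invertible MA root and inflates forecast variance.

## Order selection

`auto_search` is a constrained stepwise walk: seed models (2,d,2),
(0,d,0), (1,d,0), (0,d,1) with seasonal analogues (1,D,1), (0,D,0),
(1,D,0), (0,D,1) when s > 1; repeatedly evaluate all neighbours
differing by +-1 in one of p, q, P, Q within the caps (5/5/2/2 by
default, user-modifiable); move to the best information-criterion value;
stop at a local minimum.  Ties break toward fewer parameters, then lower
q, then lower p (parsimony).  Candidates that fail to converge are
skipped and logged in the returned trace, from which local optimality is
assertable.  The default criterion is AICc (small-sample correction);
note that for *order recovery* BIC is the consistent choice — with AIC
or AICc a spurious extra term wins with the usual ~16% chi-square
probability, so on short series several orders are genuinely
near-equivalent and re-selection of one specific order across
realisations should not be expected.  `delay_search` refits a fixed
order with the onset shifted over a 0..K window and returns the
criterion-minimising delay with the full comparison table.

## Diagnostics

Ljung-Box Q = n(n+2) sum_{k<=L} r_k^2/(n-k) against chi-square with
L - fitdf degrees of freedom; `fitdf` counts only the ARMA terms
(p+q+P+Q), not the constant or sigma^2, matching the dominant convention
(R's `Box.test` fitdf) — stated prominently because the df convention
changes the p-value and is often left implicit.  Default L =
min(24, n_eff/2).  `residual_report` adds the residual ACF with bands, a
Jarque-Bera normality check, and a white-noise verdict at alpha = 0.05
(fail to reject = adequate fit).  Residuals are the standardised
one-step innovations of the differenced model.

## Effects and the counterfactual

The pointwise effect at post-onset horizon k sums each intervention's
closed-form transfer response (step: omega_0; ramp: (k+1) omega_0;
pulse with r=1: omega_0 delta^k), with delta-method CIs from the joint
coefficient covariance; the cumulative effect is the running sum with a
CI on the sum.  The default counterfactual is the *regression-adjusted*
prediction — the fitted model's one-step predictions with every
intervention regressor zeroed — which is exactly the arithmetic implied
by quoting "step + k ramp fewer events"; a dynamic-forecast variant
(refit the pre-period, forecast across the post-period with inputs at
zero) is available as a sensitivity mode.  Effects computed beyond the
observed study period are returned but flagged as extrapolation.  On a
log-transformed outcome, effects are additionally reported as percent
change.

## Synthetic data

`make_sarima_dataset` draws a SARIMA realisation (burn-in of at least
10(p+q+s) discarded before integration), adds transfer-function impact
signals on the level scale, and records the full truth for recovery
scoring; byte-identical output given the same seed.

`make_quetiapine_like_fixture` is the synthetic stand-in for the kind of
monthly dispensing series produced by Australian claims data under
Safety-Net co-payment seasonality: 48 months (2011-01..2014-12),
baseline 29,000 + 110/month trend, a fixed sum-zero monthly profile with
a +3,200 December peak and a −2,600 January trough, SARIMA
(2,1,0)(0,1,1)_12 noise with phi = (−0.45, −0.35), Theta = −0.6, and an
injected policy impact from month 37: step −3,285 and ramp −1,397
dispensings/month.  The noise scale sigma = 600 was fixed once so that
the fitted step's standard error is of the order typical for a national
dispensing analysis of this size (step ≈ 10% of the series level,
roughly five to six standard errors).  What the fixture does *not* emulate: calendar
artefacts (trading days, holidays), outliers, heteroscedasticity,
slowly drifting seasonal amplitude, and reporting revisions — so green
recovery tests demonstrate correctness of the estimator under the stated
model, not robustness to real-data pathologies.  One consequence worth
stating: across fixture realisations the step/ramp *estimates* vary with
sampling noise (SE ~550 and ~100), and information criteria frequently
prefer a neighbouring order to the generating one, as expected in a
48-point series; single-realisation agreement with any particular
published analysis is therefore approximate by nature.

## Problem sizes used in the test suite

Simulation-based tests use sizes chosen to make their statistical
assertions sharp but cheap: AR(1) interval coverage at n = 300 over 200
replicates; step-impact CI recovery on seasonal ITS at n = 120 over 50
seeds; Ljung-Box size at n = 1000 over 500 replicates; order-recovery
checks at n = 500 over 10–12 seeds under BIC; oracle-equivalence against
statsmodels SARIMAX on 20 datasets of n = 200.  All random draws are
seeded; the acceptance script derives every stream from its `--seed`.

## Known limitations

* Gaussian likelihood only — not suitable for small counts.
* h > 0 numerator lags and r > 1 denominators are accepted but
  unsupported by the closed-form effect table (delays are modelled by
  shifting the onset instead).
* No missing-data handling or irregular spacing, by design.
* Control-series designs are two pipeline runs compared narratively;
  no formal synthetic-control machinery.
* Wald CIs undercover modestly in very short series, a generic
  small-sample property of maximum-likelihood ARIMA inference.
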