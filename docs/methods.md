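# Methods

## Model

Each one-minute ECG segment `x` (6000 samples at 100 Hz) is modeled as
an ARIMA(p, d, q) conditional mean whose innovations follow a
GARCH-family conditional variance. Writing `w = (1 − L)^d x` for the
differenced series and `ε_t` for the innovations,

```
(1 − Σ a_k L^k) w_t = (1 + Σ b_k L^k) ε_t,     ε_t = σ_t Z_t,  Z_t ~ N(0,1)
```

with the variance recursion chosen from:

* ARCH(q):      σ²_t = α₀ + Σᵢ αᵢ ε²_{t−i}
* GARCH(p, q):  adds Σⱼ βⱼ σ²_{t−j}
* GJR(p, q):    adds Σᵢ γᵢ 1[ε_{t−i} < 0] ε²_{t−i} (leverage)
* EGARCH(p, q): log σ²_t = α₀ + Σᵢ [θᵢ Z_{t−i} + λᵢ(|Z_{t−i}| − √(2/π))]
                + Σⱼ βⱼ log σ²_{t−j}

Innovations are Gaussian throughout (quasi-MLE: the variance dynamics
remain consistently estimated under mild misspecification); Student-t
and GED innovations are out of scope.

### Parameter naming and the EGARCH form

Across all families `alpha` denotes shock loadings and `beta`
persistence coefficients; order tuples are written (p = persistence
lags, q = shock lags), so "EGARCH(1,5)" is one log-variance lag and
five shock lags. The literature sometimes swaps the α/β symbols between
the shock and persistence sides of the EGARCH recursion; this package
normalizes to the single convention above.

A form that multiplies a *shared* news-impact function
g(Z) = θZ + λ(|Z| − E|Z|) by per-lag loadings is not identifiable (the
loading and (θ, λ) only enter through their product), so the EGARCH
implementation uses the identifiable per-lag form: one sign coefficient
θᵢ and one magnitude coefficient λᵢ per shock lag. For q = 1 this is
exactly Nelson's EGARCH(1,1). EGARCH coefficients carry no sign
restrictions; only |Σβⱼ| < 1 is enforced so log-variance is stationary.

## Estimation

**ARIMA.** Conditional (CSS-style) Gaussian likelihood with zero
pre-sample values, innovations from
ε_t = w_t − Σ a_k w_{t−k} − Σ b_k ε_{t−k}, summed over t > max(p, q).
At segment length 6000 this coincides asymptotically with the exact
state-space likelihood (the test suite cross-checks against
statsmodels' exact MLE). The mean of the differenced series is
subtracted before fitting and added back in fitted values; the
recursion itself has no intercept. Stationarity and invertibility are
enforced by optimizing in partial-autocorrelation space (the
Levinson–Durbin bijection from (−1, 1)^k, applied to the AR polynomial
and the negated MA polynomial), starting from a Hannan–Rissanen
long-AR regression, with L-BFGS-B followed by a Nelder–Mead polish and
the innovation variance concentrated out. Objective tolerance 1e−8.

**Volatility models.** Gaussian quasi-MLE over t > max(p, q) with the
first max(p, q) variances pinned to the sample variance of the input
(pre-sample shocks zero). Positivity is handled by log-transforming
α₀, αᵢ, βⱼ (GARCH side) and tanh-bounding Σβ for EGARCH; covariance
stationarity (Σα + Σβ + ½Σγ < 1, with ½γ from the symmetric-innovation
expectation of the indicator) is a hard barrier in the objective.
Optimization runs Nelder–Mead then L-BFGS-B from **two starts** — a
persistent one (α ≈ 0.1, β ≈ 0.8) and a low-persistence one — because
on data with no ARCH effect the likelihood is exactly flat along the
ridge α → 0, α₀ = var·(1 − β), and a single persistent start would
report an arbitrary β. On a near-tie the less persistent solution wins,
and a final parsimony sweep shrinks the dynamics toward zero whenever
that costs less than a 1e−4 relative likelihood change (it never fires
on genuinely heteroskedastic data, where halving persistence costs
hundreds of log-likelihood units).

**Composite.** Stage 1 fits the ARIMA mean, stage 2 the volatility
model on its innovations. Joint mode (the default) then re-maximizes
Σₜ −½(log 2π + log σₜ²(θ_vol) + εₜ²(θ_mean)/σₜ²(θ_vol)) over both
parameter blocks from the two-stage start (Nelder–Mead); the two-stage
iterate is kept whenever the optimizer fails to improve on it, so the
joint likelihood never decreases. Joint refinement is
heteroskedasticity-weighted (GLS-style) re-estimation of the mean:
*in-sample* the unweighted CSS fit minimizes one-step MSE by
construction, so the composite's advantage is a *held-out* property —
its mean estimates are statistically more efficient under real
heteroskedasticity and predict new segments from the same process
better. The error-ordering study is designed accordingly (estimate on
one segment, evaluate on held-out segments), mirroring the
estimate-on-half / validate-on-rest design of the underlying study.

**Fitted values.** One-step conditional means on the original scale are
`fitted_t = x_t − ε_t` through the integration relation; the first
d + max(p, q) positions copy the observation (no prediction exists
there), so every segment yields a full-length vector and all models are
scored over identical index sets. A pure volatility model has zero
conditional mean: its "fitted" series is identically zero at predicted
indices, with the σₜ path exported separately for ±σ envelopes.

## Diagnostics

* **Moments** use population (biased) estimators; kurtosis is the raw
  fourth standardized moment (3 under Gaussianity, ≥ 1 always).
* **Engle ARCH-LM**: squared demeaned residuals regressed on a constant
  and their first `lags` lags (default 1); statistic n_eff·R² against
  the χ²(lags) critical value (3.8415 at 5% with one lag).
* **Wilcoxon signed-rank** (paired, e.g. segment vs. an equal-length
  series simulated from the fitted volatility model, paired by index):
  W = sum of positive-difference midranks, zero differences dropped,
  z = (W − n(n+1)/4) / √((n(n+1)(2n+1) − tieadj)/24) with
  tieadj = Σ(t³ − t)/2 over tied groups — exactly the enumerated null
  mean and (tie-conditional) variance. Two-sided p from the normal
  approximation without continuity correction. That approximation's
  worst-case deviation from the exact enumerated p is ≈ 0.05–0.10 for
  n ≤ 10 and falls below 0.01 only around n ≈ 40–60; the test suite
  therefore asserts exactness of W and z against enumeration at small n
  and the < 0.01 p-agreement at n = 60.
* **Distribution comparison**: shared-bin histograms, a Gaussian
  reference density from the first sample's moments, ECDFs, and the
  two-sample Kolmogorov–Smirnov distance as a numeric stand-in for the
  visual overlay.

## Order selection and metrics

AIC and BIC are used in per-observation normalized form
(2k/n − 2 ln L/n and k ln n/n − 2 ln L/n); for fixed segment length the
ranking is identical to the classical criteria (property-tested).
`k` counts every estimated coefficient including the ARIMA innovation
variance and the volatility α₀. Grid search fits every candidate,
excludes non-converged fits, and breaks ties by fewer parameters then
lexicographically smaller orders. Shipped defaults are ARIMA(5,2,4) and
EGARCH(1,5) — defaults, not constants.

MAPE divides by |observed|; since ECG amplitudes cross zero, the
default excludes zero-observation indices and reports their count (a
naive mode keeping them — and hence producing the huge MAPE spreads
seen with unguarded division — is available). Group aggregation reports
mean and sample std (ddof = 1; 0 for singleton groups) per metric,
label and model.

## Synthetic data

`synthetic.make_ecg_like` builds surrogate segments as a quasi-periodic
spike train (Gaussian bumps of ~1 mV, width 25 ms, at ~1 Hz with
jittered intervals) plus a composite ARIMA–EGARCH noise process. It
makes no claim of physiological fidelity (no P/T waves, no respiratory
modulation, no artifacts); it exists to carry the statistical structure
the diagnostics target — heavy tails (segment kurtosis ≫ 3, driven by
the spikes, as in real ECG), volatility clustering, nonstationary mean
(d = 1 noise). Passing tests on it show the estimators and tests work
as specified, not that real recordings follow the model.

Regime defaults live in `src/ecgvol/regimes.yaml`. The apnea-like
regime has stronger volatility persistence and shock loading
(β = 0.95, λ = 0.35, θ = −0.15) than the normal-like one (β = 0.80,
λ = 0.15, θ = −0.05); the innovation scale is ~1 µV so the integrated
baseline wander stays small against the beats. The homoskedastic
control zeroes every dynamic (i.i.d. Gaussian samples, no beats) and
exists purely for test-size calibration. All generators are pure
functions of their parameters and seed.

## Study sizes

The simulation studies in `ecgvol.studies` (shared by the test suite
and `scripts/acceptance.py`) use: parameter recovery at n = 20000
averaged over 20 seeds per family; test-size calibration with 10⁴
replicates (n = 500 for Engle, paired n = 50 for Wilcoxon); the
held-out error ordering with 25 replicates × (1 training + 2 evaluation)
segments of n = 6000, i.e. 50 evaluation segments; and BIC selection
over a 30-candidate grid at n = 6000 for 20 seeds. These sizes keep
Monte-Carlo error well inside the assertion bands while the whole
battery completes in a few minutes on one CPU.

## Known limitations

* Conditional (not exact) ARIMA likelihood: negligible at n = 6000 but
  not for very short series.
* Gaussian innovations only; heavy-tailed innovation families would
  change the quasi-MLE weighting, not the interface.
* No apnea *detection* is provided — the package models segments; using
  the fitted parameters as classifier features is downstream work.
* The WFDB reader covers signal formats 16 and 212 and MIT-format
  annotation streams, which is sufficient for the Apnea-ECG database
  layout, not the full WFDB specification.
* One-step prediction only; multi-step forecasting and seasonal ARIMA
  are out of scope.
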