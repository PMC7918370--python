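# Methods

`tsgc` compares the mean curves of groups of time series measured on a common
grid. It was built around a concrete use case — chlorophyll-fluorescence
de-etiolation curves of *Arabidopsis* genotypes, 27 seedlings (3 genotypes ×
3 experiments × 3 replicas) sampled 121 times at 2-minute intervals — but the
machinery is generic: any panel of complete, equally spaced series with a
group label per subject.

## The model

Stage 1 fits a single linear mixed model to the whole panel:

    y_ij = b0 + b1·t_i + b2·t_i² + Σ_g b_g·1[group(j)=g]
         + u_0j + u_1j·t_i + u_2j·t_i² + ε_ij

* `t_i` is the integer time index 1..T. Minutes are a reporting convention
  (`minutes = interval·(index−1)`); coefficients are reported on the index
  scale.
* Groups are dummy-coded against a reference; group enters the fixed part
  only. Putting group in the random part is redundant (each subject already
  has its own curve) and destabilizes the fit.
* `(u_0j, u_1j, u_2j)` — subject-specific intercept, slope and curvature —
  are drawn from an unstructured (fully free, symmetric PD) 3×3 covariance.
* Estimation is maximum likelihood by default so mean structures (quadratic
  vs cubic) can be ranked by AIC; REML is available behind a flag but its
  likelihoods are not comparable across mean structures.
* AIC/BIC count k = #fixed + q(q+1)/2 + 1 free parameters (fixed effects,
  free covariance entries, residual variance): k = 12 for the standard
  three-group quadratic model.

Stage 1 intentionally leaves serial structure in ε_ij: with measurements
minutes apart, ε_ij is autocorrelated, and any per-timepoint test computed
from the stage-1 fit alone inherits that misspecification.

Stage 2 therefore models each subject's residual series with its own
ARIMA(p_j, d_j, q_j): `d_j` from repeated KPSS level-stationarity tests
(with a configurable floor, default `min_d = 1`, because smooth trends
typically survive the quadratic fit), and `(p_j, q_j)` by a stepwise AICc
neighbourhood search in the style of the Hyndman–Khandakar auto-ARIMA
algorithm, starting from {(0,d,0), (1,d,0), (0,d,1), (2,d,2)} and moving by
±1 steps in p and/or q (toggling a constant/drift term when d ≤ 1) until no
neighbour improves. Candidates whose AR or MA roots sit on the unit circle
are skipped when d = 0 (they are numerically fragile overfits); at d ≥ 1 a
unit MA root is the legitimate signature of (possibly forced)
overdifferencing and is kept. Seasonal orders are carried on the interface
but never fitted — the target data are nonseasonal.

The combined fit adds the ARIMA one-step in-sample prediction ε̂_ij to the
stage-1 fitted value; the remainder r_ij = ε_ij − ε̂_ij should be white,
which the ACF diagnostics check against the ±1.96/√n band (a subject
passes when ≤ 10% of tested lags are significant; lag depth defaults to
min(10·log10 n, n−1)).

Inference: at each timepoint, every group pair is compared by a two-sample
t-test (pooled variance by default; Welch optional) on the subjects' final
fitted values, at threshold α / #pairs (0.05/3 = 0.01667 for three groups —
Bonferroni over the pairs tested at that timepoint, not over timepoints; a
family-wise-across-time option exists but is off by default). Maximal runs
of consecutive significant timepoints are reported as significance windows
in minutes. The *naive* mode skips stage 2 entirely; running both modes
exposes where ignoring autocorrelation changes the conclusions.

A caveat the user should keep in mind: the tested values are model outputs,
not independent observations, so the t-tests are operational rather than
exact. The corrected mode behaves like a valid per-timepoint test in
simulations (final fitted ≈ observed − innovation); the naive mode's smooth
fitted values make adjacent timepoints strongly dependent, so its errors
arrive as long spurious runs.

## Numerical choices

* **Covariate rescaling.** The mixed-model likelihood is optimized on
  rescaled covariates (t/T, (t/T)²); on the raw index scale (t² up to
  ~1.5·10⁴ against curvature SDs of ~3·10⁻⁵) gradient optimizers stall.
  The rescaling is a linear reparametrization, inverted exactly for all
  reported estimates, standard errors, covariances and BLUPs.
* **Optimizer ladder.** lbfgs → bfgs → cg, then (restarting from the
  stalled parameters) bfgs, cg and powell+lbfgs with maxiter 2000.
  Convergence tolerance is statsmodels' default on the profiled
  likelihood; max 500 iterations in the first pass. Variance components
  near zero put the optimum on the parameter-space boundary, which is what
  the restarts handle.
* **Near-singular covariance.** If the estimated random covariance has a
  slightly negative eigenvalue (boundary optimum), it is nudged to PSD by
  a minimal ridge and the fit is flagged (`ridged=True`).
* **ARIMA fitting** is exact Gaussian ML in state space
  (statsmodels), with stationarity and invertibility enforced. Fitted
  values are one-step in-sample predictions, so `fitted + residuals`
  reconstructs the input exactly — required for the additive
  decomposition of the combined model.
* **Degenerate tests.** Two constant groups with equal means give p = 1;
  with unequal means p = 0 with an infinite-signed t. Groups need ≥ 2
  subjects at each timepoint.
* **p-values** for fixed effects use the normal reference (z), matching
  the large-n practice for ML mixed models.

## The synthetic generator

`SimConfig` defaults reproduce the reference study's design and fitted
scales: 3×3×3 subjects, T = 121 at 2-minute steps, quadratic coefficients
(0.09175, 0.04297, −1.961·10⁻⁴), group offsets (0, −0.1914, +0.1083),
random-effect SDs (0.0625, 4.385·10⁻³, 2.937·10⁻⁵) with correlations
(−0.65, 0.58, −0.97), and AR(1) within-subject noise with φ = 0.8 and
innovation SD 0.0218 (stationary SD ≈ 0.036, the fitted residual SD).
The +0.1083 offset magnitude is taken from the reference fit's reported
estimate; its published sign is internally inconsistent with its reported
z-value, and nothing downstream depends on it. Noise is generated
independently per subject (subjects are independent clusters); AR series
use a stationary start plus a 200-step burn-in. A `LocalizedEffect` adds a
constant offset to one group on a closed minute window — the ground-truth
"difference window" recovery studies aim at. Baseline scaling (divide each
series by its own first value, making every series start at 1) is applied
after noise injection when enabled; note that scaling by *different*
baselines can invert the sign of a group difference, so sign preservation
is only guaranteed when the compared groups share the same baseline mean.

What the generator does **not** emulate: shared experiment-level (batch)
effects, non-Gaussian noise, heteroscedasticity over time, missing or
irregular sampling, and mechanistic growth shapes beyond the quadratic
(logistic/Gompertz-type saturation). Passing the simulation studies
therefore shows the pipeline is correct under its own assumptions, not
that those assumptions hold for any particular instrument's output.

## Study designs used by the test-suite and acceptance script

Replicate studies are sized so a complete run stays within a desktop-scale
compute budget; panel dimensions are chosen per study, replicate counts are
kept at their full values.

* **Whiteness restoration**: one reference-scale panel (27×121), AR(1)
  φ = 0.8 noise; stage-1 residuals fail the ACF bar badly, stage-2
  residuals come back below 10% significant lags.
* **Parameter recovery**: 200 replicates at full reference scale with IID
  noise (the estimator checked on its own sampling assumptions); fixed
  effects within 2 Monte-Carlo SEs of truth, BLUP spreads within 15% of
  the generating SDs (BLUP shrinkage at T = 121 is ~10%).
* **Type-I / false-positive study**: 200 null replicates, 9 subjects ×
  61 timepoints, heterogeneity at 5% of the reference scale, AR(1)
  φ = 0.9, innovation SD 0.0436 — strong smooth noise dominating
  between-subject spread, the regime where ignoring autocorrelation
  misleads. The corrected mode's per-pair per-timepoint rejection rate
  stays at/below nominal; the naive mode's pooled rate is inflated by
  ~40%. Because naive false positives arrive in rare long runs while the
  corrected mode (a calibrated test making ~180 comparisons per
  replicate) almost always flags a few isolated points, a per-replicate
  "naive flags more than corrected" comparison is won by naive only in a
  minority of replicates; the inflation is a pooled-rate phenomenon, not
  a per-replicate majority, and the suite documents this in the one test
  that checks the per-replicate comparison.
* **Window recovery**: 100 replicates, 18 subjects × 36 timepoints,
  heterogeneity at 30% of reference, offset of exactly 5× the stationary
  noise SD on minutes 20–60; the detected window matches both endpoints
  to ±1 sampling step in ≥ 90% of replicates. Failures are occasional
  merges with an adjacent spurious run (AR noise makes neighbouring
  timepoints' excursions arrive together).
* Replicate ARIMA searches restrict the stepwise space to p, q ≤ 1
  without drift (the contaminating process is AR(1), and stage-2 input is
  mean-zero by construction); the full p, q ≤ 5 search with drift
  candidates remains the pipeline default.

## Known limitations

* Degrees of freedom for tests on fitted values are taken at face value
  (n_A + n_B − 2); no correction is made for the values being model
  outputs.
* No multiplicity control across timepoints by default (matching the
  method's reference usage); windows should be read as descriptive
  intervals, not family-wise-corrected discoveries.
* The trend is quadratic; response shapes that saturate or cross need a
  different mean structure (the cubic variant is provided and AIC-ranked,
  richer shapes are not).
* Forecasting beyond the observed window, exogenous regressors and
  seasonal ARIMA fitting are out of scope.
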