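# Methods

## Model and assumptions

`sdmax` fits a presence-background maximum-entropy model: a Gibbs
distribution π_λ(x) ∝ exp(λ·f(x)) over a finite set of landscape cells,
chosen so that the model's feature expectations match the presence-sample
feature means to within a per-feature slack β. By convex duality this is
the L1-regularized maximum-likelihood fit of the exponential family

J(λ) = −(1/m) Σ_presences λ·f(xᵢ) + log Σ_background e^{λ·f(x)} + Σⱼ βⱼ|λⱼ|,

and among all distributions satisfying the box constraints
|E[fⱼ] − presence mean fⱼ| ≤ βⱼ it has maximal entropy. The assumptions
this inherits: presences are an unbiased sample from the species'
occupancy distribution (no survey bias correction is attempted), the
background sample represents available environment, and the response is
log-linear in the chosen features.

**Features.** Linear and quadratic transforms only. Each predictor is
min-max scaled to [0, 1] using bounds from the training background; at
projection time values outside the bounds are clamped into [0, 1] rather
than extrapolated, so e^{λ·f} stays finite under novel climates. Quadratic
features are squares of the scaled values and are "owned" by their source
layer for importance accounting. Hinge, product and threshold features are
deliberately out of scope: the restricted family keeps the objective
smooth enough for exact coordinate solves and keeps every downstream claim
testable.

**Regularization.** βⱼ = β₀·sⱼ/√m with sⱼ the presence standard deviation
of feature j, floored at 1e-4 (a constant feature otherwise gets zero
slack and an unbounded coefficient). β₀ defaults to 1.0 in the pipeline —
the scale-aware convention for presence-background fits — and the
calibration experiments use β₀ = 0.05 where near-unbiased coefficient
recovery is the point.

## Optimization

Cyclic coordinate descent with an *exact* one-dimensional solve per
coefficient: the coordinate objective g(t) = −aⱼt + log Σ e^{η+t fⱼ} + βⱼ|t|
is strictly convex with monotone smooth derivative E_t[fⱼ] − aⱼ ± βⱼ, so the
minimizer is 0 when |E₀[fⱼ] − aⱼ| ≤ βⱼ and otherwise the bracketed root of
the appropriate branch (Brent, xtol 1e-12). The background linear predictor
is cached and updated incrementally; each update's objective improvement is
recorded in a trace whose per-variable totals are the raw material of
percent contribution. Exact solves make the trace well-defined, which is
why a quasi-Newton method is not used for the production fit.

Convergence requires both (a) objective improvement below `tol`
(default 1e-6) over a full cycle and (b) the KKT stationarity residual —
max over features of the constraint violation, and of |gap − β| on active
coefficients — at or below 10·tol. The objective criterion alone leaves
residuals of order √tol; requiring the certificate means every returned
model is verifiably optimal, not merely stalled. Non-convergence within
`max_iter` cycles (default 500) flags the model and warns; it does not
raise.

`sdmax.reference.fit_maxent_lbfgs` is an independent check, never the
implementation: the L1 objective rewritten with λ = u − v (u, v ≥ 0) is
solved by L-BFGS-B and then polished by damped Newton steps on the active
set. On random small instances the two routes agree to ~1e-15 in objective
and ~1e-6 in coefficients (the test suite asserts 1e-4).

## Outputs

Raw output exp(λ·f − log Z) is normalized over the *training* background
(sums to 1 there; relative Gibbs weights elsewhere). The logistic map
q = e^H p_raw / (1 + e^H p_raw), with H the entropy of the fitted training
distribution, fixes the typical cell (p_raw = e^{−H}) at 0.5 — the
default-prevalence convention; the null model maps everything to 0.5.
Training gain = mean presence log-probability minus log Z plus log N,
i.e. nats of improvement over a uniform landscape; it is 0 for the null
model and bounded by log N.

## Evaluation choices

- **Folds** partition the presences only; the background is shared across
  folds. This keeps per-fold AUCs on a common footing and mirrors how
  presence-background cross-validation is normally run. Fold membership is
  a seeded permutation split into k blocks differing by ≤1 in size.
- **AUC** is the Mann–Whitney statistic (ties ½), hence invariant to any
  monotone transform of scores; fold models are scored on the linear
  predictor directly.
- **Threshold** τ* maximizes sensitivity + specificity over observed
  scores, prediction "suitable iff score ≥ τ"; ties resolve to the smallest
  qualifying τ. An equal-sensitivity-specificity rule is available but not
  default. The threshold reported by cross-validation comes from a
  full-data refit — the same model later used for mapping.
- **PC** credits each coordinate update's objective improvement to the
  owning variable, floors negative totals at zero, normalizes to 100.
- **PI** permutes one predictor's raw values jointly across presence and
  background rows (fresh permutation per repeat, default 10), rebuilds
  features, and records the AUC drop, floored at zero, normalized to 100.
  Permuting raw values (not single feature columns) keeps a variable's
  linear and quadratic features consistent.
- **Jackknife** refits with each variable alone and each variable
  excluded, scored by training gain (an AUC variant would be possible but
  gain is the natural fit-quality scale here); with one variable, the
  "without" model is the null model with gain 0.

## Range change

Both gain and loss percentages use the *current* suitable-cell count as
denominator: loss% = 100·|C∖F|/|C|, gain% = 100·|F∖C|/|C|. This is the only
convention under which change% = gain% − loss% holds exactly row by row,
and the package asserts that identity to machine precision. Cell counts
are the base quantity; multiply by per-cell area for km². Ensemble futures
are cell-wise arithmetic means over members, valid only where every member
is valid.

## Synthetic data: what it emulates, what it does not

Layers are white Gaussian noise smoothed by a truncated Gaussian kernel
(reflected boundaries) and re-standardized to zero mean / unit variance
over valid cells — so a stated generating coefficient has the same meaning
at any smoothing radius. Default radius 3 cells gives landscape-like
patchiness (lag-1 neighbour correlation ≈ 0.9) on the default 150×150
grid. When target inter-layer correlations are requested, the fields are
empirically whitened and mixed by the Cholesky factor of the target
matrix, so realized correlations hit the targets to float precision while
staying spatially smooth. The truth surface is exp(λ*·f) normalized over
valid cells — the same family the fitter assumes, which is what makes
coefficient recovery a well-posed claim. Presences are drawn with
replacement (records cluster) and placed at cell centers.

Passing tests on these landscapes demonstrates correctness of the
machinery, not field realism: there is no survey bias, no observation
error, no dispersal limitation, no non-equilibrium occupancy, and the true
response is exactly log-linear. Real-data performance claims do not follow.

## Study conditions used by the calibration experiments

The calibration scenario is a 150×150 grid, six layers (two informative
with generating coefficients +2.0 and −1.5 on standardized values, four
pure noise), 2 000 presences, 10 000 background cells, β₀ = 0.05. Under it:
coefficient recovery lands within 10 % relative error with noise
coefficients below 0.1 in most seeds; 10-fold CV AUC is ≈ 0.95 against
≈ 0.52 for a uniform-truth species at 500 presences; noise variables take
< 1 % of PC and PI; and excluding a noise variable moves the training gain
by < 0.1 %. Fitted coefficients are compared to the generating ones on the
raw-variable scale, λ_raw = λ_scaled/(max − min), using the stored
background bounds. The determinism demonstration uses a smaller 60×60,
4-layer, 200-presence configuration — the property is size-independent and
the small run keeps the full double execution quick.

## Numerical and degenerate-input choices

- Cells are half-open boxes ([x₀, x₀+w) × (y₀−h, y₀]); extraction is
  cell-center sampling, no interpolation, no reprojection. NoData in any
  layer invalidates the cell for all layers (the model needs complete
  predictor vectors).
- Grids must co-register within 1e-6 of a cell; the first offending layer
  is named in the error.
- Background sampling is uniform without replacement; requests beyond the
  valid-cell count fall back to the full set with a warning. The 10 000
  default mirrors common practice; the source record is silent on this, so
  it is exposed in config.
- Presence thinning to one record per cell is on by default in the
  pipeline (toggle in config); the fitter itself accepts duplicates, which
  are statistically legitimate under the Gibbs likelihood.
- The collinearity cut is strict (|r| > 0.70 drops; exactly 0.70 is kept).
  The drop rule — priority list, then larger mean |r| against remaining
  candidates, then reverse input order — is a deterministic stand-in for
  the expert judgement such screens normally encode; the priority list lets
  a user reproduce any expert choice. A constant column is an error (r is
  undefined), named explicitly.
- All-zero importance vectors (no signal) are returned as zeros rather
  than renormalized.
- An empty current range makes gain/loss percentages undefined and raises,
  rather than returning infinities.

## Known limitations

- Noise-coefficient estimates on strongly autocorrelated landscapes have
  heavy-tailed sampling variability (few effective patches under the
  presence distribution); with four simultaneous noise variables the
  joint |λ̂| < 0.1 bound fails in a sizeable minority of seeds at the
  calibration sample sizes. This is a property of the estimation problem,
  not of the optimizer — the KKT certificate holds in every seed.
- Only linear + quadratic features; no cloglog output; no sample-bias
  grids; no extrapolation diagnostics (novel climates are clamped
  silently).
- No reprojection: all inputs must share one CRS and grid; the reader
  refuses misaligned stacks rather than resampling.
- The logistic output's prevalence-0.5 convention is a display/threshold
  convenience, not an occupancy probability.
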