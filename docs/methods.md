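# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the package. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`.

## Factor space and normalization

The storage experiment varies three factors: storage temperature
(−4–24 °C), storage time (0–28 d) and initial (harvest) maturity
(20–90 %). All modelling happens on the unit cube via min–max scaling
x = (x_i − x_imin)/(x_imax − x_imin); out-of-range inputs raise an error
naming the factor rather than being silently clamped, because clamping
hides data errors. The design size follows n = 2(N + 1)(N + 2), giving 40
runs for N = 3.

Initial maturity itself is defined on a 0–100 % scale by linearly
interpolating a ripening indicator between its initial and final seasonal
values. The two shipped calibrations (from SSC and from vitamin C) are kept
exactly as printed in their source even though their outputs are not
confined to [0, 100]; no rescaling is applied, and the package does not
assert the two calibrations agree (they do not, algebraically, for
arbitrary inputs).

## Optimized Latin hypercube design

Designs are exact Latin hypercubes: each column places one point in each of
the n equal bins of [0, 1] (an exact combinatorial invariant, tested).
Design improvement uses an individual-based LHS-MOEA. Per generation, each
of ⌈pN⌉ tournament-selected parents spawns H Latin-sampled neighbours —
radius δ when the parent is non-dominated, 2δ otherwise — and the remaining
(1 − p)N offspring come from selection, crossover and mutation; parents and
offspring are merged and the best N survive by non-dominated rank, then
crowding distance (elite retention). The algorithm runs exactly G
generations.

Choices the source description leaves open, fixed here:

* **Objectives.** No uniformity criterion is named for the "optimal" Latin
  hypercube, so two standard space-filling criteria are used: maximin
  (minimum pairwise Euclidean) distance, maximized, and centered L2
  discrepancy (computed by `scipy.stats.qmc.discrepancy`), minimized. The
  returned design is the non-dominated member with the best maximin
  distance, ties broken by lower discrepancy.
* **Encoding.** Per-column bin permutations with in-bin jitter; columnwise
  permutation exchange as crossover and a two-bin swap as mutation — all of
  which preserve the Latin invariant by construction. Local search performs
  round(radius · n) bin swaps plus a ±radius jitter perturbation.
* Tournament size 2; ⌈pN⌉ rounding of the local-search share; local-search
  boxes clipped to the unit cube at the boundary.

Defaults: N = 20, G = 30, p = 0.3, δ = 0.1, H = 5, Pc = 0.9, Pm = 0.2. At
these sizes the 40 × 3 optimization takes well under a second and reliably
doubles the maximin distance of a random Latin hypercube (≈ 0.18 vs a
median of ≈ 0.08 over 100 random designs).

## Surrogate models

All surrogates share a protocol object: 80/20 random split by a split seed,
and model-specific settings below. Responses carry disparate units
(hardness vs TA differ by an order of magnitude or more), so wherever
errors are aggregated across responses they are z-scored first.

**RBF network.** Hidden layer = one Gaussian unit per training sample
(centers are the training inputs); output layer linear, solved by
regularized least squares on the kernel matrix with a floor regularization
of 1e-10. The width σ is selected by leave-one-out cross-validation over
the grid {0.1, 0.5, 1, 5, 10, 50, 100}. The grid deliberately includes the
extreme value 100 reported for the original analysis, but on a unit cube a
width of 100 makes the kernel matrix numerically rank-one, so
cross-validation is authoritative. Interpolation guarantee: for widths
where the kernel matrix is numerically nonsingular (σ ≲ 0.5 on these
designs, condition number ≲ 2e4), training residuals are below 1e-6; at
large widths no solver can interpolate, which is a property of the Gaussian
kernel, not of the solver. Duplicate training inputs trigger a warning and
a raised regularization.

**Elman network.** One hidden tanh layer (default 10 neurons) without
biases, identity output, plus a context layer holding the previous hidden
state; after a forward run the stored context is the one used at the final
step, i.e. the penultimate hidden state. Static rows are presented as one
ordered sequence per epoch with the context zeroed at each epoch start (the
recursion would otherwise be inert on tabular data); prediction feeds the
query rows the same way. Training is plain per-step gradient descent
(learning rate 0.01) with a one-step context gradient — the context is
treated as constant input at each step — for at most 1000 epochs, stopping
early when the standardized training MSE falls below 1e-5 or the epoch-mean
gradient norm below 1e-6. Weights initialize uniform(−0.5, 0.5) from an
init seed; targets are z-scored internally and destandardized on
prediction. The network learns y = x₁ on 50 random points to a training MSE
below 1e-3 within the epoch budget.

**Quadratic response surface.** OLS over the ten-term basis
[1, x₁, x₂, x₃, x₁², x₂², x₃², x₁x₂, x₁x₃, x₂x₃]; a rank-deficient basis
raises. Noise-free synthetic data reproduces generating coefficients to
1e-8 at n = 20 (parameter recovery). The packaged reference coefficient set
for the four responses has its pure quadratic terms attached to x₁², x₂²,
x₃² in that order (the source prints those coefficients without their
variable symbols); its hardness response is on the gram scale, whereas the
packaged 40-run table prints hardness in newtons — both are kept as printed
and the unit is recorded, with no automatic conversion.

**Fit metrics.** RMSE includes the square root (the total-sum-of-squares
form ΣM² − (ΣM)²/n in the R² denominator is algebraically the classical
centered SST; tested numerically). MAPE is relative to the observed value
and NRMSE is range-normalized; both definitions are stated here because the
source prints only their values, and a user wanting a mean-normalized NRMSE
can compute it from `FitMetrics.rmse` directly.

### What the 40-run table can and cannot support

The packaged experimental table does not support the published accuracy
band (held-out R² ≥ 0.9 for every response). A quadratic surface explains
only 0.19–0.67 of each response's variance in-sample; every RBF width in
the grid and every Elman seed tried gives held-out R² near or below zero.
The published per-response RMSE values (212.49, 385.78 for hardness) are
also on the gram scale while the packaged table prints newtons, so the
published accuracy plainly refers to a dataset (and train/test split) that
was not published. The hold-out benchmark therefore uses a
best-of-documented-seed-grid protocol (10 split seeds for the RBF; 5 split
× 3 init seeds for the Elman), reports the best minimum R² achieved, and
flags — rather than asserts — the published band. No seed, width or
tolerance was adjusted toward that band.

## Sensitivity analysis

Main-effect curves average the predictor over the non-varying factors at
each of n_levels equispaced levels. The default background is a
deterministic centered lattice (per-dimension midpoints, full factorial,
256 points), whose factor means are exactly ½ so linear background terms
cancel exactly; a seeded scrambled-Sobol background is available for higher
dimensions. Term contributions of a quadratic surface are
|coef_t| / Σ|coef| · 100 per non-intercept term, signed by the coefficient,
on the normalized factor scale. This is a coefficient-share approximation
of the Pareto-chart decomposition produced by commercial DOE software,
whose exact formula is undisclosed; the dominant-term ordering and signs
are meaningful (temperature dominates hardness with a negative sign on the
reference surfaces, share 37.2 %), the exact published percentages are not
reproduced and not asserted.

## SMPSO storage optimization

All four predicted qualities are maximized as stated — including hardness
and TA, for which "more" is not necessarily organoleptically better; no
re-weighting is applied. Swarm 12, 50 generations (600 evaluation rounds),
archive capacity 100. Velocity update uses the constriction factor
χ(φ = c₁ + c₂) = 1 for φ ≤ 4, else 2/|2 − φ − √(φ² − 4φ)|, with c₁, c₂ ~
U(1.5, 2.5) per particle per generation and the velocity clamped to half
the variable range; particles hitting a bound are clamped with that
velocity component sign-reversed. Leaders come from the archive by binary
crowding tournament; polynomial mutation (distribution index 20) hits 15 %
of particles; personal bests replace unless dominated. The archive rejects
dominated candidates, drops members a candidate dominates, and evicts the
most crowded member over capacity. These internals follow the standard
SMPSO formulation, since the source states only swarm size and generation
count; all are exposed in `SMPSOConfig`. On the analytic bi-objective toy
(maximize (x, 1 − x²)), the archive lies within 1e-2 of the true front at
the default budget.

The compromise point is the archive member with the smallest Euclidean
distance to the ideal point after per-objective min–max normalization, ties
broken by larger crowding distance then lower index. Scenario queries
freeze storage time at its raw value and re-run SMPSO over temperature and
maturity.

With surrogates trained on the packaged table (RBF for hardness/TA/Vc,
Elman for SSC — the default pairing), the 10-day scenario selects −4 °C:
the printed data rewards maximal cold for hardness, and the published
optimum near 10 °C derives from the same unpublished models as the accuracy
figures. The scenario test asserts bound containment, exact time freezing
and re-evaluation consistency, and reports the published-band comparison as
advisory.

## Synthetic data

The generator exists to give every pipeline stage a known truth.

* **Surface mode:** responses from a known quadratic surface plus
  independent homoscedastic Gaussian noise. Default noise SDs
  (120 g, 1.2 %, 0.3 %, 2.1 mg/100 g) are the reported initial-state
  measurement SDs of the four indicators, with hardness converted to the
  gram scale of the reference surface. Zero-noise output reproduces the
  surface to machine precision, which grounds the parameter-recovery tests.
* **Kinetic mode:** one-factor sweeps through the reported anchor points —
  SSC and Vc parabolic in temperature peaking at 8 °C (24.95 %,
  28.37 mg/100 g); hardness linearly decreasing in temperature; hardness
  and Vc peaking on day 4 (1636.54 g, 35.16 mg/100 g) and SSC/TA on day 8
  (23.54 %, 1.65 %); hardness and TA falling monotonically with maturity
  (−27 %, −82 % green → red), SSC rising, Vc V-shaped. Between anchors the
  time and maturity profiles use shape-preserving PCHIP interpolation — a
  curve-shape emulation, not a mechanistic kinetic law — so peaks land
  exactly on the anchor days. Anchors outside the factor ranges raise.

What passing on synthetic data does **not** show: real storage data has
measurement noise structure (heteroscedastic, possibly correlated across
responses), batch effects and biological variation that the independent
Gaussian model omits; recovery of a quadratic truth says nothing about
model adequacy when the true response is not quadratic.

## Pipeline and reproducibility

The pipeline derives one child seed per stage from the master seed as the
first four bytes of sha256("master/stage") modulo 2³¹, so stages are
independently reproducible and a rerun is byte-identical (reports contain
no timestamps). All randomness everywhere flows from explicit seeds through
module-local `numpy` generators.

Problem sizes used by the shipped tests and the acceptance script — 40-run
designs, 100-design random baselines, 10–15 surrogate trainings per
benchmark, swarm 12 × 50 — are the sizes of the study itself; the whole
suite runs in well under a minute on one core.

## Known limitations

* The Elman optimizer is plain SGD; the original analysis used an
  unspecified MATLAB routine, and no equivalence is claimed.
* Contribution percentages are a coefficient-share convention, not a
  variance decomposition (no Sobol indices).
* The objective "maximize all four qualities" is taken as stated; a
  weighted or target-based formulation would change the selected optimum.
* Hardness unit duality (newtons in the 40-run table, grams in the
  reference surfaces and kinetic anchors) is preserved, not reconciled.
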