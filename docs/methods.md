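# Methods

## Problem and estimand

Given i.i.d. observations of covariates L, a binary treatment A and an
outcome Y, with Y^1 ⫫ A | L (no unmeasured confounding), consistency
(Y = Y^A), and positivity (g(L) = P(A=1|L) > σ > 0), the package estimates
the conditional counterfactual mean

    m(Z) = E(Y^1 | Z),    Z ⊆ L,

the function minimizing the counterfactual prediction error
E[(Y^1 − m(Z))^2] over functions of Z.  When Z is a strict subset of L this
equals E[Q(L) | Z] with Q(L) = E(Y | A=1, L).  Predictions of E(Y^0 | Z)
are obtained by relabeling A ↦ 1−A and rerunning; there is no separate code
path.

## Function class: penalized cosine sieve

All learners share the same final stage: a regression of a (pseudo-)outcome
on Z within the tensor-product cosine sieve

    h(m(Z)) = Σ_{j≤J} γ_j b_j(Z),

where h is the identity (continuous Y) or logit (binary Y), and each b_j is
a product of univariate cosines ψ_0 = 1, ψ_k(u) = √2 cos(kπu) evaluated on
min-max-rescaled coordinates.  The basis is orthonormal in L²[0,1]; the
multi-indices are enumerated by the weight Π(j_k+1) over active
coordinates (ties: smaller index-sum, then earlier coordinates first),
include products of at most D′ = 2 covariates by default, and form a
prefix-closed ordering.  Rescaling ranges are learned from training data;
out-of-range prediction points are clipped to [0,1] rather than
extrapolating the oscillating basis.  Defaults J = 10/20/50 for
dim(Z) = 2/5/20, matching the simulation-study settings; other dimensions
use the rate rule round(C·d^{D′}·n^{1/3}·log^{D′−1} n).

Coefficients are fitted by an in-package cyclic coordinate-descent lasso
(tolerance 1e-7, at most 1e5 passes; logistic loss is handled by a
proximal-Newton outer loop with step halving).  The solver supports
observation weights (normalized to mean one over positive-weight rows, so
weight scale is irrelevant and zero-weight rows equal deleted rows),
offsets on the link scale, and fractional responses in [0,1] under the
Bernoulli deviance — the mechanism by which imputed outcome probabilities
are regressed on the probability scale.  The constant basis function is
never penalized in final fits; the targeting fluctuation penalizes every
coordinate.  Features are deliberately not standardized before
penalization: the lasso KKT conditions then bound exactly the score
coordinates that the targeting step is meant to control.

Penalty level λ: `select_lambda` cross-validates over a 50-point log grid
spanning ±2.5 decades around the anchor √(log J / n) (the grid always
contains the anchor; ties resolve to the larger λ).  CV is the default for
data-analysis fits.  The simulation benchmark instead fixes λ at the
anchor: cross-validation cannot distinguish the cross-fitted nuisance
estimate — itself a function of L — from signal, and measurably absorbs
that noise into the final fit, which does not represent the fixed
standard-order penalty the study design states.

## Nuisance estimation and cross-fitting

g(L) and Q(L) (trained on treated rows only; at least 10 required) are
estimated by pluggable learners:

* `random_forest`: a regression forest with the classical defaults
  (500 trees, minimum leaf size 5, one third of features per split).
  Binary responses are averaged on the mean scale — leaf means are
  probabilities — which is markedly smoother than a classification forest
  grown to purity.
* `super_learner`: a cross-validated convex stack (simplex-constrained
  least squares for the identity link, log-loss for the logistic link;
  the combination never does worse than its best member on the same folds)
  over main-effects GLM, all-pairs interaction GLM (unregularized, hence
  deliberately unstable on small folds), forward-stepwise GLM by AIC
  (at most 10 terms), the regression forest, and a spline additive model
  with mild ridge shrinkage.
* `custom`: any object with fit(X, y)/predict(X) on the mean scale.

K-fold cross-fitting (default K = 5, seeded folds whose sizes differ by at
most one) trains both nuisances on each fold's complement and predicts on
the held-out fold, so no observation's nuisance values depend on its own
outcome.  Propensities are clipped to [clip_lo, 1−clip_lo]; logistic-link
outcome predictions to [1e-3, 1−1e-3] so logit offsets stay finite.
Default clip_lo differs by context: 1% for data-analysis fits (the
threshold used in the critical-care application this methodology was
developed for), and 1e-6 — numerical safety only, effectively no trimming —
inside the simulation benchmark, whose design specifies no trimming.

## The targeting step (i-learner)

The imputation loss Σ(A_i Y_i + (1−A_i)Q̂(L_i) − m(Z_i))² is not
Neyman-orthogonal: its gap to the doubly robust loss is driven by the score

    S_j = (1/n) Σ_i A_i (1−ĝ_i)/ĝ_i (Y_i − Q̂(L_i)) b_j(Z_i).

The i-learner shrinks every S_j by fluctuating the initial outcome fit
along the clever-covariate submodel

    h(E(Y|A=1,L)) = h(Q̂⁽⁰⁾(L)) + ε′ b(Z) (1−ĝ(L))/ĝ(L),

fitting ε by l1-penalized regression on treated rows with
λ = √(log J / n_treated) and no extra intercept (the constant basis
function already contributes a clever covariate).  With the identity link
the lasso KKT conditions imply max_j |S_j| ≤ λ after the update — the
property the acceptance suite verifies across seeds.  With the logit link
the fluctuation acts on the logit scale with offset logit(Q̂⁽⁰⁾), keeping
Q̂* and therefore all imputed outcomes inside (0,1); the post-update score
is reported as a diagnostic but not asserted, since the Bernoulli score
weights differ from the identity-link statement.

Cross-fitting protocol: for each fold k, the fluctuation is fitted on the
treated rows of the other K−1 folds (using that fold's nuisance models
evaluated there, with a basis whose ranges come from those training folds),
then applied to fold k with the out-of-fold ĝ and Q̂⁽⁰⁾.  Imputed outcomes
are pooled across folds and the final sieve regression runs once on all n
rows.

## Meta-learners

With ĝ, Q̂ (or the targeted Q̂*) in hand:

* naive — sieve of Y on Z over treated rows (ignores confounding);
* ipw — sieve over treated rows with weights A/ĝ, normalized to mean one
  among the treated so λ remains comparable across learners;
* imputation — sieve of A·Y + (1−A)·Q̂ on Z over all rows;
* dr — sieve of the pseudo-outcome (A/ĝ)(Y−Q̂) + Q̂, always with the
  identity link because pseudo-outcomes are unbounded even for binary Y;
* cdr — dr with predictions clipped to [0,1] (clipped fraction reported);
* ilearner — imputation applied to Q̂*.

For binary outcomes the naive/ipw/imputation/i-learner predictions are
sigmoid outputs and lie in (0,1) by construction; dr can and does escape
the unit interval when ĝ is small (ĝ=0.02, Y=1, Q̂=0.5 gives φ=25.5).

## Synthetic-data mechanisms

Both mechanisms draw d = 20 jointly Gaussian covariates with a random
correlation matrix: off-diagonals N(0, 0.25) truncated to [−0.5, 0.5]
(so correlations vary over that range), projected to the nearest
positive-definite correlation matrix (eigenvalue floor 1e-6, via
alternating projections).  Each benchmark replication redraws the
correlation matrix; this dominates the across-replication variability of,
e.g., the treated fraction.

Mechanism 1 (continuous): V1 = exp(L1/2), V2 = L2/(1+exp(L1)) + 10,
V3 = (L1·L3/25 + 0.6)³, V4 = (L2+L4+20)²;
b(L) = 210 + 27.4·V1 + 13.7·(V2+V3+V4); Y^a ~ N(b(L), 1);
π(L) = expit(−(V1 − 0.5·V2 + 0.25·V3 + 0.1·V4)).  As written the 0.1·V4
term (≈ +40) makes π ≈ 0 for essentially every draw, so almost nobody is
treated; the `standardize_V` switch z-scores V1..V4 inside the propensity
formula only, restoring overlap (treated fraction ≈ 1/2).  The switch is
off by default for fidelity to the design as stated; the benchmark of this
mechanism is therefore exercised property-wise (finite, improving MSEs
under `standardize_V`) rather than as a numeric target.

Mechanism 2 (binary): K = Σ_j L_j/j, K* = Σ_j L_j/(p−j+1) with p = d = 20;
π(L) = expit(−(2 + 2 sin K + 2 cos K)) ∈ [0.008, 0.70], treated fraction
≈ 0.15; b(L) = expit(2.5 − 2 cos(2K*)) ∈ [0.62, 0.99].  The "cos2K*" index notation
is read literally as cos(2K*); `cos_form="cos_sq"` switches to cos²(K*).
Neither mechanism has a treatment effect (Y^1 and Y^0 are i.i.d. given L),
so E(Y^1|Z) equals the plain regression function E(Y|Z) — which the test
suite uses as an independent cross-check of the truth oracle.

Truth oracle: E(Y^1|Z) = E[b(L)|Z] is exact (b itself) when Z = L, and is
otherwise computed by Monte-Carlo over the closed-form Gaussian conditional
law of the remaining coordinates given Z (default 200 draws per point,
standard error ≈ 0.01 on the probability scale, negligible relative to the
measured MSEs).  Validation MSE uses 500 fresh points per replication.

What the generator does not emulate: real covariates are not jointly
Gaussian, real propensities and outcome models are not smooth functions of
two linear indices, and real data contain measurement error and missing
values.  Passing benchmarks therefore demonstrates correctness of the
estimators and their relative behavior under the stated designs, not
clinical performance.

## Problem sizes and observed behavior

The full-scale studies use 500 replications per cell.  The test suite and the
acceptance script scale this down: 10 replications per tabulated cell in
the suite, 25/20 in the acceptance script, with everything else (n, J,
dim(Z), K = 5, nuisance settings) at the study conditions.  At the
(n=1000, dim 20, J=50) cell the mean MSEs come out near the full-scale reference values
(≈ 0.018 for both imputation-based learners).  At the dim(Z)=2 cells the
true m(Z) is nearly constant (the outcome index K* weights the first two
covariates by 1/20 and 1/19, so Var m(Z) ≈ 5e-6): reference MSEs there are
almost entirely final-fit estimation noise, and this implementation's
penalized fits produce substantially *smaller* errors (≈ 0.002) than the
reference 0.017–0.025.  Similarly, the unconstrained DR-learner's fraction of
predictions outside the unit interval under stacked nuisances is far below
the reference ≈ 32% here, because the anchor-penalized final fit shrinks the
wild pseudo-outcome regression toward its mean; reproducing that figure
would require a near-unpenalized final fit, which simultaneously
contradicts the penalty level that reproduces the dim-20 rows.  These
cells are reported as genuine cross-implementation differences rather than
calibrated away.

## Numerical choices and edge cases

* Coordinate descent: tolerance 1e-7 on the max coefficient change,
  ≤ 1e5 passes; λ-path CV warm-starts descending.  Deterministic given
  inputs; all fold assignments and simulations are seeded.
* Logistic probabilities clipped to [1e-12, 1−1e-12] at prediction;
  IRLS weights floored at 1e-9·(1−1e-9).
* Degenerate (constant) covariate columns rescale to 0.5 with a warning.
* Constant training outcomes short-circuit every base learner to a
  constant predictor (GLM solvers are not exercised on single-class data).
* An all-zero stacking solution falls back to uniform weights with a
  warning.
* Model files store floats as hexadecimal for bit-exact round-trips.

## Known limitations

* Sparsity/smoothness of m is assumed on the h-scale; when it fails the
  learners return the best approximation within the truncated class.
* The score-shrinkage guarantee is stated and asserted for the identity
  link only.
* No confidence intervals; debiased-lasso inference is out of scope.
* The benchmark's nuisance learners are Python analogs of the R wrappers
  the studies name (randomForest/ranger, glm, step, gam); exact numeric
  parity with those implementations is not attempted.
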