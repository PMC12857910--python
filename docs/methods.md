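# Methods

## Model

`trajmix` fits a truncated Dirichlet-process (DP) mixture of
longitudinal regression models. Subjects (not observations) are the
mixture units: subject *i* draws a component z_i from stick-breaking
weights pi_k = v_k prod_{j<k}(1 - v_j) with v_k ~ Beta(1, alpha) and
k = 1..K. The truncation level K caps the number of representable
components; the K-th stick takes the remainder mass so the weights sum
to one exactly. K defaults to 30 and is a computational ceiling, not a
claim about the data — the DP prior decides how many components are
actually occupied.

Given z_i = k, a continuous target d follows

    y_it = x_it' w_{k,d} + z_it' u_{i,d} + eps_it,
    eps_it ~ N(0, 1/lambda_{k,d}),

with w_{k,d} ~ N(w0_d, diag(p0_d)^-1), lambda_{k,d} ~ Gamma(a0_d, b0_d)
(independent per component and target), and optional random effects
u_{i,d} ~ N(0, Sigma_re[k,d]) on a user-chosen subset of predictors.
Sigma_re is unstructured (all entries free) and carries an
inverse-Wishart(S0_d, nu0_d) prior; it is indexed per component and per
target, the finest granularity consistent with the per-component
residual variances. Binary targets follow
Bernoulli(sigmoid(x_it' w_{k,d})) with the same Gaussian coefficient
prior and no random effects. Targets are conditionally independent
given z_i, so the subject-level log-likelihood is the sum over targets
and visits; errors are uncorrelated within and across targets. Missing
target cells simply drop out of the likelihood (ignorable missingness);
rows with missing predictors are rejected at load. Count outcomes are
out of scope.

## Variational inference

The mean-field factorization is

    q(v) q(z) prod_{k,d} q(w_{k,d}) q(lambda_{k,d}) prod_{i,d} q(u_{i,d}),

with Beta sticks, a categorical per subject (the responsibility matrix
R), Gaussians for all coefficients and random effects, and Gammas for
the residual precisions. Every update is the exact maximizer of the
objective over its own factor, so the traced objective is non-decreasing
across sweeps; the test suite enforces this with slack 1e-8 on every
dataset it touches, and it is the main correctness oracle for all the
update algebra.

Two deliberate departures from a textbook fully-variational treatment:

* **Sigma_re is a point estimate.** A full variational factor over an
  inverse-Wishart would couple awkwardly with the per-component
  responsibilities; instead Sigma_re[k,d] is updated by an EM-style MAP
  step, (S0 + sum_i R_ik E[u_i u_i']) / (nu0 + q + 1 + sum_i R_ik).
  The inverse-Wishart log-prior is included in the traced objective, so
  the sweep remains a coordinate ascent on one fixed functional and
  monotonicity is preserved. The update keeps Sigma_re positive
  definite whenever S0 is.
* **Binary targets use the Jaakkola–Jordan bound.** The logistic
  likelihood is replaced by its quadratic lower bound with one local
  parameter xi per (component, observation); the bound restores
  Gaussian conjugacy for the coefficients, and the optimal
  xi^2 = E[(x'w)^2] is closed-form. The traced objective is therefore
  the bounded ELBO. The bound never exceeds the exact Bernoulli
  log-likelihood and touches it at xi = |x'w|.

Sweep order: responsibilities, sticks, coefficients, precisions, random
effects (subject posteriors then covariances), logistic coefficients
and bounds. One wrinkle: all component factors are initialized at the
shared prior, so recomputing responsibilities before any component has
adapted would assign every subject the same row and symmetry could
never break. The first sweep therefore keeps the seeded Dirichlet
responsibilities and updates everything else; all later sweeps lead
with the responsibility update. Any fixed order of exact coordinate
updates preserves the ascent property.

Residual precisions can optionally be pinned (`lambda_fixed`), which
reduces the single-component model to conjugate Bayesian linear
regression; in that regime the converged coefficient posterior matches
the closed-form Normal posterior and the ELBO equals the exact log
marginal likelihood to floating-point precision — both are asserted
against independent closed-form oracles in the tests.

## Initialization, convergence, degeneracy

Responsibilities initialize from a symmetric Dirichlet(1) draw per
subject under a seeded generator; everything downstream is
deterministic given the seed. Convergence is declared when the relative
ELBO change over one sweep drops below 1e-6 (default; cap 500 sweeps).
Multiple restarts (seeds seed, seed+1, ...) keep the run with the best
final ELBO; 3 restarts is the recommended default for real analyses.
Components that lose essentially all responsibility mass need no
special handling: the no-data limit of every update is exactly the
prior, so empty components park at their priors and remain available.

A known behavior of truncated-DP variational mixtures: on some datasets
a local optimum splits one true group across two components with nearly
identical curves, and the bounded ELBO can tie with or slightly exceed
the unsplit solution. Restarts mitigate but cannot abolish this; the
occupied-component count (mass > 1%) should be read alongside the
fitted curves, which is what `viz_model_trajs` is for.

## Data-informed priors

`generate_prior` seeds the prior from pooled (population-level) fits,
which are well-defined even with one observation per subject:

* Coefficient prior means are the pooled OLS (or logistic) estimates;
  prior standard deviations are `inflation` (default 10) times the
  pooled-fit standard errors, so the prior is centered on the
  population average but wide enough for components to spread out.
* The residual-precision Gamma uses shape a0 = 2 (finite prior mean and
  variance) and rate b0 = a0 * s2_w, where s2_w is the variance of
  pooled-fit residuals *centered within subject*. Centering matters:
  the raw pooled residual variance absorbs the between-group spread the
  mixture itself is meant to explain, and using it would bias every
  component's residual variance upward (by ~25% on the bundled
  three-group preset). When subjects are too short to center (e.g., one
  visit each) the pooled estimate is the fallback.
* The random-effect scale S0 is the between-subject variance of
  per-subject mean residuals times the identity, with nu0 = q + 2 so
  the prior mean of Sigma_re equals that scale — between-subject spread
  is precisely what a random effect models.
* If the pooled logistic fit fails (complete separation,
  non-convergence), binary coefficients fall back to a zero-mean prior
  with standard deviation 2.5 per coefficient, a standard
  weakly-informative logistic scale.
* The DP concentration is calibrated from the analyst's estimate of the
  trajectory count: alpha solves E[#occupied clusters] =
  sum_{i<n} alpha/(alpha+i) = k_est by bracketed root-finding (Brent,
  tolerance well below 1e-10 on the cluster-count scale). alpha is then
  fixed; no hyperprior is placed on it.

## Out-of-sample assignment

`assign_trajectory` scores each subject under each component with
plug-in posterior-mean parameters (coefficient means, precision a/b)
plus E[log pi]; for random-effect targets the subject effects are
marginalized analytically, y_i | k ~ N(X mu_w, sigma^2 I + Z Sigma_re Z').
Plug-in rather than fully posterior-predictive scoring is a documented
simplification — the difference is small once posteriors concentrate.
Subjects with no usable observations receive the prior weights E[pi]
and a warning flag. On training data the MAP labels agree with the
fitted responsibilities' argmax for >= 99% of subjects (small
discrepancies are possible because training responsibilities integrate
over parameter uncertainty while assignment plugs in means).

## Synthetic cohorts

The generator draws each subject's group from the true proportions,
visit times uniformly over a window (default 0–10), predictors as a
polynomial basis in time, and outcomes from the generative model above.
Presets (pinned seeds, shared by tests and the acceptance script):

* `separated3` — 3 quadratic groups (proportions .40/.35/.25), n = 300,
  5 visits, residual sd 1, mean curves >= ~6 sd apart: easy recovery.
* `overlap2` — 2 linear groups ~1.5 sd apart, n = 200: deliberately
  ambiguous, used for ELBO/behavioral checks, not recovery claims.
* `binary2` — 2 groups seen only through one binary target with logit
  intercepts ±4 and slopes ∓0.8, n = 400, 6 visits.
* `ranint1` — 1 group, random intercept sd 2, residual sd 0.5, n = 500:
  the random-effect recovery benchmark (true variance 4.0).

What the generator does *not* emulate: informative dropout or
missingness, correlated residuals, heavy-tailed noise, measurement
batch effects, and covariates beyond polynomial time. Passing the
recovery tests therefore demonstrates the estimator's correctness under
its own assumptions, not robustness to their violation.

Problem sizes throughout (hundreds of subjects, a few visits each,
K up to 30) are desk-scale by design: each fit takes seconds, the whole
test suite about a minute.

## Numerical choices

* Responsibilities are normalized in log space (log-sum-exp); a subject
  whose log-likelihood is -inf under every component raises an error
  naming the subject.
* Posterior covariance solves use explicit inverses of M x M (M small)
  matrices with symmetrization; prior precisions p0 > 0 guarantee
  non-singularity.
* jj_lambda(xi) = tanh(xi/2)/(4 xi) switches to its limit 1/8 below
  1e-6 to avoid 0/0.
* Model files are versioned JSON with floats serialized at full repr
  precision, so save/load round-trips are bit-exact; corrupted or
  future-versioned files raise explicit errors.
* Reported residual sd is sqrt(b/(a-1)) (the posterior-mean variance);
  assignment uses the posterior-mean precision a/b. Both are stated in
  the summary/assignment docs.

## Limitations

Variational posteriors can understate uncertainty relative to MCMC,
particularly for the stick weights; credible intervals for coefficients
in well-populated components are close to exact because those
conditionals are genuinely Gaussian. The Sigma_re point estimate
carries no posterior uncertainty. The JJ bound makes binary-target
ELBO values lower bounds of a lower bound; comparisons across models
should use the same target configuration.
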