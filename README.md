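# trajmix

Bayesian nonparametric trajectory analysis for longitudinal data.

Trajectory analysis partitions the subjects of a longitudinal study into
latent subgroups, each with its own pattern of change over time — for
example, distinct patterns of lung-function decline in a COPD cohort, or
of symptom severity in a behavioral study. `trajmix` implements a
Dirichlet-process mixture of multi-target longitudinal regression models
fitted by coordinate-ascent variational inference (CAVI), so the number
of groups is inferred from the data rather than fixed in advance, prior
knowledge can be injected when cohorts are small, and fitting stays fast
at large n. It is aimed at biostatisticians and epidemiologists who want
an LCMM-style latent-class analysis with Bayesian uncertainty, multiple
simultaneously-modeled outcomes, and a scriptable command-line workflow.

## Model

Each subject *i* carries a latent component *z*<sub>i</sub> drawn from
truncated stick-breaking weights

> π<sub>k</sub> = v<sub>k</sub> ∏<sub>j&lt;k</sub> (1 − v<sub>j</sub>),  v<sub>k</sub> ~ Beta(1, α),  k = 1…K,

the variational treatment of a Dirichlet process with concentration α.
Conditional on z<sub>i</sub> = k, each **continuous** target *d* follows

> y<sub>it</sub> = x<sub>it</sub>ᵀ w<sub>k,d</sub> + z<sub>it</sub>ᵀ u<sub>i,d</sub> + ε<sub>it</sub>,  ε<sub>it</sub> ~ N(0, λ<sub>k,d</sub>⁻¹),

with Gaussian coefficient priors w<sub>k,d</sub> ~ N(w₀, diag(p₀)⁻¹), a
Gamma(a₀, b₀) prior on each residual precision λ<sub>k,d</sub>
(estimated independently per component and per target), and optional
subject-level random effects u<sub>i,d</sub> ~ N(0, Σ<sub>k,d</sub>)
with an unstructured covariance on a chosen subset of predictors. Each
**binary** target follows Bernoulli(σ(x<sub>it</sub>ᵀ w<sub>k,d</sub>))
and is handled inside CAVI with the Jaakkola–Jordan quadratic bound.
Targets are conditionally independent given the component, so the
subject-level likelihood is a sum over targets and the algorithm scales
linearly in the number of outcomes.

Inference maximizes the evidence lower bound (ELBO) by cycling
closed-form coordinate updates; the ELBO trace is non-decreasing by
construction and the package treats that as its primary self-check.

## Worked example

The bundled generator creates a three-group cohort (300 subjects, five
visits each, quadratic mean curves separated by several residual
standard deviations), and the seven workflow tools take it from raw CSV
to per-subject assignments:

```bash
make_cohort --preset separated3 --out-data data.csv --out-truth truth.csv
generate_prior --data data.csv --predictors intercept,t,t2 --targets y \
               --k-est 3 --out prior.yaml
bayes_traj_main --data data.csv --prior prior.yaml --seed 1 \
                --num-restarts 3 --out model.json
summarize_traj_model --model model.json
assign_trajectory --model model.json --data data.csv --out assign.csv
```

`generate_prior` reports `alpha=0.3434`: the DP concentration at which a
300-subject cohort is expected to occupy three clusters a priori. The
fit prints `ELBO=-2580.1954 after 36 sweeps (converged: True)`, and the
summary shows that of the K = 30 available components exactly three hold
mass:

```
Trajectory model summary (300 subjects, truncation K=30)
Occupied components (>1% mass): 3

Component 2: 118 subjects (39.3%)
  target y:
       intercept:  0.0279  [-0.2026,  0.2583]
               t:  0.4893  [ 0.3791,  0.5996]
              t2: -0.0186  [-0.0294, -0.0077]
    residual sd: 0.9888
...
```

The coefficient posterior means sit on the simulated truths (0, 0.5,
−0.02 for this group; residual sd 1), with 95% credible intervals
covering them. `assign.csv` holds one row per subject with the posterior
probability of each component, the MAP label, and a warning flag for
subjects carrying no usable observations (those fall back to the prior
weights E[π]). `viz_data_prior_draws`, `viz_gamma_dists`, and
`viz_model_trajs` render prior predictive curves, residual-precision
densities, and fitted trajectories with ±2 sd bands; every tool
supports `-h`.

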