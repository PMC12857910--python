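"""Generative model containers and Dirichlet-process primitives.

The model is a truncated Dirichlet-process mixture of multi-target
longitudinal regressions.  Each subject i carries a latent component
z_i drawn from stick-breaking weights pi(v), v_k ~ Beta(1, alpha).
Conditional on z_i = k:

* a continuous target d follows
      y_it = x_it' w_{k,d} + z_it' u_{i,d} + eps_it,
  with eps_it ~ N(0, 1/lambda_{k,d}), lambda_{k,d} ~ Gamma(a0_d, b0_d),
  w_{k,d} ~ N(w0_d, diag(1/p0_d)), and optional random effects
  u_{i,d} ~ N(0, Sigma_re[k,d]) on a chosen subset of predictors with an
  unstructured (fully free) covariance;
* a binary target d follows Bernoulli(sigmoid(x_it' w_{k,d})) with the
  same Gaussian coefficient prior.

Targets are conditionally independent given the component, so the
subject-level log-likelihood is a sum over targets and observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PriorSpec",
    "VariationalPosterior",
    "SimSpec",
    "TrajModel",
    "stick_breaking_weights",
    "expected_num_clusters",
    "sample_generative",
]


def stick_breaking_weights(v: np.ndarray) -> np.ndarray:
    """Map K-1 stick fractions in [0, 1] to K mixture weights.

    pi_k = v_k * prod_{j<k} (1 - v_j) for k < K; the last component takes
    the remaining mass prod_j (1 - v_j), so the weights sum to 1 exactly.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError("v must be a 1-d vector of stick fractions")
    if np.any((v < 0.0) | (v > 1.0)) or not np.all(np.isfinite(v)):
        raise ValueError("stick fractions must lie in [0, 1]")
    K = v.size + 1
    pi = np.empty(K)
    rem = np.concatenate([[1.0], np.cumprod(1.0 - v)])
    pi[:-1] = v * rem[:-1]
    pi[-1] = rem[-1]
    return pi


def expected_num_clusters(alpha: float, n: int) -> float:
    """Expected number of occupied clusters under a DP(alpha) over n subjects.

    E[#clusters] = sum_{i=0}^{n-1} alpha / (alpha + i); grows like
    alpha * log(n) and is strictly increasing in both arguments.
    """
    if not np.isfinite(alpha) or alpha <= 0:
        raise ValueError("alpha must be a positive real")
    n = int(n)
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(n, dtype=float)
    return float(np.sum(alpha / (alpha + i)))


def _as_2d(x, name, shape):
    arr = np.asarray(x, dtype=float)
    if arr.shape != shape:
        raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
    return arr


@dataclass
class PriorSpec:
    """Hyperparameters of the mixture-of-regressions model.

    Coefficient priors are independent Gaussians (mean ``w0``, precision
    ``p0`` per coefficient).  Residual precisions carry Gamma(a0, b0)
    priors per continuous target.  An optional random-effect block places
    an inverse-Wishart(S0, nu0) prior on the per-component random-effect
    covariance over the predictors listed in ``re_idx``.  ``alpha`` is the
    DP concentration and ``K`` the stick-breaking truncation level.
    """

    predictor_names: list[str]
    continuous_names: list[str]
    binary_names: list[str]
    w0_c: np.ndarray  # (D_c, M)
    p0_c: np.ndarray  # (D_c, M) strictly positive
    a0: np.ndarray    # (D_c,)
    b0: np.ndarray    # (D_c,)
    w0_b: np.ndarray  # (D_b, M)
    p0_b: np.ndarray  # (D_b, M)
    alpha: float = 1.0
    K: int = 30
    re_idx: Optional[list[int]] = None        # predictor indices with random effects
    S0: Optional[np.ndarray] = None           # (D_c, q, q) IW scale per target
    nu0: Optional[np.ndarray] = None          # (D_c,) IW dof per target
    lambda_fixed: Optional[np.ndarray] = None  # (D_c,), NaN = learned

    @property
    def n_predictors(self) -> int:
        return len(self.predictor_names)

    @property
    def n_continuous(self) -> int:
        return len(self.continuous_names)

    @property
    def n_binary(self) -> int:
        return len(self.binary_names)

    @property
    def re_dim(self) -> int:
        return 0 if self.re_idx is None else len(self.re_idx)

    def __post_init__(self):
        M, Dc, Db = self.n_predictors, self.n_continuous, self.n_binary
        self.w0_c = _as_2d(self.w0_c, "w0_c", (Dc, M))
        self.p0_c = _as_2d(self.p0_c, "p0_c", (Dc, M))
        self.a0 = np.asarray(self.a0, dtype=float).reshape(Dc)
        self.b0 = np.asarray(self.b0, dtype=float).reshape(Dc)
        self.w0_b = _as_2d(self.w0_b, "w0_b", (Db, M))
        self.p0_b = _as_2d(self.p0_b, "p0_b", (Db, M))
        if self.lambda_fixed is not None:
            self.lambda_fixed = np.asarray(self.lambda_fixed, dtype=float).reshape(Dc)
        self.validate()

    def validate(self) -> None:
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError("DP concentration alpha must be positive")
        if int(self.K) < 1:
            raise ValueError("truncation level K must be a positive integer")
        for name, arr in (("p0_c", self.p0_c), ("p0_b", self.p0_b),
                          ("a0", self.a0), ("b0", self.b0)):
            if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr <= 0)):
                raise ValueError(f"{name} entries must be strictly positive and finite")
        if self.re_idx is not None:
            q = len(self.re_idx)
            if q == 0:
                raise ValueError("re_idx must be non-empty when given")
            if any(j < 0 or j >= self.n_predictors for j in self.re_idx):
                raise ValueError("re_idx entries must index predictor columns")
            if self.S0 is None or self.nu0 is None:
                raise ValueError("random-effect block requires S0 and nu0")
            self.S0 = np.asarray(self.S0, dtype=float).reshape(self.n_continuous, q, q)
            self.nu0 = np.asarray(self.nu0, dtype=float).reshape(self.n_continuous)
            for d in range(self.n_continuous):
                S = self.S0[d]
                if not np.allclose(S, S.T):
                    raise ValueError("S0 must be symmetric")
                if np.any(np.linalg.eigvalsh(S) <= 0):
                    raise ValueError("S0 must be positive definite")
                if self.nu0[d] <= q - 1:
                    raise ValueError("nu0 must exceed re_dim - 1")


@dataclass
class VariationalPosterior:
    """All variational factors of the mean-field approximation.

    Shapes (K components, Dc/Db targets, M predictors, q random-effect
    dims, n subjects, T observation rows):

    * ``gamma1``, ``gamma2``: (K-1,) stick Beta parameters;
    * ``mu_w``/``Sigma_w``: (K, Dc, M) / (K, Dc, M, M) coefficient Gaussians;
    * ``a``/``b``: (K, Dc) residual-precision Gammas;
    * ``mu_wb``/``Sigma_wb``: binary-coefficient Gaussians; ``xi``:
      (K, Db, T) local logistic-bound parameters;
    * ``R``: (n, K) subject responsibilities (rows sum to 1);
    * ``mu_u``/``Sigma_u``: (n, Dc, q)/(n, Dc, q, q) random-effect posteriors;
    * ``Sigma_re``: (K, Dc, q, q) point-estimated random-effect covariances.
    """

    gamma1: np.ndarray
    gamma2: np.ndarray
    mu_w: np.ndarray
    Sigma_w: np.ndarray
    a: np.ndarray
    b: np.ndarray
    mu_wb: np.ndarray
    Sigma_wb: np.ndarray
    xi: np.ndarray
    R: np.ndarray
    mu_u: Optional[np.ndarray] = None
    Sigma_u: Optional[np.ndarray] = None
    Sigma_re: Optional[np.ndarray] = None

    def validate(self) -> None:
        if self.R.size:
            if np.any(self.R < -1e-12):
                raise ValueError("responsibilities must be nonnegative")
            if not np.allclose(self.R.sum(axis=1), 1.0, atol=1e-8):
                raise ValueError("responsibility rows must sum to 1")
        for name, arr in (("a", self.a), ("b", self.b)):
            if arr.size and np.any(arr <= 0):
                raise ValueError(f"Gamma parameter {name} must be positive")

    def array_fields(self) -> dict[str, Optional[np.ndarray]]:
        return {
            "gamma1": self.gamma1, "gamma2": self.gamma2,
            "mu_w": self.mu_w, "Sigma_w": self.Sigma_w,
            "a": self.a, "b": self.b,
            "mu_wb": self.mu_wb, "Sigma_wb": self.Sigma_wb, "xi": self.xi,
            "R": self.R, "mu_u": self.mu_u, "Sigma_u": self.Sigma_u,
            "Sigma_re": self.Sigma_re,
        }


@dataclass
class TrajModel:
    """A fitted trajectory model: prior + variational posterior + metadata."""

    prior: PriorSpec
    posterior: VariationalPosterior
    subject_ids: list
    metadata: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return self.posterior.R.shape[1]

    def expected_weights(self) -> np.ndarray:
        """E[pi] under the stick posterior (remainder mass to component K)."""
        g1, g2 = self.posterior.gamma1, self.posterior.gamma2
        if g1.size == 0:
            return np.ones(1)
        return stick_breaking_weights(g1 / (g1 + g2))

    def component_mass(self) -> np.ndarray:
        """Fraction of subjects (responsibility mass) held by each component."""
        return self.posterior.R.sum(axis=0) / self.posterior.R.shape[0]


@dataclass
class SimSpec:
    """Ground truth for a synthetic longitudinal cohort.

    Subjects draw a group g ~ pi_true; observation times are uniform on
    ``time_range`` and predictors are the polynomial basis
    [1, t, t^2, ...] up to ``poly_degree``.  Continuous targets add
    subject-level random effects (covariance ``re_cov`` on predictor
    indices ``re_idx``) and Gaussian noise with group/target-specific
    ``sigma``; binary targets are Bernoulli through a logistic link.
    """

    n_groups: int
    pi_true: np.ndarray                     # (G,)
    coef_c: np.ndarray                      # (G, D_c, M)
    sigma_c: np.ndarray                     # (G, D_c)
    coef_b: np.ndarray                      # (G, D_b, M)
    n_subjects: int = 300
    obs_per_subject: int | tuple[int, int] = 5
    time_range: tuple[float, float] = (0.0, 10.0)
    poly_degree: int = 2
    re_idx: Optional[list[int]] = None
    re_cov: Optional[np.ndarray] = None     # (D_c, q, q)
    continuous_names: Sequence[str] = ()
    binary_names: Sequence[str] = ()
    seed: int = 0

    def __post_init__(self):
        G = self.n_groups
        self.pi_true = np.asarray(self.pi_true, dtype=float).reshape(G)
        self.coef_c = np.atleast_3d(np.asarray(self.coef_c, dtype=float))
        self.sigma_c = np.asarray(self.sigma_c, dtype=float).reshape(G, -1)
        self.coef_b = np.asarray(self.coef_b, dtype=float)
        if self.coef_b.size == 0:
            self.coef_b = self.coef_b.reshape(G, 0, self.n_predictors)
        if not self.continuous_names:
            self.continuous_names = [f"y{d+1}" for d in range(self.coef_c.shape[1])]
        if not self.binary_names:
            self.binary_names = [f"bin{d+1}" for d in range(self.coef_b.shape[1])]
        self.validate()

    @property
    def n_predictors(self) -> int:
        return self.poly_degree + 1

    @property
    def predictor_names(self) -> list[str]:
        return ["intercept"] + [f"t{'' if p == 1 else p}" for p in range(1, self.poly_degree + 1)]

    def validate(self) -> None:
        if not np.isclose(self.pi_true.sum(), 1.0):
            raise ValueError("group proportions must sum to 1")
        if np.any(self.pi_true < 0):
            raise ValueError("group proportions must be nonnegative")
        if np.any(self.sigma_c < 0):
            raise ValueError("residual standard deviations must be nonnegative")
        if self.coef_c.shape != (self.n_groups, self.sigma_c.shape[1], self.n_predictors):
            raise ValueError("coef_c shape inconsistent with groups/targets/predictors")
        if isinstance(self.obs_per_subject, tuple):
            lo, hi = self.obs_per_subject
            if lo < 1 or hi < lo:
                raise ValueError("obs_per_subject range invalid")
        elif int(self.obs_per_subject) < 1:
            raise ValueError("obs_per_subject must be >= 1")
        if self.re_cov is not None:
            if self.re_idx is None:
                raise ValueError("re_cov requires re_idx")
            q = len(self.re_idx)
            self.re_cov = np.asarray(self.re_cov, dtype=float).reshape(-1, q, q)
            for S in self.re_cov:
                if not np.allclose(S, S.T):
                    raise ValueError("re_cov must be symmetric")
                if np.any(np.linalg.eigvalsh(S) < -1e-12):
                    raise ValueError("re_cov must be positive semidefinite")


def sample_generative(spec: SimSpec, seed: Optional[int] = None):
    """Draw a synthetic cohort from the generative model.

    Returns ``(dataset, truth)`` where ``truth`` is a dict with the true
    group label and random-effect draw per subject.  Identical seeds give
    identical output.
    """
    from .data_io import LongitudinalDataset  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    G = spec.n_groups
    Dc = spec.coef_c.shape[1]
    Db = spec.coef_b.shape[1]
    q = 0 if spec.re_idx is None else len(spec.re_idx)

    subject_ids, rows_X, rows_Y, rows_B = [], [], [], []
    labels = np.empty(spec.n_subjects, dtype=int)
    u_true = np.zeros((spec.n_subjects, Dc, q)) if q else None

    for i in range(spec.n_subjects):
        g = int(rng.choice(G, p=spec.pi_true))
        labels[i] = g
        if isinstance(spec.obs_per_subject, tuple):
            n_i = int(rng.integers(spec.obs_per_subject[0], spec.obs_per_subject[1] + 1))
        else:
            n_i = int(spec.obs_per_subject)
        t = np.sort(rng.uniform(spec.time_range[0], spec.time_range[1], size=n_i))
        X = np.vander(t, N=spec.poly_degree + 1, increasing=True)
        Y = np.empty((n_i, Dc))
        for d in range(Dc):
            mean = X @ spec.coef_c[g, d]
            if q:
                u = rng.multivariate_normal(np.zeros(q), spec.re_cov[d])
                u_true[i, d] = u
                mean = mean + X[:, spec.re_idx] @ u
            Y[:, d] = mean + rng.normal(0.0, spec.sigma_c[g, d], size=n_i)
        B = np.empty((n_i, Db))
        for d in range(Db):
            p = 1.0 / (1.0 + np.exp(-(X @ spec.coef_b[g, d])))
            B[:, d] = (rng.uniform(size=n_i) < p).astype(float)
        sid = f"S{i+1:04d}"
        subject_ids.extend([sid] * n_i)
        rows_X.append(X)
        rows_Y.append(Y)
        rows_B.append(B)

    data = LongitudinalDataset(
        subject_ids=np.asarray(subject_ids, dtype=object),
        X=np.vstack(rows_X),
        Y=np.vstack(rows_Y),
        B=np.vstack(rows_B),
        predictor_names=list(spec.predictor_names),
        continuous_names=list(spec.continuous_names),
        binary_names=list(spec.binary_names),
        subject_col="id",
    )
    truth = {"labels": labels, "u": u_true,
             "subjects": [f"S{i+1:04d}" for i in range(spec.n_subjects)]}
    return data, truth
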