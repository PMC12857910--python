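"""Coordinate-ascent variational inference for the trajectory mixture.

The mean-field factorization is

    q(v) q(z) prod_{k,d} q(w_{k,d}) q(lambda_{k,d}) prod_{i,d} q(u_{i,d})

with Beta sticks, Gaussian coefficients, Gamma residual precisions, a
categorical over component assignments per subject (the responsibility
matrix R), and Gaussian subject-level random effects.  The per-component
random-effect covariance Sigma_re is a point estimate updated in an
EM-style M-step under an inverse-Wishart(S0, nu0) prior; its log-prior
is included in the traced objective so every sweep is a coordinate
ascent step on one fixed functional.  Binary targets enter through the
Jaakkola–Jordan quadratic bound with one local parameter xi per
(component, observation), which keeps the coefficient update Gaussian;
the traced objective is therefore the bounded ELBO.

Every update is the exact maximizer of that objective over its own
factor given the others, so the trace is non-decreasing; the test suite
treats this as the primary correctness oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import betaln, digamma, gammaln, logsumexp, xlogy
from scipy.stats import invwishart

from .data_io import LongitudinalDataset
from .model import PriorSpec, TrajModel, VariationalPosterior

_LOG2PI = float(np.log(2.0 * np.pi))

__all__ = ["FitOptions", "CaviEngine", "fit", "update_sticks", "jj_lambda",
           "jj_bound", "expected_log_pi"]


def expected_log_pi(gamma1: np.ndarray, gamma2: np.ndarray) -> np.ndarray:
    """E[log pi_k] under Beta stick posteriors (component K = remainder mass)."""
    K = gamma1.size + 1
    if K == 1:
        return np.zeros(1)
    Elv = digamma(gamma1) - digamma(gamma1 + gamma2)
    El1mv = digamma(gamma2) - digamma(gamma1 + gamma2)
    out = np.empty(K)
    out[:-1] = Elv + np.concatenate([[0.0], np.cumsum(El1mv[:-1])])
    out[-1] = El1mv.sum()
    return out


class ConfigError(ValueError):
    """Prior/data/option mismatch detected before fitting."""


class NumericalError(RuntimeError):
    """A variational update produced a non-finite or singular quantity."""


@dataclass
class FitOptions:
    """Options controlling the CAVI run."""

    max_iter: int = 500
    tol: float = 1e-6          # relative ELBO change per sweep
    seed: int = 0
    n_restarts: int = 1
    k_override: Optional[int] = None   # overrides PriorSpec.K when set
    verbose: bool = False

    def __post_init__(self):
        if self.max_iter < 1:
            raise ConfigError("max_iter must be >= 1")
        if not self.tol > 0:
            raise ConfigError("tol must be positive")
        if self.n_restarts < 1:
            raise ConfigError("n_restarts must be >= 1")


def update_sticks(R: np.ndarray, alpha: float):
    """Beta(gamma1, gamma2) stick posterior from responsibilities.

    gamma1[k] = 1 + sum_i R[i,k]; gamma2[k] = alpha + sum_i sum_{j>k} R[i,j]
    for k = 1..K-1 (the last stick is the implicit remainder).
    """
    R = np.asarray(R, dtype=float)
    Nk = R.sum(axis=0)
    tail = np.concatenate([np.cumsum(Nk[::-1])[::-1][1:], [0.0]])
    gamma1 = 1.0 + Nk[:-1]
    gamma2 = alpha + tail[:-1]
    return gamma1, gamma2


def jj_lambda(xi: np.ndarray) -> np.ndarray:
    """lambda(xi) = tanh(xi/2) / (4 xi), continuous at 0 with value 1/8."""
    xi = np.abs(np.asarray(xi, dtype=float))
    out = np.full(xi.shape, 0.125)
    nz = xi > 1e-6
    out[nz] = np.tanh(xi[nz] / 2.0) / (4.0 * xi[nz])
    return out


def jj_bound(b, Ez, Ez2, xi):
    """Per-observation quadratic lower bound on E[log p(b | z)].

    log p(b|z) = (b - 1/2) z - log(2 cosh(z/2)) >= (b - 1/2) E[z]
    + log sigmoid(xi) - xi/2 - lambda(xi) (E[z^2] - xi^2); equality holds
    at xi = |z| for a point-mass posterior.
    """
    xi = np.abs(xi)
    lam = jj_lambda(xi)
    log_sig = -np.log1p(np.exp(-xi))
    return (b - 0.5) * Ez + log_sig - xi / 2.0 - lam * (Ez2 - xi ** 2)


class CaviEngine:
    """Holds the data, the prior, and the current variational state.

    Exposes each coordinate update as a method so unit tests can exercise
    them in isolation; :func:`fit` drives full sweeps.
    """

    def __init__(self, data: LongitudinalDataset, prior: PriorSpec,
                 K: Optional[int] = None):
        if data.predictor_names != prior.predictor_names:
            raise ConfigError(
                f"predictor columns {data.predictor_names} do not match "
                f"prior predictors {prior.predictor_names}")
        if data.continuous_names != prior.continuous_names:
            raise ConfigError(
                f"continuous targets {data.continuous_names} do not match "
                f"prior targets {prior.continuous_names}")
        if data.binary_names != prior.binary_names:
            raise ConfigError(
                f"binary targets {data.binary_names} do not match "
                f"prior targets {prior.binary_names}")
        self.data = data
        self.prior = prior
        self.K = int(K if K is not None else prior.K)
        self.n = data.n_subjects
        self.M = len(prior.predictor_names)
        self.Dc = prior.n_continuous
        self.Db = prior.n_binary
        self.q_re = prior.re_dim

        self.X = data.X
        self.subj = data.subject_rows
        self.mask_c = data.mask_c
        self.mask_b = data.mask_b
        self.Yf = np.nan_to_num(data.Y)
        self.Bf = np.nan_to_num(data.B)
        if self.q_re:
            self.Z = self.X[:, prior.re_idx]
            self.Zouter = self.Z[:, :, None] * self.Z[:, None, :]
        self.q: Optional[VariationalPosterior] = None

    # ------------------------------------------------------------------ state

    def init_state(self, seed: int = 0) -> VariationalPosterior:
        """Seeded symmetric-Dirichlet responsibilities; factors at their priors."""
        rng = np.random.default_rng(seed)
        K, M, Dc, Db, q = self.K, self.M, self.Dc, self.Db, self.q_re
        pr = self.prior
        R = rng.dirichlet(np.ones(K), size=self.n) if K > 1 else np.ones((self.n, 1))
        state = VariationalPosterior(
            gamma1=np.ones(K - 1),
            gamma2=np.full(K - 1, pr.alpha),
            mu_w=np.broadcast_to(pr.w0_c, (K, Dc, M)).copy(),
            Sigma_w=np.stack([[np.diag(1.0 / pr.p0_c[d]) for d in range(Dc)]
                              for _ in range(K)]) if Dc else np.zeros((K, 0, M, M)),
            a=np.broadcast_to(pr.a0, (K, Dc)).copy(),
            b=np.broadcast_to(pr.b0, (K, Dc)).copy(),
            mu_wb=np.broadcast_to(pr.w0_b, (K, Db, M)).copy(),
            Sigma_wb=np.stack([[np.diag(1.0 / pr.p0_b[d]) for d in range(Db)]
                               for _ in range(K)]) if Db else np.zeros((K, 0, M, M)),
            xi=np.ones((K, Db, self.data.n_obs)),
            R=R,
        )
        if q:
            Sre0 = np.stack([pr.S0[d] / (pr.nu0[d] + q + 1) for d in range(Dc)])
            state.Sigma_re = np.broadcast_to(Sre0, (K, Dc, q, q)).copy()
            state.mu_u = np.zeros((self.n, Dc, q))
            state.Sigma_u = np.broadcast_to(Sre0, (self.n, Dc, q, q)).copy()
        self.q = state
        return state

    # -------------------------------------------------------------- expectations

    def _lam_moments(self, k: int, d: int):
        """(E[lambda], E[log lambda]) for component k, continuous target d."""
        lf = self.prior.lambda_fixed
        if lf is not None and np.isfinite(lf[d]):
            return float(lf[d]), float(np.log(lf[d]))
        a, b = self.q.a[k, d], self.q.b[k, d]
        return float(a / b), float(digamma(a) - np.log(b))

    def _lambda_is_fixed(self, d: int) -> bool:
        lf = self.prior.lambda_fixed
        return lf is not None and bool(np.isfinite(lf[d]))

    def expected_log_pi(self) -> np.ndarray:
        """E[log pi_k] under the current stick posterior."""
        if self.K == 1:
            return np.zeros(1)
        return expected_log_pi(self.q.gamma1, self.q.gamma2)

    def _zu_rows(self, d: int):
        """Per-row E[z'u] and z'Var(u)z for target d (zeros without RE)."""
        if not self.q_re:
            zero = np.zeros(self.data.n_obs)
            return zero, zero
        mu = self.q.mu_u[self.subj, d]          # (n_obs, q)
        V = self.q.Sigma_u[self.subj, d]        # (n_obs, q, q)
        zu = np.einsum("ij,ij->i", self.Z, mu)
        zVz = np.einsum("ij,ijk,ik->i", self.Z, V, self.Z)
        return zu, zVz

    def _r2_rows(self, k: int, d: int) -> np.ndarray:
        """E[(y - x'w - z'u)^2] per row (valid where the target is observed)."""
        zu, zVz = self._zu_rows(d)
        resid = self.Yf[:, d] - self.X @ self.q.mu_w[k, d] - zu
        quad_w = np.einsum("im,mn,in->i", self.X, self.q.Sigma_w[k, d], self.X)
        return resid ** 2 + quad_w + zVz

    def _cont_loglik_subj(self) -> np.ndarray:
        """(n, K) expected Gaussian log-likelihood summed over targets/rows."""
        out = np.zeros((self.n, self.K))
        for d in range(self.Dc):
            m = self.mask_c[:, d]
            for k in range(self.K):
                Elam, Eloglam = self._lam_moments(k, d)
                rows = 0.5 * (Eloglam - _LOG2PI) - 0.5 * Elam * self._r2_rows(k, d)
                out[:, k] += np.bincount(self.subj[m], weights=rows[m],
                                         minlength=self.n)
        return out

    def _binary_bound_rows(self, k: int, d: int) -> np.ndarray:
        mu, Sig = self.q.mu_wb[k, d], self.q.Sigma_wb[k, d]
        Ez = self.X @ mu
        Ez2 = Ez ** 2 + np.einsum("im,mn,in->i", self.X, Sig, self.X)
        return jj_bound(self.Bf[:, d], Ez, Ez2, self.q.xi[k, d])

    def _binary_bound_subj(self) -> np.ndarray:
        out = np.zeros((self.n, self.K))
        for d in range(self.Db):
            m = self.mask_b[:, d]
            for k in range(self.K):
                rows = self._binary_bound_rows(k, d)
                out[:, k] += np.bincount(self.subj[m], weights=rows[m],
                                         minlength=self.n)
        return out

    def _re_prior_subj(self) -> np.ndarray:
        """(n, K) E[log N(u_i; 0, Sigma_re[k,d])] summed over RE targets."""
        out = np.zeros((self.n, self.K))
        if not self.q_re:
            return out
        q = self.q_re
        for d in range(self.Dc):
            Euu = self.q.Sigma_u[:, d] + np.einsum(
                "ij,ik->ijk", self.q.mu_u[:, d], self.q.mu_u[:, d])  # (n,q,q)
            for k in range(self.K):
                Sre = self.q.Sigma_re[k, d]
                sign, logdet = np.linalg.slogdet(Sre)
                if sign <= 0:
                    raise NumericalError(
                        f"Sigma_re for component {k+1}, target "
                        f"'{self.prior.continuous_names[d]}' is not positive definite")
                inv = np.linalg.inv(Sre)
                tr = np.einsum("ab,iab->i", inv, Euu)
                out[:, k] += -0.5 * (q * _LOG2PI + logdet + tr)
        return out

    # ------------------------------------------------------------------ updates

    def update_responsibilities(self) -> np.ndarray:
        """Posterior over components per subject (log-sum-exp normalized)."""
        log_rho = (self.expected_log_pi()[None, :]
                   + self._cont_loglik_subj()
                   + self._binary_bound_subj()
                   + self._re_prior_subj())
        norm = logsumexp(log_rho, axis=1, keepdims=True)
        if not np.all(np.isfinite(norm)):
            bad = int(np.where(~np.isfinite(norm.ravel()))[0][0])
            raise NumericalError(
                f"subject '{self.data.subjects[bad]}' has non-finite "
                "log-likelihood under every component")
        self.q.R = np.exp(log_rho - norm)
        return self.q.R

    def update_sticks(self) -> None:
        if self.K > 1:
            self.q.gamma1, self.q.gamma2 = update_sticks(self.q.R, self.prior.alpha)

    def update_coefficients(self, k: int, d: int):
        """Responsibility-weighted Bayesian linear-regression update for w_{k,d}."""
        pr = self.prior
        Elam, _ = self._lam_moments(k, d)
        if not (np.isfinite(Elam) and Elam > 0):
            raise NumericalError(
                f"residual precision for component {k+1}, target "
                f"'{pr.continuous_names[d]}' is not finite/positive")
        w = self.q.R[self.subj, k] * self.mask_c[:, d]
        A = np.diag(pr.p0_c[d]) + Elam * (self.X.T * w) @ self.X
        zu, _ = self._zu_rows(d)
        rhs = pr.p0_c[d] * pr.w0_c[d] + Elam * self.X.T @ (w * (self.Yf[:, d] - zu))
        Sig = np.linalg.inv(A)
        Sig = 0.5 * (Sig + Sig.T)
        mu = Sig @ rhs
        self.q.mu_w[k, d] = mu
        self.q.Sigma_w[k, d] = Sig
        return mu, Sig

    def update_precisions(self, k: int, d: int):
        """Gamma posterior of the residual precision for component k, target d."""
        if self._lambda_is_fixed(d):
            return self.q.a[k, d], self.q.b[k, d]
        pr = self.prior
        w = self.q.R[self.subj, k] * self.mask_c[:, d]
        self.q.a[k, d] = pr.a0[d] + 0.5 * w.sum()
        self.q.b[k, d] = pr.b0[d] + 0.5 * float(w @ self._r2_rows(k, d))
        return self.q.a[k, d], self.q.b[k, d]

    def update_random_effects(self, d: int):
        """Gaussian posterior of u_{i,d} for every subject (batched)."""
        q = self.q_re
        inv_Sre = np.linalg.inv(self.q.Sigma_re[:, d])          # (K, q, q)
        A = np.einsum("ik,kab->iab", self.q.R, inv_Sre)          # (n, q, q)
        m = self.mask_c[:, d]
        Elam = np.array([self._lam_moments(k, d)[0] for k in range(self.K)])
        c_subj = self.q.R @ Elam                                  # (n,)
        ZtZ = np.zeros((self.n, q, q))
        np.add.at(ZtZ, self.subj[m], self.Zouter[m])
        A += c_subj[:, None, None] * ZtZ
        rhs = np.zeros((self.n, q))
        for k in range(self.K):
            resid = (self.Yf[:, d] - self.X @ self.q.mu_w[k, d]) * m
            wrow = self.q.R[self.subj, k] * Elam[k]
            np.add.at(rhs, self.subj, (wrow * resid)[:, None] * self.Z)
        try:
            V = np.linalg.inv(A)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(
                f"random-effect posterior for target "
                f"'{self.prior.continuous_names[d]}' is singular") from exc
        V = 0.5 * (V + np.swapaxes(V, 1, 2))
        self.q.Sigma_u[:, d] = V
        self.q.mu_u[:, d] = np.einsum("iab,ib->ia", V, rhs)
        return self.q.mu_u[:, d], self.q.Sigma_u[:, d]

    def update_re_covariance(self, k: int, d: int) -> np.ndarray:
        """MAP update of Sigma_re[k,d] under the inverse-Wishart prior."""
        pr = self.prior
        q = self.q_re
        Euu = self.q.Sigma_u[:, d] + np.einsum(
            "ij,ik->ijk", self.q.mu_u[:, d], self.q.mu_u[:, d])
        Nk = self.q.R[:, k].sum()
        S = pr.S0[d] + np.einsum("i,iab->ab", self.q.R[:, k], Euu)
        Sre = S / (pr.nu0[d] + q + 1.0 + Nk)
        Sre = 0.5 * (Sre + Sre.T)
        if np.any(np.linalg.eigvalsh(Sre) <= 0):
            raise NumericalError(
                f"Sigma_re update for component {k+1}, target "
                f"'{pr.continuous_names[d]}' lost positive definiteness")
        self.q.Sigma_re[k, d] = Sre
        return Sre

    def update_logistic_coefficients(self, k: int, d: int):
        """Gaussian coefficient update for a binary target under the JJ bound."""
        pr = self.prior
        lam = jj_lambda(self.q.xi[k, d])
        w = self.q.R[self.subj, k] * self.mask_b[:, d]
        A = np.diag(pr.p0_b[d]) + 2.0 * (self.X.T * (w * lam)) @ self.X
        rhs = pr.p0_b[d] * pr.w0_b[d] + self.X.T @ (w * (self.Bf[:, d] - 0.5))
        Sig = np.linalg.inv(A)
        Sig = 0.5 * (Sig + Sig.T)
        mu = Sig @ rhs
        self.q.mu_wb[k, d] = mu
        self.q.Sigma_wb[k, d] = Sig
        return mu, Sig

    def update_xi(self, k: int, d: int) -> np.ndarray:
        """Optimal local bound parameter: xi^2 = E[(x'w)^2] per row."""
        mu, Sig = self.q.mu_wb[k, d], self.q.Sigma_wb[k, d]
        Ez2 = (self.X @ mu) ** 2 + np.einsum("im,mn,in->i", self.X, Sig, self.X)
        self.q.xi[k, d] = np.sqrt(np.maximum(Ez2, 0.0))
        return self.q.xi[k, d]

    def sweep(self, first: bool = False) -> None:
        """One full CAVI sweep.

        The first sweep keeps the seeded Dirichlet responsibilities (all
        component factors start at the shared prior, so recomputing R
        before any component has adapted would erase the symmetry
        breaking); later sweeps lead with the responsibility update.
        """
        if not first:
            self.update_responsibilities()
        self.update_sticks()
        for k in range(self.K):
            for d in range(self.Dc):
                self.update_coefficients(k, d)
                self.update_precisions(k, d)
        if self.q_re:
            for d in range(self.Dc):
                self.update_random_effects(d)
            for k in range(self.K):
                for d in range(self.Dc):
                    self.update_re_covariance(k, d)
        for k in range(self.K):
            for d in range(self.Db):
                self.update_logistic_coefficients(k, d)
                self.update_xi(k, d)

    # -------------------------------------------------------------------- ELBO

    def compute_elbo(self) -> float:
        """Bounded evidence lower bound (plus the Sigma_re log-prior term)."""
        pr, st = self.prior, self.q
        elbo = 0.0

        # sticks: E[log p(v|alpha)] + H[q(v)]
        if self.K > 1:
            g1, g2 = st.gamma1, st.gamma2
            El1mv = digamma(g2) - digamma(g1 + g2)
            elbo += float(np.sum(np.log(pr.alpha) + (pr.alpha - 1.0) * El1mv))
            ent = (betaln(g1, g2) - (g1 - 1) * digamma(g1) - (g2 - 1) * digamma(g2)
                   + (g1 + g2 - 2) * digamma(g1 + g2))
            elbo += float(np.sum(ent))

        # assignments
        elbo += float(np.sum(st.R * self.expected_log_pi()[None, :]))
        elbo -= float(np.sum(xlogy(st.R, st.R)))

        # continuous likelihood terms
        Rrow = st.R[self.subj]
        for d in range(self.Dc):
            m = self.mask_c[:, d]
            for k in range(self.K):
                Elam, Eloglam = self._lam_moments(k, d)
                rows = 0.5 * (Eloglam - _LOG2PI) - 0.5 * Elam * self._r2_rows(k, d)
                elbo += float(np.sum(Rrow[m, k] * rows[m]))

        # coefficient priors/entropies (continuous and binary)
        def _gauss_terms(mu_all, Sig_all, w0, p0, D):
            s = 0.0
            for d in range(D):
                for k in range(self.K):
                    mu, Sig = mu_all[k, d], Sig_all[k, d]
                    dv = mu - w0[d]
                    s += -0.5 * float(np.sum(
                        _LOG2PI - np.log(p0[d]) + p0[d] * (dv ** 2 + np.diag(Sig))))
                    sign, logdet = np.linalg.slogdet(Sig)
                    if sign <= 0:
                        raise NumericalError("coefficient covariance lost definiteness")
                    s += 0.5 * (self.M * (1.0 + _LOG2PI) + logdet)
            return s

        elbo += _gauss_terms(st.mu_w, st.Sigma_w, pr.w0_c, pr.p0_c, self.Dc)
        elbo += _gauss_terms(st.mu_wb, st.Sigma_wb, pr.w0_b, pr.p0_b, self.Db)

        # residual-precision priors/entropies
        for d in range(self.Dc):
            if self._lambda_is_fixed(d):
                continue
            a0, b0 = pr.a0[d], pr.b0[d]
            for k in range(self.K):
                a, b = st.a[k, d], st.b[k, d]
                Elam, Eloglam = a / b, digamma(a) - np.log(b)
                elbo += float(a0 * np.log(b0) - gammaln(a0)
                              + (a0 - 1.0) * Eloglam - b0 * Elam)
                elbo += float(a - np.log(b) + gammaln(a) + (1.0 - a) * digamma(a))

        # random effects: prior term, entropy, and Sigma_re IW log-prior
        if self.q_re:
            elbo += float(np.sum(st.R * self._re_prior_subj()))
            for d in range(self.Dc):
                sign, logdet = np.linalg.slogdet(st.Sigma_u[:, d])
                if np.any(sign <= 0):
                    raise NumericalError("random-effect posterior covariance "
                                         "lost definiteness")
                elbo += float(np.sum(0.5 * (self.q_re * (1.0 + _LOG2PI) + logdet)))
                for k in range(self.K):
                    elbo += float(invwishart.logpdf(
                        st.Sigma_re[k, d], df=pr.nu0[d], scale=pr.S0[d]))

        # binary bound terms
        for d in range(self.Db):
            m = self.mask_b[:, d]
            for k in range(self.K):
                rows = self._binary_bound_rows(k, d)
                elbo += float(np.sum(Rrow[m, k] * rows[m]))

        if not np.isfinite(elbo):
            raise NumericalError("ELBO is non-finite")
        return elbo


def fit(data: LongitudinalDataset, prior: PriorSpec,
        opts: Optional[FitOptions] = None) -> TrajModel:
    """Fit the truncated DP mixture of longitudinal regressions by CAVI.

    Runs ``n_restarts`` seeded restarts and keeps the run with the best
    final ELBO.  The returned model records the full ELBO trace, which is
    non-decreasing across sweeps within each restart.
    """
    opts = opts or FitOptions()
    best = None
    for r in range(opts.n_restarts):
        engine = CaviEngine(data, prior, K=opts.k_override)
        engine.init_state(seed=opts.seed + r)
        trace = []
        converged = False
        for it in range(opts.max_iter):
            engine.sweep(first=(it == 0))
            e = engine.compute_elbo()
            trace.append(e)
            if opts.verbose:
                print(f"restart {r} sweep {it + 1}: ELBO = {e:.6f}")
            if it > 0 and abs(e - trace[-2]) <= opts.tol * abs(trace[-2]):
                converged = True
                break
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], engine, trace, converged, opts.seed + r)

    _, engine, trace, converged, used_seed = best
    engine.update_responsibilities()  # final E-step so R matches the stored factors
    meta = {
        "n_iter": len(trace),
        "converged": bool(converged),
        "final_elbo": float(trace[-1]),
        "elbo_trace": [float(e) for e in trace],
        "seed": int(used_seed),
        "K": int(engine.K),
        "n_subjects": int(data.n_subjects),
        "n_obs": int(data.n_obs),
    }
    return TrajModel(prior=prior, posterior=engine.q,
                     subject_ids=list(data.subjects), metadata=meta)
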