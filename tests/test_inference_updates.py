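"""Unit-level oracles for each coordinate update of the CAVI engine."""

import numpy as np
import pytest
from scipy.special import digamma, expit

import trajmix as tm
from trajmix.inference import CaviEngine, jj_bound, jj_lambda, update_sticks

from conftest import flat_gaussian_prior, make_tiny_continuous


def make_engine(K=2, lam_fixed=None, seed=0, data=None, prior=None):
    data = data if data is not None else make_tiny_continuous()
    prior = prior if prior is not None else flat_gaussian_prior(K=K,
                                                               lam_fixed=lam_fixed)
    eng = CaviEngine(data, prior)
    eng.init_state(seed=seed)
    return eng, data, prior


class TestSticks:
    def test_all_mass_in_first_component(self):
        R = np.zeros((10, 3))
        R[:, 0] = 1.0
        g1, g2 = update_sticks(R, alpha=1.0)
        assert g1[0] == pytest.approx(11.0)
        assert g2[0] == pytest.approx(1.0)

    def test_uniform_responsibilities(self):
        R = np.full((4, 2), 0.5)
        g1, g2 = update_sticks(R, alpha=2.0)
        assert g1[0] == pytest.approx(3.0)
        assert g2[0] == pytest.approx(4.0)

    def test_vectorized_matches_double_loop(self):
        rng = np.random.default_rng(0)
        R = rng.dirichlet(np.ones(5), size=20)
        g1, g2 = update_sticks(R, alpha=1.7)
        for k in range(4):
            g1_loop = 1.0 + sum(R[i, k] for i in range(20))
            g2_loop = 1.7 + sum(R[i, j] for i in range(20) for j in range(5)
                                if j > k)
            assert g1[k] == pytest.approx(g1_loop, rel=1e-12)
            assert g2[k] == pytest.approx(g2_loop, rel=1e-12)


class TestResponsibilities:
    def test_single_component_gives_ones(self):
        eng, _, _ = make_engine(K=1)
        R = eng.update_responsibilities()
        np.testing.assert_allclose(R, 1.0)

    def test_identical_components_split_evenly(self):
        eng, _, _ = make_engine(K=2)
        # identical component factors and symmetric E[log pi]
        eng.q.gamma1[:] = 1.0
        eng.q.gamma2[:] = 1.0
        elogpi = eng.expected_log_pi()
        # Beta(1,1) sticks give E[log v] = E[log(1-v)], so both components
        # carry the same E[log pi]; identical factors then split mass evenly
        assert elogpi[0] == pytest.approx(elogpi[1])
        R = eng.update_responsibilities()
        np.testing.assert_allclose(R, 0.5, atol=1e-12)

    def test_matches_direct_arithmetic_single_subject(self):
        """Brute-force oracle: one subject, two Gaussian components."""
        X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0]])
        y = np.array([0.2, 1.1, 1.9])
        data = tm.LongitudinalDataset(
            subject_ids=np.array(["A"] * 3, dtype=object), X=X, Y=y[:, None],
            B=np.empty((3, 0)), predictor_names=["intercept", "t"],
            continuous_names=["y"], binary_names=[])
        eng, _, _ = make_engine(K=2, data=data)
        rng = np.random.default_rng(3)
        for k in range(2):
            eng.q.mu_w[k, 0] = rng.normal(size=2)
            A = rng.normal(size=(2, 2))
            eng.q.Sigma_w[k, 0] = A @ A.T + 0.1 * np.eye(2)
            eng.q.a[k, 0] = 2.0 + k
            eng.q.b[k, 0] = 1.5
        eng.q.gamma1[:] = 2.0
        eng.q.gamma2[:] = 3.0

        elogpi = eng.expected_log_pi()
        log_rho = []
        for k in range(2):
            acc = elogpi[k]
            Elam = eng.q.a[k, 0] / eng.q.b[k, 0]
            Eloglam = digamma(eng.q.a[k, 0]) - np.log(eng.q.b[k, 0])
            for t in range(3):
                x = X[t]
                r2 = ((y[t] - x @ eng.q.mu_w[k, 0]) ** 2
                      + x @ eng.q.Sigma_w[k, 0] @ x)
                acc += 0.5 * (Eloglam - np.log(2 * np.pi)) - 0.5 * Elam * r2
            log_rho.append(acc)
        expected = np.exp(log_rho - np.max(log_rho))
        expected /= expected.sum()
        R = eng.update_responsibilities()
        np.testing.assert_allclose(R[0], expected, rtol=1e-10)


class TestCoefficientUpdate:
    def test_no_responsibility_mass_returns_prior(self):
        eng, _, prior = make_engine(K=2)
        eng.q.R[:, 1] = 0.0
        eng.q.R[:, 0] = 1.0
        mu, Sig = eng.update_coefficients(1, 0)
        np.testing.assert_allclose(mu, prior.w0_c[0], atol=1e-12)
        np.testing.assert_allclose(Sig, np.diag(1.0 / prior.p0_c[0]), atol=1e-12)

    def test_matches_conjugate_closed_form(self):
        """K=1, known precision: textbook Bayesian linear regression."""
        lam = 4.0
        eng, data, prior = make_engine(K=1, lam_fixed=lam)
        mu, Sig = eng.update_coefficients(0, 0)
        X, y = data.X, data.Y[:, 0]
        A = np.diag(prior.p0_c[0]) + lam * X.T @ X
        Sig_star = np.linalg.inv(A)
        mu_star = Sig_star @ (prior.p0_c[0] * prior.w0_c[0] + lam * X.T @ y)
        np.testing.assert_allclose(mu, mu_star, rtol=1e-12)
        np.testing.assert_allclose(Sig, Sig_star, rtol=1e-12)

    def test_infinite_prior_precision_pins_coefficient(self):
        prior = flat_gaussian_prior(K=1, lam_fixed=4.0, p0=(1e14, 2.0),
                                    w0=(7.0, 0.0))
        eng, _, _ = make_engine(K=1, prior=prior)
        mu, _ = eng.update_coefficients(0, 0)
        assert mu[0] == pytest.approx(7.0, abs=1e-5)


class TestPrecisionUpdate:
    def test_no_mass_returns_prior(self):
        eng, _, prior = make_engine(K=2)
        eng.q.R[:, 1] = 0.0
        eng.q.R[:, 0] = 1.0
        a, b = eng.update_precisions(1, 0)
        assert a == pytest.approx(prior.a0[0])
        assert b == pytest.approx(prior.b0[0])

    def test_point_mass_residuals_direct_substitution(self):
        """Residuals [1, 1] fully assigned with a0 = b0 = 1 give (a, b) = (2, 2)."""
        X = np.array([[1.0], [1.0]])
        y = np.array([1.0, 1.0])
        data = tm.LongitudinalDataset(
            subject_ids=np.array(["A", "B"], dtype=object), X=X, Y=y[:, None],
            B=np.empty((2, 0)), predictor_names=["intercept"],
            continuous_names=["y"], binary_names=[])
        prior = tm.PriorSpec(
            predictor_names=["intercept"], continuous_names=["y"],
            binary_names=[], w0_c=[[0.0]], p0_c=[[1.0]], a0=[1.0], b0=[1.0],
            w0_b=np.zeros((0, 1)), p0_b=np.ones((0, 1)), alpha=1.0, K=1)
        eng = CaviEngine(data, prior)
        eng.init_state(seed=0)
        eng.q.mu_w[0, 0] = 0.0          # point-mass coefficients at zero
        eng.q.Sigma_w[0, 0] = 1e-300
        a, b = eng.update_precisions(0, 0)
        assert a == pytest.approx(2.0)
        assert b == pytest.approx(2.0)

    def test_expected_residual_matches_expansion_oracle(self):
        eng, data, _ = make_engine(K=2, seed=4)
        rng = np.random.default_rng(9)
        eng.q.mu_w[0, 0] = rng.normal(size=2)
        A = rng.normal(size=(2, 2))
        eng.q.Sigma_w[0, 0] = A @ A.T + 0.05 * np.eye(2)
        a, b = eng.update_precisions(0, 0)
        # explicit expansion E[r^2] = (y - x mu)^2 + x' Sigma x per row
        X, y = data.X, data.Y[:, 0]
        acc = 0.0
        for t in range(X.shape[0]):
            r2 = ((y[t] - X[t] @ eng.q.mu_w[0, 0]) ** 2
                  + X[t] @ eng.q.Sigma_w[0, 0] @ X[t])
            acc += eng.q.R[eng.subj[t], 0] * r2
        assert b == pytest.approx(eng.prior.b0[0] + 0.5 * acc, rel=1e-12)
        assert a == pytest.approx(eng.prior.a0[0]
                                  + 0.5 * eng.q.R[:, 0].sum() * 5, rel=1e-12)


def make_re_engine(n_subjects=1, seed=0, lam=4.0, sre=2.0):
    rng = np.random.default_rng(seed)
    obs = 4
    n = n_subjects * obs
    X = np.column_stack([np.ones(n), rng.uniform(0, 10, n)])
    y = rng.normal(size=n)
    ids = np.repeat([f"S{i}" for i in range(n_subjects)], obs).astype(object)
    data = tm.LongitudinalDataset(
        subject_ids=ids, X=X, Y=y[:, None], B=np.empty((n, 0)),
        predictor_names=["intercept", "t"], continuous_names=["y"],
        binary_names=[])
    prior = tm.PriorSpec(
        predictor_names=["intercept", "t"], continuous_names=["y"],
        binary_names=[], w0_c=[[0.0, 0.0]], p0_c=[[0.5, 0.5]],
        a0=[2.0], b0=[2.0], w0_b=np.zeros((0, 2)), p0_b=np.ones((0, 2)),
        alpha=1.0, K=1, re_idx=[0], S0=[[[1.0]]], nu0=[3.0],
        lambda_fixed=[lam])
    eng = CaviEngine(data, prior)
    eng.init_state(seed=0)
    eng.q.Sigma_re[0, 0] = np.array([[sre]])
    return eng, data


class TestRandomEffects:
    def test_single_subject_matches_ridge_closed_form(self):
        lam, sre = 4.0, 2.0
        eng, data = make_re_engine(lam=lam, sre=sre)
        rng = np.random.default_rng(1)
        eng.q.mu_w[0, 0] = rng.normal(size=2)
        mu_u, Sig_u = eng.update_random_effects(0)
        Z = data.X[:, :1]
        resid = data.Y[:, 0] - data.X @ eng.q.mu_w[0, 0]
        A = 1.0 / sre + lam * float(Z[:, 0] @ Z[:, 0])
        mu_star = lam * float(Z[:, 0] @ resid) / A
        assert mu_u[0, 0] == pytest.approx(mu_star, rel=1e-10)
        assert Sig_u[0, 0, 0] == pytest.approx(1.0 / A, rel=1e-10)

    def test_shrinkage_limit_zero_covariance(self):
        eng, _ = make_re_engine(sre=1e-12)
        mu_u, _ = eng.update_random_effects(0)
        assert abs(mu_u[0, 0]) < 1e-9

    def test_re_covariance_map_update_formula(self):
        eng, _ = make_re_engine(n_subjects=6, seed=2)
        rng = np.random.default_rng(5)
        eng.q.mu_u[:, 0, 0] = rng.normal(size=6)
        eng.q.Sigma_u[:, 0, 0, 0] = rng.uniform(0.1, 1.0, size=6)
        Sre = eng.update_re_covariance(0, 0)
        Euu = eng.q.Sigma_u[:, 0, 0, 0] + eng.q.mu_u[:, 0, 0] ** 2
        expected = (1.0 + np.sum(eng.q.R[:, 0] * Euu)) / (3.0 + 1 + 1
                                                          + eng.q.R[:, 0].sum())
        assert Sre[0, 0] == pytest.approx(expected, rel=1e-12)


class TestLogisticBound:
    def test_zero_coefficients_bound_is_log_half(self):
        # point mass at w = 0 -> xi = 0 and bound log(1/2) per observation
        assert jj_lambda(np.array([0.0]))[0] == pytest.approx(0.125)
        val = jj_bound(b=1.0, Ez=0.0, Ez2=0.0, xi=0.0)
        assert val == pytest.approx(np.log(0.5), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_bound_below_exact_with_equality_at_optimum(self, seed):
        rng = np.random.default_rng(seed)
        z = rng.normal(scale=3.0)
        b = float(rng.integers(0, 2))
        exact = b * z - np.log1p(np.exp(z))
        # equality at xi = |z| for a point-mass posterior
        assert jj_bound(b, z, z ** 2, abs(z)) == pytest.approx(exact, abs=1e-10)
        for xi in rng.uniform(0, 6, size=10):
            assert jj_bound(b, z, z ** 2, xi) <= exact + 1e-12

    def test_logistic_coefficient_update_matches_direct_solve(self):
        rng = np.random.default_rng(0)
        n = 30
        X = np.column_stack([np.ones(n), rng.uniform(-2, 2, n)])
        bvals = (rng.uniform(size=n) < expit(X @ [0.5, 1.0])).astype(float)
        ids = np.repeat([f"S{i}" for i in range(10)], 3).astype(object)
        data = tm.LongitudinalDataset(
            subject_ids=ids, X=X, Y=np.empty((n, 0)), B=bvals[:, None],
            predictor_names=["intercept", "t"], continuous_names=[],
            binary_names=["event"])
        prior = tm.PriorSpec(
            predictor_names=["intercept", "t"], continuous_names=[],
            binary_names=["event"], w0_c=np.zeros((0, 2)),
            p0_c=np.ones((0, 2)), a0=[], b0=[], w0_b=[[0.0, 0.0]],
            p0_b=[[1.0, 1.0]], alpha=1.0, K=1)
        eng = CaviEngine(data, prior)
        eng.init_state(seed=0)
        eng.q.xi[0, 0] = rng.uniform(0.1, 2.0, size=n)
        mu, Sig = eng.update_logistic_coefficients(0, 0)
        lam = jj_lambda(eng.q.xi[0, 0])
        A = np.eye(2) + 2.0 * (X.T * lam) @ X
        mu_star = np.linalg.solve(A, X.T @ (bvals - 0.5))
        np.testing.assert_allclose(mu, mu_star, rtol=1e-10)
        np.testing.assert_allclose(Sig, np.linalg.inv(A), rtol=1e-10)
        # xi update: xi^2 = E[(x'w)^2]
        xi = eng.update_xi(0, 0)
        Ez2 = (X @ mu) ** 2 + np.einsum("im,mn,in->i", X, Sig, X)
        np.testing.assert_allclose(xi ** 2, Ez2, rtol=1e-10)


class TestInitState:
    def test_deterministic_given_seed(self):
        e1, _, _ = make_engine(seed=42)
        e2, _, _ = make_engine(seed=42)
        np.testing.assert_array_equal(e1.q.R, e2.q.R)

    def test_rows_sum_to_one(self):
        eng, _, _ = make_engine(K=5, seed=0)
        np.testing.assert_allclose(eng.q.R.sum(axis=1), 1.0, atol=1e-12)

    def test_different_seeds_differ(self):
        e1, _, _ = make_engine(seed=0)
        e2, _, _ = make_engine(seed=1)
        assert not np.array_equal(e1.q.R, e2.q.R)


class TestElbo:
    def test_duplicating_subjects_adds_data_terms_linearly(self):
        """Replication oracle: at fixed factors the data-dependent ELBO terms
        scale linearly with the number of dataset copies."""
        base = make_tiny_continuous(n_subjects=4, obs=3, seed=2)

        def replicated(copies):
            ids = np.concatenate([
                np.array([f"{s}_c{c}" for s in base.subject_ids], dtype=object)
                for c in range(copies)])
            return tm.LongitudinalDataset(
                subject_ids=ids, X=np.tile(base.X, (copies, 1)),
                Y=np.tile(base.Y, (copies, 1)), B=np.empty((0, 0)).reshape(
                    base.n_obs * copies, 0),
                predictor_names=base.predictor_names,
                continuous_names=base.continuous_names, binary_names=[])

        prior = flat_gaussian_prior(K=3)
        elbos = []
        for copies in (1, 2, 3):
            eng = CaviEngine(replicated(copies), prior)
            eng.init_state(seed=0)
            # same per-subject responsibilities in every copy
            eng.q.R = np.tile(CaviEngine(replicated(1), prior)
                              .init_state(seed=0).R, (copies, 1))
            elbos.append(eng.compute_elbo())
        assert elbos[2] - elbos[1] == pytest.approx(elbos[1] - elbos[0],
                                                    rel=1e-9)
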