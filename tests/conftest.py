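import numpy as np
import pytest

import trajmix as tm


@pytest.fixture(scope="session")
def separated3():
    spec = tm.get_preset("separated3")
    data, truth = tm.sample_generative(spec)
    return spec, data, truth


@pytest.fixture(scope="session")
def separated3_model(separated3):
    _, data, truth = separated3
    prior = tm.generate_prior(data, k_est=3)
    model = tm.fit(data, prior, tm.FitOptions(seed=1, n_restarts=3))
    return data, truth, prior, model


@pytest.fixture(scope="session")
def binary2_model():
    spec = tm.get_preset("binary2")
    data, truth = tm.sample_generative(spec)
    prior = tm.generate_prior(data, k_est=2)
    model = tm.fit(data, prior, tm.FitOptions(seed=1, n_restarts=3))
    return data, truth, prior, model


@pytest.fixture(scope="session")
def overlap2_model():
    spec = tm.get_preset("overlap2")
    data, truth = tm.sample_generative(spec)
    prior = tm.generate_prior(data, k_est=2)
    model = tm.fit(data, prior, tm.FitOptions(seed=1, n_restarts=2))
    return data, truth, prior, model


@pytest.fixture(scope="session")
def ranint1_model():
    spec = tm.get_preset("ranint1")
    data, truth = tm.sample_generative(spec)
    prior = tm.generate_prior(data, k_est=2, K=5, re_predictors=["intercept"])
    model = tm.fit(data, prior, tm.FitOptions(seed=1))
    return data, truth, prior, model


def make_tiny_continuous(n_subjects=8, obs=5, seed=7, lam=4.0):
    """Small single-group linear dataset used by the closed-form oracles."""
    rng = np.random.default_rng(seed)
    n = n_subjects * obs
    X = np.column_stack([np.ones(n), rng.uniform(0, 10, n)])
    y = X @ np.array([1.0, -0.5]) + rng.normal(0, 1 / np.sqrt(lam), n)
    ids = np.repeat([f"S{i}" for i in range(n_subjects)], obs).astype(object)
    return tm.LongitudinalDataset(
        subject_ids=ids, X=X, Y=y[:, None], B=np.empty((n, 0)),
        predictor_names=["intercept", "t"], continuous_names=["y"],
        binary_names=[])


def flat_gaussian_prior(K=1, lam_fixed=None, p0=(0.5, 2.0), w0=(0.0, 0.0),
                        alpha=1.0):
    return tm.PriorSpec(
        predictor_names=["intercept", "t"], continuous_names=["y"],
        binary_names=[],
        w0_c=np.array([w0]), p0_c=np.array([p0]),
        a0=[2.0], b0=[2.0],
        w0_b=np.zeros((0, 2)), p0_b=np.ones((0, 2)),
        alpha=alpha, K=K,
        lambda_fixed=None if lam_fixed is None else [lam_fixed])
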