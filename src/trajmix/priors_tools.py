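"""Data-informed prior construction and prior predictive checks.

The prior-specification workflow: calibrate the DP concentration from a
rough estimate of how many trajectory groups the cohort holds, seed
coefficient priors from a pooled (population-level) regression with a
widening inflation factor, and draw mean curves from the prior for
visual sanity checks before fitting.
"""

from __future__ import annotations

import datetime
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy.optimize import brentq

from .data_io import LongitudinalDataset
from .model import PriorSpec, expected_num_clusters

__all__ = ["alpha_from_traj_estimate", "generate_prior", "sample_prior_draws",
           "save_prior_yaml", "load_prior_yaml"]

# weakly-informative fallback scale for logistic coefficients when the
# pooled logit fit fails (e.g. complete separation)
_LOGISTIC_FALLBACK_SD = 2.5


def alpha_from_traj_estimate(k_est: float, n: int) -> float:
    """Invert E[#clusters] to find the DP concentration alpha.

    Solves expected_num_clusters(alpha, n) = k_est by bracketed
    root-finding; the forward map is strictly increasing in alpha with
    range (1, n), so k_est must lie strictly inside that interval.
    """
    n = int(n)
    if not (1.0 < k_est < n):
        raise ValueError(f"k_est must lie strictly between 1 and n={n}, got {k_est}")
    lo, hi = 1e-10, 1.0
    while expected_num_clusters(hi, n) < k_est:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError("failed to bracket alpha")
    alpha = brentq(lambda a: expected_num_clusters(a, n) - k_est, lo, hi,
                   xtol=1e-14, rtol=8.9e-16, maxiter=200)
    return float(alpha)


def _pooled_ols(X: np.ndarray, y: np.ndarray, names: Sequence[str]):
    """Least squares with coefficient standard errors; flags collinearity."""
    n, M = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < M:
        # identify offending columns via the R factor of a pivoted-free QR
        _, Rf = np.linalg.qr(X)
        diag = np.abs(np.diag(Rf))
        bad = [names[j] for j in np.where(diag < 1e-8 * max(diag.max(), 1.0))[0]]
        raise ValueError(f"pooled design is rank-deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(n - M, 1)
    s2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(s2 * np.diag(XtX_inv), 1e-300))
    return beta, se, s2, resid


def _between_subject_variance(resid: np.ndarray, subj_rows: np.ndarray,
                              n_subjects: int) -> float:
    """Variance of per-subject mean residuals around the pooled fit."""
    counts = np.bincount(subj_rows, minlength=n_subjects).astype(float)
    means = np.bincount(subj_rows, weights=resid, minlength=n_subjects)
    keep = counts > 0
    means = means[keep] / counts[keep]
    if means.size < 2:
        return 0.0
    return float(np.var(means, ddof=1))


def _within_subject_variance(resid: np.ndarray, subj_rows: np.ndarray,
                             n_subjects: int, M: int, s2_pooled: float) -> float:
    """Residual-variance scale for the precision prior.

    Centers pooled-fit residuals within each subject before computing the
    variance, so between-group (and random-intercept) spread does not leak
    into the noise prior.  Falls back to the pooled estimate when subjects
    are too short to support the centering (e.g., one observation each).
    """
    dof = resid.size - n_subjects - M
    if dof < 1:
        return s2_pooled
    counts = np.bincount(subj_rows, minlength=n_subjects).astype(float)
    means = np.bincount(subj_rows, weights=resid, minlength=n_subjects)
    means = np.divide(means, counts, out=np.zeros_like(means), where=counts > 0)
    centered = resid - means[subj_rows]
    return float(centered @ centered) / dof


def generate_prior(data: LongitudinalDataset, k_est: float = 3.0,
                   inflation: float = 10.0, K: int = 30,
                   re_predictors: Optional[Sequence[str]] = None,
                   a0: float = 2.0) -> PriorSpec:
    """Construct a data-informed PriorSpec from pooled population fits.

    Per continuous target: a pooled OLS of the target on the predictors
    gives the coefficient prior means; prior standard deviations are
    ``inflation`` times the pooled-fit standard errors; the residual
    precision gets a Gamma(a0, b0) prior whose mean is the reciprocal of a
    subject-centered residual-variance estimate (pooled when subjects are
    too short to center).  Binary targets use a pooled logistic fit
    (zero-mean weakly-informative default if it fails).  The DP
    concentration is calibrated so the prior expected number of occupied
    clusters equals ``k_est``.
    """
    if data.n_subjects < 2:
        raise ValueError("need at least 2 subjects to build a prior")
    if inflation <= 0:
        raise ValueError("inflation must be positive")
    M = len(data.predictor_names)
    Dc, Db = len(data.continuous_names), len(data.binary_names)

    w0_c = np.zeros((Dc, M))
    p0_c = np.ones((Dc, M))
    a0_arr = np.full(Dc, float(a0))
    b0_arr = np.ones(Dc)
    resid_var = np.ones(Dc)
    between_var = np.ones(Dc)
    for d in range(Dc):
        m = data.mask_c[:, d]
        beta, se, s2, resid = _pooled_ols(data.X[m], data.Y[m, d],
                                          data.predictor_names)
        w0_c[d] = beta
        p0_c[d] = 1.0 / (inflation * se) ** 2
        # noise scale from subject-centered residuals: the pooled residual
        # variance mixes between-group spread into the noise prior
        sub = data.subject_rows[m]
        s2w = max(_within_subject_variance(resid, sub, data.n_subjects,
                                           M, s2), 1e-12)
        resid_var[d] = s2w
        b0_arr[d] = a0 * s2w     # prior mean precision a0/b0 = 1/s2w
        between_var[d] = max(_between_subject_variance(resid, sub,
                                                       data.n_subjects), s2w)

    w0_b = np.zeros((Db, M))
    p0_b = np.full((Db, M), 1.0 / _LOGISTIC_FALLBACK_SD ** 2)
    for d in range(Db):
        m = data.mask_b[:, d]
        try:
            import statsmodels.api as sm
            res = sm.Logit(data.B[m, d], data.X[m]).fit(disp=0, maxiter=100)
            if not np.all(np.isfinite(res.params)) or not np.all(np.isfinite(res.bse)):
                raise ValueError("non-finite pooled logistic fit")
            w0_b[d] = res.params
            p0_b[d] = 1.0 / (inflation * res.bse) ** 2
        except Exception:
            # separation or non-convergence: keep the zero-mean default
            pass

    re_idx = None
    S0 = None
    nu0 = None
    if re_predictors and Dc:
        re_idx = [data.predictor_names.index(p) for p in re_predictors]
        q = len(re_idx)
        # scale the random-effect covariance prior by the between-subject
        # spread of pooled residuals: that spread is what the effects model
        S0 = np.stack([between_var[d] * np.eye(q) for d in range(Dc)])
        nu0 = np.full(Dc, q + 2.0)

    alpha = alpha_from_traj_estimate(min(k_est, data.n_subjects - 1e-6), data.n_subjects)
    return PriorSpec(
        predictor_names=list(data.predictor_names),
        continuous_names=list(data.continuous_names),
        binary_names=list(data.binary_names),
        w0_c=w0_c, p0_c=p0_c, a0=a0_arr, b0=b0_arr,
        w0_b=w0_b, p0_b=p0_b, alpha=alpha, K=int(K),
        re_idx=re_idx, S0=S0, nu0=nu0,
    )


def sample_prior_draws(prior: PriorSpec, target: str, X_grid: np.ndarray,
                       num_draws: int = 100, seed: int = 0,
                       include_noise: bool = False) -> np.ndarray:
    """Draw mean curves from the coefficient prior on a design grid.

    Returns an array of shape (num_draws, len(grid)).  Continuous targets
    return x'w (optionally plus Gaussian noise with precision drawn from
    its Gamma prior); binary targets return sigmoid(x'w).
    """
    rng = np.random.default_rng(seed)
    X_grid = np.atleast_2d(np.asarray(X_grid, dtype=float))
    if target in prior.continuous_names:
        d = prior.continuous_names.index(target)
        w0, p0 = prior.w0_c[d], prior.p0_c[d]
        binary = False
    elif target in prior.binary_names:
        d = prior.binary_names.index(target)
        w0, p0 = prior.w0_b[d], prior.p0_b[d]
        binary = True
    else:
        raise ValueError(f"unknown target '{target}'")
    W = w0[None, :] + rng.standard_normal((num_draws, w0.size)) / np.sqrt(p0)[None, :]
    curves = W @ X_grid.T
    if binary:
        return 1.0 / (1.0 + np.exp(-curves))
    if include_noise:
        lam = rng.gamma(prior.a0[d], 1.0 / prior.b0[d], size=num_draws)
        curves = curves + rng.standard_normal(curves.shape) / np.sqrt(lam)[:, None]
    return curves


def save_prior_yaml(prior: PriorSpec, path, provenance: Optional[dict] = None) -> None:
    """Write a PriorSpec to a human-readable YAML file with provenance comments."""
    doc = {
        "predictor_names": prior.predictor_names,
        "continuous_names": prior.continuous_names,
        "binary_names": prior.binary_names,
        "w0_c": prior.w0_c.tolist(), "p0_c": prior.p0_c.tolist(),
        "a0": prior.a0.tolist(), "b0": prior.b0.tolist(),
        "w0_b": prior.w0_b.tolist(), "p0_b": prior.p0_b.tolist(),
        "alpha": float(prior.alpha), "K": int(prior.K),
        "re_idx": prior.re_idx,
        "S0": None if prior.S0 is None else prior.S0.tolist(),
        "nu0": None if prior.nu0 is None else prior.nu0.tolist(),
        "lambda_fixed": (None if prior.lambda_fixed is None
                         else prior.lambda_fixed.tolist()),
    }
    header = [f"# trajmix prior file, written {datetime.date.today().isoformat()}"]
    for key, val in (provenance or {}).items():
        header.append(f"# {key}: {val}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(header) + "\n")
        yaml.safe_dump(doc, fh, default_flow_style=None, sort_keys=False)


def load_prior_yaml(path) -> PriorSpec:
    """Read a prior file written by :func:`save_prior_yaml`."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "predictor_names" not in doc:
        raise ValueError(f"{path} is not a trajmix prior file")
    opt = lambda x: None if x is None else np.asarray(x, dtype=float)
    M = len(doc["predictor_names"])
    mat = lambda x: np.asarray(x, dtype=float).reshape(-1, M)
    return PriorSpec(
        predictor_names=doc["predictor_names"],
        continuous_names=doc["continuous_names"],
        binary_names=doc["binary_names"],
        w0_c=mat(doc["w0_c"]), p0_c=mat(doc["p0_c"]),
        a0=np.asarray(doc["a0"], dtype=float),
        b0=np.asarray(doc["b0"], dtype=float),
        w0_b=mat(doc["w0_b"]), p0_b=mat(doc["p0_b"]),
        alpha=float(doc["alpha"]), K=int(doc["K"]),
        re_idx=doc.get("re_idx"), S0=opt(doc.get("S0")), nu0=opt(doc.get("nu0")),
        lambda_fixed=opt(doc.get("lambda_fixed")),
    )
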