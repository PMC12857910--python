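"""Post-fit tools: out-of-sample assignment, summaries, visualization.

Out-of-sample likelihoods use plug-in posterior-mean parameters (the
coefficient posterior means and the posterior-mean residual precision
a/b); for targets with random effects the subject-level effects are
marginalized analytically, y_i | k ~ N(X mu_w, sigma^2 I + Z Sigma_re Z').
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp

from .data_io import LongitudinalDataset
from .inference import ConfigError, expected_log_pi
from .model import TrajModel

_LOG2PI = float(np.log(2.0 * np.pi))

__all__ = ["assign_trajectory", "summarize_model", "format_summary",
           "plot_model_trajs", "plot_prior_draws", "plot_gamma_dists"]


def _check_columns(model: TrajModel, data: LongitudinalDataset) -> None:
    pr = model.prior
    for kind, got, want in (("predictor", data.predictor_names, pr.predictor_names),
                            ("continuous target", data.continuous_names, pr.continuous_names),
                            ("binary target", data.binary_names, pr.binary_names)):
        if got != want:
            raise ConfigError(f"{kind} columns {got} do not match model columns {want}")


def _plugin_sigma2(model: TrajModel, k: int, d: int) -> float:
    """Plug-in residual variance b/a (reciprocal posterior-mean precision)."""
    lf = model.prior.lambda_fixed
    if lf is not None and np.isfinite(lf[d]):
        return float(1.0 / lf[d])
    return float(model.posterior.b[k, d] / model.posterior.a[k, d])


def _subject_loglik(model: TrajModel, data: LongitudinalDataset) -> np.ndarray:
    """(n_subjects, K) plug-in log-likelihood of each subject's observations."""
    st, pr = model.posterior, model.prior
    K = model.K
    n = data.n_subjects
    out = np.zeros((n, K))
    has_re = pr.re_idx is not None
    Z = data.X[:, pr.re_idx] if has_re else None

    for d, _name in enumerate(pr.continuous_names):
        m = data.mask_c[:, d]
        for k in range(K):
            s2 = _plugin_sigma2(model, k, d)
            resid = data.Y[:, d] - data.X @ st.mu_w[k, d]
            if not has_re:
                rows = -0.5 * (_LOG2PI + np.log(s2)) - 0.5 * resid ** 2 / s2
                out[:, k] += np.bincount(data.subject_rows[m], weights=rows[m],
                                         minlength=n)
            else:
                Sre = st.Sigma_re[k, d]
                for i in range(n):
                    rows_i = data.subject_index[data.subjects[i]]
                    rows_i = rows_i[m[rows_i]]
                    if rows_i.size == 0:
                        continue
                    r = resid[rows_i]
                    Zi = Z[rows_i]
                    C = s2 * np.eye(rows_i.size) + Zi @ Sre @ Zi.T
                    sign, logdet = np.linalg.slogdet(C)
                    out[i, k] += -0.5 * (rows_i.size * _LOG2PI + logdet
                                         + r @ np.linalg.solve(C, r))

    for d, _name in enumerate(pr.binary_names):
        m = data.mask_b[:, d]
        for k in range(K):
            p = np.clip(expit(data.X @ st.mu_wb[k, d]), 1e-12, 1 - 1e-12)
            rows = np.where(np.nan_to_num(data.B[:, d]) > 0.5, np.log(p), np.log1p(-p))
            out[:, k] += np.bincount(data.subject_rows[m], weights=rows[m],
                                     minlength=n)
    return out


def assign_trajectory(model: TrajModel, data: LongitudinalDataset) -> pd.DataFrame:
    """Assign subjects to trajectory components with posterior probabilities.

    Returns one row per subject: ``subject_id``, ``prob_k`` for each of
    the K components (rows sum to 1), the 1-based ``map_label`` (ties go
    to the lowest index), and a ``warning`` flag set for subjects with no
    usable observations, whose probabilities fall back to E[pi].
    """
    _check_columns(model, data)
    K = model.K
    loglik = _subject_loglik(model, data)
    elogpi = expected_log_pi(model.posterior.gamma1, model.posterior.gamma2)
    logp = loglik + elogpi[None, :]
    probs = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))

    n_usable = np.zeros(data.n_subjects, dtype=int)
    for d in range(len(data.continuous_names)):
        n_usable += np.bincount(data.subject_rows[data.mask_c[:, d]],
                                minlength=data.n_subjects)
    for d in range(len(data.binary_names)):
        n_usable += np.bincount(data.subject_rows[data.mask_b[:, d]],
                                minlength=data.n_subjects)
    warning = n_usable == 0
    if warning.any():
        probs[warning] = model.expected_weights()[None, :]

    out = pd.DataFrame({"subject_id": data.subjects})
    for k in range(K):
        out[f"prob_{k + 1}"] = probs[:, k]
    out["map_label"] = probs.argmax(axis=1) + 1
    out["warning"] = warning.astype(int)
    return out


def summarize_model(model: TrajModel, data: Optional[LongitudinalDataset] = None,
                    mass_threshold: float = 0.01) -> dict:
    """Quantitative model summary as a nested dict.

    Reports, per component holding more than ``mass_threshold`` of the
    responsibility mass: subject count and percentage, coefficient
    posterior means with central 95% credible intervals, and the
    posterior-mean residual standard deviation sqrt(b/(a-1)) per
    continuous target.
    """
    st, pr = model.posterior, model.prior
    n = st.R.shape[0]
    mass = model.component_mass()
    counts = np.bincount(st.R.argmax(axis=1), minlength=model.K)
    zq = 1.959963984540054  # standard normal 97.5% quantile

    components = []
    for k in range(model.K):
        if mass[k] <= mass_threshold:
            continue
        comp = {"component": k + 1,
                "n_subjects": int(counts[k]),
                "percentage": float(100.0 * mass[k]),
                "targets": {}}
        for d, name in enumerate(pr.continuous_names):
            mu, Sig = st.mu_w[k, d], st.Sigma_w[k, d]
            sd = np.sqrt(np.diag(Sig))
            a, b = st.a[k, d], st.b[k, d]
            lf = pr.lambda_fixed
            if lf is not None and np.isfinite(lf[d]):
                resid_sd = float(1.0 / np.sqrt(lf[d]))
            else:
                resid_sd = float(np.sqrt(b / (a - 1.0))) if a > 1 else float(np.sqrt(b / a))
            comp["targets"][name] = {
                "coefficients": {
                    pname: {"mean": float(mu[j]),
                            "ci_low": float(mu[j] - zq * sd[j]),
                            "ci_high": float(mu[j] + zq * sd[j])}
                    for j, pname in enumerate(pr.predictor_names)},
                "resid_sd": resid_sd,
            }
        for d, name in enumerate(pr.binary_names):
            mu, Sig = st.mu_wb[k, d], st.Sigma_wb[k, d]
            sd = np.sqrt(np.diag(Sig))
            comp["targets"][name] = {
                "coefficients": {
                    pname: {"mean": float(mu[j]),
                            "ci_low": float(mu[j] - zq * sd[j]),
                            "ci_high": float(mu[j] + zq * sd[j])}
                    for j, pname in enumerate(pr.predictor_names)},
            }
        components.append(comp)

    return {
        "n_subjects": int(n),
        "K": int(model.K),
        "n_occupied": int(np.sum(mass > mass_threshold)),
        "mass": mass.tolist(),
        "final_elbo": model.metadata.get("final_elbo"),
        "n_iter": model.metadata.get("n_iter"),
        "converged": model.metadata.get("converged"),
        "components": components,
    }


def format_summary(summary: dict) -> str:
    """Plain-text rendering of :func:`summarize_model` output."""
    lines = [
        f"Trajectory model summary ({summary['n_subjects']} subjects, "
        f"truncation K={summary['K']})",
        f"Occupied components (>1% mass): {summary['n_occupied']}",
        f"Final ELBO: {summary['final_elbo']}",
        f"Sweeps: {summary['n_iter']} (converged: {summary['converged']})",
        "",
    ]
    for comp in summary["components"]:
        lines.append(f"Component {comp['component']}: {comp['n_subjects']} subjects "
                     f"({comp['percentage']:.1f}%)")
        for tname, tinfo in comp["targets"].items():
            lines.append(f"  target {tname}:")
            for pname, ci in tinfo["coefficients"].items():
                lines.append(f"    {pname:>12s}: {ci['mean']: .4f}  "
                             f"[{ci['ci_low']: .4f}, {ci['ci_high']: .4f}]")
            if "resid_sd" in tinfo:
                lines.append(f"    residual sd: {tinfo['resid_sd']:.4f}")
        lines.append("")
    return "\n".join(lines)


def _get_pyplot():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_model_trajs(model: TrajModel, data: LongitudinalDataset, target: str,
                     out_path, x_axis: Optional[str] = None,
                     mass_threshold: float = 0.01) -> None:
    """Observed series colored by MAP label with component mean curves.

    Mean curves carry a shaded band of +/- 2 posterior-mean residual sd.
    ``x_axis`` names the predictor used on the horizontal axis (default:
    the second predictor column, i.e. the time variable when the design
    is [intercept, t, ...]).
    """
    plt = _get_pyplot()
    _check_columns(model, data)
    if target not in data.continuous_names and target not in data.binary_names:
        raise ValueError(f"unknown target '{target}'")
    xj = (data.predictor_names.index(x_axis) if x_axis
          else min(1, len(data.predictor_names) - 1))
    x = data.X[:, xj]
    assign = assign_trajectory(model, data)
    label_by_subj = dict(zip(assign["subject_id"], assign["map_label"]))
    mass = model.component_mass()
    occupied = [k for k in range(model.K) if mass[k] > mass_threshold]
    cmap = plt.get_cmap("tab10")

    fig, ax = plt.subplots(figsize=(7, 5))
    is_binary = target in data.binary_names
    if is_binary:
        d = data.binary_names.index(target)
        yobs, msk = data.B[:, d], data.mask_b[:, d]
    else:
        d = data.continuous_names.index(target)
        yobs, msk = data.Y[:, d], data.mask_c[:, d]
    for sid in data.subjects:
        rows = data.subject_index[sid]
        rows = rows[msk[rows]]
        if rows.size == 0:
            continue
        color = cmap((int(label_by_subj[sid]) - 1) % 10)
        ax.plot(x[rows], yobs[rows], "-o", color=color, alpha=0.25,
                markersize=2, linewidth=0.6)
    order = np.argsort(x)
    for pos, k in enumerate(occupied):
        if is_binary:
            curve = expit(data.X @ model.posterior.mu_wb[k, d])
            ax.plot(x[order], curve[order], color=cmap(k % 10), linewidth=2.5,
                    label=f"traj {k + 1}")
        else:
            curve = data.X @ model.posterior.mu_w[k, d]
            sd = np.sqrt(_plugin_sigma2(model, k, d))
            ax.plot(x[order], curve[order], color=cmap(k % 10), linewidth=2.5,
                    label=f"traj {k + 1}")
            ax.fill_between(x[order], curve[order] - 2 * sd, curve[order] + 2 * sd,
                            color=cmap(k % 10), alpha=0.15)
    ax.set_xlabel(x_axis or data.predictor_names[xj])
    ax.set_ylabel(target)
    ax.legend(loc="best")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def plot_prior_draws(prior, data: LongitudinalDataset, target: str, out_path,
                     num_draws: int = 50, seed: int = 0,
                     x_axis: Optional[str] = None) -> None:
    """Prior predictive mean curves over the observed data scatter."""
    from .priors_tools import sample_prior_draws

    plt = _get_pyplot()
    xj = (data.predictor_names.index(x_axis) if x_axis
          else min(1, len(data.predictor_names) - 1))
    x = data.X[:, xj]
    order = np.argsort(x)
    draws = sample_prior_draws(prior, target, data.X[order], num_draws=num_draws,
                               seed=seed)
    fig, ax = plt.subplots(figsize=(7, 5))
    if target in data.continuous_names:
        d = data.continuous_names.index(target)
        m = data.mask_c[:, d]
        ax.plot(x[m], data.Y[m, d], ".", color="0.6", markersize=2, alpha=0.5)
    elif target in data.binary_names:
        d = data.binary_names.index(target)
        m = data.mask_b[:, d]
        ax.plot(x[m], data.B[m, d], ".", color="0.6", markersize=2, alpha=0.5)
    for r in range(draws.shape[0]):
        ax.plot(x[order], draws[r], color="C0", alpha=0.2, linewidth=0.8)
    ax.set_xlabel(x_axis or data.predictor_names[xj])
    ax.set_ylabel(target)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def plot_gamma_dists(prior, out_path, model: Optional[TrajModel] = None,
                     mass_threshold: float = 0.01) -> None:
    """Prior (and optionally posterior) residual-precision Gamma densities."""
    from scipy.stats import gamma as gamma_dist

    plt = _get_pyplot()
    Dc = len(prior.continuous_names)
    if Dc == 0:
        raise ValueError("no continuous targets: no precision Gammas to plot")
    fig, axes = plt.subplots(1, Dc, figsize=(5 * Dc, 4), squeeze=False)
    for d, name in enumerate(prior.continuous_names):
        ax = axes[0, d]
        a0, b0 = prior.a0[d], prior.b0[d]
        hi = gamma_dist.ppf(0.995, a0, scale=1.0 / b0)
        if model is not None:
            mass = model.component_mass()
            for k in range(model.K):
                if mass[k] > mass_threshold:
                    a, b = model.posterior.a[k, d], model.posterior.b[k, d]
                    hi = max(hi, gamma_dist.ppf(0.995, a, scale=1.0 / b))
        grid = np.linspace(1e-9, hi, 400)
        ax.plot(grid, gamma_dist.pdf(grid, a0, scale=1.0 / b0), "k--",
                label=f"prior ({a0:.3g}, {b0:.3g})")
        if model is not None:
            mass = model.component_mass()
            for k in range(model.K):
                if mass[k] > mass_threshold:
                    a, b = model.posterior.a[k, d], model.posterior.b[k, d]
                    ax.plot(grid, gamma_dist.pdf(grid, a, scale=1.0 / b),
                            label=f"traj {k + 1}")
        ax.set_title(f"residual precision: {name}")
        ax.set_xlabel("precision")
        ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
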