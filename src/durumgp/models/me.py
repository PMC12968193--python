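"""Single-trait, multi-environment reaction-norm sampler.

Model per cell (line j, environment i):

    y_ij = alpha_i + L_j + g_j + Eg_ij + e_ij

with alpha the per-environment fixed means, L an i.i.d. line effect
(capturing non-genomic line variance), g ~ N(0, G sigma_g2) the genomic main
effect shared across environments, and the interaction
Eg ~ N(0, (Zg G Zg') o (ZE ZE') sigma_Eg2): the Hadamard structure makes Eg
independent across environments with within-environment covariance
G sigma_Eg2, which is how it is sampled.
"""

from __future__ import annotations

import warnings

import numpy as np

from ..containers import BlueSet, Kernel
from .common import (MCMCSettings, ModelSpec, PosteriorSummary,
                     check_chain_health, effective_sample_size, extract_panel,
                     kernel_eig, sample_scaled_inv_chi2, scalar_prior)

__all__ = ["fit_me"]


def fit_me(blues: BlueSet, kernel: Kernel, spec: ModelSpec, trait: str,
           envs: list[str] | None = None) -> PosteriorSummary:
    """Fit the ME model for one trait over ``envs`` (default: all)."""
    envs = list(envs) if envs is not None else list(blues.env_ids)
    y3, obs3, k = extract_panel(blues, kernel, envs, [trait])
    Y, observed = y3[:, :, 0].copy(), obs3[:, :, 0]   # lines x envs

    thin_envs = [e for i, e in enumerate(envs) if observed[:, i].sum() < 2]
    if thin_envs:
        warnings.warn(f"dropping environments with < 2 observed lines: {thin_envs}")
        keep_i = [i for i, e in enumerate(envs) if e not in thin_envs]
        envs = [envs[i] for i in keep_i]
        Y, observed = Y[:, keep_i], observed[:, keep_i]
    n, m = Y.shape

    mc: MCMCSettings = spec.mcmc
    rng = np.random.default_rng(mc.seed)
    d, v = kernel_eig(k)

    var_y = float(np.nanvar(np.where(observed, Y, np.nan), ddof=1))
    var_y = max(var_y, 1e-8)
    nu, _ = scalar_prior(spec.df_scalar, var_y)
    _, ss_g0 = scalar_prior(spec.df_scalar, 0.5 * var_y)
    _, ss_e0 = scalar_prior(spec.df_scalar, 0.5 * var_y)
    # the scaled-inverse-chi-square prior bounds a posterior away from zero
    # at roughly its own scale, so the secondary components (interaction,
    # non-genomic line) get a light prior: a truly null interaction must be
    # able to collapse below the detection threshold
    _, ss_l0 = scalar_prior(spec.df_scalar, 0.1 * var_y)
    _, ss_eg0 = scalar_prior(spec.df_scalar, 0.1 * var_y)

    fix = spec.fix_variances
    sg2 = fix.get("sigma_g2", 0.25 * var_y)
    seg2 = fix.get("sigma_Eg2", 0.25 * var_y)
    sl2 = fix.get("sigma_L2", 0.25 * var_y)
    se2 = fix.get("sigma_e2", 0.25 * var_y)

    alpha = np.array([np.nanmean(np.where(observed[:, i], Y[:, i], np.nan))
                      for i in range(m)])
    L = np.zeros(n)
    g = np.zeros(n)
    Eg = np.zeros((n, m))
    Y[~observed] = np.broadcast_to(alpha[None, :], Y.shape)[~observed]
    use_L = spec.include_line_effect

    keep = 0
    mean_alpha = np.zeros(m)
    mean_L, mean_g = np.zeros(n), np.zeros(n)
    mean_Eg = np.zeros((n, m))
    mean_fit = np.zeros((n, m))
    acc_var = {kk: 0.0 for kk in ("sigma_g2", "sigma_Eg2", "sigma_L2", "sigma_e2")}
    draws: dict[str, list] = {kk: [] for kk in acc_var}

    for it in range(mc.n_iter):
        # alpha | rest: per-environment normal mean (flat prior)
        resid = Y - L[:, None] - g[:, None] - Eg
        alpha = resid.mean(axis=0) + np.sqrt(se2 / n) * rng.standard_normal(m)

        # L | rest: i.i.d. line effect from m replicate cells per line
        if use_L:
            resid = Y - alpha[None, :] - g[:, None] - Eg
            prec = m / se2 + 1.0 / sl2
            L = (resid.sum(axis=1) / se2) / prec \
                + np.sqrt(1.0 / prec) * rng.standard_normal(n)

        # g | rest in the eigenbasis of G, pooling residuals over environments
        resid = Y - alpha[None, :] - L[:, None] - Eg
        rtil = v.T @ resid.sum(axis=1)
        prec = m / se2 + 1.0 / (d * sg2)
        gtil = (rtil / se2) / prec + np.sqrt(1.0 / prec) * rng.standard_normal(n)
        g = v @ gtil

        # Eg | rest: per environment, covariance G sigma_Eg2
        resid = Y - alpha[None, :] - L[:, None] - g[:, None]
        Rtil = v.T @ resid
        c = d[:, None] * seg2 / (d[:, None] * seg2 + se2)
        Egtil = c * Rtil + np.sqrt(c * se2) * rng.standard_normal((n, m))
        Eg = v @ Egtil

        # scalar variances
        if "sigma_g2" not in fix:
            sg2 = sample_scaled_inv_chi2(rng, nu + n,
                                         float(np.sum(gtil**2 / d)) + ss_g0)
        if "sigma_Eg2" not in fix:
            ss = float(np.sum(Egtil**2 / d[:, None]))
            seg2 = sample_scaled_inv_chi2(rng, nu + n * m, ss + ss_eg0)
        if use_L and "sigma_L2" not in fix:
            sl2 = sample_scaled_inv_chi2(rng, nu + n, float(L @ L) + ss_l0)
        fitted = alpha[None, :] + L[:, None] + g[:, None] + Eg
        if "sigma_e2" not in fix:
            E = Y - fitted
            se2 = sample_scaled_inv_chi2(rng, nu + n * m,
                                         float(np.sum(E**2)) + ss_e0)

        # augmentation
        miss = ~observed
        if miss.any():
            Y[miss] = fitted[miss] + np.sqrt(se2) * rng.standard_normal(miss.sum())

        if it >= mc.burn_in and (it - mc.burn_in) % mc.thin == 0:
            keep += 1
            mean_alpha += alpha
            mean_L += L
            mean_g += g
            mean_Eg += Eg
            mean_fit += fitted
            for kk, val in (("sigma_g2", sg2), ("sigma_Eg2", seg2),
                            ("sigma_L2", sl2), ("sigma_e2", se2)):
                acc_var[kk] += val
                if spec.store_draws:
                    draws[kk].append(val)

    stored = {k_: np.asarray(v_) for k_, v_ in draws.items()} if spec.store_draws else {}
    ess = {k_: effective_sample_size(v_) for k_, v_ in stored.items()}
    check_chain_health(ess)

    return PosteriorSummary(
        family="ME", line_ids=k.line_ids, env_ids=envs, trait_names=[trait],
        effects={"alpha": mean_alpha / keep, "L": mean_L / keep,
                 "g": mean_g / keep, "Eg": mean_Eg / keep},
        variances={kk: val / keep for kk, val in acc_var.items()},
        fitted=(mean_fit / keep)[:, :, None], observed=observed[:, :, None],
        ess=ess, draws=stored, spec=spec)
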