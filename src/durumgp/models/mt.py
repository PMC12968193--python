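"""Multi-trait, single-environment sampler.

Model: Y = 1 mu' + U + E with U ~ MN(0, G, Sigma_t) and residual rows i.i.d.
N(0, R), both covariances unstructured with inverse-Wishart full
conditionals.  Missing trait cells are augmented from their conditional
normal given the observed traits of the same line — the mechanism by which
CV2 borrows secondary-trait information.
"""

from __future__ import annotations

import warnings

import numpy as np

from ..containers import BlueSet, Kernel
from .common import (MCMCSettings, ModelSpec, PosteriorSummary,
                     check_chain_health, conditional_normal_draw,
                     effective_sample_size, extract_panel, kernel_eig,
                     sample_inv_wishart, sample_mvn_batch, wishart_prior)

__all__ = ["fit_mt"]


def fit_mt(blues: BlueSet, kernel: Kernel, spec: ModelSpec, env: str,
           traits: list[str] | None = None) -> PosteriorSummary:
    """Fit the MT model for one environment over ``traits`` (default: all)."""
    traits = list(traits) if traits is not None else list(blues.trait_names)
    y3, obs3, k = extract_panel(blues, kernel, [env], traits)
    Y, observed = y3[:, 0, :].copy(), obs3[:, 0, :]

    # a trait with no observed cell cannot be fitted
    dead = [t for j, t in enumerate(traits) if observed[:, j].sum() == 0]
    if dead:
        warnings.warn(f"dropping traits with no observed cells: {dead}")
        keep_j = [j for j, t in enumerate(traits) if t not in dead]
        traits = [traits[j] for j in keep_j]
        Y, observed = Y[:, keep_j], observed[:, keep_j]
    n, t = Y.shape
    if (observed.any(axis=1)).sum() < 10:
        raise ValueError("need >= 10 lines with at least one trait observed")

    mc: MCMCSettings = spec.mcmc
    rng = np.random.default_rng(mc.seed)
    d, v = kernel_eig(k)

    col_var = np.array([np.nanvar(np.where(observed[:, j], Y[:, j], np.nan), ddof=1)
                        if observed[:, j].sum() > 1 else 1.0 for j in range(t)])
    col_var = np.maximum(col_var, 1e-8)
    nu_t, S_t0 = wishart_prior(t, col_var)
    nu_r, S_r0 = wishart_prior(t, col_var)

    mu = np.array([np.nanmean(np.where(observed[:, j], Y[:, j], np.nan))
                   if observed[:, j].any() else 0.0 for j in range(t)])
    Sigma_t = spec.fix_variances.get("Sigma_t", 0.5 * np.diag(col_var))
    R = spec.fix_variances.get("R", 0.5 * np.diag(col_var))
    Sigma_t, R = np.atleast_2d(np.asarray(Sigma_t, float)), np.atleast_2d(np.asarray(R, float))
    U = np.zeros((n, t))
    for j in range(t):
        Y[~observed[:, j], j] = mu[j]

    # group rows by missing pattern once (patterns don't change during the run)
    rows_by_pattern: dict[bytes, list[int]] = {}
    for i in range(n):
        if not observed[i].all():
            rows_by_pattern.setdefault(observed[i].tobytes(), []).append(i)

    keep = 0
    mean_mu = np.zeros(t)
    mean_U = np.zeros((n, t))
    mean_fit = np.zeros((n, t))
    mean_St = np.zeros((t, t))
    mean_R = np.zeros((t, t))
    draws: dict[str, list] = {"Sigma_t_diag": [], "R_diag": []}

    for it in range(mc.n_iter):
        St_inv = np.linalg.inv(Sigma_t)
        R_inv = np.linalg.inv(R)

        # U | rest: rows independent in the eigenbasis of G
        Ytil = v.T @ (Y - mu[None, :])
        prec = St_inv[None, :, :] / d[:, None, None] + R_inv[None, :, :]
        mean = np.einsum("bij,bj->bi", np.linalg.inv(prec), Ytil @ R_inv.T)
        Util = sample_mvn_batch(rng, mean, prec)
        U = v @ Util

        # mu | rest (flat prior): conjugate multivariate normal
        resid_mean = (Y - U).mean(axis=0)
        mu = rng.multivariate_normal(resid_mean, R / n)

        # Sigma_t | U  (inverse-Wishart; U' G^-1 U via the eigenbasis)
        if "Sigma_t" not in spec.fix_variances:
            S = (Util / d[:, None]).T @ Util
            Sigma_t = sample_inv_wishart(rng, nu_t + n, S_t0 + S)

        # R | residuals
        E = Y - mu[None, :] - U
        if "R" not in spec.fix_variances:
            R = sample_inv_wishart(rng, nu_r + n, S_r0 + E.T @ E)

        # augmentation of missing trait cells, grouped by pattern
        for pat, rows in rows_by_pattern.items():
            pattern = np.frombuffer(pat, dtype=bool)
            for i in rows:
                Y[i] = conditional_normal_draw(rng, mu + U[i], R, Y[i], pattern)

        if it >= mc.burn_in and (it - mc.burn_in) % mc.thin == 0:
            keep += 1
            mean_mu += mu
            mean_U += U
            mean_fit += mu[None, :] + U
            mean_St += Sigma_t
            mean_R += R
            if spec.store_draws:
                draws["Sigma_t_diag"].append(np.diag(Sigma_t).copy())
                draws["R_diag"].append(np.diag(R).copy())

    mean_mu /= keep
    mean_U /= keep
    mean_fit /= keep
    stored = {k_: np.asarray(v_) for k_, v_ in draws.items()} if spec.store_draws else {}
    ess = {}
    if spec.store_draws:
        for j, tr in enumerate(traits):
            ess[f"Sigma_t[{tr}]"] = effective_sample_size(stored["Sigma_t_diag"][:, j])
            ess[f"R[{tr}]"] = effective_sample_size(stored["R_diag"][:, j])
    check_chain_health(ess)

    return PosteriorSummary(
        family="MT", line_ids=k.line_ids, env_ids=[env], trait_names=traits,
        effects={"mu": mean_mu, "U": mean_U},
        variances={"Sigma_t": mean_St / keep, "R": mean_R / keep},
        fitted=mean_fit[:, None, :], observed=observed[:, None, :],
        ess=ess, draws=stored, spec=spec)
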