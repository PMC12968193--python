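"""Multi-trait, multi-environment sampler with Kronecker covariance.

Model over the full line x environment x trait grid:

    Y = X beta + Z1 b1 + Z2 b2 + E
    b1 ~ MN(0, G, Sigma_t)             (genomic main effects)
    b2 ~ MN(0, Sigma_E (x) G, Sigma_t) (genotype-by-environment effects)
    E rows i.i.d. N(0, R)              (unstructured residual across traits)

The fixed part is one mean per (environment, trait) cell, an equivalent
reparameterisation of intercept-plus-environment-contrasts that keeps the
conditional a plain normal.  All conditionals are evaluated in the
eigenbases of G (precomputed) and Sigma_E (re-decomposed each sweep, it is
only m x m), so b2 is sampled as a stack of independent t-dimensional
normals and the full Kronecker matrix is never formed.  Sigma_t is shared
between b1 and b2 by default, as the model is written; ``separate_trait_cov``
gives each its own.
"""

from __future__ import annotations

import numpy as np

from ..containers import BlueSet, Kernel
from .common import (MCMCSettings, ModelSpec, PosteriorSummary,
                     check_chain_health, conditional_normal_draw,
                     effective_sample_size, extract_panel, kernel_eig,
                     sample_inv_wishart, sample_mvn_batch, wishart_prior)

__all__ = ["fit_mtme", "draw_b2_prior", "genomic_heritability"]


def draw_b2_prior(kernel: Kernel, Sigma_E: np.ndarray, Sigma_t: np.ndarray,
                  n_draws: int, rng: np.random.Generator) -> np.ndarray:
    """Draws of vec(b2) under the matrix-normal prior MN(0, Sigma_E (x) G, Sigma_t).

    b2 is the (m*n) x t matrix with environment-major row order (row e*n + i
    is line i in environment e); the returned array has shape
    (n_draws, n*m*t) in column-major vec order, whose covariance is
    Sigma_t (x) Sigma_E (x) G.
    """
    def chol_psd(a):
        w, q = np.linalg.eigh(np.atleast_2d(np.asarray(a, float)))
        return q * np.sqrt(np.clip(w, 0.0, None))

    Lg, Le, Lt = chol_psd(kernel.matrix), chol_psd(Sigma_E), chol_psd(Sigma_t)
    n, m, t = Lg.shape[0], Le.shape[0], Lt.shape[0]
    z = rng.standard_normal((n_draws, m, n, t))
    mixed = np.einsum("ek,dknt->dent", Le, z)
    mixed = np.einsum("ni,deit->dent", Lg, mixed)
    b2 = np.einsum("tu,denu->dent", Lt, mixed)          # draws x env x line x trait
    b2 = b2.reshape(n_draws, m * n, t)
    # column-major vec of each (m*n) x t matrix: trait slowest, line fastest
    return np.transpose(b2, (0, 2, 1)).reshape(n_draws, m * n * t)


def genomic_heritability(fit: PosteriorSummary) -> np.ndarray:
    """Per-trait genomic heritability implied by an MTME fit.

    Average genetic cell variance over environments,
    Sigma_t[tt] * mean diag(G) * (1 + mean diag(Sigma_E)), against the
    residual trait variance R[tt].
    """
    St = np.atleast_2d(fit.variances["Sigma_t"])
    Se = np.atleast_2d(fit.variances["Sigma_E"])
    R = np.atleast_2d(fit.variances["R"])
    dbar = fit.variances.get("kernel_diag_mean", 1.0)
    gvar = np.diag(St) * dbar * (1.0 + float(np.mean(np.diag(Se))))
    return gvar / (gvar + np.diag(R))


def fit_mtme(blues: BlueSet, kernel: Kernel, spec: ModelSpec,
             envs: list[str] | None = None,
             traits: list[str] | None = None) -> PosteriorSummary:
    """Fit the MTME model over ``envs`` x ``traits`` (default: everything)."""
    envs = list(envs) if envs is not None else list(blues.env_ids)
    traits = list(traits) if traits is not None else list(blues.trait_names)
    Y, observed, k = extract_panel(blues, kernel, envs, traits)
    Y = Y.copy()
    n, m, t = Y.shape

    mc: MCMCSettings = spec.mcmc
    rng = np.random.default_rng(mc.seed)
    d, v = kernel_eig(k)

    col_var = np.array([
        max(float(np.nanvar(np.where(observed[:, :, j], Y[:, :, j], np.nan))), 1e-8)
        for j in range(t)])
    nu_t, S_t0 = wishart_prior(t, col_var)
    nu_r, S_r0 = wishart_prior(t, col_var)
    # Sigma_E is a relative scale across environments (Sigma_t carries the
    # trait units), so its prior centres on a modest exchangeable scale.
    nu_e, S_e0 = wishart_prior(m, np.ones(m))

    fix = spec.fix_variances
    Sigma_t = np.atleast_2d(np.asarray(fix.get("Sigma_t", 0.5 * np.diag(col_var)), float))
    Sigma_t2 = Sigma_t.copy()  # only used when separate_trait_cov
    Sigma_E = np.atleast_2d(np.asarray(fix.get("Sigma_E", 0.5 * np.eye(m)), float))
    R = np.atleast_2d(np.asarray(fix.get("R", 0.25 * np.diag(col_var)), float))

    beta = np.array([[np.nanmean(np.where(observed[:, e, j], Y[:, e, j], np.nan))
                      if observed[:, e, j].any() else 0.0
                      for j in range(t)] for e in range(m)])
    for e in range(m):
        for j in range(t):
            Y[~observed[:, e, j], e, j] = beta[e, j]
    # moment-based warm start: the scale of b2 is only weakly identified
    # against the residual, so a chain started at b2 = 0 can stall in a
    # collapsed-interaction mode.  Start from a rough main/interaction
    # decomposition of the centred data instead.
    resid0 = Y - beta[None, :, :]
    b1 = resid0.mean(axis=1)
    B2 = 0.5 * np.transpose(resid0 - b1[:, None, :], (1, 0, 2))
    if "Sigma_E" not in fix:
        Sigma_E = np.eye(m)

    # group incomplete cells by their trait-observation pattern once
    cells_by_pattern: dict[bytes, list[tuple[int, int]]] = {}
    for i in range(n):
        for e in range(m):
            pat = observed[i, e]
            if not pat.all():
                cells_by_pattern.setdefault(pat.tobytes(), []).append((i, e))

    keep = 0
    mean_beta = np.zeros((m, t))
    mean_b1 = np.zeros((n, t))
    mean_B2 = np.zeros((m, n, t))
    mean_fit = np.zeros((n, m, t))
    acc = {"Sigma_t": np.zeros((t, t)), "Sigma_E": np.zeros((m, m)),
           "R": np.zeros((t, t)), "Sigma_t2": np.zeros((t, t))}
    draws: dict[str, list] = {"Sigma_t_diag": [], "Sigma_E_diag": [], "R_diag": []}

    for it in range(mc.n_iter):
        St_inv = np.linalg.inv(Sigma_t)
        St2_inv = np.linalg.inv(Sigma_t2) if spec.separate_trait_cov else St_inv
        R_inv = np.linalg.inv(R)
        cholR = np.linalg.cholesky(R)

        # beta | rest: per-environment row means, residual covariance R/n
        resid = Y - b1[:, None, :] - np.transpose(B2, (1, 0, 2))
        beta = resid.mean(axis=0) + \
            (rng.standard_normal((m, t)) @ cholR.T) / np.sqrt(n)

        # b1 | rest: eigenbasis of G, residuals pooled over environments
        resid = Y - beta[None, :, :] - np.transpose(B2, (1, 0, 2))
        S = resid.sum(axis=1)                      # n x t
        Stil = v.T @ S
        prec = St_inv[None] / d[:, None, None] + m * R_inv[None]
        mean = np.einsum("bij,bj->bi", np.linalg.inv(prec), Stil @ R_inv.T)
        b1til = sample_mvn_batch(rng, mean, prec)
        b1 = v @ b1til

        # b2 | rest: joint eigenbasis of Sigma_E and G
        lam, P = np.linalg.eigh(Sigma_E)
        lam = np.clip(lam, 1e-10, None)
        resid = Y - beta[None, :, :] - b1[:, None, :]
        T_env = np.transpose(resid, (1, 0, 2))     # m x n x t
        T_rot = np.einsum("ek,ent->knt", P, v.T @ T_env)
        scale = (lam[:, None] * d[None, :]).reshape(-1)          # (m*n,)
        prec = St2_inv[None] / scale[:, None, None] + R_inv[None]
        rhs = (T_rot.reshape(m * n, t)) @ R_inv.T
        mean = np.einsum("bij,bj->bi", np.linalg.inv(prec), rhs)
        B2til = sample_mvn_batch(rng, mean, prec).reshape(m, n, t)
        B2 = np.einsum("ek,knt->ent", P, B2til)
        B2 = np.einsum("ni,eit->ent", v, B2)

        # trait covariance(s) | b1, b2
        S1 = (b1til / d[:, None]).T @ b1til
        flat = B2til.reshape(m * n, t)
        S2 = (flat / scale[:, None]).T @ flat
        if "Sigma_t" not in fix:
            if spec.separate_trait_cov:
                Sigma_t = sample_inv_wishart(rng, nu_t + n, S_t0 + S1)
                Sigma_t2 = sample_inv_wishart(rng, nu_t + n * m, S_t0 + S2)
            else:
                Sigma_t = sample_inv_wishart(rng, nu_t + n + n * m,
                                             S_t0 + S1 + S2)
                Sigma_t2 = Sigma_t

        # environment covariance | b2 (trace form over per-env blocks)
        if "Sigma_E" not in fix:
            C = np.einsum("ni,eit->ent", v.T, B2)  # line-mode rotation
            W = C @ St2_inv
            S_E = np.einsum("eit,fit,i->ef", W, C, 1.0 / d)
            S_E = 0.5 * (S_E + S_E.T)
            Sigma_E = sample_inv_wishart(rng, nu_e + n * t, S_e0 + S_E)

        # residual covariance | everything else
        fitted = beta[None, :, :] + b1[:, None, :] + np.transpose(B2, (1, 0, 2))
        if "R" not in fix:
            E = (Y - fitted).reshape(n * m, t)
            R = sample_inv_wishart(rng, nu_r + n * m, S_r0 + E.T @ E)

        # augmentation: conditional normal across traits within each cell
        for pat, cells in cells_by_pattern.items():
            pattern = np.frombuffer(pat, dtype=bool)
            for (i, e) in cells:
                Y[i, e] = conditional_normal_draw(rng, fitted[i, e], R,
                                                  Y[i, e], pattern)

        if it >= mc.burn_in and (it - mc.burn_in) % mc.thin == 0:
            keep += 1
            mean_beta += beta
            mean_b1 += b1
            mean_B2 += B2
            mean_fit += fitted
            acc["Sigma_t"] += Sigma_t
            acc["Sigma_t2"] += Sigma_t2
            acc["Sigma_E"] += Sigma_E
            acc["R"] += R
            if spec.store_draws:
                draws["Sigma_t_diag"].append(np.diag(Sigma_t).copy())
                draws["Sigma_E_diag"].append(np.diag(Sigma_E).copy())
                draws["R_diag"].append(np.diag(R).copy())

    stored = {k_: np.asarray(v_) for k_, v_ in draws.items()} if spec.store_draws else {}
    ess = {}
    if spec.store_draws:
        for j, tr in enumerate(traits):
            ess[f"Sigma_t[{tr}]"] = effective_sample_size(stored["Sigma_t_diag"][:, j])
            ess[f"R[{tr}]"] = effective_sample_size(stored["R_diag"][:, j])
        for e, env in enumerate(envs):
            ess[f"Sigma_E[{env}]"] = effective_sample_size(stored["Sigma_E_diag"][:, e])
    check_chain_health(ess)

    variances: dict[str, float | np.ndarray] = {
        "Sigma_t": acc["Sigma_t"] / keep, "Sigma_E": acc["Sigma_E"] / keep,
        "R": acc["R"] / keep, "kernel_diag_mean": float(np.mean(np.diag(k.matrix)))}
    if spec.separate_trait_cov:
        variances["Sigma_t_gxe"] = acc["Sigma_t2"] / keep

    return PosteriorSummary(
        family="MTME", line_ids=k.line_ids, env_ids=envs, trait_names=traits,
        effects={"beta": mean_beta / keep, "b1": mean_b1 / keep,
                 "b2": mean_B2 / keep},
        variances=variances,
        fitted=mean_fit / keep, observed=observed,
        ess=ess, draws=stored, spec=spec)
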