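"""Single-trait, single-environment GBLUP sampler.

Model: y = 1 mu + u + e with u ~ N(0, G sigma_g2) and e ~ N(0, I sigma_e2).
The chain works in the eigenbasis of G, so each sweep costs O(n^2) for the
rotation and O(n) for the component-wise conditional draws.
"""

from __future__ import annotations

import numpy as np

from ..containers import BlueSet, Kernel
from .common import (MCMCSettings, ModelSpec, PosteriorSummary,
                     check_chain_health, effective_sample_size, extract_panel,
                     kernel_eig, sample_scaled_inv_chi2, scalar_prior)

__all__ = ["fit_se"]


def fit_se(blues: BlueSet, kernel: Kernel, spec: ModelSpec, env: str,
           trait: str) -> PosteriorSummary:
    """Fit the SE model for one (environment, trait) cell of the BLUE array.

    Lines missing their BLUE are carried through by data augmentation and
    receive genomic predictions through their kernel relationships.
    """
    y3, obs3, k = extract_panel(blues, kernel, [env], [trait])
    y = y3[:, 0, 0].copy()
    observed = obs3[:, 0, 0]
    n = len(y)
    if observed.sum() < 10:
        raise ValueError(f"need >= 10 observed lines, have {int(observed.sum())}")

    mc: MCMCSettings = spec.mcmc
    rng = np.random.default_rng(mc.seed)
    d, v = kernel_eig(k)

    var_y = max(float(np.var(y[observed], ddof=1)), 1e-8)
    nu_g, ss_g0 = scalar_prior(spec.df_scalar, var_y)
    nu_e, ss_e0 = scalar_prior(spec.df_scalar, var_y)

    fix = spec.fix_variances
    sg2 = fix.get("sigma_g2", 0.5 * var_y)
    se2 = fix.get("sigma_e2", 0.5 * var_y)
    mu = float(np.mean(y[observed]))
    u = np.zeros(n)
    y[~observed] = mu  # initialise augmented cells

    keep = 0
    mean_mu, mean_u, mean_fit = 0.0, np.zeros(n), np.zeros(n)
    mean_sg2 = mean_se2 = 0.0
    draws = {"sigma_g2": [], "sigma_e2": [], "mu": []}

    for it in range(mc.n_iter):
        # u | rest: component-wise in the eigenbasis of G
        ytil = v.T @ (y - mu)
        c = d * sg2 / (d * sg2 + se2)
        utils = c * ytil + np.sqrt(c * se2) * rng.standard_normal(n)
        u = v @ utils

        # mu | rest (flat prior)
        mu = float(rng.normal(np.mean(y - u), np.sqrt(se2 / n)))

        # variances | rest (scaled inverse chi-square)
        if "sigma_g2" not in fix:
            ss = float(np.sum(utils**2 / d)) + ss_g0
            sg2 = sample_scaled_inv_chi2(rng, nu_g + n, ss)
        if "sigma_e2" not in fix:
            resid = y - mu - u
            se2 = sample_scaled_inv_chi2(rng, nu_e + n,
                                         float(resid @ resid) + ss_e0)

        # augment masked cells
        if (~observed).any():
            miss = ~observed
            y[miss] = mu + u[miss] + np.sqrt(se2) * rng.standard_normal(miss.sum())

        if it >= mc.burn_in and (it - mc.burn_in) % mc.thin == 0:
            keep += 1
            mean_mu += mu
            mean_u += u
            mean_fit += mu + u
            mean_sg2 += sg2
            mean_se2 += se2
            if spec.store_draws:
                draws["sigma_g2"].append(sg2)
                draws["sigma_e2"].append(se2)
                draws["mu"].append(mu)

    mean_mu /= keep
    mean_u /= keep
    mean_fit /= keep
    stored = {k_: np.asarray(v_) for k_, v_ in draws.items()} if spec.store_draws else {}
    ess = {k_: effective_sample_size(v_) for k_, v_ in stored.items()
           if k_.startswith("sigma")}
    check_chain_health(ess)

    return PosteriorSummary(
        family="SE", line_ids=k.line_ids, env_ids=[env], trait_names=[trait],
        effects={"mu": np.array([mean_mu]), "u": mean_u},
        variances={"sigma_g2": mean_sg2 / keep, "sigma_e2": mean_se2 / keep},
        fitted=mean_fit[:, None, None], observed=observed[:, None, None],
        ess=ess, draws=stored, spec=spec)
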