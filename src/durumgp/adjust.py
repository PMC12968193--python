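"""Plot-level phenotype adjustment: BLUEs, variance components, heritability,
and trait/environment correlation tables.

Per environment and trait the model is

    y = mu + genotype + rep + block(rep) + e

fitted twice, following standard two-stage practice: genotype fixed (REML on
the rep/block components, then GLS) to obtain per-line adjusted means on the
trait scale, and genotype random (same model otherwise) to obtain the
variance components behind the entry-mean broad-sense heritability

    h2 = sg2 / (sg2 + se2 / r),   r = harmonic mean replicate count.

The REML solver handles any set of i.i.d. variance components through the
Woodbury identity, so the same code serves both fits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import BlueSet, PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = ["AdjustmentFit", "RemlResult", "reml_fit", "compute_blues",
           "compute_all_blues", "estimate_h2", "trait_correlations",
           "env_correlations", "MissingTraitError"]


class MissingTraitError(KeyError):
    pass


@dataclass
class RemlResult:
    """REML fit of y = Xb + sum_k Z_k u_k + e with u_k ~ N(0, sk2 I)."""

    beta: np.ndarray
    beta_cov: np.ndarray
    sigma2: dict[str, float]        # per-component variances incl. "residual"
    loglik: float
    converged: bool
    n_obs: int

    def blup(self, name: str, Z: np.ndarray, X: np.ndarray, y: np.ndarray,
             all_Z: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        """BLUP and prediction-error variance of one random factor."""
        se2 = self.sigma2["residual"]
        Vinv = _v_inverse(all_Z, {k: self.sigma2[k] for k in all_Z}, se2,
                          self.n_obs)
        resid = y - X @ self.beta
        sk2 = self.sigma2[name]
        u = sk2 * Z.T @ (Vinv @ resid)
        # PEV = sk2 I - sk2^2 Z' P Z with P the REML projection
        VX = Vinv @ X
        P = Vinv - VX @ np.linalg.solve(X.T @ VX, VX.T)
        pev = sk2 * np.eye(Z.shape[1]) - sk2**2 * (Z.T @ P @ Z)
        return u, pev


def _v_inverse(Zs: dict[str, np.ndarray], s2: dict[str, float], se2: float,
               n: int) -> np.ndarray:
    V = se2 * np.eye(n)
    for k, Z in Zs.items():
        V += s2[k] * (Z @ Z.T)
    return np.linalg.inv(V)


def _indicator(levels: pd.Series) -> tuple[np.ndarray, list]:
    cats = sorted(levels.unique(), key=str)
    pos = {c: i for i, c in enumerate(cats)}
    Z = np.zeros((len(levels), len(cats)))
    Z[np.arange(len(levels)), [pos[v] for v in levels]] = 1.0
    return Z, cats


def _neg2_reml(theta: np.ndarray, y: np.ndarray, X: np.ndarray,
               W: np.ndarray, col_of: np.ndarray) -> float:
    """Profiled -2 REML log-likelihood over log variance ratios ``theta``.

    H = I + W diag(gamma) W' handled via Woodbury on the q x q system.
    """
    n, p = X.shape
    gam = np.exp(theta)[col_of]
    q = W.shape[1]
    # H^-1 = I - W (diag(1/gam) + W'W)^-1 W'
    A = W.T @ W + np.diag(1.0 / gam)
    try:
        cho = np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        return 1e12
    WtY = W.T @ np.column_stack([y, X])
    sol = np.linalg.solve(cho.T, np.linalg.solve(cho, WtY))
    HinvY = np.column_stack([y, X]) - W @ sol
    hy, HX = HinvY[:, 0], HinvY[:, 1:]
    XtHX = X.T @ HX
    XtHy = X.T @ hy
    try:
        beta = np.linalg.solve(XtHX, XtHy)
    except np.linalg.LinAlgError:
        return 1e12
    ypy = float(y @ hy - XtHy @ beta)
    if ypy <= 0:
        return 1e12
    # log|H| = log|A| + sum(log gam)
    logdetH = 2.0 * np.log(np.diag(cho)).sum() + np.log(gam).sum()
    sign, logdetXHX = np.linalg.slogdet(XtHX)
    if sign <= 0:
        return 1e12
    return (n - p) * np.log(ypy / (n - p)) + logdetH + logdetXHX


def reml_fit(y: np.ndarray, X: np.ndarray, Zs: dict[str, np.ndarray],
             tol: float = 1e-8, max_iter: int = 200) -> RemlResult:
    """REML for a Gaussian mixed model with i.i.d. variance components.

    ``Zs`` maps component name -> 0/1 incidence matrix.  Variance ratios are
    optimised on the log scale; components driven to the lower boundary are
    reported as 0.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    names = list(Zs)
    W = np.hstack([Zs[k] for k in names]) if names else np.zeros((len(y), 0))
    col_of = np.concatenate([[i] * Zs[k].shape[1] for i, k in enumerate(names)]) \
        if names else np.zeros(0, dtype=int)
    n, p = X.shape

    if not names:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        se2 = float(resid @ resid / max(n - p, 1))
        cov = se2 * np.linalg.pinv(X.T @ X)
        return RemlResult(beta, cov, {"residual": se2}, np.nan, True, n)

    obj = lambda th: _neg2_reml(th, y, X, W, col_of)
    res = optimize.minimize(obj, x0=np.full(len(names), -1.0), method="L-BFGS-B",
                            bounds=[(-25.0, 12.0)] * len(names),
                            options={"maxiter": max_iter, "ftol": tol})
    if not res.success:
        # polish with a derivative-free pass; the profiled surface is smooth
        # but can defeat finite-difference line searches near the boundary
        res2 = optimize.minimize(obj, x0=res.x, method="Nelder-Mead",
                                 options={"maxiter": max_iter,
                                          "fatol": tol, "xatol": 1e-8})
        if res2.fun <= res.fun:
            res = res2
    if not res.success:
        warnings.warn(f"REML did not converge ({res.message}); using best iterate")
    gam = np.exp(res.x)
    gam[res.x <= -24.0] = 0.0  # boundary: component estimated at zero

    # final GLS pass at the REML estimates
    V = np.eye(n)
    for g, k in zip(gam, names):
        V += g * (Zs[k] @ Zs[k].T)
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    beta = np.linalg.solve(XtVX, X.T @ Vinv @ y)
    resid = y - X @ beta
    se2 = float(resid @ Vinv @ resid / (n - p))
    sigma2 = {k: float(g * se2) for k, g in zip(names, gam)}
    sigma2["residual"] = se2
    beta_cov = se2 * np.linalg.inv(XtVX)
    return RemlResult(beta, beta_cov, sigma2, -0.5 * res.fun, bool(res.success), n)


@dataclass
class AdjustmentFit:
    trait_name: str
    env_id: str
    blues: pd.Series                # per-line adjusted mean, trait scale
    se: pd.Series
    var_components: dict[str, float]  # sigma_g2, sigma_rep2, sigma_block2, sigma_e2
    h2: float
    replicate_counts: pd.Series
    fallback_means: bool = False
    mean_vdiff: float = np.nan   # mean variance of a genotype-BLUP difference


def compute_blues(pheno: PhenotypeTable, trait: str, env: str) -> AdjustmentFit:
    """Adjusted means for one trait in one environment.

    Genotype is fixed for the BLUEs (cell-means coding, so estimates sit on
    the trait scale); the genotype-random refit supplies the variance
    components and entry-mean heritability.  A design with a single replicate
    and a single block cannot separate anything from residual: plain means
    are returned with a warning.
    """
    df = pheno.subset(trait, env).dropna(subset=["value"])
    if df.empty:
        raise MissingTraitError(f"trait {trait!r} has no records in env {env!r}")
    lines = sorted(df["line"].unique())
    if len(lines) < 2:
        raise ValueError(f"need >= 2 lines with data in env {env!r}")
    reps = pheno.records.loc[
        (pheno.records["trait"] == trait) & (pheno.records["env"] == env)]
    rep_counts = df.groupby("line")["value"].size().reindex(lines)

    y = df["value"].to_numpy(dtype=float)
    Zg, _ = _indicator(df["line"])
    n_reps = df["rep"].nunique()
    # block labels nested inside rep
    blk = df["rep"].astype(str) + ":" + df["block"].astype(str)
    n_blocks = blk.nunique()

    if n_reps == 1 and n_blocks == 1:
        logger.warning("compute_blues(%s, %s): single rep & block; "
                       "falling back to plain means", trait, env)
        means = df.groupby("line")["value"].mean().reindex(lines)
        sds = df.groupby("line")["value"].std(ddof=1).reindex(lines)
        se = (sds / np.sqrt(rep_counts)).fillna(np.nan)
        vc = {"sigma_g2": float(means.var(ddof=1)), "sigma_rep2": 0.0,
              "sigma_block2": 0.0, "sigma_e2": np.nan}
        return AdjustmentFit(trait, env, means, se, vc, np.nan,
                             rep_counts, fallback_means=True)

    Zs_fixed_fit: dict[str, np.ndarray] = {}
    if n_reps > 1:
        Zs_fixed_fit["rep"], _ = _indicator(df["rep"].astype(str))
    if n_blocks > n_reps:
        Zs_fixed_fit["block"], _ = _indicator(blk)

    fit_f = reml_fit(y, Zg, Zs_fixed_fit)
    blues = pd.Series(fit_f.beta, index=lines, name="blue")
    se = pd.Series(np.sqrt(np.diag(fit_f.beta_cov)), index=lines, name="se")

    # genotype-random refit for variance components
    X0 = np.ones((len(y), 1))
    Zs_rand = dict(Zs_fixed_fit)
    Zs_rand["genotype"] = Zg
    fit_r = reml_fit(y, X0, Zs_rand)
    vc = {
        "sigma_g2": fit_r.sigma2.get("genotype", 0.0),
        "sigma_rep2": fit_r.sigma2.get("rep", 0.0),
        "sigma_block2": fit_r.sigma2.get("block", 0.0),
        "sigma_e2": fit_r.sigma2["residual"],
    }
    fit = AdjustmentFit(trait, env, blues, se, vc, np.nan, rep_counts)
    # mean prediction-error variance of the genotype BLUPs, for the Cullis
    # heritability variant
    if fit_r.sigma2.get("genotype", 0.0) > 0:
        _, pev = fit_r.blup("genotype", Zg, X0, y, Zs_rand)
        # mean variance of a difference of two genotype BLUPs
        q = pev.shape[0]
        diag = np.diag(pev)
        vdiff = (diag[:, None] + diag[None, :] - 2.0 * pev)
        fit.mean_vdiff = float(vdiff[~np.eye(q, dtype=bool)].mean())
    fit.h2 = estimate_h2(fit)
    return fit


def estimate_h2(fit: AdjustmentFit, method: str = "entry_mean") -> float:
    """Broad-sense heritability from the genotype-random variance components.

    ``entry_mean`` (default): sg2 / (sg2 + se2/r) with r the harmonic mean of
    per-line replicate counts.  ``plot``: sg2 / (sg2 + se2).  ``cullis``:
    1 - vbar / (2 sg2) with vbar the mean variance of a difference of two
    genotype BLUPs.
    """
    sg2 = fit.var_components["sigma_g2"]
    se2 = fit.var_components["sigma_e2"]
    if not np.isfinite(se2):
        return np.nan
    if sg2 + se2 <= 0:
        warnings.warn("zero total variance; heritability undefined")
        return np.nan
    if method == "plot":
        return sg2 / (sg2 + se2)
    if method == "cullis":
        if not np.isfinite(fit.mean_vdiff) or sg2 <= 0:
            return np.nan
        return max(0.0, 1.0 - fit.mean_vdiff / (2.0 * sg2))
    if method != "entry_mean":
        raise ValueError(f"unknown heritability method {method!r}")
    r = len(fit.replicate_counts) / np.sum(1.0 / fit.replicate_counts)
    return sg2 / (sg2 + se2 / r)


def compute_all_blues(pheno: PhenotypeTable) -> tuple[BlueSet, pd.DataFrame]:
    """BLUEs for every (environment, trait) with data; also returns a tidy
    table of variance components and heritabilities."""
    lines, envs, traits = pheno.line_ids, pheno.env_ids, pheno.trait_names
    shape = (len(lines), len(envs), len(traits))
    values = np.full(shape, np.nan)
    ses = np.full(shape, np.nan)
    rows = []
    li = {l: i for i, l in enumerate(lines)}
    for j, env in enumerate(envs):
        for k, trait in enumerate(traits):
            try:
                fit = compute_blues(pheno, trait, env)
            except MissingTraitError:
                continue
            for line, v in fit.blues.items():
                values[li[line], j, k] = v
            for line, v in fit.se.items():
                ses[li[line], j, k] = v
            rows.append({"env": env, "trait": trait, **fit.var_components,
                         "h2": fit.h2})
    summary = pd.DataFrame(rows)
    return BlueSet(values, lines, envs, traits, ses), summary


_STARS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _star(p: float) -> str:
    for cut, s in _STARS:
        if p < cut:
            return s
    return ""


def trait_correlations(blues: BlueSet, env: str) -> pd.DataFrame:
    """Pairwise Pearson correlations among traits within one environment.

    Pairwise-complete over lines; entries with fewer than 3 complete pairs
    are left missing with a warning.  Returns a tidy table with r, the
    two-sided p-value and significance stars.
    """
    j = blues.env_ids.index(env)
    data = blues.values[:, j, :]
    rows = []
    for a in range(len(blues.trait_names)):
        for b in range(a, len(blues.trait_names)):
            ok = ~np.isnan(data[:, a]) & ~np.isnan(data[:, b])
            if ok.sum() < 3:
                warnings.warn(f"<3 complete pairs for "
                              f"({blues.trait_names[a]}, {blues.trait_names[b]}) "
                              f"in {env}")
                r, p = np.nan, np.nan
            elif a == b:
                r, p = 1.0, 0.0
            else:
                r, p = stats.pearsonr(data[ok, a], data[ok, b])
            rows.append({"env": env, "trait_a": blues.trait_names[a],
                         "trait_b": blues.trait_names[b], "r": r, "p": p,
                         "stars": _star(p) if np.isfinite(p) else ""})
    return pd.DataFrame(rows)


def env_correlations(blues: BlueSet, trait: str) -> tuple[pd.DataFrame, list[str]]:
    """Environment x environment Pearson correlation of per-line BLUEs for one
    trait, plus an average-linkage clustering order on distance 1 - r."""
    k = blues.trait_names.index(trait)
    data = blues.values[:, :, k]
    m = len(blues.env_ids)
    corr = np.full((m, m), np.nan)
    for a in range(m):
        for b in range(a, m):
            ok = ~np.isnan(data[:, a]) & ~np.isnan(data[:, b])
            if ok.sum() < 3:
                warnings.warn(f"<3 complete pairs between environments "
                              f"{blues.env_ids[a]} and {blues.env_ids[b]}")
                continue
            if a == b:
                corr[a, a] = 1.0
            else:
                r = stats.pearsonr(data[ok, a], data[ok, b]).statistic
                corr[a, b] = corr[b, a] = r
    table = pd.DataFrame(corr, index=blues.env_ids, columns=blues.env_ids)
    dist = 1.0 - np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(dist, 0.0)
    dist = 0.5 * (dist + dist.T)
    if m > 2:
        link = hierarchy.average(squareform(dist, checks=False))
        order = [blues.env_ids[i] for i in hierarchy.leaves_list(link)]
    else:
        order = list(blues.env_ids)
    return table, order
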