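"""Shared machinery for the Bayesian GBLUP-family samplers.

All four model families (SE, MT, ME, MTME) are Gibbs samplers over Gaussian
full conditionals with scaled-inverse-chi-square updates for scalar
variances and inverse-Wishart updates for trait/environment covariance
matrices.  Missing phenotype cells are handled by data augmentation, which
is what lets the multi-trait models borrow secondary-trait information in
CV2.  Every sampler works in the eigenbasis of the genomic kernel so no
n x n solve appears inside the chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ..containers import BlueSet, Kernel

__all__ = ["MCMCSettings", "ModelSpec", "PosteriorSummary", "predict",
           "effective_sample_size"]

FAMILIES = ("SE", "MT", "ME", "MTME")


@dataclass
class MCMCSettings:
    n_iter: int = 12_000
    burn_in: int = 2_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n_iter > self.burn_in >= 0):
            raise ValueError("need n_iter > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class ModelSpec:
    """Which model to fit and how.

    ``fix_variances`` pins named components (e.g. ``{"sigma_g2": 1.0}``) at a
    constant instead of sampling them — the degenerate-prior mode used for
    closed-form cross-checks.  ``df_scalar`` and the Wishart rule follow the
    weakly-informative defaults of standard Bayesian GBLUP software: the
    scalar prior mode puts half the phenotypic variance on each component;
    covariance priors are inverse-Wishart(dim + 3, 0.5 * diag phenotypic cov).
    """

    family: str = "SE"
    kernel_name: str = "G"
    df_scalar: float = 5.0
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    fix_variances: dict[str, float] = field(default_factory=dict)
    include_line_effect: bool = True      # the i.i.d. L_j term of the ME model
    separate_trait_cov: bool = False      # separate Sigma_t for main and GxE
    store_draws: bool = True

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")

    @property
    def label(self) -> str:
        return self.family if self.kernel_name == "G" else f"{self.family}_{self.kernel_name}"


@dataclass
class PosteriorSummary:
    """Posterior means of effects and (co)variance components, plus the
    per-cell posterior-mean linear predictor used for prediction.

    ``fitted`` always has shape (lines, envs, traits) — singleton axes for
    the families that collapse a dimension — so prediction indexing is
    uniform across families.  ``observed`` marks cells seen by the sampler;
    the fitted value of an unobserved cell is its augmentation mean.
    """

    family: str
    line_ids: list[str]
    env_ids: list[str]
    trait_names: list[str]
    effects: dict[str, np.ndarray]
    variances: dict[str, float | np.ndarray]
    fitted: np.ndarray
    observed: np.ndarray
    ess: dict[str, float]
    draws: dict[str, np.ndarray] = field(default_factory=dict)
    spec: ModelSpec | None = None

    def __post_init__(self) -> None:
        shape = (len(self.line_ids), len(self.env_ids), len(self.trait_names))
        assert self.fitted.shape == shape, (self.fitted.shape, shape)


class PredictionError(KeyError):
    pass


def predict(fit: PosteriorSummary, targets: list[tuple[str, str, str]]) -> np.ndarray:
    """Posterior predictive mean per (line, env, trait) target.

    Cells observed during fitting return their fitted mean; masked cells
    their augmented mean (the same stored array).
    """
    li = {l: i for i, l in enumerate(fit.line_ids)}
    ei = {e: j for j, e in enumerate(fit.env_ids)}
    ti = {t: k for k, t in enumerate(fit.trait_names)}
    out = np.empty(len(targets))
    for q, (line, env, trait) in enumerate(targets):
        if line not in li:
            raise PredictionError(f"line {line!r} unknown to this fit")
        if env not in ei:
            raise PredictionError(f"environment {env!r} unknown to this fit")
        if trait not in ti:
            raise PredictionError(f"trait {trait!r} unknown to this fit")
        out[q] = fit.fitted[li[line], ei[env], ti[trait]]
    return out


# ---------------------------------------------------------------------------
# numeric helpers

def kernel_eig(kernel: Kernel, floor: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the kernel with eigenvalues floored for
    invertibility (a validated kernel may still be exactly singular)."""
    d, v = np.linalg.eigh(kernel.matrix)
    return np.clip(d, floor, None), v


def sample_scaled_inv_chi2(rng: np.random.Generator, df: float, ss: float) -> float:
    """Draw from the scaled-inverse-chi-square with df and sum-of-squares ss."""
    return ss / rng.chisquare(df)


def scalar_prior(df: float, phenotypic_var: float) -> tuple[float, float]:
    """(df, df * s0^2) such that the prior mode is half the phenotypic
    variance: mode of ScaledInvChi2(nu, s2) is nu s2 / (nu + 2)."""
    s0 = 0.5 * phenotypic_var * (df + 2.0) / df
    return df, df * s0


def wishart_prior(dim: int, pheno_cov_diag: np.ndarray) -> tuple[float, np.ndarray]:
    df = dim + 3.0
    scale = 0.5 * np.diag(np.atleast_1d(pheno_cov_diag))
    # keep the prior proper even for a zero-variance input column
    scale[np.diag_indices(dim)] = np.maximum(np.diag(scale), 1e-8)
    return df, scale


def sample_inv_wishart(rng: np.random.Generator, df: float, scale: np.ndarray
                       ) -> np.ndarray:
    draw = stats.invwishart.rvs(df=df, scale=scale, random_state=rng)
    return np.atleast_2d(draw)


def sample_mvn_batch(rng: np.random.Generator, mean: np.ndarray,
                     precision: np.ndarray) -> np.ndarray:
    """Draw one sample from each N(mean[b], precision[b]^-1) in a stack."""
    cov = np.linalg.inv(precision)
    cov = 0.5 * (cov + np.swapaxes(cov, -1, -2))
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal(mean.shape)
    return mean + np.einsum("...ij,...j->...i", chol, z)


def conditional_normal_draw(rng: np.random.Generator, mean: np.ndarray,
                            cov: np.ndarray, value: np.ndarray,
                            observed: np.ndarray) -> np.ndarray:
    """Fill the unobserved entries of ``value`` with a draw from their
    conditional normal given the observed entries (row-wise model)."""
    miss = ~observed
    if not miss.any():
        return value
    out = value.copy()
    if observed.any():
        o, m = np.nonzero(observed)[0], np.nonzero(miss)[0]
        coo = cov[np.ix_(o, o)]
        cmo = cov[np.ix_(m, o)]
        k = np.linalg.solve(coo, (value[o] - mean[o]))
        cond_mean = mean[m] + cmo @ k
        cond_cov = cov[np.ix_(m, m)] - cmo @ np.linalg.solve(coo, cmo.T)
        cond_cov = 0.5 * (cond_cov + cond_cov.T)
        chol = np.linalg.cholesky(cond_cov + 1e-12 * np.eye(len(m)))
        out[m] = cond_mean + chol @ rng.standard_normal(len(m))
    else:
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
        out[:] = mean + chol @ rng.standard_normal(cov.shape[0])
    return out


def effective_sample_size(draws: np.ndarray) -> float:
    """Effective sample size of one scalar chain (arviz backend)."""
    draws = np.asarray(draws, dtype=float)
    if draws.size < 4 or np.allclose(draws, draws[0]):
        return float(draws.size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import arviz as az
        return float(az.ess(draws[np.newaxis, :]))


def check_chain_health(ess: dict[str, float], threshold: float = 100.0) -> None:
    low = {k: v for k, v in ess.items() if v < threshold}
    if low:
        warnings.warn(f"low effective sample size for variance components: "
                      f"{ {k: round(v, 1) for k, v in low.items()} }")


def extract_panel(blues: BlueSet, kernel: Kernel, envs: list[str],
                  traits: list[str]) -> tuple[np.ndarray, np.ndarray, Kernel]:
    """Align the BLUE array and kernel on the BlueSet's line order and slice
    the requested environments and traits.

    Returns (Y, observed, kernel) with Y of shape (lines, envs, traits); NaN
    cells are the augmentation targets.
    """
    missing = [l for l in blues.line_ids if l not in set(kernel.line_ids)]
    if missing:
        raise KeyError(f"lines absent from kernel: {missing[:5]}")
    k = kernel.reindex(blues.line_ids)
    ej = [blues.env_ids.index(e) for e in envs]
    tk = [blues.trait_names.index(t) for t in traits]
    y = blues.values[np.ix_(range(len(blues.line_ids)), ej, tk)].astype(float)
    return y, ~np.isnan(y), k
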