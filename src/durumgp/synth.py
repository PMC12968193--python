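"""Synthetic study generator: genotypes, target-gene alleles, true genetic and
genotype-by-environment effects, and replicated plot-level phenotypes.

The generator emulates a replicated multi-environment durum-wheat panel:
186 lines, eight sowing-by-season environments (three sowings in each of two
seasons plus two in a third), seven traits (GN, GW, NS, SL, SW, HD, PH) with
strong positive covariance among the yield components and entry-mean
heritabilities in the 0.30-0.95 band.  Genetic main effects are drawn
matrix-normally with row covariance G (the realised genomic kernel) and
column covariance Sigma_t; interaction effects with row covariance
Sigma_E (x) G.  Plot values add replicate, block-within-replicate and
residual noise, the residual variance back-computed from the per-trait
entry-mean heritability target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, Kernel, PhenotypeTable, TargetGeneTable

__all__ = [
    "GeneSpec",
    "SimulationConfig",
    "TrueEffects",
    "simulate_genotypes",
    "simulate_target_genes",
    "simulate_true_effects",
    "simulate_trials",
    "default_config",
]


class ConfigurationError(ValueError):
    """Raised for an invalid simulation configuration."""


# Substream keys so each stage is reproducible in isolation from one seed.
_STREAMS = {"genotypes": 0, "genes": 1, "effects": 2, "trials": 3, "missing": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


def _check_psd(mat: np.ndarray, name: str, tol: float = 1e-8) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ConfigurationError(f"{name} must be square, got shape {mat.shape}")
    if np.max(np.abs(mat - mat.T)) > 1e-10:
        raise ConfigurationError(f"{name} is not symmetric")
    w = np.linalg.eigvalsh(mat)
    if w.min() < -tol * max(1.0, w.max()):
        raise ConfigurationError(f"{name} is not positive semi-definite "
                                 f"(min eigenvalue {w.min():.3e})")
    return mat


def _psd_chol(mat: np.ndarray) -> np.ndarray:
    """Cholesky-like factor that tolerates exact rank deficiency."""
    w, v = np.linalg.eigh(np.asarray(mat, dtype=float))
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


@dataclass
class GeneSpec:
    """Declared alleles of one target gene with frequencies and trait effects.

    ``effects`` maps allele label -> per-trait additive effect vector; absent
    alleles contribute zero (the purely polygenic base case).
    """

    name: str
    alleles: list[str]
    freqs: list[float]
    effects: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.alleles) != len(self.freqs):
            raise ConfigurationError(f"gene {self.name}: alleles/freqs length mismatch")
        if abs(sum(self.freqs) - 1.0) > 1e-8:
            raise ConfigurationError(
                f"gene {self.name}: allele frequencies sum to {sum(self.freqs)}, not 1")
        if any(f < 0 for f in self.freqs):
            raise ConfigurationError(f"gene {self.name}: negative allele frequency")


_SEASONS = ("2021-2022", "2022-2023", "2023-2024")
DEFAULT_ENVS = [f"{s}_{season}"
                for season, k in zip(_SEASONS, (3, 3, 2))
                for s in range(1, k + 1)]
DEFAULT_TRAITS = ["GN", "GW", "NS", "SL", "SW", "HD", "PH"]

# Entry-mean heritability targets per trait, inside the study's reported bands
# (yield components moderate, spike traits higher, phenology/height near the top).
DEFAULT_H2 = {"GN": 0.45, "GW": 0.42, "NS": 0.60, "SL": 0.70,
              "SW": 0.45, "HD": 0.90, "PH": 0.85}

# Per-environment trait means: a plausible Mediterranean gradient where late
# sowing depresses the yield components and accelerates heading.
DEFAULT_TRAIT_MEANS = {"GN": 45.0, "GW": 2.0, "NS": 20.0, "SL": 8.0,
                       "SW": 2.5, "HD": 120.0, "PH": 85.0}
DEFAULT_TRAIT_SD = {"GN": 8.0, "GW": 0.35, "NS": 1.8, "SL": 0.9,
                    "SW": 0.45, "HD": 5.0, "PH": 7.0}


def _default_sigma_t(traits: list[str]) -> np.ndarray:
    """Genetic covariance with strong positive yield-component correlations."""
    corr = {
        ("GN", "GW"): 0.65, ("GN", "NS"): 0.55, ("GN", "SL"): 0.45,
        ("GN", "SW"): 0.83, ("GW", "NS"): 0.50, ("GW", "SL"): 0.45,
        ("GW", "SW"): 0.95, ("NS", "SL"): 0.60, ("NS", "SW"): 0.50,
        ("SL", "SW"): 0.50, ("HD", "PH"): 0.30,
        ("GN", "HD"): 0.10, ("GW", "HD"): 0.05, ("NS", "HD"): 0.15,
        ("SL", "HD"): 0.10, ("SW", "HD"): 0.05,
        ("GN", "PH"): 0.10, ("GW", "PH"): 0.15, ("NS", "PH"): 0.10,
        ("SL", "PH"): 0.20, ("SW", "PH"): 0.15,
    }
    t = len(traits)
    rho = np.eye(t)
    for i, a in enumerate(traits):
        for j, b in enumerate(traits):
            if i < j:
                r = corr.get((a, b), corr.get((b, a), 0.0))
                rho[i, j] = rho[j, i] = r
    sd = np.array([DEFAULT_TRAIT_SD.get(tr, 1.0) for tr in traits])
    sigma = rho * np.outer(sd, sd)
    # guard: nudge onto the PSD cone if rounding pushed an eigenvalue below 0
    w, v = np.linalg.eigh(sigma)
    if w.min() < 0:
        sigma = (v * np.clip(w, 1e-8, None)) @ v.T
    return sigma


def _default_sigma_e(env_labels: list[str]) -> np.ndarray:
    """Exchangeable-with-season-blocks interaction covariance: environments in
    the same season correlate 0.5, across seasons 0.25, unit scale."""
    seasons = [e.split("_", 1)[1] if "_" in e else e for e in env_labels]
    m = len(env_labels)
    sig = np.full((m, m), 0.25)
    for i in range(m):
        for j in range(m):
            if seasons[i] == seasons[j]:
                sig[i, j] = 0.5
        sig[i, i] = 1.0
    return sig


def _default_gene_specs() -> list[GeneSpec]:
    return [
        GeneSpec("Vrn-A1", ["spring", "winter"], [0.6, 0.4]),
        GeneSpec("Ppd-A1", ["GS100", "GS105", "wild"], [0.35, 0.35, 0.30]),
        GeneSpec("Ppd-B1", ["insensitive", "sensitive"], [0.55, 0.45]),
        GeneSpec("Rht-B1", ["Rht-B1a", "Rht-B1b"], [0.3, 0.7]),
    ]


@dataclass
class SimulationConfig:
    n_lines: int = 186
    n_markers: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    gene_spec: list[GeneSpec] = field(default_factory=_default_gene_specs)
    env_labels: list[str] = field(default_factory=lambda: list(DEFAULT_ENVS))
    trait_names: list[str] = field(default_factory=lambda: list(DEFAULT_TRAITS))
    Sigma_t: np.ndarray | None = None
    Sigma_E: np.ndarray | None = None
    env_means: np.ndarray | None = None   # envs x traits
    h2_target: float | dict[str, float] | np.ndarray | None = None  # envs x traits
    n_reps: int = 2
    n_blocks_per_rep: int = 2
    rep_var_frac: float = 0.05    # of total genetic variance
    block_var_frac: float = 0.05
    missing_rate: float = 0.0     # plot-level missing-data injection, default off
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.maf_range
        if not (0.0 < low <= high <= 0.5):
            raise ConfigurationError(f"invalid maf_range {self.maf_range}: "
                                     "need 0 < low <= high <= 0.5")
        if len(set(self.env_labels)) != len(self.env_labels):
            raise ConfigurationError("environment labels must be unique")
        if self.Sigma_t is None:
            self.Sigma_t = _default_sigma_t(self.trait_names)
        self.Sigma_t = _check_psd(self.Sigma_t, "Sigma_t")
        if self.Sigma_t.shape[0] != self.n_traits:
            raise ConfigurationError("Sigma_t dimension != number of traits")
        if self.Sigma_E is None:
            self.Sigma_E = _default_sigma_e(self.env_labels)
        self.Sigma_E = _check_psd(self.Sigma_E, "Sigma_E")
        if self.Sigma_E.shape[0] != self.n_envs:
            raise ConfigurationError("Sigma_E dimension != number of environments")
        if self.env_means is None:
            base = np.array([DEFAULT_TRAIT_MEANS.get(t, 0.0) for t in self.trait_names])
            sd = np.array([DEFAULT_TRAIT_SD.get(t, 1.0) for t in self.trait_names])
            # sowing-date gradient: later sowing index shifts the mean downward
            shift = np.linspace(0.5, -0.5, self.n_envs)[:, None]
            self.env_means = base[None, :] + shift * sd[None, :]
        self.env_means = np.asarray(self.env_means, dtype=float)
        if self.env_means.shape != (self.n_envs, self.n_traits):
            raise ConfigurationError(
                f"env_means shape {self.env_means.shape} != "
                f"({self.n_envs}, {self.n_traits})")
        self.h2_target = self._expand_h2(self.h2_target)
        if np.any(self.h2_target <= 0) or np.any(self.h2_target > 1):
            raise ConfigurationError("h2_target entries must lie in (0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must be in [0, 1)")

    def _expand_h2(self, h2) -> np.ndarray:
        shape = (self.n_envs, self.n_traits)
        if h2 is None:
            row = np.array([DEFAULT_H2.get(t, 0.5) for t in self.trait_names])
            return np.broadcast_to(row, shape).copy()
        if np.isscalar(h2):
            return np.full(shape, float(h2))
        if isinstance(h2, dict):
            row = np.array([float(h2[t]) for t in self.trait_names])
            return np.broadcast_to(row, shape).copy()
        arr = np.asarray(h2, dtype=float)
        if arr.shape != shape:
            raise ConfigurationError(f"h2_target shape {arr.shape} != {shape}")
        return arr

    @property
    def n_envs(self) -> int:
        return len(self.env_labels)

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    @property
    def line_ids(self) -> list[str]:
        return [f"G{i + 1:03d}" for i in range(self.n_lines)]


def default_config(**overrides) -> SimulationConfig:
    """The study-design configuration; keyword overrides for scaled runs."""
    return SimulationConfig(**overrides)


@dataclass
class TrueEffects:
    """Generative truth: genetic values, G x E deviations, environment means."""

    genetic_values: np.ndarray      # lines x traits
    gxe_values: np.ndarray          # lines x envs x traits
    env_trait_means: np.ndarray     # envs x traits
    line_ids: list[str]
    env_labels: list[str]
    trait_names: list[str]

    def total_value(self) -> np.ndarray:
        """lines x envs x traits array of env mean + genetic + G x E."""
        return (self.env_trait_means[None, :, :]
                + self.genetic_values[:, None, :]
                + self.gxe_values)


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw biallelic dosages under Hardy-Weinberg equilibrium.

    Allele frequencies are uniform on ``maf_range``; dosages are
    Binomial(2, p) per line and marker.
    """
    if config.n_lines < 2 or config.n_markers < 1:
        raise ConfigurationError("need n_lines >= 2 and n_markers >= 1")
    rng = _rng(config.seed, "genotypes")
    p = rng.uniform(*config.maf_range, size=config.n_markers)
    dosages = rng.binomial(2, p[None, :], size=(config.n_lines, config.n_markers))
    geno = GenotypeMatrix(dosages.astype(float), config.line_ids,
                          [f"M{i + 1:05d}" for i in range(config.n_markers)])
    if config.missing_rate > 0:
        mrng = _rng(config.seed, "missing")
        drop = mrng.random(geno.dosages.shape) < config.missing_rate
        geno.dosages[drop] = np.nan
    return geno


def simulate_target_genes(config: SimulationConfig) -> TargetGeneTable:
    """Sample one categorical allele per line for each declared target gene."""
    if not config.gene_spec:
        raise ConfigurationError("gene_spec is empty")
    rng = _rng(config.seed, "genes")
    calls = {}
    for gene in config.gene_spec:
        idx = rng.choice(len(gene.alleles), size=config.n_lines, p=gene.freqs)
        calls[gene.name] = [gene.alleles[i] for i in idx]
    table = pd.DataFrame(calls, index=pd.Index(config.line_ids, name="line"))
    return TargetGeneTable(table, {g.name: list(g.alleles) for g in config.gene_spec})


def draw_matrix_normal(rng: np.random.Generator, row_chol: np.ndarray,
                       col_chol: np.ndarray) -> np.ndarray:
    """One draw from MN(0, row_cov, col_cov) given factor matrices."""
    z = rng.standard_normal((row_chol.shape[1], col_chol.shape[1]))
    return row_chol @ z @ col_chol.T


def simulate_true_effects(config: SimulationConfig, kernel_G: Kernel,
                          genes: TargetGeneTable | None = None) -> TrueEffects:
    """Draw genetic main effects and G x E deviations.

    genetic_values ~ MN(0, G, Sigma_t); gxe_values reshaped from
    MN(0, Sigma_E (x) G, Sigma_t).  Declared target-gene allele effects are
    added to genetic_values on top of the polygenic draw.
    """
    if kernel_G.n_lines != config.n_lines:
        raise ConfigurationError(
            f"kernel has {kernel_G.n_lines} lines, config expects {config.n_lines}")
    rng = _rng(config.seed, "effects")
    Lg = _psd_chol(kernel_G.matrix)
    Lt = _psd_chol(config.Sigma_t)
    Le = _psd_chol(config.Sigma_E)
    n, m, t = config.n_lines, config.n_envs, config.n_traits

    genetic = draw_matrix_normal(rng, Lg, Lt)
    if genes is not None:
        for gene in config.gene_spec:
            if not gene.effects:
                continue
            labels = genes.calls[gene.name].astype(str).to_numpy()
            for allele, eff in gene.effects.items():
                genetic[labels == allele] += np.asarray(eff, dtype=float)[None, :]

    # chol(Sigma_E (x) G) = chol(Sigma_E) (x) chol(G): mix independent
    # line-blocks across environments with the Sigma_E factor.
    z = rng.standard_normal((m, n, t))
    mixed = np.einsum("ek,knt->ent", Le, z)          # environment factor
    gxe_env_major = np.einsum("ni,eit->ent", Lg, mixed) @ Lt.T
    gxe = np.transpose(gxe_env_major, (1, 0, 2))     # lines x envs x traits
    return TrueEffects(genetic, gxe, config.env_means.copy(),
                       kernel_G.line_ids, list(config.env_labels),
                       list(config.trait_names))


def residual_variance(config: SimulationConfig, kernel_diag_mean: float = 1.0
                      ) -> np.ndarray:
    """Per-(env, trait) residual variance implied by the heritability target.

    Entry-mean heritability h2 = sg2 / (sg2 + se2/r) inverted for se2 with
    sg2 the total (main + interaction) genetic variance of the cell.
    """
    sg_tot = kernel_diag_mean * np.outer(np.diag(config.Sigma_E) + 1.0,
                                         np.diag(config.Sigma_t))
    h2 = config.h2_target
    if np.any(h2 <= 0):
        raise ConfigurationError("h2_target must be positive")
    return config.n_reps * sg_tot * (1.0 - h2) / h2


def simulate_trials(true_effects: TrueEffects, config: SimulationConfig
                    ) -> PhenotypeTable:
    """Expand true cell values into replicated, blocked plot records."""
    if config.n_reps < 1 or config.n_blocks_per_rep < 1:
        raise ConfigurationError("replication/block counts must be positive")
    rng = _rng(config.seed, "trials")
    n, m, t = config.n_lines, config.n_envs, config.n_traits
    cell = true_effects.total_value()          # lines x envs x traits
    sig_eps = residual_variance(config)        # envs x traits
    gvar = np.outer(np.diag(config.Sigma_E) + 1.0, np.diag(config.Sigma_t))
    sig_rep = config.rep_var_frac * gvar
    sig_block = config.block_var_frac * gvar

    rows = []
    for e, env in enumerate(true_effects.env_labels):
        rep_eff = rng.normal(0.0, np.sqrt(sig_rep[e])[None, :],
                             size=(config.n_reps, t))
        for r in range(config.n_reps):
            # randomised incomplete blocks: fresh line permutation per replicate
            order = rng.permutation(n)
            block_of = np.empty(n, dtype=int)
            block_of[order] = np.arange(n) % config.n_blocks_per_rep
            blk_eff = rng.normal(0.0, np.sqrt(sig_block[e])[None, :],
                                 size=(config.n_blocks_per_rep, t))
            noise = rng.normal(0.0, np.sqrt(sig_eps[e])[None, :], size=(n, t))
            values = (cell[:, e, :] + rep_eff[r][None, :]
                      + blk_eff[block_of] + noise)
            for i, line in enumerate(true_effects.line_ids):
                for k, trait in enumerate(true_effects.trait_names):
                    rows.append((line, env, r + 1, block_of[i] + 1, trait,
                                 values[i, k]))
    df = pd.DataFrame(rows, columns=["line", "env", "rep", "block", "trait", "value"])
    if config.missing_rate > 0:
        mrng = _rng(config.seed, "missing")
        keep = mrng.random(len(df)) >= config.missing_rate
        df = df.loc[keep]
    return PhenotypeTable(df)
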