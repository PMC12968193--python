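"""Site-regression (SREG) decomposition and GGE-biplot quantities.

For one trait's line x environment table of adjusted means, centring each
environment column removes the environment main effect; the singular value
decomposition of what remains (genotype main effect plus genotype x
environment interaction, "G+GE") gives the biplot scores.  The fraction of
G+GE variation on the first two components is (l1^2 + l2^2) / sum(l_k^2).

Missing cells are completed beforehand by iterative low-rank SVD
approximation (rank 2 by default, matching the two-component biplot), with
plain column-mean imputation available as a single-shot fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GxETable", "BiplotResult", "impute_missing", "sreg_decompose"]


@dataclass
class GxETable:
    """Lines x environments adjusted means for one trait (NaN = missing)."""

    values: np.ndarray
    line_ids: list[str]
    env_ids: list[str]
    trait: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.line_ids), len(self.env_ids)):
            raise ValueError("table shape does not match labels")
        if len(self.env_ids) < 2:
            raise ValueError("need at least 2 environments")

    @classmethod
    def from_blues(cls, blues, trait: str) -> "GxETable":
        frame = blues.matrix(trait)
        return cls(frame.to_numpy(), list(frame.index), list(frame.columns), trait)


@dataclass
class BiplotResult:
    genotype_scores: np.ndarray     # lines x 2
    env_scores: np.ndarray          # envs x 2
    singular_values: np.ndarray     # all components, decreasing
    variance_fraction: float        # first two components' share of G+GE
    line_ids: list[str]
    env_ids: list[str]
    trait: str = ""

    def scores_frame(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        g = pd.DataFrame(self.genotype_scores, index=self.line_ids,
                         columns=["PC1", "PC2"])
        e = pd.DataFrame(self.env_scores, index=self.env_ids,
                         columns=["PC1", "PC2"])
        return g, e


def impute_missing(table: GxETable, rank: int = 2, tol: float = 1e-6,
                   max_iter: int = 500) -> GxETable:
    """Complete missing cells by iterative rank-``rank`` SVD approximation.

    Missing cells start at their column means; each iteration replaces them
    with the rank-r reconstruction of the current matrix until the largest
    absolute change drops below ``tol``.
    """
    x = table.values.copy()
    miss = np.isnan(x)
    if not miss.any():
        return table
    dead_cols = np.nonzero(miss.all(axis=0))[0]
    if dead_cols.size:
        raise ValueError("environment(s) fully missing: "
                         f"{[table.env_ids[j] for j in dead_cols]}")
    if miss.all(axis=1).any():
        dead = [table.line_ids[i] for i in np.nonzero(miss.all(axis=1))[0]]
        raise ValueError(f"line(s) fully missing: {dead}")

    col_means = np.nanmean(x, axis=0)
    x[miss] = np.take(col_means, np.nonzero(miss)[1])
    for _ in range(max_iter):
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        recon = (u[:, :rank] * s[:rank]) @ vt[:rank]
        delta = np.max(np.abs(recon[miss] - x[miss]))
        x[miss] = recon[miss]
        if delta < tol:
            break
    return GxETable(x, list(table.line_ids), list(table.env_ids), table.trait)


def sreg_decompose(table: GxETable, scaling: str = "genotype",
                   env_standardize: bool = False) -> BiplotResult:
    """SREG/GGE decomposition of a complete line x environment table.

    Each environment column is centred (removing the environment main
    effect); the SVD of the remainder yields genotype and environment
    scores.  ``scaling``: "genotype" puts the singular values on the
    genotype scores (default), "symmetric" splits them as sqrt between both
    sets.  Sign convention: within each component, the largest-magnitude
    environment loading is positive.
    """
    x = table.values
    if np.isnan(x).any():
        raise ValueError("table has missing cells; run impute_missing first")
    centered = x - x.mean(axis=0, keepdims=True)
    if env_standardize:
        sd = centered.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance environment; cannot standardize")
        centered = centered / sd
    if np.allclose(centered, 0.0):
        raise ValueError("zero-variance table: nothing to decompose")

    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # fix signs so each component's dominant environment loading is positive
    for k in range(len(s)):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0

    s2 = s**2
    frac = float(s2[:2].sum() / s2.sum())
    if scaling == "genotype":
        gscores = u[:, :2] * s[:2]
        escores = vt[:2].T
    elif scaling == "symmetric":
        gscores = u[:, :2] * np.sqrt(s[:2])
        escores = vt[:2].T * np.sqrt(s[:2])
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    if len(s) < 2:  # a single environment pair can yield one component
        pad = np.zeros((gscores.shape[0], 2 - gscores.shape[1]))
        gscores = np.hstack([gscores, pad])
        escores = np.hstack([escores, np.zeros((escores.shape[0], 2 - escores.shape[1]))])
    return BiplotResult(gscores, escores, s, frac,
                        list(table.line_ids), list(table.env_ids), table.trait)
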