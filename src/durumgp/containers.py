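"""Shared data containers for the genomic-prediction workflow.

The containers are deliberately thin: labelled numpy arrays plus the
invariants each stage relies on (unique line IDs, consistent axis labels,
symmetric PSD kernels).  Everything serialises to tidy CSV so intermediate
results stay inspectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PHENO_COLUMNS = ["line", "env", "rep", "block", "trait", "value"]


class ValidationError(ValueError):
    """Raised when a container invariant is violated."""


def _check_unique(labels, what: str) -> list:
    labels = list(labels)
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")
    return labels


@dataclass
class GenotypeMatrix:
    """Lines x markers dosage matrix coded 0/1/2 with NaN for missing calls."""

    dosages: np.ndarray
    line_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.line_ids = _check_unique(self.line_ids, "line IDs")
        self.marker_ids = _check_unique(self.marker_ids, "marker IDs")
        if self.dosages.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        observed = self.dosages[~np.isnan(self.dosages)]
        bad = observed[~np.isin(observed, (0.0, 1.0, 2.0))]
        if bad.size:
            rows, cols = np.nonzero(
                ~np.isnan(self.dosages) & ~np.isin(self.dosages, (0.0, 1.0, 2.0))
            )
            raise ValidationError(
                "dosages outside {0,1,2}: first offender at "
                f"line {self.line_ids[rows[0]]!r}, marker {self.marker_ids[cols[0]]!r} "
                f"(value {self.dosages[rows[0], cols[0]]!r})"
            )

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=pd.Index(self.line_ids, name="line"),
                            columns=self.marker_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        return cls(df.to_numpy(dtype=float), [str(i) for i in df.index],
                   [str(c) for c in df.columns])


@dataclass
class TargetGeneTable:
    """Categorical allele calls for a handful of characterised genes.

    ``alleles`` maps each gene to its declared allele set; every observed
    label must come from that set.
    """

    calls: pd.DataFrame  # index = line IDs, columns = gene names
    alleles: dict[str, list[str]]

    def __post_init__(self) -> None:
        _check_unique(self.calls.index, "line IDs")
        for gene in self.calls.columns:
            if gene not in self.alleles:
                raise ValidationError(f"gene {gene!r} has no declared allele set")
            observed = set(self.calls[gene].dropna().astype(str))
            extra = observed - set(self.alleles[gene])
            if extra:
                raise ValidationError(
                    f"gene {gene!r}: labels {sorted(extra)} outside declared alleles"
                )

    @property
    def line_ids(self) -> list[str]:
        return [str(i) for i in self.calls.index]

    @property
    def gene_names(self) -> list[str]:
        return [str(c) for c in self.calls.columns]


class PhenotypeTable:
    """Plot-level phenotype records: line, env, rep, block(rep), trait, value."""

    def __init__(self, records: pd.DataFrame):
        missing = [c for c in PHENO_COLUMNS if c not in records.columns]
        if missing:
            raise ValidationError(f"phenotype table missing columns: {missing}")
        df = records.loc[:, PHENO_COLUMNS].copy()
        df["line"] = df["line"].astype(str)
        df["env"] = df["env"].astype(str)
        df["trait"] = df["trait"].astype(str)
        df["value"] = pd.to_numeric(df["value"], errors="raise")
        key = ["line", "env", "rep", "trait"]
        dup = df.duplicated(subset=key, keep=False)
        if dup.any():
            offender = df.loc[dup, key].iloc[0].tolist()
            raise ValidationError(
                f"duplicate plot record for (line, env, rep, trait) = {tuple(offender)}"
            )
        self.records = df.reset_index(drop=True)

    @property
    def line_ids(self) -> list[str]:
        return sorted(self.records["line"].unique())

    @property
    def env_ids(self) -> list[str]:
        return sorted(self.records["env"].unique())

    @property
    def trait_names(self) -> list[str]:
        return sorted(self.records["trait"].unique())

    def subset(self, trait: str, env: str) -> pd.DataFrame:
        mask = (self.records["trait"] == trait) & (self.records["env"] == env)
        return self.records.loc[mask]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class Kernel:
    """Symmetric PSD line x line relationship matrix (G or G2)."""

    matrix: np.ndarray
    line_ids: list[str]
    provenance: str = "G"
    min_eigenvalue: float = field(default=np.nan)
    jitter: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.line_ids = _check_unique(self.line_ids, "line IDs")
        n = len(self.line_ids)
        if self.matrix.shape != (n, n):
            raise ValidationError(
                f"kernel shape {self.matrix.shape} does not match {n} line IDs"
            )
        asym = np.max(np.abs(self.matrix - self.matrix.T)) if n else 0.0
        if asym > 1e-10:
            raise ValidationError(f"kernel asymmetric beyond tolerance: {asym:.3e}")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def reindex(self, line_ids: list[str]) -> "Kernel":
        """Return the kernel restricted/reordered to ``line_ids``."""
        pos = {l: i for i, l in enumerate(self.line_ids)}
        missing = [l for l in line_ids if l not in pos]
        if missing:
            raise ValidationError(f"lines absent from kernel: {missing[:5]}")
        idx = np.array([pos[l] for l in line_ids])
        return Kernel(self.matrix[np.ix_(idx, idx)], list(line_ids),
                      self.provenance, self.min_eigenvalue, self.jitter)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=pd.Index(self.line_ids, name="line"),
                            columns=self.line_ids)


class BlueSet:
    """Adjusted means as a lines x environments x traits array with NaN mask."""

    def __init__(self, values: np.ndarray, line_ids, env_ids, trait_names,
                 se: np.ndarray | None = None):
        self.values = np.asarray(values, dtype=float)
        self.line_ids = _check_unique(line_ids, "line IDs")
        self.env_ids = _check_unique(env_ids, "environment IDs")
        self.trait_names = _check_unique(trait_names, "trait names")
        shape = (len(self.line_ids), len(self.env_ids), len(self.trait_names))
        if self.values.shape != shape:
            raise ValidationError(f"BLUE array shape {self.values.shape} != {shape}")
        self.se = None if se is None else np.asarray(se, dtype=float)
        if self.se is not None and self.se.shape != shape:
            raise ValidationError("standard-error array shape mismatch")

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell is observed."""
        return ~np.isnan(self.values)

    def copy(self) -> "BlueSet":
        return BlueSet(self.values.copy(), list(self.line_ids), list(self.env_ids),
                       list(self.trait_names),
                       None if self.se is None else self.se.copy())

    def matrix(self, trait: str) -> pd.DataFrame:
        """Lines x environments table for one trait."""
        t = self.trait_names.index(trait)
        return pd.DataFrame(self.values[:, :, t],
                            index=pd.Index(self.line_ids, name="line"),
                            columns=self.env_ids)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, line in enumerate(self.line_ids):
            for j, env in enumerate(self.env_ids):
                for k, trait in enumerate(self.trait_names):
                    v = self.values[i, j, k]
                    if np.isnan(v):
                        continue
                    rows.append({
                        "line": line, "env": env, "trait": trait, "blue": v,
                        "se": np.nan if self.se is None else self.se[i, j, k],
                    })
        return pd.DataFrame(rows, columns=["line", "env", "trait", "blue", "se"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BlueSet":
        lines = sorted(df["line"].astype(str).unique())
        envs = sorted(df["env"].astype(str).unique())
        traits = sorted(df["trait"].astype(str).unique())
        shape = (len(lines), len(envs), len(traits))
        values = np.full(shape, np.nan)
        se = np.full(shape, np.nan)
        li = {l: i for i, l in enumerate(lines)}
        ei = {e: j for j, e in enumerate(envs)}
        ti = {t: k for k, t in enumerate(traits)}
        for row in df.itertuples(index=False):
            i, j, k = li[str(row.line)], ei[str(row.env)], ti[str(row.trait)]
            values[i, j, k] = row.blue
            if hasattr(row, "se"):
                se[i, j, k] = row.se
        return cls(values, lines, envs, traits, se)
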