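"""Readers and writers for the tabular interchange formats.

Everything is CSV/TSV with a declared schema: phenotypes long
(line, env, rep, block, trait, value) or wide (one column per trait),
genotypes as line x marker dosage tables, kernels as square labelled
matrices, adjusted means as tidy (line, env, trait, blue, se) tables.
Genotypes can also come from a VCF (diploid, biallelic records).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (BlueSet, GenotypeMatrix, Kernel, PhenotypeTable,
                         TargetGeneTable, ValidationError, PHENO_COLUMNS)

logger = logging.getLogger(__name__)

__all__ = ["read_phenotypes", "write_phenotypes", "read_genotypes",
           "write_genotypes", "read_kernel", "write_kernel", "read_blues",
           "write_blues", "read_target_genes", "write_target_genes"]


def _sep(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a plot-level phenotype table, long or wide.

    A long table has a ``trait``/``value`` pair; a wide table has one
    numeric column per trait after the design columns and is melted.
    """
    df = pd.read_csv(path, sep=_sep(path))
    design = ["line", "env", "rep", "block"]
    missing = [c for c in design if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing mandatory columns {missing}")
    if "trait" in df.columns and "value" in df.columns:
        long = df[PHENO_COLUMNS]
    else:
        trait_cols = [c for c in df.columns if c not in design]
        if not trait_cols:
            raise ValidationError(f"{path}: no trait columns found")
        long = df.melt(id_vars=design, value_vars=trait_cols,
                       var_name="trait", value_name="value")
    bad = pd.to_numeric(long["value"], errors="coerce").isna() & long["value"].notna()
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise ValidationError(
            f"{path}: unparseable numeric value {long['value'].iloc[row]!r} "
            f"at row {row}")
    long = long.dropna(subset=["value"])
    return PhenotypeTable(long)


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.records.to_csv(path, sep=_sep(path), index=False)


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read a dosage matrix from CSV/TSV (first column = line ID, header =
    marker IDs) or a VCF (``format='vcf'`` or a .vcf/.vcf.gz suffix)."""
    fmt = format or ("vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "table")
    if fmt == "vcf":
        return _read_vcf(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    arr = df.to_numpy(dtype=float)
    observed = arr[~np.isnan(arr)]
    bad = ~np.isin(observed, (0.0, 1.0, 2.0))
    if bad.any():
        rows, cols = np.nonzero(~np.isnan(arr) & ~np.isin(arr, (0.0, 1.0, 2.0)))
        raise ValidationError(
            f"{path}: dosage {arr[rows[0], cols[0]]!r} outside {{0,1,2}} at "
            f"line {df.index[rows[0]]!r}, marker {df.columns[cols[0]]!r}")
    return GenotypeMatrix.from_frame(df)


def _read_vcf(path: str | Path) -> GenotypeMatrix:
    """Diploid biallelic VCF -> dosage matrix; multi-allelic records skipped."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, ids = [], []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped += 1
            continue
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = np.asarray(rec.gt_types, dtype=float)
        dosage = np.where(gt == 0, 0.0,
                          np.where(gt == 1, 1.0,
                                   np.where(gt == 3, 2.0, np.nan)))
        rows.append(dosage)
        ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
    if n_skipped:
        logger.info("read_genotypes: skipped %d multi-allelic VCF records",
                    n_skipped)
    if not rows:
        raise ValidationError(f"{path}: no usable biallelic records")
    return GenotypeMatrix(np.asarray(rows).T, samples, ids)


def write_genotypes(geno: GenotypeMatrix, path: str | Path) -> None:
    geno.to_frame().to_csv(path, sep=_sep(path))


def read_kernel(path: str | Path, provenance: str = "G") -> Kernel:
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if list(df.index.astype(str)) != list(map(str, df.columns)):
        raise ValidationError(f"{path}: kernel row/column labels differ")
    return Kernel(df.to_numpy(dtype=float), [str(i) for i in df.index], provenance)


def write_kernel(kernel: Kernel, path: str | Path) -> None:
    kernel.to_frame().to_csv(path, sep=_sep(path))


def read_blues(path: str | Path) -> BlueSet:
    df = pd.read_csv(path, sep=_sep(path))
    need = {"line", "env", "trait", "blue"}
    if not need.issubset(df.columns):
        raise ValidationError(f"{path}: BLUE table needs columns {sorted(need)}")
    if "se" not in df.columns:
        df["se"] = np.nan
    return BlueSet.from_frame(df)


def write_blues(blues: BlueSet, path: str | Path) -> None:
    blues.to_frame().to_csv(path, sep=_sep(path), index=False)


def read_target_genes(path: str | Path) -> TargetGeneTable:
    df = pd.read_csv(path, sep=_sep(path), index_col=0, dtype=str)
    alleles = {g: sorted(df[g].dropna().unique()) for g in df.columns}
    return TargetGeneTable(df, alleles)


def write_target_genes(genes: TargetGeneTable, path: str | Path) -> None:
    genes.calls.to_csv(path, sep=_sep(path))
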