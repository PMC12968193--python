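"""Genomic relationship kernels.

``vanraden_g`` builds the genome-wide additive kernel from SNP dosages:
G = ZZ' / (2 * sum_i p_i (1 - p_i)) with Z the allele-frequency-centred
dosage matrix.  ``target_gene_g2`` applies the same centring-and-scaling to a
one-hot encoding of categorical allele calls at a few characterised genes
(vernalisation, photoperiod, dwarfing loci), which reduces exactly to the
genome-wide formula when a gene is biallelic.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import Kernel, GenotypeMatrix, TargetGeneTable

logger = logging.getLogger(__name__)

__all__ = ["vanraden_g", "target_gene_g2", "validate_kernel", "KernelError"]


class KernelError(ValueError):
    """Raised when a kernel cannot be constructed or validated."""


def _scaled_cross_product(centered: np.ndarray, denom: float, line_ids,
                          provenance: str) -> Kernel:
    g = centered @ centered.T / denom
    g = 0.5 * (g + g.T)  # symmetrise rounding noise
    return validate_kernel(Kernel(g, list(line_ids), provenance))


def vanraden_g(genotypes: GenotypeMatrix, max_missing: float = 0.2,
               min_maf: float = 0.01) -> Kernel:
    """Genome-wide additive relationship kernel from 0/1/2 dosages.

    Missing dosages are imputed to the marker mean; markers with missing
    fraction above ``max_missing`` or minor-allele frequency below
    ``min_maf`` are dropped (monomorphic markers always are).
    """
    if genotypes.n_lines < 2:
        raise KernelError("need at least 2 lines")
    x = genotypes.dosages.copy()
    miss_frac = np.isnan(x).mean(axis=0)
    col_mean = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
    p = col_mean / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = (miss_frac <= max_missing) & (maf >= min_maf) & (maf > 0.0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("vanraden_g: dropped %d of %d markers (missingness/MAF filters)",
                    n_dropped, genotypes.n_markers)
    if not keep.any():
        raise KernelError("no polymorphic marker survives filtering")
    x, p = x[:, keep], p[keep]
    # marker-mean imputation before centring
    idx = np.nonzero(np.isnan(x))
    x[idx] = (2.0 * p)[idx[1]]
    z = x - 2.0 * p[None, :]
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    return _scaled_cross_product(z, denom, genotypes.line_ids, "G")


def _one_hot(labels: np.ndarray, classes: list[str]) -> np.ndarray:
    return (labels[:, None] == np.asarray(classes)[None, :]).astype(float)


def target_gene_g2(genes: TargetGeneTable, joint: bool = False) -> Kernel:
    """Allelic kernel from target-gene calls.

    Each gene's observed allele classes become indicator columns on the
    homozygous-dosage scale (an inbred line carries 0 or 2 copies of a
    class), and the genome-wide centring-and-scaling formula is applied
    literally to that matrix.  A biallelic gene therefore reduces exactly to
    the genome-wide kernel of its 0/2 dosage recoding.  With ``joint=True`` a
    single categorical factor over the observed multi-gene allele
    combinations is encoded instead of one factor per gene.
    """
    calls = genes.calls.astype(str)
    if joint:
        combo = calls.apply(lambda r: "|".join(r.values), axis=1).to_numpy()
        factors = [combo]
    else:
        factors = [calls[g].to_numpy() for g in calls.columns]

    blocks, freqs = [], []
    for labels in factors:
        classes = sorted(set(labels))
        if len(classes) < 2:
            continue  # a monomorphic gene carries no relationship information
        h = 2.0 * _one_hot(labels, classes)   # allele-copy dosage, inbred
        f = h.mean(axis=0) / 2.0              # class frequency
        blocks.append(h - 2.0 * f[None, :])
        freqs.append(f)
    if not blocks:
        raise KernelError("all target genes are monomorphic")
    z = np.hstack(blocks)
    f = np.concatenate(freqs)
    denom = 2.0 * float(np.sum(f * (1.0 - f)))
    return _scaled_cross_product(z, denom, genes.line_ids, "G2")


_JITTER_LADDER = (1e-8, 1e-6, 1e-4)


def validate_kernel(kernel: Kernel, jitter_cap: float = 1e-4) -> Kernel:
    """Check symmetry and positive semi-definiteness, jittering if needed.

    A minimum eigenvalue below -1e-8 triggers the smallest diagonal jitter
    from {1e-8, 1e-6, 1e-4} (bounded by ``jitter_cap``) that restores PSD;
    the jitter and the final minimum eigenvalue are recorded on the kernel.
    """
    mat = kernel.matrix
    asym = float(np.max(np.abs(mat - mat.T))) if mat.size else 0.0
    if asym > 1e-10:
        raise KernelError(f"kernel asymmetric beyond 1e-10: {asym:.3e}")
    min_eig = float(np.linalg.eigvalsh(mat).min())
    tol = -1e-8
    if min_eig >= tol:
        return Kernel(mat, kernel.line_ids, kernel.provenance, min_eig, 0.0)
    for jit in _JITTER_LADDER:
        if jit > jitter_cap:
            break
        cand = mat + jit * np.eye(mat.shape[0])
        cand_min = float(np.linalg.eigvalsh(cand).min())
        if cand_min >= tol:
            logger.warning("validate_kernel: applied diagonal jitter %.0e "
                           "(min eigenvalue %.3e -> %.3e)", jit, min_eig, cand_min)
            return Kernel(cand, kernel.line_ids, kernel.provenance, cand_min, jit)
    raise KernelError(
        f"kernel not PSD (min eigenvalue {min_eig:.3e}) and jitter ladder "
        f"up to {jitter_cap:.0e} could not repair it")
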