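#!/usr/bin/env python
"""Build the genome-wide (G) and target-gene (G2) relationship kernels.

Reads results/data/genotypes.csv and target_genes.csv, writes
results/kernel_G.csv and results/kernel_G2.csv with PSD diagnostics.
"""

import argparse
from pathlib import Path

import numpy as np

from durumgp import io as io_mod
from durumgp.kernels import target_gene_g2, vanraden_g


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    geno = io_mod.read_genotypes(args.data / "genotypes.csv")
    genes = io_mod.read_target_genes(args.data / "target_genes.csv")
    g = vanraden_g(geno)
    g2 = target_gene_g2(genes)
    args.out.mkdir(parents=True, exist_ok=True)
    io_mod.write_kernel(g, args.out / "kernel_G.csv")
    io_mod.write_kernel(g2, args.out / "kernel_G2.csv")

    for name, k in (("G", g), ("G2", g2)):
        off = k.matrix[np.triu_indices(k.n_lines, 1)]
        print(f"{name}: {k.n_lines} lines | mean diagonal "
              f"{np.mean(np.diag(k.matrix)):.3f} | off-diagonal sd "
              f"{off.std():.3f} | min eigenvalue {k.min_eigenvalue:.2e} | "
              f"jitter {k.jitter:g}")
    print(f"wrote {args.out}/kernel_G.csv and kernel_G2.csv")


if __name__ == "__main__":
    main()
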