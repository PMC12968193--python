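#!/usr/bin/env python
"""SREG/GGE biplot analysis of each trait's line x environment BLUE table.

Centres out the environment main effects, decomposes the remaining G+GE
variation, reports the share carried by the first two components, and draws
one biplot per trait under results/figures/.
"""

import argparse
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from durumgp import io as io_mod
from durumgp.sreg import GxETable, impute_missing, sreg_decompose


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--blues", type=Path, default=Path("results/blues.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    blues = io_mod.read_blues(args.blues)
    figdir = args.out / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for trait in blues.trait_names:
        table = impute_missing(GxETable.from_blues(blues, trait))
        bip = sreg_decompose(table)
        rows.append({"trait": trait,
                     "pct_first2": 100 * bip.variance_fraction})
        g, e = bip.scores_frame()
        g.assign(kind="genotype").to_csv(
            args.out / f"sreg_scores_{trait}.csv")

        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(g.PC1, g.PC2, s=8, alpha=0.5, label="lines")
        for env, row in e.iterrows():
            scale = 0.9 * max(g.PC1.abs().max(), g.PC2.abs().max()) \
                / max(e.PC1.abs().max(), e.PC2.abs().max())
            ax.annotate(env, (row.PC1 * scale, row.PC2 * scale), fontsize=7)
            ax.plot([0, row.PC1 * scale], [0, row.PC2 * scale],
                    color="tab:red", lw=0.8)
        ax.axhline(0, lw=0.4, color="gray")
        ax.axvline(0, lw=0.4, color="gray")
        ax.set_xlabel("component 1")
        ax.set_ylabel("component 2")
        ax.set_title(f"{trait}: G+GE biplot "
                     f"({100 * bip.variance_fraction:.1f}% on 2 components)")
        fig.tight_layout()
        fig.savefig(figdir / f"sreg_{trait}.svg")
        plt.close(fig)

    summary = pd.DataFrame(rows)
    summary.to_csv(args.out / "sreg_variance_fractions.csv", index=False)
    print("share of G+GE variation on the first two components:")
    print(summary.round(1).to_string(index=False))
    print(f"\nbiplots under {figdir}/")


if __name__ == "__main__":
    main()
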