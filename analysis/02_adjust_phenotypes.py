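#!/usr/bin/env python
"""Adjust plot-level data to per-environment BLUEs; report variance
components, entry-mean heritabilities and trait/environment correlations.

Reads results/data/phenotypes.csv (from 01_simulate_trial.py), writes
results/blues.csv, results/heritability.csv, results/trait_correlations.csv
and results/env_correlations_<trait>.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from durumgp import io as io_mod
from durumgp.adjust import (compute_all_blues, env_correlations,
                            trait_correlations)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--pheno", type=Path, default=Path("results/data/phenotypes.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    pheno = io_mod.read_phenotypes(args.pheno)
    blues, summary = compute_all_blues(pheno)
    args.out.mkdir(parents=True, exist_ok=True)
    io_mod.write_blues(blues, args.out / "blues.csv")
    summary.to_csv(args.out / "heritability.csv", index=False)

    h2 = summary.groupby("trait")["h2"].agg(["min", "max"]).round(3)
    print("entry-mean heritability by trait (range over environments):")
    print(h2.to_string())

    corr_frames = [trait_correlations(blues, env) for env in blues.env_ids]
    corr = pd.concat(corr_frames, ignore_index=True)
    corr.to_csv(args.out / "trait_correlations.csv", index=False)
    off = corr[corr.trait_a != corr.trait_b]
    print("\nstrongest trait correlations across environments:")
    print(off.nlargest(3, "r")[["env", "trait_a", "trait_b", "r", "stars"]]
          .round(3).to_string(index=False))

    for trait in blues.trait_names:
        table, order = env_correlations(blues, trait)
        table.loc[order, order].to_csv(
            args.out / f"env_correlations_{trait}.csv")
    print(f"\nwrote BLUEs and correlation tables under {args.out}/")


if __name__ == "__main__":
    main()
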