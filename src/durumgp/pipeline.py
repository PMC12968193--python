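"""End-to-end pipeline: phenotypes -> BLUEs -> kernels -> cross-validated
model grid -> ranking -> SREG, with a run manifest and per-stage resume.

A stage is skipped when its output files already exist with the checksums
recorded in the manifest; deleting an output re-runs just that stage.  All
randomness is governed by the single seed in the configuration, so reruns
are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import adjust, cv as cv_mod, io as io_mod, kernels as kern_mod, sreg as sreg_mod
from .models import MCMCSettings, ModelSpec
from .containers import BlueSet
from .synth import SimulationConfig, simulate_genotypes, simulate_target_genes, \
    simulate_true_effects, simulate_trials
from .kernels import vanraden_g

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    out_dir: str
    pheno: str | None = None
    geno: str | None = None
    target_genes: str | None = None
    envs: list[str] | None = None
    traits: list[str] | None = None
    models: list[str] = field(default_factory=lambda: ["SE", "MT", "ME", "MTME"])
    schemes: list[str] = field(default_factory=lambda: ["CV1", "CV2"])
    kernels: list[str] = field(default_factory=lambda: ["G"])
    n_folds: int = 5
    n_cycles: int = 10
    mcmc: dict = field(default_factory=dict)
    seed: int = 0
    top_n: int = 20
    simulate: dict | None = None     # SimulationConfig overrides, if simulating

    def __post_init__(self) -> None:
        if not self.models or not self.schemes or not self.kernels:
            raise ValueError("model/scheme/kernel grid must be non-empty")
        for p in (self.pheno, self.geno, self.target_genes):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if self.pheno is None and self.simulate is None:
            raise ValueError("either a phenotype file or a simulate block is required")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


@dataclass
class RunManifest:
    config: dict
    stages: dict = field(default_factory=dict)   # name -> {outputs, sha, seconds}
    warnings: list = field(default_factory=list)

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"config": self.config, "stages": self.stages,
             "warnings": self.warnings}, indent=2, default=str))

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        raw = json.loads(path.read_text())
        return cls(raw["config"], raw["stages"], raw.get("warnings", []))


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage_current(manifest: RunManifest, name: str, outputs: list[Path]) -> bool:
    rec = manifest.stages.get(name)
    if rec is None:
        return False
    if set(rec["outputs"]) != {str(p) for p in outputs}:
        return False
    return all(p.exists() and _sha(p) == rec["sha"][str(p)] for p in outputs)


def _record(manifest: RunManifest, name: str, outputs: list[Path],
            seconds: float) -> None:
    manifest.stages[name] = {
        "outputs": [str(p) for p in outputs],
        "sha": {str(p): _sha(p) for p in outputs},
        "seconds": round(seconds, 3),
    }


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute every stage of the analysis, resuming where outputs exist."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        manifest = RunManifest.load(manifest_path)
        manifest.config = config.__dict__.copy()
    else:
        manifest = RunManifest(config.__dict__.copy())

    def stage(name: str, outputs: list[Path], fn) -> None:
        if _stage_current(manifest, name, outputs):
            logger.info("stage %s: outputs current, skipping", name)
            return
        t0 = time.time()
        try:
            fn()
        except Exception:
            manifest.save(manifest_path)
            logger.error("stage %s failed; completed outputs preserved", name)
            raise
        _record(manifest, name, outputs, time.time() - t0)
        manifest.save(manifest_path)

    # ------------------------------------------------------------- simulate
    pheno_path = Path(config.pheno) if config.pheno else out / "phenotypes.csv"
    geno_path = Path(config.geno) if config.geno else out / "genotypes.csv"
    genes_path = Path(config.target_genes) if config.target_genes else out / "target_genes.csv"
    if config.simulate is not None:
        def do_sim() -> None:
            sim = SimulationConfig(seed=config.seed, **(config.simulate or {}))
            geno = simulate_genotypes(sim)
            genes = simulate_target_genes(sim)
            g = vanraden_g(geno)
            truth = simulate_true_effects(sim, g, genes)
            pheno = simulate_trials(truth, sim)
            io_mod.write_genotypes(geno, geno_path)
            io_mod.write_target_genes(genes, genes_path)
            io_mod.write_phenotypes(pheno, pheno_path)
        stage("simulate", [pheno_path, geno_path, genes_path], do_sim)

    # ---------------------------------------------------------------- blues
    blues_path = out / "blues.csv"
    h2_path = out / "variance_components.csv"
    def do_blues() -> None:
        pheno = io_mod.read_phenotypes(pheno_path)
        blues, summary = adjust.compute_all_blues(pheno)
        io_mod.write_blues(blues, blues_path)
        summary.to_csv(h2_path, index=False)
    stage("blues", [blues_path, h2_path], do_blues)

    # -------------------------------------------------------------- kernels
    kernel_paths = {}
    for kname in config.kernels:
        kernel_paths[kname] = out / f"kernel_{kname}.csv"
    def do_kernels() -> None:
        if "G" in config.kernels:
            geno = io_mod.read_genotypes(geno_path)
            io_mod.write_kernel(kern_mod.vanraden_g(geno), kernel_paths["G"])
        if "G2" in config.kernels:
            genes = io_mod.read_target_genes(genes_path)
            io_mod.write_kernel(kern_mod.target_gene_g2(genes), kernel_paths["G2"])
    stage("kernels", list(kernel_paths.values()), do_kernels)

    # ------------------------------------------------------------------- cv
    cv_path = out / "cv_results.csv"
    agg_path = out / "cv_aggregate.csv"
    def do_cv() -> None:
        blues = io_mod.read_blues(blues_path)
        envs = config.envs or blues.env_ids
        traits = config.traits or blues.trait_names
        mcmc = MCMCSettings(seed=config.seed, **config.mcmc)
        folds = cv_mod.make_folds(blues.line_ids, config.n_folds,
                                  config.n_cycles, config.seed)
        results = []
        for kname in config.kernels:
            kernel = io_mod.read_kernel(kernel_paths[kname], kname)
            for family in config.models:
                for scheme in config.schemes:
                    if family == "SE" and scheme != config.schemes[0]:
                        continue  # CV1 and CV2 coincide for the SE scope
                    spec = ModelSpec(family=family, kernel_name=kname, mcmc=mcmc)
                    for env in envs:
                        for trait in traits:
                            plan = cv_mod.build_mask(
                                folds, scheme, [env], [trait], blues,
                                scope_envs=envs, scope_traits=traits)
                            results.append(cv_mod.run_cv(spec, blues, kernel, plan))
        pd.concat([r.records for r in results], ignore_index=True) \
            .to_csv(cv_path, index=False)
        pd.concat([r.aggregate() for r in results], ignore_index=True) \
            .to_csv(agg_path, index=False)
    stage("cv", [cv_path, agg_path], do_cv)

    # -------------------------------------------------------------- ranking
    rank_path = out / "ranking.csv"
    def do_rank() -> None:
        records = pd.read_csv(cv_path)
        results = []
        for (model, scheme, kname), grp in records.groupby(
                ["model", "scheme", "kernel"]):
            results.append(cv_mod.CVResult(grp.reset_index(drop=True),
                                           f"{model}_{scheme}_{kname}"))
        cv_mod.rank_models(results, config.top_n).to_csv(rank_path, index=False)
    stage("ranking", [rank_path], do_rank)

    # ----------------------------------------------------------------- sreg
    sreg_path = out / "sreg_scores.csv"
    def do_sreg() -> None:
        blues = io_mod.read_blues(blues_path)
        rows = []
        for trait in (config.traits or blues.trait_names):
            table = sreg_mod.GxETable.from_blues(blues, trait)
            table = sreg_mod.impute_missing(table)
            bip = sreg_mod.sreg_decompose(table)
            g, e = bip.scores_frame()
            for frame, kind in ((g, "genotype"), (e, "environment")):
                for label, row in frame.iterrows():
                    rows.append({"trait": trait, "kind": kind, "id": label,
                                 "PC1": row.PC1, "PC2": row.PC2,
                                 "var_fraction_2pc": bip.variance_fraction})
        pd.DataFrame(rows).to_csv(sreg_path, index=False)
    stage("sreg", [sreg_path], do_sreg)

    manifest.save(manifest_path)
    return manifest
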