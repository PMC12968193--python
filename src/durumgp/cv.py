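"""CV1/CV2 cross-validation: fold construction, cell masking, cross-validated
model execution, prediction-ability computation and Top-N model ranking.

CV1 hides every cell of a test line within the model's scope (a brand-new,
never-phenotyped candidate).  CV2 hides only the target-trait cells of test
lines in the target environments, so the sampler still sees their
secondary-trait and other-environment records and can borrow strength
through Sigma_t / Sigma_E.  Prediction ability is the Pearson correlation
between predicted and observed BLUEs of the masked cells, computed per
environment per cycle by pooling the k folds of that cycle, then summarised
as mean and SD over cycles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BlueSet, Kernel
from .models import ModelSpec, fit_se, fit_mt, fit_me, fit_mtme, predict

logger = logging.getLogger(__name__)

__all__ = ["FoldAssignment", "MaskPlan", "CVResult", "make_folds",
           "build_mask", "masked_blues", "run_cv", "rank_models"]

SCHEMES = ("CV1", "CV2")


@dataclass
class FoldAssignment:
    """Per cycle, a partition of the line set into k near-equal folds."""

    folds: list[list[list[str]]]       # [cycle][fold] -> line IDs
    k: int
    n_cycles: int
    seed: int

    def test_lines(self, cycle: int, fold: int) -> list[str]:
        return self.folds[cycle][fold]


def make_folds(line_ids: list[str], k: int, n_cycles: int, seed: int
               ) -> FoldAssignment:
    """Independent uniformly-random k-fold partitions, one per cycle.

    Fold sizes differ by at most one; the remainder lines land one per fold
    in random order.
    """
    n = len(line_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available lines")
    rng = np.random.default_rng(seed)
    cycles = []
    for _ in range(n_cycles):
        perm = rng.permutation(n)
        sizes = np.full(k, n // k)
        extra = rng.permutation(k)[: n % k]
        sizes[extra] += 1
        folds, start = [], 0
        for s in sizes:
            folds.append([line_ids[i] for i in perm[start:start + s]])
            start += s
        cycles.append(folds)
    return FoldAssignment(cycles, k, n_cycles, seed)


@dataclass
class MaskPlan:
    """Which (line, env, trait) cells each (cycle, fold) hides from training."""

    scheme: str
    target_envs: list[str]
    target_traits: list[str]
    scope_envs: list[str]              # environments visible to the model
    scope_traits: list[str]            # traits visible to the model
    masks: dict[tuple[int, int], set[tuple[str, str, str]]] = field(default_factory=dict)
    folds: FoldAssignment | None = None


def build_mask(folds: FoldAssignment, scheme: str, target_envs: list[str],
               target_traits: list[str], blues: BlueSet,
               scope_envs: list[str] | None = None,
               scope_traits: list[str] | None = None) -> MaskPlan:
    """Translate fold memberships into hidden cells under CV1 or CV2.

    Cells already missing in the data stay missing and are never scored.
    A fold whose masking would leave a target environment with fewer than 2
    training lines (for any target trait) is rejected.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    scope_envs = list(scope_envs) if scope_envs is not None else list(blues.env_ids)
    scope_traits = (list(scope_traits) if scope_traits is not None
                    else list(blues.trait_names))
    for e in target_envs:
        if e not in blues.env_ids:
            raise KeyError(f"target environment {e!r} not in the BLUE set")
    for t in target_traits:
        if t not in blues.trait_names:
            raise KeyError(f"target trait {t!r} not in the BLUE set")
    li = {l: i for i, l in enumerate(blues.line_ids)}
    ei = {e: j for j, e in enumerate(blues.env_ids)}
    ti = {t: k_ for k_, t in enumerate(blues.trait_names)}

    if scheme == "CV1":
        mask_envs, mask_traits = scope_envs, scope_traits
    else:
        mask_envs, mask_traits = target_envs, target_traits

    plan = MaskPlan(scheme, list(target_envs), list(target_traits),
                    scope_envs, scope_traits, folds=folds)
    for c in range(folds.n_cycles):
        for f in range(folds.k):
            test = set(folds.test_lines(c, f))
            cells = {
                (l, e, t)
                for l in test for e in mask_envs for t in mask_traits
                if not np.isnan(blues.values[li[l], ei[e], ti[t]])
            }
            # training support check in every target environment
            for e in target_envs:
                for t in target_traits:
                    col = blues.values[:, ei[e], ti[t]]
                    n_train = sum(1 for l in blues.line_ids
                                  if not np.isnan(col[li[l]])
                                  and (l, e, t) not in cells)
                    if n_train < 2:
                        raise ValueError(
                            f"cycle {c} fold {f}: masking leaves environment "
                            f"{e!r} (trait {t!r}) with {n_train} training lines")
            plan.masks[(c, f)] = cells
    return plan


def masked_blues(blues: BlueSet, cells: set[tuple[str, str, str]]) -> BlueSet:
    """Copy of the BLUE set with the given cells hidden (set to NaN)."""
    out = blues.copy()
    li = {l: i for i, l in enumerate(out.line_ids)}
    ei = {e: j for j, e in enumerate(out.env_ids)}
    ti = {t: k_ for k_, t in enumerate(out.trait_names)}
    for (l, e, t) in cells:
        out.values[li[l], ei[e], ti[t]] = np.nan
    return out


@dataclass
class CVResult:
    """Tidy per-cycle prediction abilities plus aggregation helpers."""

    records: pd.DataFrame   # model, scheme, kernel, env, trait, cycle, r
    label: str

    def aggregate(self) -> pd.DataFrame:
        g = self.records.groupby(["model", "scheme", "kernel", "env", "trait"],
                                 dropna=False)
        agg = g["r"].agg(mean_r="mean", sd_r="std", n_cycles="count").reset_index()
        return agg

    def overall_mean(self) -> float:
        """Mean ability over environments (mean of per-environment means)."""
        agg = self.aggregate()
        return float(agg.groupby("env")["mean_r"].mean().mean())


def _default_fitter(spec: ModelSpec, blues_train: BlueSet, kernel: Kernel,
                    plan: MaskPlan, fit_seed: int):
    """Fit the spec's family on the training BLUEs; returns a predict callable."""
    spec_run = ModelSpec(
        family=spec.family, kernel_name=spec.kernel_name,
        df_scalar=spec.df_scalar,
        mcmc=type(spec.mcmc)(spec.mcmc.n_iter, spec.mcmc.burn_in,
                             spec.mcmc.thin, fit_seed),
        fix_variances=dict(spec.fix_variances),
        include_line_effect=spec.include_line_effect,
        separate_trait_cov=spec.separate_trait_cov,
        store_draws=False)
    fits = []
    if spec.family == "SE":
        for e in plan.target_envs:
            for t in plan.target_traits:
                fits.append(fit_se(blues_train, kernel, spec_run, e, t))
    elif spec.family == "MT":
        for e in plan.target_envs:
            fits.append(fit_mt(blues_train, kernel, spec_run, e,
                               plan.scope_traits))
    elif spec.family == "ME":
        for t in plan.target_traits:
            fits.append(fit_me(blues_train, kernel, spec_run, t,
                               plan.scope_envs))
    elif spec.family == "MTME":
        fits.append(fit_mtme(blues_train, kernel, spec_run,
                             plan.scope_envs, plan.scope_traits))

    def predict_cells(targets: list[tuple[str, str, str]]) -> np.ndarray:
        out = np.full(len(targets), np.nan)
        for fit in fits:
            e_set, t_set = set(fit.env_ids), set(fit.trait_names)
            idx = [q for q, (l, e, t) in enumerate(targets)
                   if e in e_set and t in t_set]
            if idx:
                out[idx] = predict(fit, [targets[q] for q in idx])
        return out

    return predict_cells


def run_cv(model_spec: ModelSpec, blues: BlueSet, kernel: Kernel,
           mask_plan: MaskPlan, fitter=None, label: str | None = None,
           per_fold: bool = False) -> CVResult:
    """Cross-validated prediction abilities for one model under one mask plan.

    ``fitter`` (for testing or custom models) replaces the default family
    dispatch; it receives (spec, training BlueSet, kernel, plan, fit_seed)
    and must return a callable mapping (line, env, trait) targets to
    predictions.  A fold whose fit fails is recorded as missing for its
    cycle, not a run abort.  With ``per_fold`` the correlation is computed
    per fold instead of pooling the folds of a cycle.
    """
    folds = mask_plan.folds
    if folds is None:
        raise ValueError("mask plan carries no fold assignment")
    fitter = fitter or _default_fitter
    li = {l: i for i, l in enumerate(blues.line_ids)}
    ei = {e: j for j, e in enumerate(blues.env_ids)}
    ti = {t: k_ for k_, t in enumerate(blues.trait_names)}
    label = label or f"{model_spec.label}_{mask_plan.scheme}"

    rows = []
    for c in range(folds.n_cycles):
        pooled: dict[tuple[str, str], list[tuple[float, float]]] = {}
        failed = False
        for f in range(folds.k):
            cells = sorted(mask_plan.masks[(c, f)])
            score_cells = [(l, e, t) for (l, e, t) in cells
                           if e in mask_plan.target_envs
                           and t in mask_plan.target_traits]
            if not score_cells:
                continue
            train = masked_blues(blues, mask_plan.masks[(c, f)])
            fit_seed = (model_spec.mcmc.seed * 1009 + c * folds.k + f) % (2**31 - 1)
            logger.info("%s: cycle %d fold %d (%d masked cells)",
                        label, c, f, len(cells))
            try:
                predict_cells = fitter(model_spec, train, kernel, mask_plan,
                                       fit_seed)
                preds = predict_cells(score_cells)
            except Exception as exc:  # a single fold failure is not fatal
                warnings.warn(f"{label}: cycle {c} fold {f} failed: {exc}")
                failed = True
                continue
            for (l, e, t), p in zip(score_cells, preds):
                obs = blues.values[li[l], ei[e], ti[t]]
                key = (e, t, f) if per_fold else (e, t)
                pooled.setdefault(key, []).append((p, obs))

        groups: dict[tuple[str, str], list] = {}
        for key, pairs in pooled.items():
            e, t = key[0], key[1]
            groups.setdefault((e, t), []).append(pairs)
        for e in mask_plan.target_envs:
            for t in mask_plan.target_traits:
                pair_sets = groups.get((e, t), [])
                rs = []
                for pairs in pair_sets:
                    arr = np.asarray(pairs)
                    if len(arr) < 3 or np.std(arr[:, 0]) == 0 or np.std(arr[:, 1]) == 0:
                        warnings.warn(
                            f"{label}: degenerate predictions in env {e}, trait "
                            f"{t}, cycle {c}; ability recorded as missing")
                        rs.append(np.nan)
                    else:
                        rs.append(stats.pearsonr(arr[:, 0], arr[:, 1]).statistic)
                r = float(np.nanmean(rs)) if rs and not np.all(np.isnan(rs)) else np.nan
                if failed and not pair_sets:
                    r = np.nan
                rows.append({"model": model_spec.family,
                             "scheme": mask_plan.scheme,
                             "kernel": model_spec.kernel_name,
                             "env": e, "trait": t, "cycle": c, "r": r})
    return CVResult(pd.DataFrame(rows), label)


def rank_models(results: list[CVResult], top_n: int = 20) -> pd.DataFrame:
    """Top-N table over (model, scheme, kernel, env, trait) combinations,
    sorted by mean ability, ties broken by smaller SD then label."""
    if not results:
        raise ValueError("no results to rank")
    frames = []
    for res in results:
        agg = res.aggregate()
        # label grammar: scheme suffix except for SE (where CV1/CV2 coincide),
        # kernel suffix only for the non-default G2 kernel
        agg["label"] = [
            "_".join([row.model]
                     + ([row.scheme] if row.model != "SE" else [])
                     + ([row.kernel] if row.kernel == "G2" else []))
            for row in agg.itertuples()]
        frames.append(agg)
    table = pd.concat(frames, ignore_index=True)
    table["sd_r"] = table["sd_r"].fillna(np.inf)
    table = table.sort_values(["mean_r", "sd_r", "label", "env", "trait"],
                              ascending=[False, True, True, True, True],
                              kind="mergesort").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table.loc[table["sd_r"] == np.inf, "sd_r"] = np.nan
    return table.head(top_n)
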