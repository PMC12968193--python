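"""Cross-validation: folds, masking, leakage, scoring, ranking."""

import numpy as np
import pandas as pd
import pytest

from durumgp.containers import BlueSet, Kernel
from durumgp.cv import (CVResult, build_mask, make_folds, masked_blues,
                        rank_models, run_cv)
from durumgp.models import ModelSpec, MCMCSettings


def _blues(n_lines=20, envs=("E1", "E2"), traits=("A", "B"), seed=0):
    rng = np.random.default_rng(seed)
    vals = rng.normal(size=(n_lines, len(envs), len(traits)))
    return BlueSet(vals, [f"L{i:03d}" for i in range(n_lines)],
                   list(envs), list(traits))


class TestFolds:
    def test_186_lines_into_5_folds(self):
        folds = make_folds([f"L{i}" for i in range(186)], 5, 1, 0)
        sizes = sorted(len(f) for f in folds.folds[0])
        assert sizes == [37, 37, 37, 37, 38]

    def test_partition_property_every_cycle(self):
        lines = [f"L{i}" for i in range(47)]
        folds = make_folds(lines, 5, 4, 3)
        for cycle in folds.folds:
            flat = [l for fold in cycle for l in fold]
            assert sorted(flat) == sorted(lines)
            assert len(set(flat)) == len(flat)

    def test_cycles_differ_but_reruns_are_identical(self):
        lines = [f"L{i}" for i in range(40)]
        a = make_folds(lines, 4, 2, 9)
        b = make_folds(lines, 4, 2, 9)
        assert a.folds == b.folds
        assert a.folds[0] != a.folds[1]

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b", "c"], 5, 1, 0)


class TestMasks:
    def test_cv1_masks_all_cells_of_test_lines(self):
        blues = _blues()
        folds = make_folds(blues.line_ids, 4, 1, 0)
        plan = build_mask(folds, "CV1", ["E1"], ["A"], blues)
        for f in range(4):
            test = set(folds.test_lines(0, f))
            cells = plan.masks[(0, f)]
            assert {l for (l, _, _) in cells} == test
            for l in test:  # whole scope hidden, both envs and traits
                assert {(l, e, t) for e in blues.env_ids
                        for t in blues.trait_names} <= cells

    def test_cv2_keeps_secondary_cells_observed(self):
        blues = _blues()
        folds = make_folds(blues.line_ids, 4, 1, 0)
        plan = build_mask(folds, "CV2", ["E1"], ["A"], blues)
        cells = plan.masks[(0, 0)]
        assert all(e == "E1" and t == "A" for (_, e, t) in cells)
        test = folds.test_lines(0, 0)
        train = masked_blues(blues, cells)
        i = train.line_ids.index(test[0])
        assert np.isnan(train.values[i, 0, 0])        # target cell hidden
        assert not np.isnan(train.values[i, 0, 1])    # secondary trait kept
        assert not np.isnan(train.values[i, 1, 0])    # other environment kept

    def test_cv2_mask_count_equals_fold_size(self):
        blues = _blues(n_lines=30)
        folds = make_folds(blues.line_ids, 5, 2, 1)
        plan = build_mask(folds, "CV2", ["E2"], ["B"], blues)
        for (c, f), cells in plan.masks.items():
            assert len(cells) == len(folds.test_lines(c, f))

    def test_already_missing_cells_stay_out_of_the_mask(self):
        blues = _blues(n_lines=12)
        blues.values[0, 0, 0] = np.nan
        folds = make_folds(blues.line_ids, 3, 1, 5)
        plan = build_mask(folds, "CV2", ["E1"], ["A"], blues)
        line0 = blues.line_ids[0]
        for cells in plan.masks.values():
            assert (line0, "E1", "A") not in cells

    def test_no_leakage_into_training_structures(self):
        """Every masked cell must be NaN in the BlueSet handed to a sampler,
        for every scheme and model scope."""
        blues = _blues(n_lines=15)
        folds = make_folds(blues.line_ids, 3, 1, 2)
        li = {l: i for i, l in enumerate(blues.line_ids)}
        ei = {e: j for j, e in enumerate(blues.env_ids)}
        ti = {t: k for k, t in enumerate(blues.trait_names)}
        for scheme in ("CV1", "CV2"):
            for scope_envs, scope_traits in [
                    (["E1"], ["A"]),                 # SE scope
                    (["E1"], ["A", "B"]),            # MT scope
                    (["E1", "E2"], ["A"]),           # ME scope
                    (["E1", "E2"], ["A", "B"])]:     # MTME scope
                plan = build_mask(folds, scheme, ["E1"], ["A"], blues,
                                  scope_envs=scope_envs,
                                  scope_traits=scope_traits)
                for cells in plan.masks.values():
                    train = masked_blues(blues, cells)
                    for (l, e, t) in cells:
                        assert np.isnan(train.values[li[l], ei[e], ti[t]])

    def test_undersized_environment_rejected(self):
        blues = _blues(n_lines=3)
        folds = make_folds(blues.line_ids, 2, 1, 0)
        with pytest.raises(ValueError, match="training lines"):
            build_mask(folds, "CV1", ["E1"], ["A"], blues)


class TestRunCV:
    def _plan(self, blues, scheme="CV2", n_cycles=2):
        folds = make_folds(blues.line_ids, 4, n_cycles, 7)
        return build_mask(folds, scheme, ["E1"], ["A"], blues)

    def test_perfect_predictions_give_unit_ability(self):
        blues = _blues(n_lines=24, seed=3)
        plan = self._plan(blues)
        kernel = Kernel(np.eye(24), blues.line_ids)
        truth = {(l, "E1", "A"): blues.values[i, 0, 0]
                 for i, l in enumerate(blues.line_ids)}

        def oracle_fitter(spec, train, k, p, seed):
            return lambda targets: np.array([truth[t] for t in targets])

        res = run_cv(ModelSpec("SE"), blues, kernel, plan, fitter=oracle_fitter)
        assert np.allclose(res.records["r"], 1.0)
        assert res.aggregate()["sd_r"].iloc[0] == pytest.approx(0.0)

    def test_constant_predictions_recorded_missing_with_warning(self):
        blues = _blues(n_lines=24, seed=3)
        plan = self._plan(blues)
        kernel = Kernel(np.eye(24), blues.line_ids)

        def constant_fitter(spec, train, k, p, seed):
            return lambda targets: np.zeros(len(targets))

        with pytest.warns(UserWarning, match="degenerate"):
            res = run_cv(ModelSpec("SE"), blues, kernel, plan,
                         fitter=constant_fitter)
        assert res.records["r"].isna().all()

    def test_failing_fold_is_missing_not_fatal(self):
        blues = _blues(n_lines=24, seed=3)
        plan = self._plan(blues, n_cycles=1)

        def broken_fitter(spec, train, k, p, seed):
            raise RuntimeError("boom")

        kernel = Kernel(np.eye(24), blues.line_ids)
        with pytest.warns(UserWarning, match="failed"):
            res = run_cv(ModelSpec("SE"), blues, kernel, plan,
                         fitter=broken_fitter)
        assert res.records["r"].isna().all()

    def test_real_fit_recovers_signal(self, small_panel, small_blues):
        cfg, geno, kernel, truth, pheno = small_panel
        blues, _ = small_blues
        folds = make_folds(blues.line_ids, 4, 2, 5)
        plan = build_mask(folds, "CV1", [blues.env_ids[0]],
                          [blues.trait_names[0]], blues)
        spec = ModelSpec("SE", mcmc=MCMCSettings(800, 200, 2, 5))
        res = run_cv(spec, blues, kernel, plan)
        assert res.records["r"].notna().all()
        assert res.aggregate()["mean_r"].iloc[0] > 0.0

    def test_aggregation_identity(self):
        records = pd.DataFrame({
            "model": "SE", "scheme": "CV1", "kernel": "G",
            "env": ["E1"] * 3 + ["E2"] * 3, "trait": "A",
            "cycle": [0, 1, 2] * 2, "r": [0.5, 0.6, 0.7, 0.2, 0.3, 0.4]})
        res = CVResult(records, "SE")
        assert res.overall_mean() == pytest.approx((0.6 + 0.3) / 2)


class TestRanking:
    def _result(self, model, scheme, r_values, env="E1"):
        records = pd.DataFrame({
            "model": model, "scheme": scheme, "kernel": "G", "env": env,
            "trait": "A", "cycle": range(len(r_values)), "r": r_values})
        return CVResult(records, f"{model}_{scheme}")

    def test_single_entry_ranks_first(self):
        table = rank_models([self._result("SE", "CV1", [0.5, 0.6])])
        assert table["rank"].tolist() == [1]

    def test_tie_broken_by_smaller_sd(self):
        a = self._result("MT", "CV1", [0.5, 0.7])    # mean .6, sd .141
        b = self._result("ME", "CV1", [0.55, 0.65])  # mean .6, sd .071
        table = rank_models([a, b])
        assert table.iloc[0]["model"] == "ME"

    def test_shuffle_invariance_and_truncation(self):
        results = [self._result("SE", "CV1", [0.1 * i, 0.1 * i])
                   for i in range(1, 7)]
        full = rank_models(results, top_n=3)
        shuffled = rank_models(results[::-1], top_n=3)
        assert full.equals(shuffled)
        assert len(full) == 3

    def test_label_grammar(self):
        table = rank_models([self._result("MTME", "CV2", [0.8])])
        assert table.iloc[0]["label"] == "MTME_CV2"
        records = pd.DataFrame({
            "model": "SE", "scheme": "CV1", "kernel": "G2", "env": "E1",
            "trait": "A", "cycle": [0], "r": [0.5]})
        table2 = rank_models([CVResult(records, "SE_G2")])
        assert table2.iloc[0]["label"] == "SE_G2"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_models([])
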