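"""Adjusted means (BLUEs), variance components, heritability, correlations."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import durumgp as d
from durumgp.adjust import (AdjustmentFit, compute_blues, env_correlations,
                            estimate_h2, reml_fit, trait_correlations)
from durumgp.containers import BlueSet, PhenotypeTable, Kernel
from durumgp.synth import simulate_true_effects, simulate_trials


def _pheno_from_rows(rows):
    return PhenotypeTable(pd.DataFrame(
        rows, columns=["line", "env", "rep", "block", "trait", "value"]))


def _balanced_pheno(n_lines=12, n_reps=2, noise=0.3, seed=0):
    rng = np.random.default_rng(seed)
    truth = rng.normal(10.0, 2.0, n_lines)
    rows = []
    for i in range(n_lines):
        for r in range(n_reps):
            rows.append((f"L{i:02d}", "E1", r + 1, 1, "T",
                         truth[i] + rng.normal(0, noise)))
    return _pheno_from_rows(rows), truth


class TestBlues:
    def test_balanced_design_equals_plot_means(self):
        pheno, _ = _balanced_pheno()
        fit = compute_blues(pheno, "T", "E1")
        means = pheno.records.groupby("line")["value"].mean()
        assert np.allclose(fit.blues.to_numpy(),
                           means.loc[fit.blues.index].to_numpy(), atol=1e-6)

    def test_translation_equivariance(self):
        pheno, _ = _balanced_pheno(seed=4)
        shifted = PhenotypeTable(pheno.records.assign(
            value=pheno.records["value"] + 17.5))
        a = compute_blues(pheno, "T", "E1").blues
        b = compute_blues(shifted, "T", "E1").blues
        assert np.allclose(b.to_numpy() - a.to_numpy(), 17.5, atol=1e-6)

    def test_unbalanced_blues_match_lme4_oracle(self, tmp_path):
        """Small unbalanced system: BLUEs equal the GLS solution of an
        independent REML implementation (lme4 through Rscript)."""
        rng = np.random.default_rng(8)
        rows = []
        for i in range(6):
            for r in (1, 2):
                rows.append((f"L{i}", "E1", r, 1 + (i % 2), "T",
                             10 + i + 0.5 * r + rng.normal(0, 0.4)))
        rows = rows[:-1]  # delete one plot -> unbalanced
        pheno = _pheno_from_rows(rows)
        fit = compute_blues(pheno, "T", "E1")

        csv = tmp_path / "pheno.csv"
        pheno.records.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            df <- read.csv("{csv}")
            df$line <- factor(df$line); df$rep <- factor(df$rep)
            df$blk <- interaction(df$rep, df$block)
            m <- lmer(value ~ 0 + line + (1|rep) + (1|blk), data = df,
                      control = lmerControl(check.nobs.vs.nlev = "ignore",
                                            check.nobs.vs.nRE = "ignore"))
            cat(fixef(m), sep = "\\n")
        """)
        res = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=180)
        assert res.returncode == 0, res.stderr
        oracle = np.array([float(x) for x in res.stdout.strip().split()])
        assert np.allclose(fit.blues.to_numpy(), oracle, atol=2e-3)

    def test_single_rep_single_block_falls_back_to_means(self):
        rows = [(f"L{i}", "E1", 1, 1, "T", float(i)) for i in range(5)]
        fit = compute_blues(_pheno_from_rows(rows), "T", "E1")
        assert fit.fallback_means
        assert np.allclose(fit.blues.to_numpy(), np.arange(5.0))

    def test_missing_trait_raises(self):
        pheno, _ = _balanced_pheno()
        with pytest.raises(KeyError):
            compute_blues(pheno, "absent", "E1")


class TestHeritability:
    def _fit(self, sg2, se2, r=2.0):
        counts = pd.Series(np.full(10, r), index=[f"L{i}" for i in range(10)])
        return AdjustmentFit("T", "E1", pd.Series(dtype=float),
                             pd.Series(dtype=float),
                             {"sigma_g2": sg2, "sigma_rep2": 0.0,
                              "sigma_block2": 0.0, "sigma_e2": se2},
                             np.nan, counts)

    def test_noiseless_limit(self):
        assert estimate_h2(self._fit(2.0, 0.0)) == pytest.approx(1.0)

    def test_pure_noise_limit(self):
        assert estimate_h2(self._fit(0.0, 3.0)) == pytest.approx(0.0)

    def test_entry_mean_formula(self):
        # sg2 = 1, se2 = 1, r = 2 -> 1 / (1 + 0.5) = 2/3
        assert estimate_h2(self._fit(1.0, 1.0)) == pytest.approx(2 / 3)

    def test_plot_basis_variant(self):
        assert estimate_h2(self._fit(1.0, 1.0), method="plot") == pytest.approx(0.5)

    def test_recovery_from_simulation(self):
        """sigma_g2 = sigma_e2 = 1 at r = 2: the entry-mean estimate should
        land near the generative value 2/3."""
        cfg = d.default_config(
            n_lines=500, n_markers=50, env_labels=["E1"], trait_names=["T"],
            Sigma_t=np.eye(1), Sigma_E=np.zeros((1, 1)),
            env_means=np.zeros((1, 1)), h2_target=2 / 3, n_reps=2,
            rep_var_frac=0.0, block_var_frac=0.0, seed=11)
        eye = Kernel(np.eye(500), cfg.line_ids)
        pheno = simulate_trials(simulate_true_effects(cfg, eye), cfg)
        fit = compute_blues(pheno, "T", "E1")
        assert abs(fit.h2 - 2 / 3) < 0.1

    def test_cullis_matches_entry_mean_on_balanced_design(self):
        rng = np.random.default_rng(0)
        rows = []
        truth = rng.normal(0, 1, 100)
        for i in range(100):
            for r in (1, 2):
                rows.append((f"L{i:03d}", "E1", r, 1, "T",
                             truth[i] + rng.normal(0, 1)))
        fit = compute_blues(_pheno_from_rows(rows), "T", "E1")
        assert estimate_h2(fit, "cullis") == pytest.approx(fit.h2, abs=0.02)

    def test_scale_invariance(self):
        pheno, _ = _balanced_pheno(n_lines=30, noise=1.0, seed=2)
        scaled = PhenotypeTable(pheno.records.assign(
            value=pheno.records["value"] * 7.0))
        a = compute_blues(pheno, "T", "E1").h2
        b = compute_blues(scaled, "T", "E1").h2
        assert a == pytest.approx(b, abs=1e-4)


class TestRemlSolver:
    def test_matches_direct_gls_with_known_components(self):
        """With a single variance component the REML estimate must satisfy
        the GLS normal equations at its own estimates."""
        rng = np.random.default_rng(3)
        n, q = 60, 6
        Z = np.zeros((n, q))
        Z[np.arange(n), rng.integers(0, q, n)] = 1.0
        u = rng.normal(0, 1.0, q)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [2.0, 0.5] + Z @ u + rng.normal(0, 0.5, n)
        fit = reml_fit(y, X, {"grp": Z})
        V = fit.sigma2["residual"] * np.eye(n) + fit.sigma2["grp"] * Z @ Z.T
        Vinv = np.linalg.inv(V)
        beta_gls = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
        assert np.allclose(fit.beta, beta_gls, atol=1e-8)


class TestCorrelations:
    def _blues(self, data, traits):
        arr = np.asarray(data, dtype=float)[:, None, :]
        return BlueSet(arr, [f"L{i}" for i in range(arr.shape[0])],
                       ["E1"], traits)

    def test_self_correlation_is_one(self):
        b = self._blues(np.random.default_rng(0).normal(size=(10, 2)), ["A", "B"])
        tab = trait_correlations(b, "E1")
        assert tab.loc[(tab.trait_a == "A") & (tab.trait_b == "A"), "r"].item() == 1.0

    def test_exact_linearity(self):
        b = self._blues(np.array([[1, 2], [2, 4], [3, 6], [4, 8.0]]), ["A", "B"])
        tab = trait_correlations(b, "E1")
        r = tab.loc[(tab.trait_a == "A") & (tab.trait_b == "B"), "r"].item()
        assert r == pytest.approx(1.0)

    def test_textbook_pearson_value(self):
        x = np.array([1, 2, 3, 4, 5.0])
        y = np.array([2, 1, 4, 3, 5.0])
        b = self._blues(np.column_stack([x, y]), ["A", "B"])
        tab = trait_correlations(b, "E1")
        r = tab.loc[(tab.trait_a == "A") & (tab.trait_b == "B"), "r"].item()
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert r == pytest.approx(expected)

    def test_too_few_pairs_warns_and_is_missing(self):
        data = np.array([[1, np.nan], [2, 1], [3, 2], [4, np.nan]])
        b = self._blues(data, ["A", "B"])
        with pytest.warns(UserWarning):
            tab = trait_correlations(b, "E1")
        r = tab.loc[(tab.trait_a == "A") & (tab.trait_b == "B"), "r"].item()
        assert np.isnan(r)

    def test_significance_stars(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        b = self._blues(np.column_stack([x, x + rng.normal(0, 0.1, 200)]),
                        ["A", "B"])
        tab = trait_correlations(b, "E1")
        star = tab.loc[(tab.trait_a == "A") & (tab.trait_b == "B"), "stars"].item()
        assert star == "***"

    def test_env_correlations_duplicate_and_anticorrelated(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=20)
        vals = np.stack([base, base, -base], axis=1)[:, :, None]
        b = BlueSet(vals, [f"L{i}" for i in range(20)],
                    ["E1", "E2", "E3"], ["T"])
        tab, order = env_correlations(b, "T")
        assert tab.loc["E1", "E2"] == pytest.approx(1.0)
        assert tab.loc["E1", "E3"] == pytest.approx(-1.0)
        # duplicated environments cluster adjacently
        assert abs(order.index("E1") - order.index("E2")) == 1
        # symmetry and unit diagonal
        assert np.allclose(tab.to_numpy(), tab.to_numpy().T)
        assert np.allclose(np.diag(tab.to_numpy()), 1.0)

    def test_env_correlation_recovery(self):
        rng = np.random.default_rng(9)
        shared = rng.normal(size=(500, 1))
        vals = (np.sqrt(0.6) * shared
                + np.sqrt(0.4) * rng.normal(size=(500, 4)))[:, :, None]
        b = BlueSet(vals, [f"L{i}" for i in range(500)],
                    ["E1", "E2", "E3", "E4"], ["T"])
        tab, _ = env_correlations(b, "T")
        off = tab.to_numpy()[np.triu_indices(4, 1)]
        assert np.all(np.abs(off - 0.6) < 0.15)
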