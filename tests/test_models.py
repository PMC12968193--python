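"""Gibbs samplers: oracle equivalence, reduction chain, recovery, prediction."""

import numpy as np
import pytest

import durumgp as d
from durumgp.containers import BlueSet, Kernel
from durumgp.models import (MCMCSettings, ModelSpec, PredictionError,
                            draw_b2_prior, fit_me, fit_mt, fit_mtme, fit_se,
                            genomic_heritability, predict)
from durumgp.synth import simulate_genotypes, simulate_true_effects


def _panel(n_lines, n_markers, envs, traits, Sigma_t, Sigma_E, h2, seed):
    """BLUE-level synthetic data: true cell values plus matched noise."""
    cfg = d.default_config(
        n_lines=n_lines, n_markers=n_markers, env_labels=envs,
        trait_names=traits, Sigma_t=np.atleast_2d(Sigma_t),
        Sigma_E=np.atleast_2d(Sigma_E),
        env_means=np.zeros((len(envs), len(traits))), h2_target=h2, seed=seed)
    geno = simulate_genotypes(cfg)
    kernel = d.vanraden_g(geno)
    truth = simulate_true_effects(cfg, kernel)
    rng = np.random.default_rng(seed + 10_000)
    dbar = float(np.mean(np.diag(kernel.matrix)))
    gvar = dbar * np.diag(cfg.Sigma_t) * (1.0 + float(np.mean(np.diag(cfg.Sigma_E))))
    noise_var = gvar * (1.0 - h2) / h2
    y = truth.total_value() + rng.normal(
        0, 1, (n_lines, len(envs), len(traits))) * np.sqrt(noise_var)[None, None, :]
    blues = BlueSet(y, cfg.line_ids, list(envs), list(traits))
    return cfg, kernel, truth, blues


MC = MCMCSettings(n_iter=3000, burn_in=800, thin=2, seed=17)


class TestSE:
    def test_fixed_variance_chain_matches_closed_form_blup(self):
        cfg, kernel, truth, blues = _panel(
            50, 200, ["E1"], ["T"], 1.0, 0.0, 0.5, seed=21)
        spec = ModelSpec("SE", mcmc=MCMCSettings(8000, 1000, 2, 3),
                         fix_variances={"sigma_g2": 1.0, "sigma_e2": 1.0})
        fit = fit_se(blues, kernel, spec, "E1", "T")
        y = blues.values[:, 0, 0]
        G = kernel.matrix
        Vinv = np.linalg.inv(G + np.eye(50))
        one = np.ones(50)
        mu = (one @ Vinv @ y) / (one @ Vinv @ one)
        u_star = G @ Vinv @ (y - mu * one)
        assert np.corrcoef(fit.effects["u"], u_star)[0, 1] > 0.999

    def test_constant_response_gives_null_effects(self):
        lines = [f"L{i}" for i in range(30)]
        blues = BlueSet(np.full((30, 1, 1), 5.0), lines, ["E1"], ["T"])
        kernel = Kernel(np.eye(30), lines)
        fit = fit_se(blues, kernel, ModelSpec("SE", mcmc=MC), "E1", "T")
        assert np.all(np.abs(fit.effects["u"]) < 0.2)

    def test_line_permutation_equivariance(self):
        cfg, kernel, truth, blues = _panel(
            40, 120, ["E1"], ["T"], 1.0, 0.0, 0.5, seed=22)
        fit = fit_se(blues, kernel, ModelSpec("SE", mcmc=MC), "E1", "T")
        perm = np.random.default_rng(0).permutation(40)
        lines_p = [blues.line_ids[i] for i in perm]
        blues_p = BlueSet(blues.values[perm], lines_p, ["E1"], ["T"])
        fit_p = fit_se(blues_p, kernel, ModelSpec("SE", mcmc=MC), "E1", "T")
        # identical up to Monte-Carlo error: the permuted eigenbasis re-maps
        # the random-number stream, so bit equality is not expected
        a, b = fit_p.fitted[:, 0, 0], fit.fitted[perm, 0, 0]
        assert np.corrcoef(a, b)[0, 1] > 0.995
        assert np.max(np.abs(a - b)) < 0.15

    def test_seeded_determinism(self):
        cfg, kernel, truth, blues = _panel(
            30, 100, ["E1"], ["T"], 1.0, 0.0, 0.5, seed=23)
        a = fit_se(blues, kernel, ModelSpec("SE", mcmc=MC), "E1", "T")
        b = fit_se(blues, kernel, ModelSpec("SE", mcmc=MC), "E1", "T")
        assert np.array_equal(a.fitted, b.fitted)
        assert a.variances == b.variances

    def test_masked_lines_predicted_through_kernel(self):
        cfg, kernel, truth, blues = _panel(
            60, 60, ["E1"], ["T"], 1.0, 0.0, 0.8, seed=24)
        hidden = blues.copy()
        hidden.values[:15, 0, 0] = np.nan
        fit = fit_se(hidden, kernel, ModelSpec("SE", mcmc=MC), "E1", "T")
        r = np.corrcoef(fit.fitted[:15, 0, 0], truth.total_value()[:15, 0, 0])[0, 1]
        assert r > 0.2  # genomic relationships carry signal to unphenotyped lines


class TestMT:
    def test_single_trait_reduces_to_se(self):
        cfg, kernel, truth, blues = _panel(
            50, 80, ["E1"], ["T"], 1.0, 0.0, 0.5, seed=25)
        f_se = fit_se(blues, kernel, ModelSpec("SE", mcmc=MC), "E1", "T")
        f_mt = fit_mt(blues, kernel, ModelSpec("MT", mcmc=MC), "E1", ["T"])
        r = np.corrcoef(f_se.fitted.ravel(), f_mt.fitted.ravel())[0, 1]
        assert r > 0.99

    def test_genetic_correlation_recovery(self):
        St = np.array([[1.0, 0.9], [0.9, 1.0]])
        cfg, kernel, truth, blues = _panel(
            200, 150, ["E1"], ["A", "B"], St, 0.0, 0.5, seed=1)
        spec = ModelSpec("MT", mcmc=MCMCSettings(6000, 1500, 5, 7))
        fit = fit_mt(blues, kernel, spec, "E1")
        St_hat = fit.variances["Sigma_t"]
        r = St_hat[0, 1] / np.sqrt(St_hat[0, 0] * St_hat[1, 1])
        assert abs(r - 0.9) < 0.15

    def test_null_correlation_recovery(self):
        cfg, kernel, truth, blues = _panel(
            200, 150, ["E1"], ["A", "B"], np.eye(2), 0.0, 0.5, seed=2)
        spec = ModelSpec("MT", mcmc=MCMCSettings(6000, 1500, 5, 7))
        fit = fit_mt(blues, kernel, spec, "E1")
        St_hat = fit.variances["Sigma_t"]
        r = St_hat[0, 1] / np.sqrt(St_hat[0, 0] * St_hat[1, 1])
        assert abs(r) < 0.15

    def test_secondary_trait_augmentation_borrows_information(self):
        """Masking trait A of some lines while keeping trait B observed must
        beat a fit without the secondary trait (the CV2 mechanism)."""
        St = np.array([[1.0, 0.9], [0.9, 1.0]])
        cfg, kernel, truth, blues = _panel(
            120, 90, ["E1"], ["A", "B"], St, 0.0, 0.5, seed=3)
        hidden = blues.copy()
        hidden.values[:30, 0, 0] = np.nan
        f_mt = fit_mt(hidden, kernel, ModelSpec("MT", mcmc=MC), "E1")
        single = BlueSet(hidden.values[:, :, :1], hidden.line_ids, ["E1"], ["A"])
        f_se = fit_se(single, kernel, ModelSpec("SE", mcmc=MC), "E1", "A")
        obs = blues.values[:30, 0, 0]
        r_mt = np.corrcoef(f_mt.fitted[:30, 0, 0], obs)[0, 1]
        r_se = np.corrcoef(f_se.fitted[:30, 0, 0], obs)[0, 1]
        assert r_mt > r_se


class TestME:
    def test_single_environment_reduces_to_se(self):
        # the i.i.d. line effect is dropped: with one environment it is an
        # extra component SE does not have
        cfg, kernel, truth, blues = _panel(
            50, 80, ["E1"], ["T"], 1.0, 0.0, 0.5, seed=26)
        f_se = fit_se(blues, kernel, ModelSpec("SE", mcmc=MC), "E1", "T")
        f_me = fit_me(blues, kernel,
                      ModelSpec("ME", mcmc=MC, include_line_effect=False),
                      "T", ["E1"])
        r = np.corrcoef(f_se.fitted.ravel(), f_me.fitted.ravel())[0, 1]
        assert r > 0.98

    def test_null_interaction_variance_recovery(self):
        cfg, kernel, truth, blues = _panel(
            200, 100, ["E1", "E2", "E3", "E4"], ["T"], 1.0, np.zeros((4, 4)),
            0.5, seed=27)
        spec = ModelSpec("ME", mcmc=MCMCSettings(5000, 1500, 5, 7),
                         include_line_effect=False)
        fit = fit_me(blues, kernel, spec, "T")
        assert fit.variances["sigma_Eg2"] < 0.1 * fit.variances["sigma_g2"]

    def test_interaction_variance_recovery(self):
        cfg, kernel, truth, blues = _panel(
            150, 110, ["E1", "E2", "E3"], ["T"], 1.0, np.eye(3), 0.5, seed=28)
        spec = ModelSpec("ME", mcmc=MCMCSettings(5000, 1500, 5, 7))
        fit = fit_me(blues, kernel, spec, "T")
        assert abs(fit.variances["sigma_Eg2"] - 1.0) < 0.5
        assert abs(fit.variances["sigma_g2"] - 1.0) < 0.5


class TestMTME:
    def test_single_cell_scope_reduces_to_se(self):
        cfg, kernel, truth, blues = _panel(
            50, 80, ["E1"], ["T"], 1.0, 0.0, 0.5, seed=29)
        f_se = fit_se(blues, kernel, ModelSpec("SE", mcmc=MC), "E1", "T")
        f_mtme = fit_mtme(blues, kernel, ModelSpec("MTME", mcmc=MC))
        r = np.corrcoef(f_se.fitted.ravel(), f_mtme.fitted.ravel())[0, 1]
        assert r > 0.98

    def test_prior_b2_covariance_is_triple_kronecker(self):
        """vec(b2) prior draws must reproduce Sigma_t (x) Sigma_E (x) G."""
        rng = np.random.default_rng(0)
        G = np.array([[1.0, 0.5, 0.2, 0.0], [0.5, 1.0, 0.1, 0.0],
                      [0.2, 0.1, 1.0, 0.3], [0.0, 0.0, 0.3, 1.0]])
        kernel = Kernel(G, ["a", "b", "c", "d"])
        Se = np.array([[1.0, 0.4], [0.4, 0.8]])
        St = np.array([[1.0, -0.3], [-0.3, 0.6]])
        draws = draw_b2_prior(kernel, Se, St, 20_000, rng)
        emp = np.cov(draws.T)
        expected = np.kron(St, np.kron(Se, G))
        n = draws.shape[0]
        mc_se = np.sqrt((np.outer(np.diag(expected), np.diag(expected))
                         + expected**2) / n)
        assert np.all(np.abs(emp - expected) < 4 * mc_se + 1e-12)

    def test_separate_trait_covariance_option_runs(self):
        St = np.array([[1.0, 0.5], [0.5, 1.0]])
        cfg, kernel, truth, blues = _panel(
            40, 60, ["E1", "E2"], ["A", "B"], St, np.eye(2), 0.5, seed=30)
        spec = ModelSpec("MTME", mcmc=MCMCSettings(800, 200, 2, 5),
                         separate_trait_cov=True)
        fit = fit_mtme(blues, kernel, spec)
        assert "Sigma_t_gxe" in fit.variances


@pytest.fixture(scope="module")
def fitted():
    cfg, kernel, truth, blues = _panel(
        30, 50, ["E1"], ["T"], 1.0, 0.0, 0.5, seed=31)
    hidden = blues.copy()
    hidden.values[:5, 0, 0] = np.nan
    return fit_se(hidden, kernel, ModelSpec("SE", mcmc=MC), "E1", "T")


class TestPredict:

    def test_empty_targets(self, fitted):
        assert predict(fitted, []).size == 0

    def test_duplicated_target_duplicates_prediction(self, fitted):
        line = fitted.line_ids[0]
        out = predict(fitted, [(line, "E1", "T"), (line, "E1", "T")])
        assert out[0] == out[1]

    def test_masked_cells_return_stored_augmentation_mean(self, fitted):
        line = fitted.line_ids[0]
        assert not fitted.observed[0, 0, 0]
        out = predict(fitted, [(line, "E1", "T")])
        assert out[0] == fitted.fitted[0, 0, 0]

    def test_unknown_line_raises_with_id(self, fitted):
        with pytest.raises(PredictionError, match="nonexistent"):
            predict(fitted, [("nonexistent", "E1", "T")])

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            MCMCSettings(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            ModelSpec(family="XX")
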