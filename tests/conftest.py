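"""Shared fixtures: small synthetic panels generated at test time."""

import numpy as np
import pytest

import durumgp as d
from durumgp.synth import (SimulationConfig, simulate_genotypes,
                           simulate_target_genes, simulate_true_effects,
                           simulate_trials)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """60 lines, two environments, two correlated traits, h2 = 0.5."""
    return d.default_config(
        n_lines=60, n_markers=80,
        env_labels=["1_2021-2022", "2_2021-2022"],
        trait_names=["GN", "GW"],
        Sigma_t=np.array([[1.0, 0.7], [0.7, 1.0]]),
        Sigma_E=np.array([[1.0, 0.5], [0.5, 1.0]]),
        env_means=np.array([[40.0, 2.0], [38.0, 1.8]]),
        h2_target=0.5, seed=101)


@pytest.fixture(scope="session")
def small_panel(small_config):
    """(config, genotypes, kernel, true effects, phenotypes) tuple."""
    geno = simulate_genotypes(small_config)
    kernel = d.vanraden_g(geno)
    truth = simulate_true_effects(small_config, kernel)
    pheno = simulate_trials(truth, small_config)
    return small_config, geno, kernel, truth, pheno


@pytest.fixture(scope="session")
def small_blues(small_panel):
    *_, pheno = small_panel
    blues, summary = d.compute_all_blues(pheno)
    return blues, summary


@pytest.fixture(scope="session")
def gene_table(small_config):
    return simulate_target_genes(small_config)
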