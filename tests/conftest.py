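"""Shared fixtures: small synthetic experiments, generated at test time."""

import numpy as np
import pytest

from pmscreen.reference import ParticleBetas
from pmscreen.simulate import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """Small but structurally complete experiment: 1 cell line, 2 particles."""
    return SimulationConfig(
        seed=7,
        cell_lines=("J774",),
        particles=("SiO2", "TiO2"),
        doses_proteomic=(0.0, 30.0, 100.0),
        doses_cytotox=(0.0, 30.0, 100.0, 300.0),
        n_bio_replicates=2,
        n_spots=2,
        n_peptides_total=40,
        n_responsive=12,
        beta_true={
            "SiO2": ParticleBetas(0.22, -0.056, 0.037),
            "TiO2": ParticleBetas(0.073, -0.016, 0.019),
        },
        mz_range=(700.0, 1100.0),
        mz_step=0.05,
    )


@pytest.fixture(scope="session")
def noise_free_config(tiny_config) -> SimulationConfig:
    from dataclasses import replace

    return replace(
        tiny_config,
        intensity_cv=0.0,
        baseline_amplitude=0.0,
        detector_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def tiny_experiment(tiny_config):
    return simulate_experiment(tiny_config)


@pytest.fixture(scope="session")
def noise_free_experiment(noise_free_config):
    return simulate_experiment(noise_free_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def medium_config() -> SimulationConfig:
    """One cell line, all three particles, study noise and spot structure."""
    return SimulationConfig(
        seed=11,
        cell_lines=("J774",),
        particles=("SiO2", "EHC6802", "TiO2"),
        n_bio_replicates=3,
        n_spots=5,
        n_peptides_total=200,
        n_responsive=60,
        mz_step=0.25,
    )


@pytest.fixture(scope="session")
def medium_experiment(medium_config):
    return simulate_experiment(medium_config)


@pytest.fixture(scope="session")
def medium_result(medium_experiment):
    from pmscreen.config import PipelineConfig
    from pmscreen.pipeline import analyze_experiment

    exp = medium_experiment
    config = PipelineConfig(seed=exp.config.seed, processing={"top_n": 150})
    return analyze_experiment(exp.spectra, exp.design, exp.cytotox, config)
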