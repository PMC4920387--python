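"""Shared fixtures and oracle helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from befmix import (
    GeneratorConfig,
    MixtureObservation,
    build_design,
    default_species_pool,
    generate_experiment,
)


@pytest.fixture(scope="session")
def species_pool():
    return default_species_pool()


@pytest.fixture(scope="session")
def design(species_pool):
    return build_design(species_pool, seed=0)


@pytest.fixture(scope="session")
def experiment():
    """One default synthetic experiment, shared read-only across tests."""
    return generate_experiment(GeneratorConfig(), seed=42)


@pytest.fixture(scope="session")
def noise_free_experiment():
    return generate_experiment(GeneratorConfig(noise_sd=0.0), seed=7)


def random_mixture(rng: np.random.Generator) -> MixtureObservation:
    """A random valid mixture observation (for fuzz/property tests)."""
    s = int(rng.choice([2, 3, 4, 6, 8]))
    mono = rng.uniform(20.0, 900.0, s)
    ry = rng.uniform(0.0, 1.2, s)
    if ry.sum() == 0:  # avoid the all-dead degenerate case
        ry[0] = 0.5
    return MixtureObservation(
        species=tuple(f"sp{i}" for i in range(s)),
        mixture_biomass=tuple(mono * ry),
        monoculture_biomass=tuple(mono),
    )
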