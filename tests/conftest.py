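"""Shared fixtures: packaged species, cycles, and synthetic parameterizations."""

from __future__ import annotations

import numpy as np
import pytest

from corticogenesis import (
    SpeciesParams,
    Strategy,
    constant_cycle,
    for_species,
    load_species,
    reference_strategy,
)


@pytest.fixture(scope="session")
def mouse() -> SpeciesParams:
    return load_species("mouse")


@pytest.fixture(scope="session")
def macaque() -> SpeciesParams:
    return load_species("macaque")


@pytest.fixture(scope="session")
def human() -> SpeciesParams:
    return load_species("human")


@pytest.fixture(scope="session")
def mouse_cycle():
    return for_species("mouse", mode="constant")


@pytest.fixture(scope="session")
def mouse_age_cycle():
    return for_species("mouse", mode="age_dependent")


@pytest.fixture(scope="session")
def mouse_reference() -> Strategy:
    return reference_strategy("mouse", mode="constant")


@pytest.fixture(scope="session")
def toy_species() -> SpeciesParams:
    """A small synthetic species for fast search tests (not a real animal)."""
    return SpeciesParams(
        name="toy", t0=0.0, tF=4.0, tM=3.0, phi=0.5, N_adult=1e6
    )


@pytest.fixture(scope="session")
def toy_cycle():
    return constant_cycle(24.0)


def synthetic_species(rng: np.random.Generator) -> SpeciesParams:
    """Draw a random but biologically plausible species parameterization."""
    t0 = rng.uniform(5.0, 50.0)
    duration = rng.uniform(4.0, 80.0)
    tF = t0 + duration
    tM = rng.uniform(t0 + 0.2 * duration, t0 + 0.8 * duration)
    return SpeciesParams(
        name=f"synthetic-{rng.integers(1e6)}",
        t0=t0,
        tF=tF,
        tM=tM,
        phi=float(rng.uniform(0.1, 0.9)),
        N_adult=float(rng.uniform(1e6, 1e10)),
        death_fraction=float(rng.uniform(0.0, 0.6)),
        migration_fraction=float(rng.uniform(0.0, 0.6)),
    )
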