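import numpy as np
import pytest

from iceswitch import (
    InputSpec,
    NetworkModel,
    PromoterSpec,
    SpeciesSpec,
    ActivatorConfig,
)


@pytest.fixture(scope="session")
def death_model():
    """Pure linear death process: one species, degradation 0.3, no promoters."""
    return NetworkModel(
        species=[SpeciesSpec("X", degradation_rate=0.3)], promoters=[], label="death"
    )


@pytest.fixture(scope="session")
def birth_death_model():
    """Constant basal production k=5 and degradation 1.0: stationary Poisson(5)."""
    return NetworkModel(
        species=[SpeciesSpec("X", degradation_rate=1.0)],
        promoters=[PromoterSpec("P", basal_rate=5.0, basal_product="X")],
        label="birth_death",
    )


@pytest.fixture(scope="session")
def pure_birth_model():
    """Single channel with constant propensity 3: a Poisson process of births."""
    return NetworkModel(
        species=[SpeciesSpec("X", degradation_rate=0.0)],
        promoters=[PromoterSpec("P", basal_rate=3.0, basal_product="X")],
        label="pure_birth",
    )


@pytest.fixture
def binomial_input():
    return InputSpec("BisDC", "binomial", {"trials": 16, "p": 0.5})
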