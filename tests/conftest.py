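"""Shared fixtures: small closed-form models and burned-in reference models."""

import numpy as np
import pytest

from somiteclock import (
    ParameterSet,
    PathwayModel,
    RateLaw,
    Reaction,
    SimulationConfig,
    Species,
    build_model,
    burn_in,
    integrate,
)
from somiteclock.network import Compartment, SpeciesRole


@pytest.fixture
def decay_model():
    """dx/dt = -0.1 x, x(0) = 1: the simplest closed-form check."""
    return PathwayModel(
        model_id="decay",
        species=[Species("X", Compartment.CYTOPLASM, SpeciesRole.PROTEIN,
                         initial_value=1.0)],
        reactions=[Reaction("deg_x", reactants={"X": 1},
                            rate_law=RateLaw.mass_action("d", ["X"]))],
        parameters=ParameterSet({"d": 0.1}),
    )


@pytest.fixture
def birth_death_model():
    """0 -> X at rate k, X -> 0 mass action d: steady state k/d."""
    return PathwayModel(
        model_id="birth_death",
        species=[Species("X", Compartment.CYTOPLASM, SpeciesRole.PROTEIN,
                         initial_value=0.0)],
        reactions=[
            Reaction("syn_x", products={"X": 1},
                     rate_law=RateLaw.mass_action("k", []), kind="synthesis"),
            Reaction("deg_x", reactants={"X": 1},
                     rate_law=RateLaw.mass_action("d", ["X"]),
                     kind="degradation"),
        ],
        parameters=ParameterSet({"k": 0.5, "d": 0.25}),
    )


def _burned(model_id):
    model = build_model(model_id)
    res = burn_in(model, SimulationConfig())
    assert res.converged, f"{model_id} reference burn-in must converge"
    model.set_initial_state(res.state)
    return model


@pytest.fixture(scope="session")
def notch_model():
    return _burned("notch")


@pytest.fixture(scope="session")
def wnt_model():
    return _burned("wnt")


@pytest.fixture(scope="session")
def combined_model():
    return _burned("combined")


@pytest.fixture(scope="session")
def notch_reference(notch_model):
    return integrate(notch_model, SimulationConfig(t_end=1200.0))


@pytest.fixture(scope="session")
def wnt_reference(wnt_model):
    return integrate(wnt_model, SimulationConfig(t_end=1200.0))


@pytest.fixture(scope="session")
def combined_reference(combined_model):
    return integrate(combined_model, SimulationConfig(t_end=1200.0))


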