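import math

import pytest
from hypothesis import HealthCheck, settings

from wjdf.io_cli import default_parameter_set
from wjdf.network import (
    MetabolicNetwork,
    ParameterSet,
    ParameterValue,
    RateLawSpec,
    Reaction,
    Species,
    build_wjmsc_network,
)
from wjdf.synthetic_data import NoiseModel, generate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def network() -> MetabolicNetwork:
    return build_wjmsc_network()


@pytest.fixture(scope="session")
def params_p4(network):
    return default_parameter_set(network, "P4")


@pytest.fixture(scope="session")
def params_p9(network):
    return default_parameter_set(network, "P9")


@pytest.fixture(scope="session")
def params_combined(network):
    return default_parameter_set(network, "combined")


@pytest.fixture(scope="session")
def noiseless_p4(network, params_p4):
    """Zero-noise P4-schedule dataset generated from the P4 ground truth."""
    dataset, truth = generate_dataset(
        network,
        params_p4,
        schedule="P4",
        noise=NoiseModel(0.0, 0.0, 0.0),
        seed=1,
        condition="P4",
    )
    return dataset, truth


@pytest.fixture(scope="session")
def noiseless_pair(network, params_combined):
    """Zero-noise P4+P9-schedule datasets from the combined ground truth."""
    zero = NoiseModel(0.0, 0.0, 0.0)
    ds4, _ = generate_dataset(
        network, params_combined, schedule="P4", noise=zero, seed=1,
        condition="P4",
    )
    ds9, _ = generate_dataset(
        network, params_combined, schedule="P9", noise=zero, seed=2,
        condition="P9",
    )
    return ds4, ds9


def make_params(values: dict[str, float], condition="toy") -> ParameterSet:
    """Unbounded parameter set for toy models."""
    return ParameterSet(
        {n: ParameterValue(value=v, lower=0.0, upper=math.inf)
         for n, v in values.items()},
        condition,
    )


def decay_network(compartment: str = "extracellular") -> MetabolicNetwork:
    """One-species first-order-like decay model with frozen or live growth.

    DEG: C -> (removed), Michaelis-Menten in C; the growth reaction has no
    substrate terms, so mu == vmaxgrowth (0 freezes the cell count).
    """
    net = MetabolicNetwork(
        species=(
            Species("X", "biomass", measured=True),
            Species("C", compartment, measured=True),
        ),
        reactions=(
            Reaction(
                id="DEG",
                stoichiometry={"C": -1},
                rate_law=RateLawSpec(
                    kind="multi_substrate_mm",
                    vmax="vmaxDEG",
                    substrate_terms=(("C", "KmDEGC"),),
                ),
                pathway_tag="aa",
            ),
            Reaction(
                id="growth",
                stoichiometry={"X": 1},
                rate_law=RateLawSpec(kind="growth", vmax="vmaxgrowth"),
                pathway_tag="growth",
            ),
        ),
    )
    net.validate()
    return net
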