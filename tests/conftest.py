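"""Shared fixtures: the shipped network, calibrated assay config, toys."""

import numpy as np
import pytest

from coagsim import (
    AssayConfig,
    NetworkModel,
    Reaction,
    Species,
    calibrate_standard,
    default_network,
)


@pytest.fixture(scope="session")
def default_net() -> NetworkModel:
    return default_network()


@pytest.fixture(scope="session")
def assay_cfg(default_net) -> AssayConfig:
    """AssayConfig with PT/aPTT standards computed once per session."""
    return calibrate_standard(default_net, AssayConfig())


# -- toy networks -----------------------------------------------------------


def make_decay_toy(k: float = 0.1, x0: float = 100.0) -> NetworkModel:
    """Single species with first-order degradation and no production."""
    return NetworkModel(
        [Species("X", "zymogen", baseline_conc=x0, kdeg=k, production_rate=0.0)],
        [],
        version="toy-decay",
    )


def make_complex_toy(k: float = 0.001) -> NetworkModel:
    """Closed A + B -> A_B with no degradation (conservation toy)."""
    return NetworkModel(
        [
            Species("A", "zymogen", baseline_conc=10.0),
            Species("B", "zymogen", baseline_conc=7.0),
            Species("A_B", "complex"),
        ],
        [Reaction("complex_formation", ("A", "B"), "A_B", k=k)],
        version="toy-complex",
    )


def make_mm_toy(kcat: float = 2.0, km: float = 50.0) -> NetworkModel:
    """E catalyses S -> P (Michaelis-Menten toy)."""
    return NetworkModel(
        [
            Species("E", "zymogen", baseline_conc=5.0),
            Species("S", "zymogen", baseline_conc=50.0),
            Species("P", "active"),
        ],
        [Reaction("mm_activation", ("S",), "P", catalyst="E", kcat=kcat, km=km)],
        version="toy-mm",
    )


@pytest.fixture
def decay_toy():
    return make_decay_toy()


@pytest.fixture
def complex_toy():
    return make_complex_toy()


@pytest.fixture
def mm_toy():
    return make_mm_toy()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
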