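import numpy as np
import pytest
from hypothesis import settings

from avibind import AssayGeometry, BindingSystem, ModelParameters, RateParameters

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def geometry():
    return AssayGeometry()


@pytest.fixture(scope="session")
def baseline_system():
    """The reference dose-sweep system: kon=1e5, koff=1e-4, rtot=1e4, D=1e-14."""
    return BindingSystem(rates=RateParameters(), rtot=1e4)


def random_model_parameters(rng, geometry=None, with_dose=True):
    """One parameter set drawn log-uniformly over the literature ranges."""
    if geometry is None:
        geometry = AssayGeometry()
    rates = RateParameters(
        kon=10 ** rng.uniform(4, 6),
        koff=10 ** rng.uniform(-6, -3),
        d_antigen=10 ** rng.uniform(-15, -13),
    )
    rtot = 10 ** rng.uniform(4, 6)
    ainit = 10 ** rng.uniform(-12, -5) if with_dose else 1e-10
    return ModelParameters.from_assay(geometry, rates, rtot, ainit)
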