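import numpy as np
import pytest

from transloc.chain_model import ChainGeometryParams, rod_chain
from transloc.iftp_solver import DriveParams
from transloc.trans_friction import TransFrictionModel


@pytest.fixture(scope="session")
def reference_chain() -> ChainGeometryParams:
    """Persistence length 25 with the published interpolation constants."""
    return ChainGeometryParams(persistence_length=25.0)


@pytest.fixture(scope="session")
def stiff_chain() -> ChainGeometryParams:
    """Effectively rigid chain (rod limit to ~1e-5)."""
    return rod_chain()


@pytest.fixture(scope="session")
def reference_drive() -> DriveParams:
    """f = 20, eta_p = 4, N0 = 64 — the reference theory parameters."""
    return DriveParams(force=20.0, pore_friction=4.0, chain_length=64.0)


@pytest.fixture(scope="session")
def three_regime_model() -> TransFrictionModel:
    """A friction model with all three regimes well inside [0, 64]."""
    return TransFrictionModel(growth_coefficient=0.8, saturation_value=10.63,
                              asymptote=5.5, plateau_end=40.0,
                              decay_scale=8.0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
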