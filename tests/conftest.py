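import numpy as np
import pytest

from n2oflux.bayes_inference import McmcConfig
from n2oflux.chamber_flux import AirState, ChamberGeometry
from n2oflux.synthetic_data import (
    CampaignLayout,
    TruthSpec,
    daily_then_alternate_schedule,
    simulate_event,
)


@pytest.fixture
def default_truth():
    return TruthSpec()


@pytest.fixture
def eb_chamber():
    # cylinder, 38 cm ID, 22 cm high -> V/A = 0.22 m
    return ChamberGeometry.cylinder(0.38, 0.22)


@pytest.fixture
def room_air():
    return AirState(temperature_k=293.15)


@pytest.fixture
def fast_mcmc():
    """Reduced iteration count for tests that only need a rough posterior."""
    return McmcConfig(n_iter=3000, n_burnin=1000, seed=42)


@pytest.fixture
def single_treatment_event(default_truth):
    """One simulated event: 4 AN plots + 4 controls, standard schedule."""
    layout = CampaignLayout(treatments=("AN",))
    df = simulate_event(default_truth, daily_then_alternate_schedule(),
                        layout, seed=7)
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(20160311)
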