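import pytest

from uccea.model_spec import ModelSpec, HealthState, TransitionRow, FixedProb, Complement
from uccea.scenarios import AnalysisRequest, build_arm, load_fixture


@pytest.fixture(scope="session")
def no_ada_spec():
    return load_fixture("uc_no_ada")


@pytest.fixture(scope="session")
def ada_spec():
    return load_fixture("uc_ada")


@pytest.fixture(scope="session")
def base_request():
    return AnalysisRequest(horizon_cycles=40, response_utility=0.79, scenario="base")


def toy_geometric(stay: float = 0.9, horizon: int = 20, utility: float = 0.8,
                  cost: float = 100.0, rate: float = 0.0) -> ModelSpec:
    """Two-state model: stay alive with probability `stay`, else die."""
    return ModelSpec(
        name="toy",
        states={
            "alive": HealthState("alive", "alive", cost, utility),
            "death": HealthState("death", "death", 0.0, 0.0, is_death=True),
        },
        transitions={
            "alive": TransitionRow(
                "alive",
                (FixedProb("alive", stay * 100.0), Complement("death")),
            )
        },
        retention_series={},
        initial_distribution={"alive": 1.0},
        horizon_cycles=horizon,
        annual_discount_rate=rate,
    )
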