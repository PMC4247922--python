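import pytest

from radlv import ModelParams, State, TreatmentSchedule


@pytest.fixture(scope="session")
def set1_params() -> ModelParams:
    """Coexistence regime: weak competition, small collateral fraction."""
    return ModelParams(
        alpha1=0.1, alpha2=0.45, K1=0.65, K2=1.0, beta1=0.11, beta2=0.15, epsilon=0.05
    )


@pytest.fixture(scope="session")
def set1_schedule() -> TreatmentSchedule:
    return TreatmentSchedule(gamma=0.35, omega=50.0, L=15.0)


@pytest.fixture(scope="session")
def set2_params() -> ModelParams:
    """Eradication regime: strong symmetric competition, epsilon = 0.3."""
    return ModelParams(
        alpha1=0.2, alpha2=0.5, K1=0.65, K2=1.0, beta1=0.5, beta2=0.55, epsilon=0.3
    )


@pytest.fixture(scope="session")
def set2_schedule() -> TreatmentSchedule:
    return TreatmentSchedule(gamma=0.65, omega=10.0, L=8.0)


@pytest.fixture(scope="session")
def set3_params() -> ModelParams:
    """Cancer-win regime: strong cross-competition on healthy cells."""
    return ModelParams(
        alpha1=0.2, alpha2=0.5, K1=0.65, K2=1.0, beta1=0.48, beta2=0.05, epsilon=0.3
    )


@pytest.fixture(scope="session")
def set3_schedule_a() -> TreatmentSchedule:
    return TreatmentSchedule(gamma=0.4, omega=10.0, L=2.0)


@pytest.fixture(scope="session")
def set3_schedule_b() -> TreatmentSchedule:
    return TreatmentSchedule(gamma=0.6, omega=10.0, L=1.0)


@pytest.fixture(scope="session")
def initial_state() -> State:
    return State(0.5, 0.8)
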