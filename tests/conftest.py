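import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mgpk.dosing import DosingEvent, DosingSchedule
from mgpk.params import default_covariate_model, default_parameters
from mgpk.simulate import ErrorModel

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def params():
    return default_parameters()


@pytest.fixture
def covmodel():
    return default_covariate_model()


@pytest.fixture
def zero_error():
    return ErrorModel(proportional_cv=0.0, additive_sd=0.0, outlier_prob=0.0)


@pytest.fixture
def zuspan_schedule():
    """4 g bolus at 0, 1 g/h maintenance from 0, titrated to 1.25 g/h at 5 h."""
    return DosingSchedule.from_events(
        [
            DosingEvent(0.0, "bolus", dose=4.0),
            DosingEvent(0.0, "rate_change", rate=1.0),
            DosingEvent(5.0, "rate_change", rate=1.25),
        ],
        treatment_end=30.0,
    )


def random_params(rng: np.random.Generator):
    from mgpk.params import PKParameters

    return PKParameters(
        CL=float(rng.uniform(1.0, 10.0)),
        V1=float(rng.uniform(5.0, 40.0)),
        Q=float(rng.uniform(0.5, 8.0)),
        V2=float(rng.uniform(10.0, 80.0)),
        baseline=float(rng.uniform(0.5, 1.0)),
    )


def random_schedule(rng: np.random.Generator, n_changes: int | None = None):
    n_changes = int(rng.integers(1, 6)) if n_changes is None else n_changes
    events = [
        DosingEvent(0.0, "bolus", dose=float(rng.uniform(2.0, 6.0)),
                    bolus_duration=float(rng.uniform(0.1, 0.6))),
    ]
    t = 0.0
    for _ in range(n_changes):
        events.append(DosingEvent(t, "rate_change", rate=float(rng.uniform(0.0, 2.5))))
        t += float(rng.uniform(1.0, 8.0))
    return DosingSchedule.from_events(events, treatment_end=t + float(rng.uniform(0.0, 5.0)))
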