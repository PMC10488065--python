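import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from twamatch import SimConfig, generate_cohort
from twamatch.cohort import VitalTrace
from twamatch.io import cohort_to_dataframe

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def make_trace(values, dt=30.0, hpi=None, patient_id="T"):
    values = np.asarray(values, dtype=float)
    return VitalTrace(
        patient_id=patient_id,
        t=np.arange(values.size) * dt,
        map_mmHg=values,
        hpi_index=None if hpi is None else np.asarray(hpi, dtype=float),
    )


def random_trace(rng, n_min=20, n_max=400, dt=30.0):
    n = int(rng.integers(n_min, n_max))
    values = np.clip(rng.normal(75, 12, n), 20, 200)
    return make_trace(values, dt=dt)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimConfig(n_patients=150, seed=42)
    records, traces = generate_cohort(cfg)
    return cfg, records, traces


@pytest.fixture(scope="session")
def small_cohort_df(small_cohort):
    _, records, _ = small_cohort
    return cohort_to_dataframe(records)
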