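import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_camera():
    from mirrorsim.optics import ViewerCamera

    return ViewerCamera(eye=[0.0, 0.0, 0.0], gaze=[0.0, 0.0, -1.0],
                        up=[0.0, 1.0, 0.0])


@pytest.fixture(scope="session")
def small_cohort_df():
    """A small two-group cohort run through the full pipeline once."""
    from mirrorsim import cohortsim
    from mirrorsim.metrics import records_to_dataframe

    spec = cohortsim.calibrated_spec()
    spec.profiles = {g: spec.profiles[g] for g in ("ID", "ST")}
    spec.n_per_group = {"ID": 4, "ST": 4}
    spec.seed = 77
    records = cohortsim.generate_cohort(spec)
    return records_to_dataframe(records)
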