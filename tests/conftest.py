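import numpy as np
import pytest

import tiltsim as ts


@pytest.fixture(scope="session")
def defaults() -> ts.ModelParameters:
    return ts.default_parameters()


@pytest.fixture(scope="session")
def short_run(defaults) -> ts.ModelRun:
    """One 900 s supine realization shared by read-only tests."""
    return ts.integrate(defaults, 900.0, seed=11, store_stride=2)


@pytest.fixture(scope="session")
def ensemble_summary(defaults):
    """Paired supine/upright ensemble (n=20) shared by the acceptance and
    protocol tests; ~2 s of compute after JIT warmup."""
    return ts.run_tilt_protocol(defaults, 20, seed0=1)


def make_run_from_frame(states, time, beats=None):
    """Build a minimal ModelRun around prefabricated trajectories (protocol
    utility tests that do not need the integrator)."""
    import pandas as pd
    from tiltsim.model import ModelRun, PostureSchedule
    if beats is None:
        beats = pd.DataFrame({"beat_time_s": [], "RR_s": [],
                              "SAP_mmHg": [], "DAP_mmHg": []})
    return ModelRun(params=None, dt=np.diff(time).mean(), store_stride=1,
                    seed=0, posture=PostureSchedule.constant(0.0),
                    time=np.asarray(time, dtype=float), states=states,
                    beats=beats)
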