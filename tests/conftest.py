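import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kymostates.containers import TraceTruth
from kymostates.simulate import apo_scheme, two_state_scheme

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def apo():
    """Apo-condition scheme with every protomer active (trace benchmarks)."""
    return apo_scheme(active_fraction=1.0)


@pytest.fixture
def two_state():
    return two_state_scheme(0.328, 0.347)


@pytest.fixture
def flat_truth():
    """Inactive protomer: one outward-facing segment."""
    return TraceTruth(
        change_times=np.empty(0),
        state_labels=["out"],
        segment_heights=np.array([2.0]),
        duration=10.0,
    )


def truth_dwell_records(truth, trace_id=None):
    """Convert a ground-truth sequence into dwell records (no noise, no
    idealization) — used to test dwell statistics against the generator."""
    from kymostates.dwells import DwellRecord

    durs = truth.segment_durations()
    bounds = np.concatenate([[0.0], truth.change_times, [truth.duration]])
    n = len(truth.state_labels)
    records = []
    for i in range(n):
        records.append(
            DwellRecord(
                state=truth.state_labels[i],
                duration=float(durs[i]),
                t_start=float(bounds[i]),
                t_end=float(bounds[i + 1]),
                height=float(truth.segment_heights[i]),
                prev=truth.state_labels[i - 1] if i > 0 else None,
                next=truth.state_labels[i + 1] if i < n - 1 else None,
                left_censored=i == 0,
                right_censored=i == n - 1,
                trace_id=trace_id,
            )
        )
    return records
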