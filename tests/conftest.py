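import numpy as np
import pytest
from hypothesis import settings

import iontospike as isp

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


@pytest.fixture(scope="session")
def chopper_unit():
    return isp.default_unit("chopper")


@pytest.fixture(scope="session")
def chopper_session_600(chopper_unit):
    """600 unmodulated sweeps of the default 200 Hz chopper."""
    return isp.generate_session(chopper_unit, seed=101, n_sweeps=600)


@pytest.fixture(scope="session")
def primary_session_600():
    return isp.generate_session(isp.default_unit("primary_like"), seed=102,
                                n_sweeps=600)


def match_events(events, truth, sweep_s=1.0, tol_s=0.001):
    """Greedy matching of detected events to truth spikes within a tolerance.

    Returns (n_matched, n_false_positive).
    """
    ta = np.sort(truth["sweep"].to_numpy() * sweep_s + truth["time_s"].to_numpy())
    te = np.sort(events["sweep"].to_numpy() * sweep_s + events["time_s"].to_numpy())
    used = np.zeros(len(te), dtype=bool)
    hit = 0
    for t in ta:
        i = np.searchsorted(te, t)
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(te) and not used[j] and abs(te[j] - t) <= tol_s:
                used[j] = True
                hit += 1
                break
    return hit, int((~used).sum())
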