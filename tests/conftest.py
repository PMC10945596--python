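import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import longcall as lc

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset (10 individuals, ~66 calls, seed 1)."""
    spec = lc.SyntheticSpec(seed=1)
    table, acoustic = lc.generate_dataset(spec)
    return spec, table, acoustic


@pytest.fixture(scope="session")
def filtered_series(default_dataset):
    """Filtered IOI series per element type for the default dataset."""
    _, table, _ = default_dataset
    out = {}
    for etype in lc.ELEMENT_TYPES:
        out[etype] = lc.filter_iois(lc.compute_iois(table, etype))
    return out


@pytest.fixture()
def tiny_events():
    """A minimal hand-built two-call event table with both strata."""
    rows = []

    def ev(eid, ind, call, etype, parent, b, e):
        rows.append(dict(event_id=eid, individual_id=ind, long_call_id=call,
                         element_type=etype, parent_pulse_id=parent,
                         begin_time=b, end_time=e))

    # call A: three pulses 1.7 s apart; two bubbles in p1, two in p2
    ev("p1", "indA", "callA", "full_pulse", None, 0.0, 1.4)
    ev("p2", "indA", "callA", "full_pulse", None, 1.7, 3.1)
    ev("p3", "indA", "callA", "full_pulse", None, 3.4, 4.8)
    ev("s1", "indA", "callA", "bubble_sub_pulse", "p1", 0.10, 0.20)
    ev("s2", "indA", "callA", "bubble_sub_pulse", "p1", 0.30, 0.40)
    ev("s3", "indA", "callA", "bubble_sub_pulse", "p2", 1.80, 1.90)
    ev("s4", "indA", "callA", "bubble_sub_pulse", "p2", 2.00, 2.10)
    # call B: two pulses, one grumble pair
    ev("q1", "indB", "callB", "full_pulse", None, 0.0, 1.0)
    ev("q2", "indB", "callB", "full_pulse", None, 2.0, 3.0)
    ev("g1", "indB", "callB", "grumble_sub_pulse", "q1", 0.05, 0.10)
    ev("g2", "indB", "callB", "grumble_sub_pulse", "q1", 0.17, 0.22)
    return lc.EventTable(pd.DataFrame(rows))


def onsets_to_table(onsets, element_type="full_pulse", duration=0.1,
                    call="call_0", individual="ind_0"):
    """Event table from a plain vector of onsets (helper for rhythm tests)."""
    onsets = np.asarray(onsets, dtype=float)
    return lc.EventTable(pd.DataFrame({
        "event_id": [f"e{i}" for i in range(len(onsets))],
        "individual_id": individual,
        "long_call_id": call,
        "element_type": element_type,
        "begin_time": onsets,
        "end_time": onsets + duration,
    }))
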