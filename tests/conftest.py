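import numpy as np
import pandas as pd
import pytest

from vocalnet import EventTable, GroupLayout, SimulationConfig


@pytest.fixture(scope="session")
def layout() -> GroupLayout:
    return GroupLayout.default_square()


@pytest.fixture()
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=123, duration_s=30.0, call_rate_hz=0.2)


@pytest.fixture(scope="session")
def quiet_config() -> SimulationConfig:
    """No background noise, no cage clicks: detection ground truth is exact."""
    return SimulationConfig(seed=42, duration_s=30.0, call_rate_hz=0.2,
                            noise_level=0.0, click_rate_hz=0.0)


def make_table(rows) -> EventTable:
    """rows: iterable of (bird_id, start_s, end_s)."""
    return EventTable(pd.DataFrame(
        [{"bird_id": b, "start_s": s, "end_s": e} for b, s, e in rows],
        columns=["bird_id", "start_s", "end_s"],
    ))


@pytest.fixture(scope="session")
def worked_sequence_table() -> EventTable:
    """Caller sequence 1,1,2,3,1,1,3,1,3,4 as an event table (1 s apart)."""
    seq = ["1", "1", "2", "3", "1", "1", "3", "1", "3", "4"]
    return make_table((b, float(i), float(i) + 0.1) for i, b in enumerate(seq))
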