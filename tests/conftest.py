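import numpy as np
import pandas as pd
import pytest

from meanet import standard_mea_layout
from meanet.data import PULSE_COLUMNS, SPIKE_COLUMNS, SpikeEventSet


@pytest.fixture(scope="session")
def emap():
    return standard_mea_layout()


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


def make_pulse_table(emap, n_pulses=50, ipi_s=0.3, session_id="s1"):
    """Complete pulse table: every analysis electrode stimulated in layout
    order, n_pulses pulses each, one pulse every ipi_s."""
    rows, t = [], 0.0
    for eid in emap.analysis_ids:
        for trial in range(n_pulses):
            rows.append(
                {"stim_electrode_id": eid, "pulse_time_s": t, "trial_index": trial, "session_id": session_id}
            )
            t += ipi_s
    return pd.DataFrame(rows, columns=PULSE_COLUMNS)


def make_spikes(records, session_id="s1", kind="stimulation", day=10, culture="c1", batch="b1"):
    """Spike table from (electrode_id, time_s) pairs, sorted by time."""
    df = pd.DataFrame(records, columns=["electrode_id", "time_s"])
    df["session_id"] = session_id
    df["session_kind"] = kind
    df["day_in_vitro"] = day
    df["culture_id"] = culture
    df["batch_id"] = batch
    return df.sort_values("time_s", ignore_index=True)[SPIKE_COLUMNS]


@pytest.fixture
def stim_session_factory(emap):
    def build(spike_records, n_pulses=50, duration=None):
        pulses = make_pulse_table(emap, n_pulses=n_pulses)
        spikes = make_spikes(spike_records)
        return SpikeEventSet(spikes=spikes, pulses=pulses, duration_s=duration)

    return build
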