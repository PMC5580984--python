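import numpy as np
import pytest
from hypothesis import settings

import flowfect as ff

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

ROLE_NAMES = {"fsc_a": "FSC-A", "fsc_h": "FSC-H", "ssc_a": "SSC-A",
              "dna_label": "FITC-A", "protein": "mCherry-A",
              "viability": "Ghost780-A"}


def make_table(sample_id="t", timepoint_h=None, **cols):
    """EventTable from role -> array keyword columns."""
    roles = list(cols)
    values = np.column_stack([np.asarray(cols[r], dtype=float) for r in roles])
    channels = [ff.Channel(name=ROLE_NAMES.get(r, r), role=r if r in ROLE_NAMES else "other")
                for r in roles]
    return ff.EventTable(values=values, channels=channels,
                         sample_id=sample_id, timepoint_h=timepoint_h)


def lognormal(rng, median, sigma_log10, n):
    return 10.0 ** rng.normal(np.log10(median), sigma_log10, n)


@pytest.fixture(scope="session")
def default_cfg():
    return ff.SimulationConfig(n_events=20000, seed=1)


@pytest.fixture(scope="session")
def default_sample(default_cfg):
    return ff.simulate_sample(default_cfg)


@pytest.fixture(scope="session")
def default_controls(default_cfg):
    return ff.simulate_controls(default_cfg)
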