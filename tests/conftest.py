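import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bovine():
    from opsintune.sequences import bovine_reference

    return bovine_reference()


@pytest.fixture(scope="session")
def lws_reference():
    from opsintune.synthetic import reference_opsin

    return reference_opsin("lws")


@pytest.fixture(scope="session")
def sws1_reference():
    from opsintune.synthetic import reference_opsin

    return reference_opsin("sws1")


#: Mean normalized opsin read counts over a four-stage developmental
#: series (day-degrees), used as a small printed-table replay fixture.
DEVELOPMENTAL_COUNTS = {
    "rh1-1": [1, 1, 10, 30740],
    "sws1-1": [0, 1, 3, 698],
    "sws2": [0, 0, 1, 351],
    "rh2-1": [9, 4, 20, 211],
    "rh2-2": [3, 6, 22, 219],
    "rh2-3": [0, 0, 10, 754],
    "rh2-4": [0, 1, 4, 513],
    "lws1": [0, 1, 0, 2],
    "lws2": [0, 0, 0, 1240],
    "lws3": [1, 0, 0, 8],
    "lws4": [0, 0, 2, 304],
}

DEVELOPMENTAL_STAGES = ["225dd", "320dd", "410dd", "800dd"]


@pytest.fixture()
def developmental_counts():
    import pandas as pd

    from opsintune.expression import CountMatrix

    df = pd.DataFrame(DEVELOPMENTAL_COUNTS, index=DEVELOPMENTAL_STAGES).T
    return CountMatrix(counts=df, normalized=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
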