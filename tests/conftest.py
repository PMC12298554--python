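import numpy as np
import pytest

from mignn.data import FeatureDims, SessionSample


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_session(rng, session_id="s0", n=5, dims=(4, 6, 5), label=12.0,
                 scale="PHQ8", modalities=("A", "V", "T")):
    widths = dict(zip(("A", "V", "T"), dims))
    features = {m: rng.standard_normal((n, widths[m])) for m in modalities}
    return SessionSample(session_id=session_id, features=features,
                         label=label, scale=scale)


@pytest.fixture
def tiny_cohort(rng):
    return [make_session(rng, f"s{i}", n=3 + i, label=float(3 * i))
            for i in range(4)]


@pytest.fixture
def small_dims():
    return FeatureDims(4, 6, 5)
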