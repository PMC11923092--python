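import numpy as np
import pytest

TABLE1_RATES = dict(ka=1e5, kd=1e-2, kf=1e-2, ku=1e-3)


@pytest.fixture
def table1_rates():
    """Representative two-step rate set (ka 1/(M s); kd, kf, ku 1/s)."""
    return dict(TABLE1_RATES)


@pytest.fixture
def pts_times():
    """Log-spaced gel sampling grid out to 300 s, anchored at 0."""
    return np.concatenate([[0.0], np.logspace(0, np.log10(300.0), 11)])
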