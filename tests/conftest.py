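import numpy as np
import pytest

from rctadjust.generate import TrialSample


def make_counts_sample(events_treated, n_treated, events_control, n_control):
    """Trial with given event counts per arm and a zero covariate.

    With C identically zero the likelihood depends on the data only
    through the 2x2 arm-by-outcome table, so closed-form oracles apply.
    """
    treatment = np.repeat([1, 0], [n_treated, n_control]).astype(np.int8)
    outcome = np.concatenate(
        [
            np.repeat([1, 0], [events_treated, n_treated - events_treated]),
            np.repeat([1, 0], [events_control, n_control - events_control]),
        ]
    ).astype(np.int8)
    covariate = np.zeros(n_treated + n_control)
    risk = np.full(n_treated + n_control, 0.5)
    return TrialSample(
        treatment=treatment, covariate=covariate, outcome=outcome, risk=risk
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230213)
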