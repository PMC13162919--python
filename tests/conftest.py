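import numpy as np
import pytest

from fusesurv.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def toy4():
    """4-patient toy set: times 1..4, all events, binary covariate."""
    return {
        "X": np.array([[0.0], [1.0], [0.0], [1.0]]),
        "time": np.array([1.0, 2.0, 3.0, 4.0]),
        "event": np.array([1, 1, 1, 1]),
    }


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortSpec(n_patients=398, seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """Small cohort with a compact feature set for fast nested CV."""
    spec = CohortSpec(
        n_patients=250,
        family_sizes={"A": 4, "B": 5, "C": 3},
        true_group_effects={"B": [0.5, -0.4, 0.3, 0.2, -0.2]},
        seed=5,
    )
    return generate_cohort(spec)


def make_surv(rng, n, censor=0.3, signal=None):
    """Independent exponential survival data with optional linear signal."""
    if signal is None:
        lp = np.zeros(n)
        X = None
    else:
        X = rng.normal(size=(n, len(signal)))
        lp = X @ np.asarray(signal)
    T = rng.exponential(np.exp(-lp))
    if censor > 0:
        C = rng.exponential(T.mean() / censor, size=n)
    else:
        C = np.full(n, np.inf)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    return X, time, event
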