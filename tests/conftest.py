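import numpy as np
import pytest

import stickyhmm as sh


@pytest.fixture(scope="session")
def mmpp_small():
    """Small ground-truth MMPP session: 3 states, 8 neurons, 6 trials x 4 s."""
    spec = sh.random_mmpp_spec(
        3, 8, n_trials=6, trial_duration=4.0, seed=123, diag_range=(0.85, 0.98)
    )
    dataset, paths = sh.generate_mmpp(spec)
    return spec, dataset, paths


@pytest.fixture(scope="session")
def mmpp_small_counts(mmpp_small):
    _, dataset, _ = mmpp_small
    return sh.bin_spikes(dataset, 0.05)


@pytest.fixture()
def rng():
    return np.random.default_rng(987)


def random_counts(rng, K=2, N=3, T=10, lam=1.5, dt=0.05):
    return sh.BinnedCounts(counts=rng.poisson(lam, size=(K, N, T)), dt=dt)
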