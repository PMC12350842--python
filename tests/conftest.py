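import numpy as np
import pytest

import dlds


@pytest.fixture(scope="session")
def worm_fixture():
    """A small worm-like labeled recording with ground truth (session-cached)."""
    return dlds.generate_worm_fixture(seed=0, n_traces=40, T=900, n_labeled=20)


@pytest.fixture(scope="session")
def small_fit():
    """A quick fitted model on generated data, reused by read-only tests."""
    rec, truth = dlds.generate_dlds_data(p=3, M=3, T=120, n_traces=12, seed=4)
    hyper = dlds.Hyperparameters(p=3, M=3, lam_dyn=0.9, lam_x_sparse=1e-3,
                                 lam_c_sparse=1e-3, max_iter=60, conv_tol=1e-6,
                                 seed=9)
    model, lat, coef = dlds.fit(rec, hyper)
    return rec, truth, model, lat, coef


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
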