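import numpy as np
import pytest

import alarmnet as an


@pytest.fixture(scope="session")
def cfg():
    return an.generate_community(1)


@pytest.fixture(scope="session")
def true_idx(cfg):
    return an.true_indices(cfg)


@pytest.fixture(scope="session")
def predator_trials(cfg):
    return an.simulate_predator_trials(cfg, 9, seed=2)


@pytest.fixture(scope="session")
def playbacks(cfg, true_idx):
    return an.simulate_playbacks(cfg, true_idx, 6, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_index_inputs(rng, n_recv=4, n_pred=5, n_call=3):
    """Random (I, epsilon, A) triple for oracle comparisons."""
    import pandas as pd
    preds = [f"p{k}" for k in range(n_pred)]
    I = pd.DataFrame(rng.uniform(0, 1, (n_pred, n_call)), index=preds,
                     columns=[f"c{k}" for k in range(n_call)])
    eps = pd.DataFrame(rng.uniform(0, 1, (n_recv, n_pred)),
                       index=[f"r{k}" for k in range(n_recv)], columns=preds)
    A = pd.Series(rng.uniform(0.1, 2.0, n_pred), index=preds)
    return I, eps, A
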