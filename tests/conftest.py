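import numpy as np
import pytest

from ppcdrift import generate_session
from ppcdrift.session import KernelParams, TimingConfig
from ppcdrift.synthetic import DEFAULT_MIX

ALL_SELECTIVE_MIX = {k: v / sum(DEFAULT_MIX.values()) for k, v in DEFAULT_MIX.items()}


@pytest.fixture(scope="session")
def timing():
    return TimingConfig()


@pytest.fixture(scope="session")
def kernel():
    return KernelParams.cytosolic()


@pytest.fixture(scope="session")
def clean_session():
    """Small noiseless, drift-free session: ground truth exactly recoverable."""
    return generate_session(
        n_neurons=24, n_trials=24, noise_sd=0.0, drift_rate=0.0,
        error_rate=0.25, seed=2,
    )


@pytest.fixture(scope="session")
def noisy_session():
    """Default study conditions without drift."""
    return generate_session(seed=11, drift_rate=0.0)


@pytest.fixture(scope="session")
def drift_session():
    """Default study conditions with delay-period drift toward the
    opposite representation on error trials."""
    return generate_session(seed=11, drift_rate=0.5)


def brute_force_auroc(pos, neg):
    """Exhaustive pairwise auROC oracle: (wins + 0.5*ties) / (n_pos*n_neg)."""
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    wins = sum(1.0 for p in pos for n in neg if p > n)
    ties = sum(1.0 for p in pos for n in neg if p == n)
    return (wins + 0.5 * ties) / (pos.size * neg.size)
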