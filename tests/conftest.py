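import numpy as np
import pytest

from seqvote import (
    ClassPrototype,
    LocalClassifierBank,
    SequencePattern,
)


def euclidean_bank_1d(means_0, means_1):
    """A T-point, d=1 Euclidean bank with the given prototype mean tracks."""
    m0 = np.asarray(means_0, dtype=float).reshape(-1, 1)
    m1 = np.asarray(means_1, dtype=float).reshape(-1, 1)
    T = m0.shape[0]
    eye = np.broadcast_to(np.eye(1), (T, 1, 1)).copy()
    p0 = ClassPrototype("0", 0, m0, eye)
    p1 = ClassPrototype("1", 0, m1, eye.copy())
    return LocalClassifierBank(p0, p1, metric="euclidean")


@pytest.fixture
def three_point_bank():
    """T=3, d=1 Euclidean bank with prototypes at 0 and 1 everywhere."""
    return euclidean_bank_1d([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])


@pytest.fixture
def three_point_training_set():
    """Four labeled samples for the 3-point refinement walk-through.

    Three are classified correctly by independent voting; the fourth
    (``s3``) votes (1, 1, 0) and is misclassified until points 0 and 2 are
    forced to agree, which flips its assignment to (0, 1, 0).
    """
    pats = [
        SequencePattern("s1", "0", np.array([[0.1], [0.2], [0.1]])),
        SequencePattern("s2", "1", np.array([[0.9], [0.8], [0.9]])),
        SequencePattern("s3", "0", np.array([[0.8], [0.9], [0.15]])),
        SequencePattern("s4", "1", np.array([[0.9], [0.9], [0.8]])),
    ]
    sides = [0, 1, 0, 1]
    return pats, sides


def random_submodular_model(rng, T=None, long_range=True, pair_prob=0.35,
                            lam_scale=1.5):
    """A random energy model with symmetric non-negative smoothness terms."""
    from seqvote import EnergyModel, SmoothnessTermSet

    if T is None:
        T = int(rng.integers(2, 13))
    unary = rng.random((T, 2)) * 3.0
    ts = SmoothnessTermSet()
    for t in range(T):
        hi = T if long_range else min(t + 2, T)
        for tp in range(t + 1, hi):
            if rng.random() < pair_prob:
                ts.add(t, tp, float(rng.random() * lam_scale))
    return EnergyModel(unary, ts)
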