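import numpy as np
import pytest

import coat2fcm as c2


@pytest.fixture(scope="session")
def default_phantom():
    """The canonical noisy phantom: 128x128, one lesion, contrast 30, noise 5."""
    return c2.generate_phantom(128, 128, 1, 30.0, 5.0, False, seed=1)


@pytest.fixture(scope="session")
def pectoral_phantom():
    """Noiseless phantom with a pectoral triangle, for preprocessing tests."""
    return c2.generate_phantom(128, 128, 1, 30.0, 0.0, True, seed=3)


@pytest.fixture(scope="session")
def mixture3():
    """Well-separated 3-component mixture used for recovery tests."""
    return c2.generate_mixture(600, 3, 2, 8.0, 1.0, seed=3)


def matched_centroid_error(centroids: np.ndarray, true_centers: np.ndarray) -> float:
    """Max distance between fitted centroids and true centers under the
    best one-to-one matching."""
    from scipy.optimize import linear_sum_assignment

    d = np.linalg.norm(centroids[:, None] - true_centers[None], axis=2)
    r, c = linear_sum_assignment(d)
    return float(d[r, c].max())


def best_label_agreement(pred: np.ndarray, truth: np.ndarray, c: int) -> float:
    """Fraction of points labelled identically under the best permutation."""
    from itertools import permutations

    best = 0.0
    for perm in permutations(range(c)):
        mapped = np.asarray(perm)[pred]
        best = max(best, float((mapped == truth).mean()))
    return best
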