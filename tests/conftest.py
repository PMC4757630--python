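import itertools

import numpy as np
import pytest
from scipy.sparse.csgraph import minimum_spanning_tree as _mst

from foundertrace import HVSIHaplotype, STRProfile
from foundertrace.network import _distance_matrix


@pytest.fixture
def hap():
    """Factory for HVS-I haplotypes from terse variant sets."""

    def make(sample_id, variants, role="source", population="P"):
        return HVSIHaplotype(sample_id, population, role,
                             frozenset(variants))

    return make


@pytest.fixture
def profile():
    """Factory for STR profiles from repeat dicts."""

    def make(sample_id, repeats, role="source", population="P"):
        return STRProfile(sample_id, population, role, dict(repeats))

    return make


def steiner_minimum(X, w, max_added=3):
    """Brute-force weighted Steiner minimum over candidate median vectors.

    Enumerates every vector whose coordinates appear among the observed
    values of its character, tries adding up to ``max_added`` of them, and
    returns the smallest spanning cost. Independent oracle for network
    construction; only feasible for tiny inputs.
    """
    X = np.unique(np.asarray(X, dtype=np.int16), axis=0)
    w = np.asarray(w, dtype=float)

    def cost(pts):
        if len(pts) <= 1:
            return 0.0
        return float(_mst(_distance_matrix(pts, w)).sum())

    ranges = [sorted(set(X[:, c])) for c in range(X.shape[1])]
    observed = {r.tobytes() for r in X}
    candidates = [np.array(v, dtype=np.int16)
                  for v in itertools.product(*ranges)]
    candidates = [c for c in candidates if c.tobytes() not in observed]
    best = cost(X)
    for k in range(1, max_added + 1):
        for combo in itertools.combinations(candidates, k):
            trial = np.vstack([X, np.stack(combo)])
            best = min(best, cost(trial))
    return best
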