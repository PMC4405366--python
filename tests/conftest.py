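import numpy as np
import pytest

from tadens import (Ensemble, generate, p53_tad_fixture,
                    wild_type_like_spec)


@pytest.fixture(scope="session")
def wt_topology():
    return p53_tad_fixture()


@pytest.fixture(scope="session")
def small_wt_ensemble():
    """A modest wild-type-like synthetic ensemble shared across tests."""
    ensemble, truth = generate(wild_type_like_spec(n_frames=400, seed=2))
    return ensemble, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def oracle_relabeled_expectations(p, min_run=3):
    """Independent enumeration oracle: exact per-site expected helicity
    after the >=min_run relabeling for independent Bernoulli(p) sites,
    plus mean and variance of the per-frame segment-mean helicity.

    Written without reference to the package internals: itertools pattern
    walk, string-style run scanning."""
    import itertools
    n = len(p)
    site_exp = np.zeros(n)
    mean_sq = 0.0
    mean_e = 0.0
    for pattern in itertools.product((0, 1), repeat=n):
        prob = 1.0
        for s, pi in zip(pattern, p):
            prob *= pi if s else (1.0 - pi)
        if prob == 0.0:
            continue
        labeled = list(pattern)
        i = 0
        while i < n:
            if pattern[i]:
                j = i
                while j < n and pattern[j]:
                    j += 1
                if j - i < min_run:
                    for k in range(i, j):
                        labeled[k] = 0
                i = j
            else:
                i += 1
        site_exp += prob * np.asarray(labeled)
        frac = sum(labeled) / n
        mean_e += prob * frac
        mean_sq += prob * frac * frac
    return site_exp, mean_e, mean_sq - mean_e ** 2


def make_toy_ensemble(rng, n_res=6, n_frames=10, spread=6.0,
                      sequence=None):
    """Random-coordinate toy ensemble for oracle comparisons."""
    from tadens import Topology
    seq = sequence or "ACDEFGHIKLMNPQRSTVWY"[:n_res]
    topo = Topology.from_sequence(seq)
    coords = rng.uniform(-spread, spread, size=(n_frames, n_res, 3))
    return Ensemble(topology=topo, coordinates=coords)
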