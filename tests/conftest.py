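import numpy as np
import pytest
from hypothesis import settings

import smnet as sm

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


def random_proximity(rng: np.random.Generator, n: int, density: float) -> sm.ProximityGraph:
    """Random symmetric proximity graph with the given edge density."""
    w = rng.uniform(0.0, 1.0, (n, n))
    w = (w + w.T) / 2
    mask = rng.random((n, n)) < density
    mask = np.triu(mask, k=1)
    mask = mask | mask.T
    w = np.where(mask, np.maximum(w, 1e-6), 0.0)
    np.fill_diagonal(w, 0.0)
    return sm.ProximityGraph(weights=w)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def worked_closure():
    """3-node graph w12 = w23 = 0.8, w13 = 0.2: edge (0,2) is semi-metric."""
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 0.8
    w[1, 2] = w[2, 1] = 0.8
    w[0, 2] = w[2, 0] = 0.2
    p = sm.ProximityGraph(weights=w)
    return sm.metric_closure(sm.proximity_to_distance(p))


@pytest.fixture
def toy_parcellation():
    """4 regions: 2 left-frontal, 1 left-temporal, 1 right-frontal."""
    return sm.Parcellation(
        ids=("LF1", "LF2", "LT1", "RF1"),
        labels=("l_front_1", "l_front_2", "l_temp_1", "r_front_1"),
        hemisphere=("left", "left", "left", "right"),
        lobe=("frontal", "frontal", "temporal", "frontal"),
        centroids=np.array([[-40.0, 30, 20], [-35, 40, 25], [-50, -20, -10],
                            [40, 30, 20]]),
    )


@pytest.fixture(scope="session")
def default_study():
    """One generator-default study, shared across read-only tests."""
    return sm.make_group_study(seed=7)


def build_subject(sid, group, weights, node_ids=None, correlation=None):
    """Assemble a classified Subject from a raw weights matrix."""
    prox = sm.ProximityGraph(weights=np.asarray(weights, float), node_ids=node_ids)
    closure = sm.metric_closure(sm.proximity_to_distance(prox))
    corr = correlation
    n_neg = None
    if corr is not None:
        corr = np.asarray(corr, float)
        tri = np.triu_indices(corr.shape[0], k=1)
        n_neg = int((corr[tri] < 0).sum())
    return sm.Subject(subject_id=sid, group_label=group, proximity=prox,
                      closure=closure, correlation=corr, n_negative=n_neg)
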