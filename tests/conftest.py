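import itertools

import numpy as np
import pytest

from mesopath.geometry import Frame, SelectionPair, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def full_selection():
    def make(n_atoms):
        idx = np.arange(n_atoms)
        return SelectionPair(align_set=idx, measure_set=idx)

    return make


@pytest.fixture
def random_frame(rng):
    def make(n_atoms=5, scale=3.0, generator=None):
        g = generator or rng
        return Frame(coords=g.normal(0.0, scale, size=(n_atoms, 3)))

    return make


def random_rotation_matrix(generator):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=generator).as_matrix()


@pytest.fixture
def blob_distance_matrix(rng):
    """Euclidean distance matrix of well-separated planar blobs."""

    def make(sizes, sep=30.0, spread=1.0, generator=None):
        g = generator or rng
        k = len(sizes)
        centers = np.array([[i * sep, (i % 2) * sep] for i in range(k)], dtype=float)
        pts = np.concatenate(
            [c + g.normal(0.0, spread, size=(s, 2)) for c, s in zip(centers, sizes)]
        )
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        labels = np.repeat(np.arange(k), sizes)
        return D, labels

    return make


def exhaustive_kmedoids_cost(D, k):
    """Global optimum by enumerating every k-subset of medoids."""
    n = D.shape[0]
    best_cost, best_medoids = np.inf, None
    for medoids in itertools.combinations(range(n), k):
        cost = D[:, medoids].min(axis=1).sum()
        if cost < best_cost:
            best_cost, best_medoids = cost, medoids
    return best_cost, best_medoids


def enumerate_min_path_weight(G, source, sink):
    """Brute-force minimum total weight over all simple paths; None if none."""
    import networkx as nx

    best = None
    for path in nx.all_simple_paths(G, source, sink):
        w = sum(G.edges[a, b]["weight"] for a, b in zip(path[:-1], path[1:]))
        if best is None or w < best:
            best = w
    return best
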