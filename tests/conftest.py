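import numpy as np
import pytest

import softmsm as sm


@pytest.fixture(scope="session")
def small_spec():
    """2-state benchmark spec at reduced size (20 x 1000 frames)."""
    return sm.default_benchmark_spec(seed=0, n_trajectories=20, n_frames=1000)


@pytest.fixture(scope="session")
def small_benchmark(small_spec):
    return sm.make_benchmark_ensemble(small_spec)


@pytest.fixture(scope="session")
def hard_assignment(small_benchmark):
    """Hard (0/1) assignment from the true hidden state paths."""
    return sm.StateAssignment.from_labels(
        small_benchmark.ground_truth.state_paths, 2, 250.0)


@pytest.fixture(scope="session")
def angle_features(small_benchmark):
    """cos/sin-embedded phi+psi features of the small benchmark."""
    b = small_benchmark
    angles = sm.FeatureSeries(
        [np.concatenate([a, c], axis=1) for a, c in zip(b.phi.arrays, b.psi.arrays)],
        list(b.phi.labels) + list(b.psi.labels), 250.0, "rad")
    return sm.circular_embed(angles)


def count_transition_matrix(paths, k, lag=1):
    """Brute-force row-normalized transition-count matrix (test oracle)."""
    C = np.zeros((k, k))
    for p in paths:
        for a, b in zip(p[:-lag], p[lag:]):
            C[a, b] += 1
    return C / C.sum(axis=1, keepdims=True)


def semi_markov_path(n_frames, mean_dwell_frames, rng, pareto_shape=1.5):
    """Two-state alternating path with heavy-tailed (Pareto) dwell times.

    Dwells have the same mean as a matched Markov chain but infinite
    variance, so the path violates the Chapman-Kolmogorov relation.
    """
    # Pareto(shape a, scale m): mean = a*m/(a-1); match the target mean.
    scale = mean_dwell_frames * (pareto_shape - 1) / pareto_shape
    path = np.empty(n_frames, dtype=np.int64)
    t, s = 0, int(rng.integers(2))
    while t < n_frames:
        dwell = max(1, int(np.ceil(scale * (1 + rng.pareto(pareto_shape)))))
        path[t:t + dwell] = s
        t += dwell
        s = 1 - s
    return path
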