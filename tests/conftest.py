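import numpy as np
import pytest

import spatcoex as sx


@pytest.fixture(scope="session")
def default_spec():
    return sx.default_spec()


@pytest.fixture(scope="session")
def small_spec():
    """Asymmetric-competition community on a small lattice (fast runs)."""
    s = sx.default_spec().replace(lattice_side=50)
    return (
        s.with_param("c11", 0.3)
        .with_param("c22", 0.3)
        .with_param("c12", 0.1)
        .with_param("c21", 0.1)
    )


@pytest.fixture(scope="session")
def longrange_coex_ensemble(small_spec):
    """Long-range (mean-field geometry) stationary ensemble, reused by
    several statistical tests to keep the suite fast."""
    lr = sx.longrange_spec(small_spec)
    return lr, sx.run_ensemble(
        lr, 10, 42, run=sx.RunConfig(max_generations=300), keep_states=True,
        keep_trajectories=True,
    )


def brute_force_pair_counts(pattern_a, pattern_b, r_edges):
    """Independent oracle: enumerate every ordered pair, bin by torus
    distance into left-open annuli (r_k, r_{k+1}]."""
    L = pattern_a.lattice_side
    counts = np.zeros(len(r_edges) - 1, dtype=int)
    same = pattern_a.species_label == pattern_b.species_label
    for i, p in enumerate(pattern_a.points):
        for j, q in enumerate(pattern_b.points):
            if same and i == j:
                continue
            d = sx.torus_distance(p, q, L)
            for k in range(len(r_edges) - 1):
                if r_edges[k] < d <= r_edges[k + 1]:
                    counts[k] += 1
                    break
    return counts


def brute_force_annulus_sites(L, r_edges):
    """Oracle for the discrete annulus normaliser (offsets per bin)."""
    counts = np.zeros(len(r_edges) - 1, dtype=int)
    for dx in range(L):
        for dy in range(L):
            ddx = min(dx, L - dx)
            ddy = min(dy, L - dy)
            d = np.hypot(ddx, ddy)
            for k in range(len(r_edges) - 1):
                if r_edges[k] < d <= r_edges[k + 1]:
                    counts[k] += 1
                    break
    return counts
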