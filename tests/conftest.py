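import numpy as np
import pytest

from ipqtl.genetics_core import BackcrossGenotypes, GeneticMap, calc_genotype_probs


@pytest.fixture
def three_marker_map():
    return GeneticMap(
        chromosomes=["1"],
        marker_names={"1": ["m1", "m2", "m3"]},
        positions={"1": np.array([0.0, 10.0, 20.0])},
    )


@pytest.fixture
def typed_marker_setup():
    """One fully typed marker, 8 individuals, the hand-computed toy data."""
    gmap = GeneticMap(
        chromosomes=["1"],
        marker_names={"1": ["m1"]},
        positions={"1": np.array([0.0])},
    )
    geno = BackcrossGenotypes(
        map=gmap, matrix=np.array([[0], [0], [0], [0], [1], [1], [1], [1]], dtype=np.int8)
    )
    probs = calc_genotype_probs(gmap, geno, step=2.5, error_prob=0.0)
    y = np.array([1.0, 1.2, 0.8, 1.0, 2.0, 2.2, 1.8, 2.0])
    return probs, y


def brute_force_posterior(positions, obs, error_prob, grid, marker_cols, map_function="haldane"):
    """Exhaustive enumeration of all 2^G hidden-state paths on one chromosome.

    Independent oracle for the forward-backward posterior: obs is one
    individual's genotype codes (0/1/-1) at the markers; returns P(het) at
    every grid position.
    """
    from itertools import product

    from ipqtl.genetics_core import map_to_recomb

    G = len(grid)
    r = [map_to_recomb(grid[j + 1] - grid[j], map_function) for j in range(G - 1)]
    marg = np.zeros((G, 2))  # per-position marginals accumulated over paths
    for path in product((0, 1), repeat=G):
        p = 0.5
        for j in range(1, G):
            p *= r[j - 1] if path[j] != path[j - 1] else 1.0 - r[j - 1]
        for k, col in enumerate(marker_cols):
            o = obs[k]
            if o == -1:
                continue
            p *= (1.0 - error_prob) if path[col] == o else error_prob
        for j in range(G):
            marg[j, path[j]] += p
    return marg[:, 1] / marg.sum(axis=1)
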