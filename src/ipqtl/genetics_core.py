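"""Genetic maps, map functions, and conditional genotype probabilities.

A backcross has two genotype classes at every autosomal locus: homozygous
for the recurrent strain (coded 0) or heterozygous (coded 1). Conditional
probabilities of the heterozygous state on a pseudomarker grid are computed
with a two-state hidden Markov model by the forward-backward algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MISSING",
    "GeneticMap",
    "BackcrossGenotypes",
    "GenotypeProbGrid",
    "map_to_recomb",
    "recomb_to_map",
    "calc_genotype_probs",
]

#: sentinel for an untyped genotype in the integer genotype matrix
MISSING: int = -1


def map_to_recomb(d, map_function: str = "haldane"):
    """Convert genetic distance in cM to a recombination fraction.

    Haldane (default, no interference): r = (1 - exp(-2 d / 100)) / 2.
    Kosambi: r = tanh(2 d / 100) / 2.

    Accepts scalars or arrays; raises ``ValueError`` on negative distance.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distance must be non-negative")
    m = 2.0 * d / 100.0
    if map_function == "haldane":
        r = 0.5 * (1.0 - np.exp(-m))
    elif map_function == "kosambi":
        r = 0.5 * np.tanh(m)
    else:
        raise ValueError(f"unknown map function: {map_function!r}")
    return r if r.ndim else float(r)


def recomb_to_map(r, map_function: str = "haldane"):
    """Inverse of :func:`map_to_recomb` (cM from recombination fraction)."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    if map_function == "haldane":
        d = -50.0 * np.log(1.0 - 2.0 * r)
    elif map_function == "kosambi":
        d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    else:
        raise ValueError(f"unknown map function: {map_function!r}")
    return d if d.ndim else float(d)


@dataclass
class GeneticMap:
    """Ordered chromosomes with marker names and cM positions.

    Parameters
    ----------
    chromosomes
        Ordered chromosome labels.
    marker_names
        Per-chromosome marker name lists; names are globally unique.
    positions
        Per-chromosome non-decreasing cM positions (same lengths as names).
    """

    chromosomes: list[str]
    marker_names: dict[str, list[str]]
    positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.positions = {c: np.asarray(p, dtype=float) for c, p in self.positions.items()}
        seen: set[str] = set()
        for chrom in self.chromosomes:
            names = self.marker_names.get(chrom)
            pos = self.positions.get(chrom)
            if names is None or pos is None or len(names) == 0:
                raise ValueError(f"chromosome {chrom!r} has no markers")
            if len(names) != len(pos):
                raise ValueError(f"chromosome {chrom!r}: names/positions length mismatch")
            if not np.all(np.isfinite(pos)):
                raise ValueError(f"chromosome {chrom!r}: non-finite positions")
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"chromosome {chrom!r}: positions must be non-decreasing")
            if np.any(pos < 0):
                raise ValueError(f"chromosome {chrom!r}: negative position")
            dup = seen.intersection(names)
            if dup or len(set(names)) != len(names):
                raise ValueError(f"duplicate marker names: {sorted(dup) or 'within chromosome'}")
            seen.update(names)

    @property
    def n_markers(self) -> int:
        return sum(len(self.marker_names[c]) for c in self.chromosomes)

    def all_marker_names(self) -> list[str]:
        out: list[str] = []
        for c in self.chromosomes:
            out.extend(self.marker_names[c])
        return out

    def chrom_slices(self) -> dict[str, slice]:
        """Column slice of each chromosome in the concatenated marker order."""
        out: dict[str, slice] = {}
        start = 0
        for c in self.chromosomes:
            n = len(self.marker_names[c])
            out[c] = slice(start, start + n)
            start += n
        return out


@dataclass
class BackcrossGenotypes:
    """Individuals x markers genotype matrix for a backcross.

    Codes: 0 recurrent homozygote, 1 heterozygote, MISSING (-1) untyped.
    Column order follows the map's concatenated marker order.
    """

    map: GeneticMap
    matrix: np.ndarray
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise ValueError("genotype matrix must be 2-D")
        if self.matrix.shape[1] != self.map.n_markers:
            raise ValueError(
                f"genotype matrix has {self.matrix.shape[1]} columns, "
                f"map has {self.map.n_markers} markers"
            )
        bad = ~np.isin(self.matrix, (0, 1, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be 0, 1 or MISSING")
        if not self.individual_ids:
            self.individual_ids = [f"ind{i + 1}" for i in range(self.matrix.shape[0])]
        elif len(self.individual_ids) != self.matrix.shape[0]:
            raise ValueError("individual_ids length mismatch")

    @property
    def n_individuals(self) -> int:
        return self.matrix.shape[0]


@dataclass
class GenotypeProbGrid:
    """Per-chromosome grid positions and P(heterozygote) posteriors.

    ``p_het[chrom]`` has shape (n_individuals, n_grid_positions); the grid
    is the union of true marker positions and pseudomarkers at a fixed step.
    """

    chromosomes: list[str]
    grid_positions: dict[str, np.ndarray]
    p_het: dict[str, np.ndarray]
    is_marker: dict[str, np.ndarray]
    step: float
    error_prob: float
    map_function: str = "haldane"
    individual_ids: list[str] = field(default_factory=list)

    @property
    def n_individuals(self) -> int:
        return self.p_het[self.chromosomes[0]].shape[0]

    def n_positions(self) -> int:
        return sum(len(self.grid_positions[c]) for c in self.chromosomes)

    def locus_column(self, chrom: str, position: float) -> np.ndarray:
        """p_het column at the grid position nearest ``position`` on ``chrom``."""
        if chrom not in self.grid_positions:
            raise KeyError(f"unknown chromosome {chrom!r}")
        pos = self.grid_positions[chrom]
        j = int(np.argmin(np.abs(pos - position)))
        return self.p_het[chrom][:, j]

    def stacked(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Concatenate all chromosomes: (chrom index array, positions, p_het)."""
        chrom_idx = np.concatenate(
            [np.full(len(self.grid_positions[c]), i) for i, c in enumerate(self.chromosomes)]
        )
        pos = np.concatenate([self.grid_positions[c] for c in self.chromosomes])
        p = np.concatenate([self.p_het[c] for c in self.chromosomes], axis=1)
        return chrom_idx, pos, p


def _build_grid(pos: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Grid = marker positions union regular steps from the first marker.

    Returns (grid, marker_col_of_each_input_marker, is_marker mask).
    Marker positions are always retained exactly.
    """
    lo, hi = float(pos[0]), float(pos[-1])
    n_steps = int(np.floor((hi - lo) / step + 1e-9))
    pseudo = lo + step * np.arange(n_steps + 1)
    grid = np.union1d(np.round(pos, 10), np.round(pseudo, 10))
    # map each marker to its grid column
    marker_cols = np.searchsorted(grid, np.round(pos, 10))
    is_marker = np.zeros(len(grid), dtype=bool)
    is_marker[marker_cols] = True
    return grid, marker_cols, is_marker


def _forward_backward_chrom(
    obs: np.ndarray,
    grid: np.ndarray,
    marker_cols: np.ndarray,
    error_prob: float,
    map_function: str,
) -> np.ndarray:
    """Posterior P(het) at every grid position for all individuals.

    obs: (n, n_markers) with codes 0/1/MISSING. States: 0 hom, 1 het,
    stationary prior 1/2 each; emission only at typed marker positions.
    Scaled forward-backward, vectorized over individuals.
    """
    n, _ = obs.shape
    G = len(grid)
    # emission likelihoods per grid position: shape (n, G, 2); 1 where no signal
    emit = np.ones((n, G, 2))
    e = error_prob
    for k, col in enumerate(marker_cols):
        o = obs[:, k]
        typed0 = o == 0
        typed1 = o == 1
        # match with prob 1-e, mismatch with prob e, symmetric in states
        emit[typed0, col, 0] *= 1.0 - e
        emit[typed0, col, 1] *= e
        emit[typed1, col, 0] *= e
        emit[typed1, col, 1] *= 1.0 - e

    r = map_to_recomb(np.diff(grid), map_function=map_function)
    r = np.atleast_1d(r)

    alpha = np.empty((G, n, 2))
    a = 0.5 * emit[:, 0, :]
    a /= a.sum(axis=1, keepdims=True)
    alpha[0] = a
    for j in range(1, G):
        rj = r[j - 1]
        stay, switch = 1.0 - rj, rj
        prev = alpha[j - 1]
        a = np.empty_like(prev)
        a[:, 0] = prev[:, 0] * stay + prev[:, 1] * switch
        a[:, 1] = prev[:, 0] * switch + prev[:, 1] * stay
        a *= emit[:, j, :]
        a /= a.sum(axis=1, keepdims=True)
        alpha[j] = a

    beta = np.empty((G, n, 2))
    beta[G - 1] = 1.0
    for j in range(G - 2, -1, -1):
        rj = r[j]
        stay, switch = 1.0 - rj, rj
        nxt = beta[j + 1] * emit[:, j + 1, :]
        b = np.empty_like(nxt)
        b[:, 0] = nxt[:, 0] * stay + nxt[:, 1] * switch
        b[:, 1] = nxt[:, 0] * switch + nxt[:, 1] * stay
        b /= b.sum(axis=1, keepdims=True)
        beta[j] = b

    post = alpha * beta
    post /= post.sum(axis=2, keepdims=True)
    return post[:, :, 1].T  # (n, G)


def calc_genotype_probs(
    gmap: GeneticMap,
    geno: BackcrossGenotypes,
    step: float = 2.5,
    error_prob: float = 0.001,
    map_function: str = "haldane",
) -> GenotypeProbGrid:
    """Conditional heterozygote probabilities on a pseudomarker grid.

    At each grid position the posterior of the hidden two-state Markov chain
    (recurrent homozygote / heterozygote, stationary prior 1/2 each) is
    computed by forward-backward. Transitions between adjacent grid positions
    use the map function's recombination fraction; typed markers emit the
    observed genotype with probability ``1 - error_prob``.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if not 0 <= error_prob < 0.5:
        raise ValueError("error_prob must lie in [0, 0.5)")
    if geno.map is not gmap and geno.map.all_marker_names() != gmap.all_marker_names():
        raise ValueError("genotypes were built against a different map")

    slices = gmap.chrom_slices()
    grid_positions: dict[str, np.ndarray] = {}
    p_het: dict[str, np.ndarray] = {}
    is_marker: dict[str, np.ndarray] = {}
    for chrom in gmap.chromosomes:
        pos = gmap.positions[chrom]
        grid, marker_cols, marker_mask = _build_grid(pos, step)
        obs = geno.matrix[:, slices[chrom]]
        p = _forward_backward_chrom(obs, grid, marker_cols, error_prob, map_function)
        grid_positions[chrom] = grid
        p_het[chrom] = p
        is_marker[chrom] = marker_mask

    return GenotypeProbGrid(
        chromosomes=list(gmap.chromosomes),
        grid_positions=grid_positions,
        p_het=p_het,
        is_marker=is_marker,
        step=step,
        error_prob=error_prob,
        map_function=map_function,
        individual_ids=list(geno.individual_ids),
    )
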