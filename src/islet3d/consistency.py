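"""Shuffle-normalized KL-divergence consistency of cell rankings.

For each oscillation, cells are ranked either by a functional value (degree
or phase — *cellular* consistency) or by their distance to the centre of
gravity of the top subpopulation (*regional* consistency). Each ranking is
turned into a strictly positive probability vector with a normal density
over ranks, and consecutive oscillations are compared with

    D_KL(P_i || P_j) = sum_n P_i(n) * log(P_i(n) / P_j(n))

normalized by the KL divergence of shuffled rankings, so 0 means a perfectly
predictable ranking and ~1 means completely random.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

DEFAULT_SIGMA_FRACTION = 1.0 / 6.0
DEFAULT_N_SHUFFLES = 100


@dataclass
class RankVector:
    oscillation: int
    mode: str                 # "cellular" | "regional"
    basis: str                # "degree" | "phase"
    ranks: np.ndarray         # (N,) permutation of 1..N; 1 = best
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=int)
        n = self.ranks.size
        if not np.array_equal(np.sort(self.ranks), np.arange(1, n + 1)):
            raise ValueError("ranks must be a permutation of 1..N")


@dataclass
class ConsistencyResult:
    pairs: list[tuple[int, int]]       # compared oscillation indices
    raw_kl: np.ndarray                 # per pair
    normalizer: np.ndarray             # per pair, from shuffles
    normalized_kl: np.ndarray          # raw / normalizer
    n_shuffles: int
    seed: int

    @property
    def mean_normalized(self) -> float:
        return float(self.normalized_kl.mean())


def rank_cells(
    values: np.ndarray,
    basis: str,
    mode: str = "cellular",
    positions: np.ndarray | None = None,
    top_set: np.ndarray | None = None,
    cell_ids: np.ndarray | None = None,
    oscillation: int = 0,
) -> RankVector:
    """Dense ranks 1..N for one oscillation.

    Cellular mode ranks by descending degree or ascending phase; regional
    mode ranks by ascending distance to the COG of the top subpopulation.
    Ties break by ascending cell id; missing (NaN) values rank last.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if cell_ids is None:
        cell_ids = np.arange(n)
    cell_ids = np.asarray(cell_ids)
    if mode == "regional":
        if positions is None or top_set is None:
            raise ValueError("regional mode needs positions and the top set")
        cog = positions[np.isin(cell_ids, top_set)].mean(axis=0)
        keys = np.linalg.norm(positions - cog, axis=1)
    elif mode == "cellular":
        if basis == "degree":
            keys = -values          # descending: highest degree ranks first
        elif basis == "phase":
            keys = values.copy()    # ascending: earliest phase ranks first
        else:
            raise ValueError(f"unknown basis {basis!r}")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    keys = np.where(np.isnan(keys), np.inf, keys)   # flagged cells rank last
    order = np.lexsort((cell_ids, keys))
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    return RankVector(
        oscillation=oscillation, mode=mode, basis=basis, ranks=ranks, cell_ids=cell_ids
    )


def rank_pdf(
    ranks: np.ndarray | RankVector, sigma_fraction: float = DEFAULT_SIGMA_FRACTION
) -> np.ndarray:
    """Strictly positive probability vector over cells from their ranks.

    P(n) is the normal density at rank_n with mean (N+1)/2 and SD
    ``sigma_fraction * N`` (default N/6: the rank range spans about +-3 SD),
    renormalized to sum to exactly 1.
    """
    r = ranks.ranks if isinstance(ranks, RankVector) else np.asarray(ranks)
    n = r.size
    dens = norm.pdf(r, loc=(n + 1) / 2.0, scale=sigma_fraction * n)
    return dens / dens.sum()


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """D_KL(p || q) = sum p * log(p / q), natural log; requires p, q > 0."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(p <= 0) or np.any(q <= 0):
        raise ValueError("KL divergence requires strictly positive vectors")
    return float(np.sum(p * np.log(p / q)))


def normalized_consistency(
    rank_vectors: list[RankVector] | list[np.ndarray],
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    normalizer_mode: str = "mean",
    seed: int = 0,
    sigma_fraction: float = DEFAULT_SIGMA_FRACTION,
    all_pairs: bool = False,
) -> ConsistencyResult:
    """Shuffle-normalized KL divergence between oscillations' rankings.

    For each consecutive pair (all pairs optionally), the raw KL divergence
    of the rank probability vectors is divided by a normalizer obtained by
    uniformly permuting the second ranking ``n_shuffles`` times: the mean
    shuffle KL by default, making the expectation for unrelated rankings 1;
    ``max`` is available as a stricter ceiling.
    """
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be at least 2")
    vectors = [
        rv.ranks if isinstance(rv, RankVector) else np.asarray(rv, dtype=int)
        for rv in rank_vectors
    ]
    indices = [
        rv.oscillation if isinstance(rv, RankVector) else i
        for i, rv in enumerate(rank_vectors)
    ]
    if len(vectors) < 2:
        raise ValueError("need rankings from at least 2 oscillations")
    rng = np.random.default_rng(seed)
    if all_pairs:
        pair_idx = [(a, b) for a in range(len(vectors)) for b in range(a + 1, len(vectors))]
    else:
        pair_idx = [(a, a + 1) for a in range(len(vectors) - 1)]

    raw = np.empty(len(pair_idx))
    norms = np.empty(len(pair_idx))
    for out_i, (a, b) in enumerate(pair_idx):
        p = rank_pdf(vectors[a], sigma_fraction)
        q = rank_pdf(vectors[b], sigma_fraction)
        raw[out_i] = kl_divergence(p, q)
        shuffles = np.empty(n_shuffles)
        for s in range(n_shuffles):
            shuffles[s] = kl_divergence(p, rng.permutation(q))
        if normalizer_mode == "mean":
            norms[out_i] = shuffles.mean()
        elif normalizer_mode == "max":
            norms[out_i] = shuffles.max()
        else:
            raise ValueError(f"unknown normalizer_mode {normalizer_mode!r}")
        if norms[out_i] <= 0:
            raise ValueError("shuffle normalizer is non-positive")
    return ConsistencyResult(
        pairs=[(indices[a], indices[b]) for a, b in pair_idx],
        raw_kl=raw,
        normalizer=norms,
        normalized_kl=raw / norms,
        n_shuffles=n_shuffles,
        seed=seed,
    )
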