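"""Per-oscillation functional networks at a fixed average degree.

An edge joins two cells whose Ca2+ correlation over an oscillation window
exceeds a per-islet threshold. The threshold is calibrated so the mean degree
over all cells and oscillations is as close as possible to a target (default
7 edges per cell), which compensates inter-islet heterogeneity better than a
fixed correlation cutoff. High/low-degree subpopulations are the top/bottom
10% of cells by degree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .segmentation import OscillationSegment

DEFAULT_TARGET_DEGREE = 7.0
DEFAULT_SUBPOP_FRACTION = 0.10


@dataclass
class FunctionalNetwork:
    oscillation: int
    correlation: np.ndarray          # (N, N), in [-1, 1], diagonal 1
    threshold: float
    adjacency: np.ndarray            # (N, N) bool, symmetric, zero diagonal
    degree: np.ndarray               # (N,) int
    high_set: np.ndarray             # ids of the top-fraction cells by degree
    low_set: np.ndarray              # ids of the bottom-fraction cells
    cell_ids: np.ndarray
    flagged: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class SpatialStats:
    """Spatial summary of degree- or phase-defined subpopulations."""

    center: np.ndarray                 # islet centre of mass, um
    normalized_distance: np.ndarray    # (N,) distance to centre / max, in [0, 1]
    cog: np.ndarray                    # (K, 3) subpopulation COG per oscillation
    displacement: np.ndarray           # (K-1,) normalized COG shift per transition
    cell_ids: np.ndarray

    def mean_normalized_distance(self, ids: np.ndarray | None = None) -> float:
        if ids is None:
            return float(self.normalized_distance.mean())
        mask = np.isin(self.cell_ids, ids)
        return float(self.normalized_distance[mask].mean())


def pairwise_correlation(
    traces: np.ndarray,
    segment: OscillationSegment | slice | None = None,
    method: str = "pearson",
) -> tuple[np.ndarray, np.ndarray]:
    """Cell-by-cell correlation of the windowed traces.

    Pearson correlation of per-cell z-scored traces over the segment window
    (Spearman optionally, via rank transform). Zero-variance cells get zero
    correlation to every other cell and are returned as flagged indices.

    Returns (correlation matrix, flagged cell indices).
    """
    traces = np.asarray(traces, dtype=float)
    if isinstance(segment, OscillationSegment):
        window = traces[:, segment.window]
    elif isinstance(segment, slice):
        window = traces[:, segment]
    else:
        window = traces
    if window.shape[1] < 3:
        raise ValueError("correlation window must span at least 3 frames")
    if method == "spearman":
        from scipy.stats import rankdata

        window = rankdata(window, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    centered = window - window.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1)
    flagged = np.flatnonzero(sd == 0)
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = centered / safe_sd[:, None]
    corr = (z @ z.T) / window.shape[1]
    corr = np.clip(corr, -1.0, 1.0)
    corr[flagged, :] = 0.0
    corr[:, flagged] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr, flagged


def _pooled_offdiag(matrices: list[np.ndarray]) -> np.ndarray:
    iu = np.triu_indices(matrices[0].shape[0], k=1)
    return np.concatenate([m[iu] for m in matrices])


def calibrate_threshold(
    matrices: list[np.ndarray], target_degree: float = DEFAULT_TARGET_DEGREE
) -> tuple[float, float]:
    """One correlation threshold per islet, fixing the oscillation-averaged degree.

    The mean degree is a non-increasing step function of the threshold, so the
    threshold realising the closest achievable mean degree is found directly
    on the sorted pooled off-diagonal correlations of all oscillations (ties
    between equally close degrees resolve to the sparser network / larger
    threshold). Returns (threshold, achieved mean degree).
    """
    if not matrices:
        raise ValueError("need at least one correlation matrix")
    n = matrices[0].shape[0]
    if target_degree >= n:
        raise ValueError("target_degree must be smaller than the cell count")
    k_osc = len(matrices)
    vals = np.sort(_pooled_offdiag(matrices))[::-1]  # descending
    m = vals.size
    # Edge count c is achievable iff a strict threshold separates vals[c-1]
    # from vals[c]; ties make intermediate counts unreachable.
    target_edges = target_degree * n * k_osc / 2.0
    boundary_ok = np.empty(m + 1, dtype=bool)
    boundary_ok[0] = True
    boundary_ok[m] = True
    boundary_ok[1:m] = vals[:-1] > vals[1:]
    counts = np.flatnonzero(boundary_ok)
    # Closest achievable count; ties -> smaller count (larger threshold).
    best = counts[np.argmin(np.abs(counts - target_edges))]
    if best == m:
        threshold = float(np.nextafter(vals[-1], -np.inf))
    else:
        threshold = float(vals[best])
    achieved = 2.0 * best / (n * k_osc)
    if abs(achieved - target_degree) > 1.0:
        warnings.warn(
            f"target mean degree {target_degree} unreachable; "
            f"closest achievable is {achieved:.3f}"
        )
    return threshold, float(achieved)


def build_network(
    correlation: np.ndarray,
    threshold: float,
    cell_ids: np.ndarray | None = None,
    oscillation: int = 0,
    fraction: float = DEFAULT_SUBPOP_FRACTION,
    flagged: np.ndarray | None = None,
) -> FunctionalNetwork:
    """Threshold a correlation matrix into a functional network.

    Edge iff correlation strictly exceeds the threshold. ``high_set`` /
    ``low_set`` hold the ids of the top / bottom ``round(fraction * N)`` cells
    by degree, ties broken by ascending cell id.
    """
    correlation = np.asarray(correlation, dtype=float)
    n = correlation.shape[0]
    if cell_ids is None:
        cell_ids = np.arange(n)
    cell_ids = np.asarray(cell_ids)
    adjacency = correlation > threshold
    np.fill_diagonal(adjacency, False)
    degree = adjacency.sum(axis=1).astype(int)
    k = int(round(fraction * n))
    order_desc = np.lexsort((cell_ids, -degree))
    order_asc = np.lexsort((cell_ids, degree))
    return FunctionalNetwork(
        oscillation=oscillation,
        correlation=correlation,
        threshold=float(threshold),
        adjacency=adjacency,
        degree=degree,
        high_set=np.sort(cell_ids[order_desc[:k]]),
        low_set=np.sort(cell_ids[order_asc[:k]]),
        cell_ids=cell_ids,
        flagged=cell_ids[flagged] if flagged is not None else np.array([], dtype=int),
    )


def build_islet_networks(
    traces: np.ndarray,
    segments: list[OscillationSegment],
    cell_ids: np.ndarray | None = None,
    target_degree: float = DEFAULT_TARGET_DEGREE,
    fraction: float = DEFAULT_SUBPOP_FRACTION,
    method: str = "pearson",
) -> tuple[list[FunctionalNetwork], float, float]:
    """Correlate every analysable oscillation, calibrate one shared threshold,
    and build the per-oscillation networks.

    Returns (networks, threshold, achieved mean degree). Segments flagged
    incomplete or flat are skipped.
    """
    usable = [s for s in segments if not (s.incomplete or s.flat)]
    if not usable:
        raise ValueError("no usable oscillation segments")
    results = [pairwise_correlation(traces, s, method) for s in usable]
    matrices = [corr for corr, _ in results]
    threshold, achieved = calibrate_threshold(matrices, target_degree)
    networks = [
        build_network(corr, threshold, cell_ids, s.index, fraction, flags)
        for (corr, flags), s in zip(results, usable)
    ]
    return networks, threshold, achieved


def spatial_stats(
    positions: np.ndarray,
    sets_per_oscillation: list[np.ndarray],
    cell_ids: np.ndarray | None = None,
) -> SpatialStats:
    """Normalized radial placement of a subpopulation and its COG drift.

    The islet centre is the mean of all cell positions; per-cell distances to
    it are normalized by the maximum (so the farthest cell scores exactly 1).
    The subpopulation centre of gravity is tracked across oscillations and
    each consecutive displacement is normalized by the same maximum radius so
    islets of different sizes are comparable.
    """
    positions = np.asarray(positions, dtype=float)
    if cell_ids is None:
        cell_ids = np.arange(positions.shape[0])
    cell_ids = np.asarray(cell_ids)
    for s in sets_per_oscillation:
        if len(s) == 0:
            raise ValueError("subpopulation sets must be non-empty")
    center = positions.mean(axis=0)
    dist = np.linalg.norm(positions - center, axis=1)
    max_dist = dist.max()
    if max_dist == 0:
        raise ValueError("all cells coincide; spatial statistics undefined")
    cogs = np.array(
        [
            positions[np.isin(cell_ids, ids)].mean(axis=0)
            for ids in sets_per_oscillation
        ]
    )
    displacement = np.linalg.norm(np.diff(cogs, axis=0), axis=1) / max_dist
    return SpatialStats(
        center=center,
        normalized_distance=dist / max_dist,
        cog=cogs,
        displacement=displacement,
        cell_ids=cell_ids,
    )


def retention_rate(set_i: np.ndarray, set_j: np.ndarray) -> float:
    """Fraction of ``set_i`` still present in ``set_j``."""
    set_i = np.asarray(set_i)
    if set_i.size == 0:
        raise ValueError("set_i must be non-empty")
    return float(np.isin(set_i, set_j).sum() / set_i.size)
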