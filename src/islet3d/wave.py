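"""Ca2+ wave analysis: per-cell phase, early/late cells, and the wave axis.

Each cell's phase is the integer-frame lag that maximises its cross
correlation with the islet-average trace over an oscillation window
(positive phase = the cell lags the islet mean; negative = it leads). The
earliest/latest 10% of cells define the wave, whose axis is the first
principal component of their positions oriented early->late. Axis change
between oscillations is the squared Euclidean distance between consecutive
unit axes, normalized by the variability of axes fit to randomly drawn
early/late sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .segmentation import OscillationSegment

DEFAULT_EXCLUSION_RADIUS = 50.0   # um from the subpopulation COG
DEFAULT_N_RESAMPLES = 50_000
DEFAULT_SUBPOP_FRACTION = 0.10


@dataclass
class PhaseMap:
    """Per-cell phase for one oscillation (seconds; negative = leads)."""

    oscillation: int
    phase: np.ndarray                # (N,) s; NaN for flagged cells
    max_correlation: np.ndarray      # (N,) peak lagged correlation
    early_set: np.ndarray            # ids of the most-leading cells
    late_set: np.ndarray             # ids of the most-lagging cells
    cell_ids: np.ndarray
    flagged: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def early_late_lag(self) -> float:
        return early_late_time_lag(self)


@dataclass
class WaveAxisResult:
    """Wave axes across oscillations and their normalized variability."""

    axes: np.ndarray                 # (K, 3) unit vectors, early->late
    excluded: list[np.ndarray]       # per oscillation, ids dropped as outliers
    raw_change: np.ndarray           # (K-1,) squared distance between axes, [0, 4]
    normalized_change: np.ndarray    # (K-1,) raw / resampling normalizer
    normalizer: float
    n_resamples: int
    seed: int


def _lagged_correlation(traces: np.ndarray, reference: np.ndarray, lag: int) -> np.ndarray:
    """Pearson r of traces[:, t] against reference[t - lag], all cells at once."""
    t = reference.size
    if lag >= 0:
        a = traces[:, lag:]
        b = reference[: t - lag]
    else:
        a = traces[:, : t + lag]
        b = reference[-lag:]
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean()
    denom = np.sqrt((a**2).sum(axis=1) * (b**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (a @ b) / denom, np.nan)


def phase_map(
    traces: np.ndarray,
    segment: OscillationSegment,
    sampling_rate: float,
    max_lag: float | None = None,
    cell_ids: np.ndarray | None = None,
    fraction: float = DEFAULT_SUBPOP_FRACTION,
) -> PhaseMap:
    """Assign every cell the lag maximising its correlation with the islet mean.

    Lags run over integer frames in [-max_lag, +max_lag] seconds (default:
    half the oscillation period, capped so at least 3 frames overlap).
    Ties resolve to the smallest |lag|, then to the negative lag.
    Zero-variance cells get NaN phase and are excluded from the sets.
    """
    traces = np.asarray(traces, dtype=float)
    n = traces.shape[0]
    if cell_ids is None:
        cell_ids = np.arange(n)
    cell_ids = np.asarray(cell_ids)
    window = traces[:, segment.window]
    t = window.shape[1]
    if max_lag is None:
        max_lag = (segment.period if np.isfinite(segment.period) else t / sampling_rate) / 2.0
    max_lag_frames = int(round(max_lag * sampling_rate))
    max_lag_frames = min(max_lag_frames, (t - 3) // 2)
    if max_lag_frames < 0:
        raise ValueError("window too short for the requested max_lag")
    reference = window.mean(axis=0)

    lags = np.arange(-max_lag_frames, max_lag_frames + 1)
    corr = np.full((n, lags.size), -np.inf)
    for j, lag in enumerate(lags):
        corr[:, j] = _lagged_correlation(window, reference, int(lag))
    flagged = np.flatnonzero(np.all(~np.isfinite(corr) | (corr == -np.inf), axis=1))
    corr = np.where(np.isfinite(corr), corr, -np.inf)
    # Tie-break: smallest |lag| first, then the negative one.
    tie_order = np.lexsort((lags, np.abs(lags)))
    best = tie_order[np.argmax(corr[:, tie_order], axis=1)]
    phase = lags[best] / sampling_rate
    max_corr = corr[np.arange(n), best]
    phase = phase.astype(float)
    phase[flagged] = np.nan
    max_corr = max_corr.astype(float)
    max_corr[flagged] = np.nan
    if flagged.size:
        warnings.warn(f"{flagged.size} zero-variance cells excluded from phase sets")

    valid = np.flatnonzero(np.isfinite(phase))
    k = int(round(fraction * n))
    order = valid[np.lexsort((cell_ids[valid], phase[valid]))]
    early = np.sort(cell_ids[order[:k]])
    late = np.sort(cell_ids[order[len(order) - k :]])
    return PhaseMap(
        oscillation=segment.index,
        phase=phase,
        max_correlation=max_corr,
        early_set=early,
        late_set=late,
        cell_ids=cell_ids,
        flagged=cell_ids[flagged],
    )


def depolarization_times(
    traces: np.ndarray,
    segment: OscillationSegment,
    sampling_rate: float,
    cell_ids: np.ndarray | None = None,
    fraction: float = DEFAULT_SUBPOP_FRACTION,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell rising half-max crossing time within the window (seconds).

    The first upward crossing of each cell's own half-max level is linearly
    interpolated between frames; times are relative to the window start.
    Returns (times with NaN for non-crossing cells, ids of the earliest
    ``round(fraction * N)`` cells — the "depolarize-first" set).
    """
    traces = np.asarray(traces, dtype=float)
    n = traces.shape[0]
    if cell_ids is None:
        cell_ids = np.arange(n)
    cell_ids = np.asarray(cell_ids)
    window = traces[:, segment.window]
    half = 0.5 * (window.min(axis=1) + window.max(axis=1))
    above = window > half[:, None]
    times = np.full(n, np.nan)
    for i in range(n):
        if window[i].max() <= window[i].min():
            continue
        idx = np.flatnonzero(~above[i, :-1] & above[i, 1:])
        if idx.size == 0:
            if above[i, 0]:
                times[i] = 0.0
            continue
        j = idx[0]
        frac = (half[i] - window[i, j]) / (window[i, j + 1] - window[i, j])
        times[i] = (j + frac) / sampling_rate
    missing = np.flatnonzero(np.isnan(times))
    if missing.size:
        warnings.warn(f"{missing.size} cells never cross half-max; excluded")
    valid = np.flatnonzero(np.isfinite(times))
    k = int(round(fraction * n))
    order = valid[np.lexsort((cell_ids[valid], times[valid]))]
    first_set = np.sort(cell_ids[order[:k]])
    return times, first_set


def _principal_axis(points: np.ndarray) -> np.ndarray:
    """First PC of a point cloud via the 3x3 position covariance.

    Deterministic sign convention before any orientation flip: the component
    of largest magnitude is made positive (lexicographic order breaks exact
    magnitude ties).
    """
    centered = points - points.mean(axis=0)
    cov = centered.T @ centered / max(len(points) - 1, 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    axis = eigvecs[:, np.argmax(eigvals)]
    lead = np.argmax(np.abs(np.round(axis, 12)))
    if axis[lead] < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def wave_axis(
    positions: np.ndarray,
    early_set: np.ndarray,
    late_set: np.ndarray,
    cell_ids: np.ndarray | None = None,
    exclusion_radius: float = DEFAULT_EXCLUSION_RADIUS,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit wave axis (early->late) from early/late cell positions.

    Cells farther than ``exclusion_radius`` from their own set's centre of
    gravity are dropped as spurious; the axis is the first principal
    component of the retained early+late positions, oriented from the early
    COG toward the late COG. Returns (axis, excluded ids).
    """
    positions = np.asarray(positions, dtype=float)
    if cell_ids is None:
        cell_ids = np.arange(positions.shape[0])
    cell_ids = np.asarray(cell_ids)

    retained = []
    excluded = []
    cogs = []
    for ids in (early_set, late_set):
        mask = np.isin(cell_ids, ids)
        pts = positions[mask]
        if pts.shape[0] == 0:
            raise ValueError("early/late set has no cells with known positions")
        cog = pts.mean(axis=0)
        keep = np.linalg.norm(pts - cog, axis=1) <= exclusion_radius
        if not keep.any():
            raise ValueError("all cells of one set fall outside the exclusion radius")
        retained.append(pts[keep])
        excluded.append(cell_ids[mask][~keep])
        cogs.append(pts[keep].mean(axis=0))
    points = np.vstack(retained)
    if points.shape[0] < 2:
        raise ValueError("need at least 2 retained cells to fit a wave axis")
    axis = _principal_axis(points)
    direction = cogs[1] - cogs[0]
    if axis @ direction < 0:
        axis = -axis
    return axis, np.concatenate(excluded)


def _batched_resample_axes(
    positions: np.ndarray,
    k_early: int,
    k_late: int,
    n_resamples: int,
    rng: np.random.Generator,
    exclusion_radius: float,
    chunk: int = 5_000,
) -> np.ndarray:
    """Axes for randomly drawn early/late sets (disjoint, uniform), batched.

    Outlier exclusion and the early->late orientation match ``wave_axis``;
    the PCA is a batched 3x3 eigendecomposition with mask weights standing in
    for excluded cells.
    """
    n = positions.shape[0]
    out = np.empty((n_resamples, 3))
    done = 0
    while done < n_resamples:
        b = min(chunk, n_resamples - done)
        # Draw k_early + k_late distinct cells per resample.
        picks = np.argsort(rng.random((b, n)), axis=1)[:, : k_early + k_late]
        groups = (picks[:, :k_early], picks[:, k_early:])
        masks = []
        cogs = []
        for g in groups:
            pts = positions[g]                       # (b, k, 3)
            cog = pts.mean(axis=1, keepdims=True)
            keep = (
                np.linalg.norm(pts - cog, axis=2) <= exclusion_radius
            )                                        # (b, k)
            # Guard: never drop an entire set in a resample.
            empty = ~keep.any(axis=1)
            keep[empty] = True
            masks.append(keep)
            w = keep[..., None]
            cogs.append((pts * w).sum(axis=1) / w.sum(axis=1))
        pts_all = np.concatenate([positions[g] for g in groups], axis=1)
        w = np.concatenate(masks, axis=1)[..., None].astype(float)
        mean = (pts_all * w).sum(axis=1, keepdims=True) / w.sum(axis=1, keepdims=True)
        centered = (pts_all - mean) * w
        cov = np.einsum("bki,bkj->bij", centered, centered)
        _, vecs = np.linalg.eigh(cov)
        axes = vecs[:, :, -1]                        # largest eigenvalue last
        direction = cogs[1] - cogs[0]
        flip = np.einsum("bi,bi->b", axes, direction) < 0
        axes[flip] *= -1
        out[done : done + b] = axes
        done += b
    return out


def wave_axis_variability(
    axes: np.ndarray,
    positions: np.ndarray,
    set_size: int,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int = 0,
    normalizer_mode: str = "max",
    exclusion_radius: float = DEFAULT_EXCLUSION_RADIUS,
) -> WaveAxisResult:
    """Axis change between consecutive oscillations, resampling-normalized.

    Raw change is the squared Euclidean distance between consecutive unit
    axes (0 for identical axes, 4 for antipodal). The normalizer is the
    maximum (default; ``mean`` and ``p95`` available) change between pairs of
    axes fit to ``n_resamples`` randomly drawn early/late sets of the true
    size, i.e. the variability attainable with no wave structure at all.
    """
    axes = np.atleast_2d(np.asarray(axes, dtype=float))
    if axes.shape[0] < 2:
        raise ValueError("need axes from at least 2 oscillations")
    positions = np.asarray(positions, dtype=float)
    raw = np.sum(np.diff(axes, axis=0) ** 2, axis=1)

    rng = np.random.default_rng(seed)
    sampled = _batched_resample_axes(
        positions, set_size, set_size, 2 * n_resamples, rng, exclusion_radius
    )
    changes = np.sum((sampled[0::2] - sampled[1::2]) ** 2, axis=1)
    if normalizer_mode == "max":
        normalizer = float(changes.max())
    elif normalizer_mode == "mean":
        normalizer = float(changes.mean())
    elif normalizer_mode == "p95":
        normalizer = float(np.percentile(changes, 95))
    else:
        raise ValueError(f"unknown normalizer_mode {normalizer_mode!r}")
    if normalizer <= 0:
        warnings.warn("degenerate resampling normalizer; returning raw changes")
        normalizer = 1.0
    return WaveAxisResult(
        axes=axes,
        excluded=[],
        raw_change=raw,
        normalized_change=raw / normalizer,
        normalizer=normalizer,
        n_resamples=n_resamples,
        seed=seed,
    )


def early_late_time_lag(pm: PhaseMap) -> float:
    """Mean phase of the late set minus mean phase of the early set (s, >= 0)."""
    if pm.early_set.size == 0 or pm.late_set.size == 0:
        raise ValueError("both phase sets must be non-empty")
    idx_early = np.isin(pm.cell_ids, pm.early_set)
    idx_late = np.isin(pm.cell_ids, pm.late_set)
    return float(np.nanmean(pm.phase[idx_late]) - np.nanmean(pm.phase[idx_early]))
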