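"""Synthetic 3D islet generator with known ground truth.

Emulates light-sheet recordings of glucose-stimulated beta-cell Ca2+
oscillations: cells packed in a sphere at beta-cell spacing, slow square-ish
oscillations, a planar travelling wave imposing per-cell phase lags along a
per-oscillation axis, a radial noise gradient (quieter centre) and a shared
spatially correlated noise field. Every analysis stage in the package is
tested against the ground truth this module records.

Geometry is micrometres, time is seconds, fluorescence is arbitrary units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .datasets import IsletDataset, VolumeSeries

# Rejection-sampling retry budget per cell when packing the sphere.
DEFAULT_PACKING_ATTEMPTS = 10_000
# Guard against accidental multi-GB volume allocations in render_volume.
DEFAULT_VOXEL_BUDGET = 200_000_000

#: ROI sphere radius used by the trace-extraction convention (micrometres).
ROI_RADIUS_UM = 4.65
#: Minimum centre-to-centre cell spacing (micrometres): nuclear ROIs expanded
#: so neighbouring cell spheres never overlap.
MIN_SPACING_UM = 9.3


class PackingError(RuntimeError):
    """Raised when cells cannot be packed at the requested spacing."""


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic islet recording.

    Defaults emulate the slow-oscillation regime of intact mouse islets:
    ~500 beta-cells in a 60 um-radius islet, a 406.2 s (6.77 min) period,
    square-ish pulses, a travelling wave of ~15 um/s and 2.02 Hz sampling.
    """

    n_cells: int = 500
    islet_radius: float = 60.0            # um
    min_spacing: float = MIN_SPACING_UM   # um
    period: float = 406.2                 # s (6.77 min)
    duty_cycle: float = 0.45              # active fraction of the period
    rise_time: float = 8.0                # s, 10-90% of the sigmoidal edges
    n_oscillations: int = 6
    sampling_rate: float = 2.02           # Hz
    wave_axis_schedule: np.ndarray | None = None  # (K, 3) unit vectors
    wave_speed: float = 15.0              # um/s
    noise_sd_center: float = 0.05         # AU, independent noise at r = 0
    noise_sd_edge: float = 0.15           # AU, independent noise at r = R
    shared_noise_sd: float = 0.05         # AU, spatially correlated component
    shared_noise_length_scale: float = 20.0  # um, squared-exponential kernel
    amplitude: float = 1.0                # AU pulse height
    baseline: float = 0.1                 # AU resting fluorescence
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0.0 < self.duty_cycle < 1.0:
            raise ValueError("duty_cycle must lie in (0, 1)")
        if self.min_spacing <= 0:
            raise ValueError("min_spacing must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.n_oscillations < 1:
            raise ValueError("n_oscillations must be >= 1")
        if self.wave_speed <= 0:
            raise ValueError("wave_speed must be positive")
        if self.wave_axis_schedule is not None:
            sched = np.asarray(self.wave_axis_schedule, dtype=float)
            if sched.shape != (self.n_oscillations, 3):
                raise ValueError(
                    f"wave_axis_schedule has shape {sched.shape}; expected "
                    f"({self.n_oscillations}, 3) — one unit vector per oscillation"
                )
            norms = np.linalg.norm(sched, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise ValueError("wave_axis_schedule entries must have unit norm")
            self.wave_axis_schedule = sched

    def noiseless(self) -> "SyntheticConfig":
        """Copy of the config with every noise source switched off."""
        return replace(self, noise_sd_center=0.0, noise_sd_edge=0.0, shared_noise_sd=0.0)


@dataclass
class GroundTruth:
    """What the generator actually imposed — the oracle for recovery tests."""

    lags: np.ndarray            # (K, N) imposed per-cell lag, seconds
    axes: np.ndarray            # (K, 3) imposed wave axes (unit, early->late)
    boundaries: np.ndarray      # (K+1,) oscillation boundary frame indices
    noise_sd: np.ndarray        # (N,) independent-noise SD per cell, AU
    template: np.ndarray = field(repr=False, default=None)  # (N, T) noiseless traces
    active_onsets: np.ndarray = None  # (K,) lag-free active-phase onset times, s
    active_duration: float = 0.0      # s, per-cell active-phase duration


def _logistic(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _pack_sphere(
    n_cells: int,
    radius: float,
    min_spacing: float,
    rng: np.random.Generator,
    attempts_per_cell: int = DEFAULT_PACKING_ATTEMPTS,
) -> np.ndarray:
    """Rejection-sample cell centres inside a sphere at pairwise >= min_spacing."""
    if n_cells == 1:
        return np.zeros((1, 3))
    placed = np.empty((n_cells, 3))
    count = 0
    budget = attempts_per_cell * n_cells
    spent = 0
    while count < n_cells:
        if spent >= budget:
            raise PackingError(
                f"could not place {n_cells} cells with min_spacing="
                f"{min_spacing} um inside radius {radius} um "
                f"(placed {count} after {spent} attempts)"
            )
        # Uniform point in the ball: direction x radius ~ R * U^(1/3).
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        r = radius * rng.random() ** (1.0 / 3.0)
        p = v * r
        spent += 1
        if count == 0 or (
            np.min(np.linalg.norm(placed[:count] - p, axis=1)) >= min_spacing
        ):
            placed[count] = p
            count += 1
    return placed


def random_axis_schedule(n: int, rng: np.random.Generator) -> np.ndarray:
    """n independent uniform unit vectors on the sphere."""
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def rotate_axis(axis: np.ndarray, angle_deg: float, about: np.ndarray) -> np.ndarray:
    """Rotate a unit vector by angle_deg about another (Rodrigues formula)."""
    a = np.asarray(axis, dtype=float)
    k = np.asarray(about, dtype=float)
    k = k / np.linalg.norm(k)
    th = np.deg2rad(angle_deg)
    rotated = (
        a * np.cos(th)
        + np.cross(k, a) * np.sin(th)
        + k * np.dot(k, a) * (1 - np.cos(th))
    )
    return rotated / np.linalg.norm(rotated)


def generate_islet(config: SyntheticConfig) -> tuple[IsletDataset, GroundTruth]:
    """Generate one synthetic islet recording plus its ground truth.

    Each cell's trace is ``baseline + amplitude * pulse(t - lag)`` summed over
    oscillations, where the pulse is a smoothed square wave (logistic edges)
    active for ``duty_cycle * period`` seconds, and the lag of cell n in
    oscillation k is ``(proj_n - min_m proj_m) / wave_speed`` with proj the
    projection of the cell position onto that oscillation's wave axis — i.e.
    the wave sweeps along the axis, cells at the low-projection pole lead.
    Independent Gaussian noise has an SD interpolated linearly from the islet
    centre to the edge; a shared component is drawn per frame from a
    squared-exponential spatial kernel over the cell positions.

    Deterministic given ``config.seed``.
    """
    root = np.random.SeedSequence(config.seed)
    s_pos, s_axes, s_indep, s_shared = [np.random.default_rng(s) for s in root.spawn(4)]

    positions = _pack_sphere(
        config.n_cells, config.islet_radius, config.min_spacing, s_pos
    )
    n = config.n_cells
    k_osc = config.n_oscillations

    if config.wave_axis_schedule is not None:
        axes = np.array(config.wave_axis_schedule, dtype=float)
    else:
        axes = random_axis_schedule(k_osc, s_axes)

    # Imposed lags: wave origin at the minimal projection onto each axis.
    proj = positions @ axes.T                      # (N, K)
    lags = (proj - proj.min(axis=0)).T / config.wave_speed  # (K, N)

    period = config.period
    active = config.duty_cycle * period
    # Lag-free onset centred in each period so shifted pulses stay inside it.
    t0 = 0.5 * (period - active)
    n_frames = int(round(k_osc * period * config.sampling_rate))
    t = np.arange(n_frames) / config.sampling_rate
    scale = config.rise_time / (2.0 * np.log(9.0))  # logistic 10-90% width

    template = np.zeros((n, n_frames))
    onsets = np.empty(k_osc)
    for k in range(k_osc):
        onsets[k] = k * period + t0
        t_on = onsets[k] + lags[k][:, None]        # (N, 1)
        t_off = t_on + active
        template += _logistic((t[None, :] - t_on) / scale) * _logistic(
            (t_off - t[None, :]) / scale
        )
    template = config.baseline + config.amplitude * template

    radii = np.linalg.norm(positions, axis=1)
    noise_sd = config.noise_sd_center + (
        config.noise_sd_edge - config.noise_sd_center
    ) * (radii / config.islet_radius)

    traces = template.copy()
    if np.any(noise_sd > 0):
        traces += s_indep.normal(size=(n, n_frames)) * noise_sd[:, None]
    if config.shared_noise_sd > 0 and n > 1:
        d2 = np.sum((positions[:, None, :] - positions[None, :, :]) ** 2, axis=-1)
        corr = np.exp(-d2 / (2.0 * config.shared_noise_length_scale**2))
        corr[np.diag_indices(n)] += 1e-9  # jitter for the Cholesky factor
        chol = np.linalg.cholesky(corr)
        z = s_shared.normal(size=(n_frames, n))
        traces += config.shared_noise_sd * (z @ chol.T).T
    elif config.shared_noise_sd > 0:
        traces += config.shared_noise_sd * s_shared.normal(size=(1, n_frames))

    boundaries = np.round(
        np.arange(k_osc + 1) * period * config.sampling_rate
    ).astype(int)
    boundaries[-1] = n_frames

    dataset = IsletDataset(
        cell_ids=np.arange(n),
        positions=positions,
        traces=traces,
        sampling_rate=config.sampling_rate,
    )
    truth = GroundTruth(
        lags=lags,
        axes=axes,
        boundaries=boundaries,
        noise_sd=noise_sd,
        template=template,
        active_onsets=onsets,
        active_duration=active,
    )
    return dataset, truth


def render_volume(
    dataset: IsletDataset,
    voxel_size: float,
    cell_radius: float = ROI_RADIUS_UM,
    voxel_budget: int = DEFAULT_VOXEL_BUDGET,
) -> VolumeSeries:
    """Rasterise the islet as a 4D image series (T, Z, Y, X).

    Every voxel whose centre lies within ``cell_radius`` of a cell centre
    carries that cell's trace value at each frame (nearest cell wins on
    overlap); background voxels are 0.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    if cell_radius < voxel_size:
        raise ValueError("cell_radius must be >= voxel_size")
    pos = dataset.positions
    lo = pos.min(axis=0) - cell_radius - voxel_size
    hi = pos.max(axis=0) + cell_radius + voxel_size
    shape = np.ceil((hi - lo) / voxel_size).astype(int) + 1  # (x, y, z) extents
    nx, ny, nz = shape
    total = int(dataset.n_frames) * int(nz) * int(ny) * int(nx)
    if total > voxel_budget:
        raise ValueError(
            f"volume would hold {total} voxels, over the budget of {voxel_budget}; "
            "reduce the frame count, coarsen voxel_size or raise voxel_budget"
        )
    origin = lo[::-1]  # store as (z, y, x)

    z, y, x = (origin[i] + np.arange((nz, ny, nx)[i]) * voxel_size for i in range(3))
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    centers_vox = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    dist, owner = cKDTree(pos).query(centers_vox)
    inside = dist <= cell_radius

    data = np.zeros((dataset.n_frames, nz * ny * nx), dtype=np.float32)
    data[:, inside] = dataset.traces[owner[inside]].T.astype(np.float32)
    data = data.reshape(dataset.n_frames, nz, ny, nx)
    return VolumeSeries(data=data, voxel_size=voxel_size, origin=origin)


def extract_traces(
    volume: VolumeSeries, centers: np.ndarray, radius: float
) -> np.ndarray:
    """Mean intensity within a sphere around each centre, per frame.

    This is the spherical-ROI convention used to pull single-cell traces out
    of a nuclear-centre-annotated image series; sphere membership is computed
    once and reused across frames. Returns an (N, T) matrix.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    z, y, x = volume.voxel_centers()
    lo = np.array([x[0], y[0], z[0]]) - volume.voxel_size / 2
    hi = np.array([x[-1], y[-1], z[-1]]) + volume.voxel_size / 2
    bad = np.flatnonzero(np.any(centers < lo, axis=1) | np.any(centers > hi, axis=1))
    if bad.size:
        raise ValueError(f"centers outside the volume bounds: ids {bad.tolist()}")

    t_frames, nz, ny, nx = volume.data.shape
    flat = volume.data.reshape(t_frames, -1)
    out = np.empty((centers.shape[0], t_frames))
    for i, c in enumerate(centers):
        # Candidate voxel slab around the centre, then exact distance test.
        ix = np.flatnonzero(np.abs(x - c[0]) <= radius + volume.voxel_size)
        iy = np.flatnonzero(np.abs(y - c[1]) <= radius + volume.voxel_size)
        iz = np.flatnonzero(np.abs(z - c[2]) <= radius + volume.voxel_size)
        zz, yy, xx = np.meshgrid(z[iz], y[iy], x[ix], indexing="ij")
        d2 = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2
        kk, jj, ii = np.meshgrid(iz, iy, ix, indexing="ij")
        member = d2.ravel() <= radius**2
        lin = (kk.ravel() * ny + jj.ravel()) * nx + ii.ravel()
        lin = lin[member]
        if lin.size == 0:
            # Radius smaller than a voxel: fall back to the containing voxel.
            kji = np.round((c[::-1] - volume.origin) / volume.voxel_size).astype(int)
            kji = np.clip(kji, 0, [nz - 1, ny - 1, nx - 1])
            lin = np.array([(kji[0] * ny + kji[1]) * nx + kji[2]])
        out[i] = flat[:, lin].mean(axis=1)
    return out


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Serialise the ground truth (minus the bulky template) as JSON."""
    payload = {
        "lags_s": truth.lags.tolist(),
        "axes": truth.axes.tolist(),
        "boundaries_frames": truth.boundaries.tolist(),
        "noise_sd_au": truth.noise_sd.tolist(),
        "active_onsets_s": truth.active_onsets.tolist(),
        "active_duration_s": float(truth.active_duration),
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        lags=np.asarray(payload["lags_s"]),
        axes=np.asarray(payload["axes"]),
        boundaries=np.asarray(payload["boundaries_frames"], dtype=int),
        noise_sd=np.asarray(payload["noise_sd_au"]),
        template=None,
        active_onsets=np.asarray(payload["active_onsets_s"]),
        active_duration=payload["active_duration_s"],
    )
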