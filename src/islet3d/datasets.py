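"""Core in-memory containers shared by every analysis stage.

Positions are micrometres in an islet-local frame, traces are arbitrary
fluorescence units (AU), frames are 0-based, and time is seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class IsletDataset:
    """One recording of an islet: cell positions plus Ca2+ traces.

    Parameters
    ----------
    cell_ids : (N,) int array of unique cell identifiers.
    positions : (N, 3) float array, x/y/z in micrometres.
    traces : (N, T) float array of per-cell fluorescence (AU).
    sampling_rate : frames per second (Hz).
    condition : optional label, e.g. ``"pre"`` / ``"post"``.
    """

    cell_ids: np.ndarray
    positions: np.ndarray
    traces: np.ndarray
    sampling_rate: float
    condition: str | None = None

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=float)
        self.traces = np.asarray(self.traces, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array of micrometres")
        n = self.positions.shape[0]
        if self.cell_ids.shape != (n,):
            raise ValueError("cell_ids and positions disagree on cell count")
        if len(np.unique(self.cell_ids)) != n:
            raise ValueError("cell_ids contains duplicates")
        if self.traces.ndim != 2 or self.traces.shape[0] != n:
            raise ValueError("traces must be (N, T) with the same N as positions")
        if self.traces.shape[1] < 2:
            raise ValueError("traces need at least 2 frames")
        if not np.isfinite(self.positions).all():
            raise ValueError("positions contain non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive (Hz)")

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds."""
        return np.arange(self.n_frames) / self.sampling_rate

    def subset(self, mask: np.ndarray, condition: str | None = None) -> "IsletDataset":
        """Return a new dataset restricted to the selected cells (ids kept)."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return IsletDataset(
            cell_ids=self.cell_ids[idx],
            positions=self.positions[idx],
            traces=self.traces[idx],
            sampling_rate=self.sampling_rate,
            condition=condition if condition is not None else self.condition,
        )


@dataclass
class VolumeSeries:
    """A rendered 4D image series (T, Z, Y, X) with its spatial calibration.

    ``origin`` is the micrometre coordinate of the centre of voxel
    (z=0, y=0, x=0); voxels are cubes of side ``voxel_size`` micrometres.
    """

    data: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("volume data must be 4D (T, Z, Y, X)")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive (micrometres)")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Micrometre coordinates of voxel centres along z, y, x."""
        _, nz, ny, nx = self.data.shape
        z = self.origin[0] + np.arange(nz) * self.voxel_size
        y = self.origin[1] + np.arange(ny) * self.voxel_size
        x = self.origin[2] + np.arange(nx) * self.voxel_size
        return z, y, x
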