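"""Reading and writing the package's on-disk formats.

Positions travel as CSV (cell_id, x_um, y_um, z_um); traces as HDF5 (dataset
"traces", dataset "cell_ids", attribute "sampling_rate_hz") or as wide CSV
(one row per cell, first column cell_id, remaining columns frames, sampling
rate in a ``# sampling_rate_hz=`` comment line); volumes as multi-page TIFF.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .datasets import IsletDataset, VolumeSeries

POSITION_COLUMNS = ["cell_id", "x_um", "y_um", "z_um"]


def write_positions(dataset: IsletDataset, path: str | Path) -> None:
    pd.DataFrame(
        {
            "cell_id": dataset.cell_ids,
            "x_um": dataset.positions[:, 0],
            "y_um": dataset.positions[:, 1],
            "z_um": dataset.positions[:, 2],
        }
    ).to_csv(path, index=False)


def write_traces(dataset: IsletDataset, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("traces", data=dataset.traces)
            d.attrs["sampling_rate_hz"] = dataset.sampling_rate
            f.create_dataset("cell_ids", data=dataset.cell_ids)
    else:
        with open(path, "w") as f:
            f.write(f"# sampling_rate_hz={dataset.sampling_rate}\n")
            header = "cell_id," + ",".join(
                f"f{t}" for t in range(dataset.n_frames)
            )
            f.write(header + "\n")
            for cid, row in zip(dataset.cell_ids, dataset.traces):
                f.write(f"{cid}," + ",".join(repr(float(v)) for v in row) + "\n")


def write_dataset(
    dataset: IsletDataset, positions_path: str | Path, traces_path: str | Path
) -> None:
    write_positions(dataset, positions_path)
    write_traces(dataset, traces_path)


def _read_traces(path: Path, sampling_rate: float | None):
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            traces = f["traces"][...]
            ids = f["cell_ids"][...]
            rate = float(f["traces"].attrs.get("sampling_rate_hz", np.nan))
    else:
        with open(path) as f:
            first = f.readline()
        rate = np.nan
        skip = 0
        if first.startswith("#"):
            skip = 1
            key, _, value = first.lstrip("# ").partition("=")
            if key.strip() == "sampling_rate_hz":
                rate = float(value)
        df = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
        ids = df.iloc[:, 0].to_numpy()
        traces = df.iloc[:, 1:].to_numpy(dtype=float)
    if sampling_rate is not None:
        rate = sampling_rate
    if not np.isfinite(rate) or rate <= 0:
        raise ValueError(
            f"no sampling rate found in {path}; pass sampling_rate explicitly"
        )
    return traces, np.asarray(ids, dtype=np.int64), rate


def read_dataset(
    positions_path: str | Path,
    traces_path: str | Path,
    sampling_rate: float | None = None,
    condition: str | None = None,
) -> IsletDataset:
    """Load and join positions and traces on cell_id, validating the schema."""
    positions_path = Path(positions_path)
    traces_path = Path(traces_path)
    for p in (positions_path, traces_path):
        if not p.exists():
            raise FileNotFoundError(p)
    pos = pd.read_csv(positions_path)
    missing = [c for c in POSITION_COLUMNS if c not in pos.columns]
    if missing:
        raise ValueError(f"positions file missing columns: {missing}")
    if pos[["x_um", "y_um", "z_um"]].isna().any().any():
        raise ValueError("positions contain NaN coordinates")
    traces, trace_ids, rate = _read_traces(traces_path, sampling_rate)
    pos_ids = pos["cell_id"].to_numpy(dtype=np.int64)
    absent = np.setdiff1d(pos_ids, trace_ids)
    if absent.size:
        raise ValueError(f"traces missing for cell ids: {absent.tolist()}")
    extra = np.setdiff1d(trace_ids, pos_ids)
    if extra.size:
        raise ValueError(f"positions missing for cell ids: {extra.tolist()}")
    # Align trace rows to the positions' id order.
    lookup = {cid: i for i, cid in enumerate(trace_ids)}
    order = np.array([lookup[cid] for cid in pos_ids])
    return IsletDataset(
        cell_ids=pos_ids,
        positions=pos[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
        traces=traces[order],
        sampling_rate=rate,
        condition=condition,
    )


def write_volume(volume: VolumeSeries, path: str | Path) -> None:
    """4D stack (T, Z, Y, X) as a multi-page TIFF with voxel metadata."""
    tifffile.imwrite(
        path,
        volume.data,
        metadata={
            "voxel_size_um": volume.voxel_size,
            "origin_zyx_um": volume.origin.tolist(),
        },
    )


def read_volume(path: str | Path, voxel_size: float, origin=(0.0, 0.0, 0.0)) -> VolumeSeries:
    data = tifffile.imread(path)
    if data.ndim == 3:
        data = data[None]
    return VolumeSeries(data=data, voxel_size=voxel_size, origin=np.asarray(origin))
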