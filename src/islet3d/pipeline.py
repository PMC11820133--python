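"""End-to-end per-islet analysis: segment -> network -> wave -> consistency,
2D analysis planes, and pre/post-treatment comparison.

The full-volume (3D) analysis and thin 2D planes at configurable depths run
through the identical stages, so 2D sampling bias can be quantified on the
same recording.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datasets import IsletDataset
from . import io as _io
from .segmentation import segment_dataset, islet_mean_trace
from .network import (
    DEFAULT_TARGET_DEGREE,
    build_islet_networks,
    retention_rate,
    spatial_stats,
)
from .wave import (
    DEFAULT_EXCLUSION_RADIUS,
    depolarization_times,
    early_late_time_lag,
    phase_map,
    wave_axis,
    wave_axis_variability,
)
from .consistency import normalized_consistency, rank_cells

logger = logging.getLogger("islet3d")

DEFAULT_PLANE_HALF_THICKNESS = 3.0   # um either side of the analysis plane
DEFAULT_PLANE_DEPTHS = (0.25, 0.5)


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; loadable from YAML."""

    positions_path: str | None = None
    traces_path: str | None = None
    sampling_rate: float | None = None
    output_dir: str = "islet3d_out"
    # segmentation
    min_prominence: float | None = None
    min_separation_s: float = 60.0
    manual_peaks: list[int] | None = None
    smooth_sigma: float = 1.0
    # network
    target_degree: float = DEFAULT_TARGET_DEGREE
    subpop_fraction: float = 0.10
    correlation_method: str = "pearson"
    # wave
    exclusion_radius_um: float = DEFAULT_EXCLUSION_RADIUS
    max_lag_s: float | None = None
    n_axis_resamples: int = 2_000
    axis_normalizer_mode: str = "max"
    # consistency
    n_shuffles: int = 100
    kl_normalizer_mode: str = "mean"
    sigma_fraction: float = 1.0 / 6.0
    # planes
    plane_depths: tuple[float, ...] = DEFAULT_PLANE_DEPTHS
    plane_half_thickness_um: float = DEFAULT_PLANE_HALF_THICKNESS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.subpop_fraction <= 0.5:
            raise ValueError("subpop_fraction must lie in (0, 0.5]")
        for count in (self.n_axis_resamples, self.n_shuffles):
            if count < 1:
                raise ValueError("resample and shuffle counts must be >= 1")
        for d in self.plane_depths:
            if not 0.0 < d < 1.0:
                raise ValueError("plane depths must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if "plane_depths" in payload:
            payload["plane_depths"] = tuple(payload["plane_depths"])
        return cls(**payload)


@dataclass
class AnalysisBlock:
    """All per-islet results for one cell population (3D islet or a 2D plane)."""

    label: str
    n_cells: int
    metrics: pd.DataFrame
    threshold: float
    mean_degree: float
    degrees: pd.DataFrame
    phases: pd.DataFrame
    axes: pd.DataFrame
    network_spatial: dict
    wave_spatial: dict
    retention: dict                       # per-transition retention rates
    early_late_lag_s: list[float]
    axis_raw_change: list[float]
    axis_normalized_change: list[float]
    consistency: dict                     # {(analysis, mode): mean normalized KL}
    sets: dict                            # per-oscillation id lists

    def summary(self) -> dict:
        periods = self.metrics["period_s"].to_numpy(dtype=float)
        return {
            "label": self.label,
            "n_cells": self.n_cells,
            "n_oscillations": int(len(self.metrics)),
            "mean_period_s": float(np.nanmean(periods)) if len(periods) else np.nan,
            "mean_duty_cycle": float(np.nanmean(self.metrics["duty_cycle"])),
            "threshold": self.threshold,
            "mean_degree": self.mean_degree,
            "network_spatial": self.network_spatial,
            "wave_spatial": self.wave_spatial,
            "retention": self.retention,
            "early_late_lag_s": self.early_late_lag_s,
            "axis_raw_change": self.axis_raw_change,
            "axis_normalized_change": self.axis_normalized_change,
            "consistency": {f"{a}_{m}": v for (a, m), v in self.consistency.items()},
        }


@dataclass
class IsletReport:
    condition: str | None
    config: PipelineConfig
    block3d: AnalysisBlock
    planes: dict = field(default_factory=dict)   # depth fraction -> AnalysisBlock

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "parameters": {
                k: v
                for k, v in asdict(self.config).items()
                if not k.endswith("_path") and k != "output_dir"
            },
            "islet_3d": self.block3d.summary(),
            "planes_2d": {str(d): b.summary() for d, b in self.planes.items()},
        }

    def save(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.block3d.metrics.to_csv(outdir / "segments.csv", index=False)
        self.block3d.degrees.to_csv(outdir / "degrees.csv", index=False)
        self.block3d.phases.to_csv(outdir / "phases.csv", index=False)
        self.block3d.axes.to_csv(outdir / "axes.csv", index=False)
        report_path = outdir / "report.json"
        report_path.write_text(json.dumps(_jsonify(self.to_dict()), indent=2, sort_keys=True))
        return report_path


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def extract_plane(
    dataset: IsletDataset,
    depth_fraction: float,
    half_thickness: float = DEFAULT_PLANE_HALF_THICKNESS,
) -> IsletDataset:
    """Cells within ``half_thickness`` um of a constant-z analysis plane.

    The plane sits at ``z_min + depth_fraction * (z_max - z_min)`` of the
    cell z-extent. The subset keeps original cell ids, so every downstream
    stage runs unchanged on it.
    """
    if not 0.0 < depth_fraction < 1.0:
        raise ValueError("depth_fraction must lie in (0, 1)")
    z = dataset.positions[:, 2]
    plane = z.min() + depth_fraction * (z.max() - z.min())
    mask = np.abs(z - plane) <= half_thickness
    if not mask.any():
        raise ValueError(
            f"no cells within {half_thickness} um of the plane at depth "
            f"{depth_fraction}; consider a thicker slab"
        )
    return dataset.subset(mask)


def analyze_population(
    dataset: IsletDataset, config: PipelineConfig, label: str = "islet_3d"
) -> AnalysisBlock:
    """Run segmentation, network, wave and consistency stages on one dataset."""
    logger.info("[%s] %d cells, %d frames", label, dataset.n_cells, dataset.n_frames)
    segments, metrics = segment_dataset(
        dataset,
        min_prominence=config.min_prominence,
        min_separation=config.min_separation_s,
        manual_peaks=np.asarray(config.manual_peaks) if config.manual_peaks else None,
        smooth_sigma=config.smooth_sigma,
    )
    usable = [s for s in segments if not (s.incomplete or s.flat)]
    if len(usable) < 2:
        raise RuntimeError(
            f"stage 'segment' on {label}: need >= 2 complete oscillations, "
            f"found {len(usable)}"
        )

    # --- network stage -----------------------------------------------------
    networks, threshold, mean_degree = build_islet_networks(
        dataset.traces,
        usable,
        dataset.cell_ids,
        target_degree=config.target_degree,
        fraction=config.subpop_fraction,
        method=config.correlation_method,
    )
    degrees = pd.concat(
        [
            pd.DataFrame(
                {
                    "oscillation": net.oscillation,
                    "cell_id": net.cell_ids,
                    "degree": net.degree,
                    "is_high": np.isin(net.cell_ids, net.high_set),
                    "is_low": np.isin(net.cell_ids, net.low_set),
                }
            )
            for net in networks
        ],
        ignore_index=True,
    )
    high_stats = spatial_stats(
        dataset.positions, [net.high_set for net in networks], dataset.cell_ids
    )
    low_stats = spatial_stats(
        dataset.positions, [net.low_set for net in networks], dataset.cell_ids
    )
    network_spatial = {
        "mean_norm_dist_all": high_stats.mean_normalized_distance(),
        "mean_norm_dist_high": float(
            np.mean([high_stats.mean_normalized_distance(n.high_set) for n in networks])
        ),
        "mean_norm_dist_low": float(
            np.mean([low_stats.mean_normalized_distance(n.low_set) for n in networks])
        ),
        "cog_displacement_high": high_stats.displacement.tolist(),
    }

    # --- wave stage --------------------------------------------------------
    phase_maps = [
        phase_map(
            dataset.traces,
            seg,
            dataset.sampling_rate,
            max_lag=config.max_lag_s,
            cell_ids=dataset.cell_ids,
            fraction=config.subpop_fraction,
        )
        for seg in usable
    ]
    phases = pd.concat(
        [
            pd.DataFrame(
                {
                    "oscillation": pm.oscillation,
                    "cell_id": pm.cell_ids,
                    "phase_s": pm.phase,
                    "max_r": pm.max_correlation,
                    "is_early": np.isin(pm.cell_ids, pm.early_set),
                    "is_late": np.isin(pm.cell_ids, pm.late_set),
                }
            )
            for pm in phase_maps
        ],
        ignore_index=True,
    )
    axes_rows = []
    axes_list = []
    for pm in phase_maps:
        axis, excluded = wave_axis(
            dataset.positions,
            pm.early_set,
            pm.late_set,
            dataset.cell_ids,
            exclusion_radius=config.exclusion_radius_um,
        )
        axes_list.append(axis)
        axes_rows.append(
            {
                "oscillation": pm.oscillation,
                "ax": axis[0],
                "ay": axis[1],
                "az": axis[2],
                "n_excluded": len(excluded),
            }
        )
    axes_arr = np.array(axes_list)
    set_size = int(round(config.subpop_fraction * dataset.n_cells))
    variability = wave_axis_variability(
        axes_arr,
        dataset.positions,
        set_size=set_size,
        n_resamples=config.n_axis_resamples,
        seed=config.seed,
        normalizer_mode=config.axis_normalizer_mode,
        exclusion_radius=config.exclusion_radius_um,
    )
    axes = pd.DataFrame(axes_rows)
    axes["raw_change"] = np.concatenate([[np.nan], variability.raw_change])
    axes["normalized_change"] = np.concatenate([[np.nan], variability.normalized_change])
    early_stats = spatial_stats(
        dataset.positions, [pm.early_set for pm in phase_maps], dataset.cell_ids
    )
    wave_spatial = {
        "mean_norm_dist_early": float(
            np.mean(
                [early_stats.mean_normalized_distance(pm.early_set) for pm in phase_maps]
            )
        ),
        "mean_norm_dist_late": float(
            np.mean(
                [early_stats.mean_normalized_distance(pm.late_set) for pm in phase_maps]
            )
        ),
        "cog_displacement_early": early_stats.displacement.tolist(),
    }
    retention = {
        "high_degree": [
            retention_rate(a.high_set, b.high_set)
            for a, b in zip(networks, networks[1:])
        ],
        "early_phase": [
            retention_rate(a.early_set, b.early_set)
            for a, b in zip(phase_maps, phase_maps[1:])
        ],
        "late_phase": [
            retention_rate(a.late_set, b.late_set)
            for a, b in zip(phase_maps, phase_maps[1:])
        ],
    }

    # --- consistency stage -------------------------------------------------
    consistency = {}
    net_cellular = [
        rank_cells(
            net.degree.astype(float), "degree", "cellular",
            cell_ids=net.cell_ids, oscillation=net.oscillation,
        )
        for net in networks
    ]
    net_regional = [
        rank_cells(
            net.degree.astype(float), "degree", "regional",
            positions=dataset.positions, top_set=net.high_set,
            cell_ids=net.cell_ids, oscillation=net.oscillation,
        )
        for net in networks
    ]
    wave_cellular = [
        rank_cells(
            pm.phase, "phase", "cellular",
            cell_ids=pm.cell_ids, oscillation=pm.oscillation,
        )
        for pm in phase_maps
    ]
    wave_regional = [
        rank_cells(
            pm.phase, "phase", "regional",
            positions=dataset.positions, top_set=pm.early_set,
            cell_ids=pm.cell_ids, oscillation=pm.oscillation,
        )
        for pm in phase_maps
    ]
    for key, vectors in {
        ("network", "cellular"): net_cellular,
        ("network", "regional"): net_regional,
        ("wave", "cellular"): wave_cellular,
        ("wave", "regional"): wave_regional,
    }.items():
        result = normalized_consistency(
            vectors,
            n_shuffles=config.n_shuffles,
            normalizer_mode=config.kl_normalizer_mode,
            seed=config.seed,
            sigma_fraction=config.sigma_fraction,
        )
        consistency[key] = result.mean_normalized

    sets = {
        "high": [net.high_set.tolist() for net in networks],
        "low": [net.low_set.tolist() for net in networks],
        "early": [pm.early_set.tolist() for pm in phase_maps],
        "late": [pm.late_set.tolist() for pm in phase_maps],
    }
    return AnalysisBlock(
        label=label,
        n_cells=dataset.n_cells,
        metrics=metrics,
        threshold=threshold,
        mean_degree=mean_degree,
        degrees=degrees,
        phases=phases,
        axes=axes,
        network_spatial=network_spatial,
        wave_spatial=wave_spatial,
        retention=retention,
        early_late_lag_s=[early_late_time_lag(pm) for pm in phase_maps],
        axis_raw_change=variability.raw_change.tolist(),
        axis_normalized_change=variability.normalized_change.tolist(),
        consistency=consistency,
        sets=sets,
    )


def analyze_dataset(dataset: IsletDataset, config: PipelineConfig) -> IsletReport:
    """Full 3D analysis plus 2D analysis planes at the configured depths."""
    block3d = analyze_population(dataset, config, label="islet_3d")
    planes: dict[float, AnalysisBlock] = {}
    for depth in config.plane_depths:
        label = f"plane_{depth}"
        try:
            subset = extract_plane(dataset, depth, config.plane_half_thickness_um)
            planes[depth] = analyze_population(subset, config, label=label)
        except (ValueError, RuntimeError) as exc:
            raise RuntimeError(f"stage 'planes' at depth {depth}: {exc}") from exc
    return IsletReport(
        condition=dataset.condition, config=config, block3d=block3d, planes=planes
    )


def run_pipeline(config: PipelineConfig) -> IsletReport:
    """Load the configured dataset, analyze it, and write every artifact."""
    if config.positions_path is None or config.traces_path is None:
        raise ValueError("config must provide positions_path and traces_path")
    dataset = _io.read_dataset(
        config.positions_path, config.traces_path, config.sampling_rate
    )
    logger.info("pipeline parameters: %s", asdict(config))
    report = analyze_dataset(dataset, config)
    report.save(config.output_dir)
    return report


# --- pre/post-treatment comparison -----------------------------------------

_PAIRED_METRICS = ("period_s", "active_s", "silent_s", "duty_cycle")


def compare_conditions(pre: IsletReport, post: IsletReport) -> pd.DataFrame:
    """Paired per-islet deltas between two recordings of the same cells.

    Oscillation-indexed quantities are truncated to the common oscillation
    count, mirroring matched pre/post treatment windows. Reports mean delta
    (post - pre) and its SEM per metric, plus subpopulation retention across
    the treatment boundary (last pre oscillation vs first post oscillation).
    """
    ids_pre = pre.block3d.degrees["cell_id"].unique()
    ids_post = post.block3d.degrees["cell_id"].unique()
    if not np.array_equal(np.sort(ids_pre), np.sort(ids_post)):
        raise ValueError("pre and post reports cover different cell sets")

    m = min(len(pre.block3d.metrics), len(post.block3d.metrics))
    rows = []

    def _row(metric: str, a: np.ndarray, b: np.ndarray) -> dict:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        k = min(a.size, b.size)
        delta = b[:k] - a[:k]
        delta = delta[np.isfinite(delta)]
        sem = float(np.std(delta, ddof=1) / np.sqrt(delta.size)) if delta.size > 1 else np.nan
        return {
            "metric": metric,
            "n_pairs": int(delta.size),
            "pre_mean": float(np.nanmean(a[:k])) if k else np.nan,
            "post_mean": float(np.nanmean(b[:k])) if k else np.nan,
            "delta_mean": float(delta.mean()) if delta.size else np.nan,
            "delta_sem": sem,
        }

    for metric in _PAIRED_METRICS:
        rows.append(
            _row(
                metric,
                pre.block3d.metrics[metric].to_numpy()[:m],
                post.block3d.metrics[metric].to_numpy()[:m],
            )
        )
    rows.append(
        _row(
            "axis_normalized_change",
            pre.block3d.axis_normalized_change,
            post.block3d.axis_normalized_change,
        )
    )
    rows.append(
        _row("early_late_lag_s", pre.block3d.early_late_lag_s, post.block3d.early_late_lag_s)
    )
    rows.append(
        _row(
            "wave_regional_consistency",
            [pre.block3d.consistency[("wave", "regional")]],
            [post.block3d.consistency[("wave", "regional")]],
        )
    )
    for name in ("early", "late"):
        r = retention_rate(
            np.asarray(pre.block3d.sets[name][-1]),
            np.asarray(post.block3d.sets[name][0]),
        )
        rows.append(
            {
                "metric": f"{name}_retention_across_boundary",
                "n_pairs": 1,
                "pre_mean": np.nan,
                "post_mean": np.nan,
                "delta_mean": r,
                "delta_sem": np.nan,
            }
        )
    return pd.DataFrame(rows)
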