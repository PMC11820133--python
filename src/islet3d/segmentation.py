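"""Oscillation identification on the islet-average Ca2+ trace.

Peaks are found (or supplied manually), depolarization/repolarization
boundaries are read off the smoothed derivative, per-oscillation windows are
padded, and period / active-phase / silent-phase / duty-cycle metrics are
computed at half-maximal Ca2+.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .datasets import IsletDataset

#: Fraction of the extremal derivative at which a depolarization or
#: repolarization edge is considered to start/stop.
EDGE_DERIVATIVE_FRACTION = 0.1


@dataclass
class OscillationSegment:
    """One oscillation of the islet-average trace (all indices are frames)."""

    index: int
    peak_frame: int
    window_start: int
    window_end: int          # inclusive
    depol_start: int
    depol_end: int
    repol_start: int
    repol_end: int
    period: float = np.nan          # s, peak-to-peak spacing
    active_duration: float = np.nan  # s above half-maximal Ca2+
    silent_duration: float = np.nan  # s, period - active
    duty_cycle: float = np.nan       # active / period
    half_max_level: float = np.nan   # AU
    incomplete: bool = False         # window truncated by the recording edge
    flat: bool = False               # degenerate window (max == min)

    @property
    def window(self) -> slice:
        return slice(self.window_start, self.window_end + 1)

    @property
    def n_frames(self) -> int:
        return self.window_end - self.window_start + 1


def islet_mean_trace(dataset: IsletDataset) -> np.ndarray:
    """Unweighted per-frame mean over all cells."""
    return dataset.traces.mean(axis=0)


def _refine_to_plateau_midpoints(trace: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """Move each peak to the midpoint of its above-half-max interval.

    On square-ish oscillations the plateau is nearly flat, so the raw argmax
    wanders with noise; the half-max crossings sit on steep edges and pin the
    plateau midpoint to within about a frame.
    """
    low = np.percentile(trace, 10)
    refined = np.empty_like(peaks)
    for i, p in enumerate(peaks):
        half = 0.5 * (trace[p] + low)
        left = p
        while left > 0 and trace[left - 1] > half:
            left -= 1
        right = p
        while right < trace.size - 1 and trace[right + 1] > half:
            right += 1
        refined[i] = (left + right) // 2
    return refined


def find_oscillation_peaks(
    mean_trace: np.ndarray,
    sampling_rate: float,
    min_prominence: float | None = None,
    min_separation: float = 60.0,
    manual_peaks: np.ndarray | None = None,
    refine: bool = True,
) -> np.ndarray:
    """Frames of the oscillation peaks of the islet-average trace.

    With ``manual_peaks`` the supplied frames are validated (in range, sorted,
    separated by ``min_separation`` seconds) and returned unchanged, mirroring
    a semi-automated workflow. Otherwise peaks are local maxima exceeding
    ``min_prominence`` (default: a quarter of the robust trace range),
    separated by at least ``min_separation`` seconds, refined to the midpoint
    of each oscillation's above-half-max plateau (disable with
    ``refine=False``).
    """
    mean_trace = np.asarray(mean_trace, dtype=float)
    if min_separation <= 0:
        raise ValueError("min_separation must be positive (seconds)")
    n = mean_trace.size
    if manual_peaks is not None:
        peaks = np.asarray(manual_peaks, dtype=int)
        if np.any((peaks < 0) | (peaks >= n)):
            raise ValueError("manual peak frames out of range")
        if np.any(np.diff(peaks) < min_separation * sampling_rate):
            raise ValueError("manual peaks closer than min_separation")
        return peaks
    if min_prominence is None:
        lo, hi = np.percentile(mean_trace, [5, 95])
        min_prominence = 0.25 * (hi - lo)
    if min_prominence <= 0:
        warnings.warn("trace has no dynamic range; no peaks found")
        return np.array([], dtype=int)
    distance = max(1, int(round(min_separation * sampling_rate)))
    idx, props = find_peaks(
        mean_trace, prominence=min_prominence, distance=distance, plateau_size=1
    )
    # Report plateau midpoints rather than plateau left edges.
    if "left_edges" in props and idx.size:
        idx = (props["left_edges"] + props["right_edges"]) // 2
    if idx.size == 0:
        warnings.warn("no oscillation peaks found")
        return idx.astype(int)
    if refine:
        idx = _refine_to_plateau_midpoints(mean_trace, idx.astype(int))
    return idx.astype(int)


def _edge_bounds(deriv: np.ndarray, extremum: int, lo: int, hi: int) -> tuple[int, int]:
    """Frames where |derivative| falls below a fraction of its edge extremum.

    Walk outwards from the extremum of the signed derivative until its
    magnitude drops below EDGE_DERIVATIVE_FRACTION of the extremal value;
    works for rising (positive) and falling (negative) edges alike.
    """
    level = abs(deriv[extremum]) * EDGE_DERIVATIVE_FRACTION
    sign = np.sign(deriv[extremum]) or 1.0
    start = extremum
    while start > lo and sign * deriv[start - 1] > level:
        start -= 1
    end = extremum
    while end < hi and sign * deriv[end + 1] > level:
        end += 1
    return start, end


def segment_oscillations(
    mean_trace: np.ndarray,
    peaks: np.ndarray,
    sampling_rate: float,
    smooth_sigma: float = 1.0,
) -> list[OscillationSegment]:
    """Delimit one analysis window per oscillation peak.

    The depolarization (rising) and repolarization (falling) edges are located
    at the extrema of the Gaussian-smoothed central-difference derivative on
    either side of each peak; edge onsets/offsets are where the derivative
    magnitude decays below a tenth of the extremum. The window extends the
    [depol_start, repol_end] core by a leading pad of x seconds and a trailing
    pad of x/2 seconds, with x = 1/4 of the active-phase duration (duty cycle
    x period). Windows are clipped to the recording (segments truncated by the
    edge are flagged ``incomplete``) and trimmed to be non-overlapping.
    """
    mean_trace = np.asarray(mean_trace, dtype=float)
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size == 0:
        raise ValueError("peaks must be non-empty")
    if np.any(np.diff(peaks) <= 0):
        raise ValueError("peaks must be sorted and strictly increasing")
    n = mean_trace.size
    smoothed = gaussian_filter1d(mean_trace, smooth_sigma) if smooth_sigma > 0 else mean_trace
    deriv = np.gradient(smoothed)

    segments: list[OscillationSegment] = []
    for i, peak in enumerate(peaks):
        left = 0 if i == 0 else (peaks[i - 1] + peak) // 2
        right = n - 1 if i == len(peaks) - 1 else (peak + peaks[i + 1]) // 2
        rise = left + int(np.argmax(deriv[left : peak + 1]))
        fall = peak + int(np.argmin(deriv[peak : right + 1]))
        depol_start, depol_end = _edge_bounds(deriv, rise, left, peak)
        repol_start, repol_end = _edge_bounds(deriv, fall, peak, right)

        core = mean_trace[depol_start : repol_end + 1]
        half = 0.5 * (core.min() + core.max())
        active_frames = int(np.count_nonzero(core > half))
        x_frames = 0.25 * active_frames
        w_start = depol_start - int(round(x_frames))
        w_end = repol_end + int(round(x_frames / 2.0))
        incomplete = w_start < 0 or w_end > n - 1
        segments.append(
            OscillationSegment(
                index=i,
                peak_frame=int(peak),
                window_start=max(w_start, 0),
                window_end=min(w_end, n - 1),
                depol_start=depol_start,
                depol_end=depol_end,
                repol_start=repol_start,
                repol_end=repol_end,
                incomplete=incomplete,
            )
        )

    # Trim overlaps at the midpoint between adjacent cores.
    for a, b in zip(segments, segments[1:]):
        if a.window_end >= b.window_start:
            mid = (a.repol_end + b.depol_start) // 2
            a.window_end = min(a.window_end, mid)
            b.window_start = max(b.window_start, mid + 1)
    return segments


def oscillation_metrics(
    mean_trace: np.ndarray,
    segments: list[OscillationSegment],
    sampling_rate: float,
) -> pd.DataFrame:
    """Per-oscillation period, active/silent durations and duty cycle.

    The period is the spacing between consecutive peak frames (the last
    segment reuses the preceding spacing). Within each window the half-max
    level is (min + max) / 2; the active phase is the total time above it,
    the silent phase the remainder of the period. Flat windows are flagged
    and their metrics left undefined. Updates the segments in place and
    returns the table.
    """
    mean_trace = np.asarray(mean_trace, dtype=float)
    if len(segments) < 2:
        warnings.warn("period estimation needs >= 2 segments; periods undefined")
    dt = 1.0 / sampling_rate
    peaks = np.array([s.peak_frame for s in segments], dtype=float)
    spacing = np.diff(peaks) * dt
    rows = []
    for i, seg in enumerate(segments):
        if len(segments) >= 2:
            seg.period = spacing[i] if i < len(spacing) else spacing[-1]
        window = mean_trace[seg.window]
        lo, hi = window.min(), window.max()
        if hi <= lo:
            seg.flat = True
        else:
            seg.half_max_level = 0.5 * (lo + hi)
            seg.active_duration = float(
                np.count_nonzero(window > seg.half_max_level) * dt
            )
            if np.isfinite(seg.period):
                seg.silent_duration = seg.period - seg.active_duration
                seg.duty_cycle = seg.active_duration / seg.period
        rows.append(
            {
                "oscillation": seg.index,
                "peak_frame": seg.peak_frame,
                "window_start": seg.window_start,
                "window_end": seg.window_end,
                "period_s": seg.period,
                "active_s": seg.active_duration,
                "silent_s": seg.silent_duration,
                "duty_cycle": seg.duty_cycle,
                "half_max_au": seg.half_max_level,
                "incomplete": seg.incomplete,
                "flat": seg.flat,
            }
        )
    return pd.DataFrame(rows)


def segment_dataset(
    dataset: IsletDataset,
    min_prominence: float | None = None,
    min_separation: float = 60.0,
    manual_peaks: np.ndarray | None = None,
    smooth_sigma: float = 1.0,
) -> tuple[list[OscillationSegment], pd.DataFrame]:
    """Convenience wrapper: mean trace -> peaks -> segments -> metrics."""
    mean = islet_mean_trace(dataset)
    peaks = find_oscillation_peaks(
        mean, dataset.sampling_rate, min_prominence, min_separation, manual_peaks
    )
    if peaks.size == 0:
        return [], pd.DataFrame()
    segments = segment_oscillations(mean, peaks, dataset.sampling_rate, smooth_sigma)
    table = oscillation_metrics(mean, segments, dataset.sampling_rate)
    return segments, table
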