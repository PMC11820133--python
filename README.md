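# islet3d

3D single-cell analysis of glucose-stimulated Ca²⁺ oscillations in
pancreatic islets. Intact mouse islets imaged volumetrically at ≈2 Hz show
slow (~6.8 min) β-cell Ca²⁺ oscillations coordinated across hundreds of
cells; this package quantifies *which* cells coordinate the islet and *where*
each oscillation's wave travels, and how stable those roles are over time.
It is aimed at labs doing volumetric islet Ca²⁺ imaging (light-sheet,
two-photon) who have per-cell positions and fluorescence traces and want the
network/wave/consistency analysis without writing it from scratch.

## What it computes

Given cell positions (μm) and an N×T trace matrix:

1. **Oscillation segmentation** — peaks of the islet-average trace,
   depolarization/repolarization boundaries from the smoothed derivative, and
   per-oscillation period, active/silent phase, and duty cycle
   (active/period) at half-maximal Ca²⁺.
2. **Functional network** (per oscillation) — Pearson correlation *r*ᵢⱼ of
   every cell pair over the oscillation window; an edge where *r*ᵢⱼ > τ with
   the per-islet threshold τ calibrated so the mean degree
   ⟨k⟩ = (2/NK)·Σ edges over all N cells and K oscillations equals 7; high-
   and low-degree cells are the top/bottom 10% by degree.
3. **Wave analysis** (per oscillation) — each cell's phase φₙ is the integer-
   frame lag maximizing its cross-correlation with the islet mean
   (φ < 0 leads); early/late cells are the top/bottom 10% by phase; the wave
   axis is the first principal component of the early+late positions
   (cells >50 μm from their set's centre of gravity excluded), oriented
   early→late; axis change between oscillations is ‖aᵢ₊₁ − aᵢ‖², normalized
   by the change attainable with randomly drawn early/late sets.
4. **Consistency** — cells ranked per oscillation by degree/phase (cellular)
   or by distance to the top-set centre of gravity (regional); each ranking
   becomes a probability vector via a normal density over ranks, and
   consecutive oscillations are compared with
   D_KL(Pᵢ‖Pⱼ) = Σₙ Pᵢ(n)·log(Pᵢ(n)/Pⱼ(n)),
   divided by the mean KL of 100 rank shuffles: 0 = perfectly predictable
   ranking, ≈1 = completely random. Subpopulation retention between
   oscillations (|∩|/|set|) is reported alongside.
5. **2D vs 3D** — the same pipeline re-run on thin planes (±3 μm) at ¼ and ½
   of the islet's z-extent, to expose single-plane sampling bias.
6. **Pre/post comparison** — paired deltas (period, duty cycle, axis change,
   consistency, retention across the treatment boundary) between two
   recordings of the same cells, truncated to a common oscillation count.

A synthetic 3D islet generator (`islet3d.synthetic`) produces recordings
with known ground truth — sphere-packed cells at 9.3 μm spacing, smoothed
square-wave pulses with a 406.2 s period, a planar travelling wave whose
axis can rotate between oscillations, a radial noise gradient and a shared
spatially correlated noise field — plus optional volume rendering and
spherical-ROI trace extraction, so every stage is testable end to end.

## Worked example

```python
import numpy as np
from islet3d import (SyntheticConfig, generate_islet, segment_dataset,
                     build_islet_networks, phase_map, wave_axis)

dataset, truth = generate_islet(SyntheticConfig(seed=1))   # 500 cells, 6 osc.
segments, metrics = segment_dataset(dataset, min_separation=200.0)
print(metrics[["period_s", "active_s", "duty_cycle"]].round(2).head(3))

networks, threshold, mean_degree = build_islet_networks(
    dataset.traces, segments, dataset.cell_ids, target_degree=7)
print(f"threshold {threshold:.3f} -> mean degree {mean_degree:.2f}")

pm = phase_map(dataset.traces, segments[0], dataset.sampling_rate)
axis, excluded = wave_axis(dataset.positions, pm.early_set, pm.late_set,
                           dataset.cell_ids)
print("wave axis", axis.round(2), "vs imposed", truth.axes[0].round(2))
```

Output:

```
   period_s  active_s  duty_cycle
0    405.94    182.67        0.45
1    406.44    182.67        0.45
2    406.44    182.67        0.45
threshold 0.949 -> mean degree 7.00
wave axis [ 0.79  0.42 -0.45] vs imposed [ 0.83  0.37 -0.42]
```

The recovered period matches the generator's 406.2 s (6.77 min) to within
one frame at 2.02 Hz, the calibrated network realises the target average
degree of 7 exactly, and the PCA wave axis agrees with the imposed wave
direction to a few degrees.

The same pipeline is available from the shell:

```bash
islet3d simulate --out demo/            # synthetic islet -> CSV/HDF5/JSON
islet3d run --positions demo/positions.csv --traces demo/traces.h5 --out demo/out
```

`demo/out/report.json` then holds every block (oscillation metrics, network
and wave summaries, consistency, 2D planes).

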