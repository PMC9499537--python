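# erkwave

Analysis of apoptosis-induced ERK signalling waves in organoid monolayer
time-lapse microscopy, paired with an agent-based synthetic-monolayer
simulator that provides ground truth for every estimator.

## The biology and the measurement problem

Human colonic organoid monolayers self-organise into dense, crypt-like
**node** compartments of proliferative cells separated by sparse fields of
differentiated cells. When a differentiated cell dies by apoptotic
extrusion, it launches a **trigger wave** of ERK kinase activity that
propagates radially outward at roughly constant speed, weakening in both
duration and amplitude with distance, and the surrounding cells migrate
toward the dying cell while the wave passes over them. The spatial reach
of these waves is commensurate with the spacing between neighbouring
nodes, which is what makes their kinematics worth measuring carefully.

ERK activity is read out per cell with a kinase translocation reporter
(ERK-KTR): active ERK exports the reporter from the nucleus, so the ratio

```
C/N = mean cytoplasmic KTR intensity / mean nuclear KTR intensity
```

rises with ERK activity, and a cell is called **ERK-active** when its mean
cytoplasmic (annulus) signal strictly exceeds its nuclear signal.

`erkwave` implements the full measurement chain:

1. **`simulate`** — an agent-based monolayer with node/non-node
   compartments, Poisson apoptosis (biased to non-node cells), radial ERK
   waves `t_on = t_a + d/v`, `D(d) = D0·(1−d/R_max)^α_D`,
   `A(d) = A0·(1−d/R_max)^α_A`, wave-directed migration, and rendering of
   calibrated H2B / KTR / caspase OME-TIFF stacks plus ground-truth CSVs.
2. **`segmentation`** — nuclear segmentation of the H2B channel
   (smoothing, Otsu, intensity-seeded watershed, per-object half-maximum
   refinement) and KTR measurement over the nucleus and a two-pixel-wide
   surrounding annulus.
3. **`tracking`** — Hungarian frame-to-frame linking with distance gating
   and gap closing; caspase-based apoptotic event detection.
4. **`waves`** — the apoptosis-referenced movement statistics

   ```
   dNuc_i,t = sqrt((x_i,t − x_a)² + (y_i,t − y_a)²)
   Mov_i,t  = dNuc_i,a − dNuc_i,t        (0 at the apoptosis frame)
   ΔMov_i,t = Mov_i,t − Mov_i,t−1        (positive = approaching)
   ```

   distance-ordered kymographs, wave speed/extent/duration estimation
   from per-distance-bin onset times, and ERK-versus-movement
   cross-correlation.
5. **`patterning`** — DBSCAN clustering of ERK-active cells with
   alpha-shape boundaries, cumulative ERK-region heat maps, node
   detection from nuclear density with nearest-neighbour spacing,
   node/non-node compartment assignment, per-cell channel quantification
   and event localisation.
6. **`piv`** — windowed normalised-cross-correlation particle image
   velocimetry of the nuclear channel and radial convergence toward an
   event.
7. **`pipeline` / `cli`** — configuration, named benchmark fixtures, and
   the end-to-end `simulate → segment → track → analyse → report` run.

## Worked example

Simulate a single apoptotic event whose wave parameters follow the
exemplar event (speed 4.7 µm/min, reach 450 µm, ~455 cells in view), then
measure the wave back from the rendered images:

```python
import numpy as np
from erkwave import (fixture_config, simulate, render, segment_stack,
                     link_tracks, detect_apoptosis_events,
                     compute_dnuc, compute_mov, estimate_wave)

cfg = fixture_config("fig3", seed=42)
rng = np.random.default_rng(cfg.rng_seed)
gt = simulate(cfg, rng)                      # ground truth
stack = render(gt, cfg, rng)                 # H2B / KTR / CASP images
measurements, _ = segment_stack(stack)       # per-nucleus C/N ratios
tracks = link_tracks(measurements)           # single-cell tracks
event = detect_apoptosis_events(stack)[0]    # the dying cell
table = compute_mov(compute_dnuc(tracks, event)[0])
ws = estimate_wave(table, event, frame_interval=stack.frame_interval)
print(f"speed  {ws.speed:.2f} µm/min")
print(f"extent {ws.extent:.1f} µm")
print(f"cells  {ws.n_cells}")
```

prints

```
speed  4.71 µm/min
extent 437.5 µm
cells  450
```

i.e. the front speed is recovered within 1% of the configured
4.7 µm/min, and the detected reach lands in the outermost 25 µm distance
bin the imaging can resolve (the configured 450 µm reach, measured at
5-minute sampling; see `docs/methods.md`). The same run is available as
one command:

```bash
erkwave run --out out/ --seed 42      # report lands in out/report.json
```

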