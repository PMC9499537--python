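# Methods

This note documents the models, estimators and numerical choices behind
`erkwave`, in the spirit of a methods supplement: what is simulated, what
is measured, which knobs matter, and what the synthetic benchmarks do and
do not demonstrate about real microscopy data.

## Coordinate and unit conventions

One convention is used everywhere: images are indexed `(row, col)`,
0-based; `x = col × pixel_size`, `y = row × pixel_size` in µm with the
origin at the top-left pixel centre; time is `frame × frame_interval` in
minutes, frame 0-based. Pixel→µm conversion happens once, when
measurements are taken; all kinematics downstream are in µm and minutes.

## The synthetic monolayer

The simulator is an agent-based model of a confluent organoid monolayer,
built to be the ground-truth oracle for the analysis modules rather than
a mechanistic model of signalling.

**Geometry.** Node (crypt-like) compartments are disks of radius
`node_radius` (default 70 µm) placed on a jittered square grid with mean
nearest-neighbour spacing `node_spacing_mean` (default 399 µm, the
measured spacing between neighbouring proliferative compartments in
mature monolayers). Grid jitter (s.d. 12 µm) breaks the lattice symmetry;
it biases the realised mean nearest-neighbour spacing a few percent below
the grid constant (realised ≈ 380 µm at defaults), which is well inside
the 10% recovery tolerance used throughout. Nuclei are seeded by dart
throwing at `node_density` (24 cells per 100×100 µm, i.e. ~10 µm
nearest-neighbour spacing — densely packed crypt-like nuclei) inside
nodes and `nonnode_density` (3 per 100×100 µm) outside, with a hard
minimum separation of 1.5 nuclear radii.

**Apoptosis.** Events arrive as a Poisson process (`apoptosis_rate`
events/frame); each event kills a non-node cell with probability
`p_nonnode` (default 0.8, reflecting the strong bias of apoptosis toward
differentiated compartments). The dying cell is visible at its event
frame and removed afterwards; its nucleus shrinks over two rendered
frames (a realistic termination signature for trackers), and the caspase
channel carries a bright spot around the event frame.

**Waves.** A cell at distance `d` from an event (distance measured at the
event frame) activates at `t_on = t_a + d/v`, with amplitude
`A(d) = A0·(1 − d/R_max)^α_A` for a duration
`D(d) = D0·(1 − d/R_max)^α_D`; cells beyond `R_max` never activate.
Concurrent waves combine by maximum, not summation — waves in these
monolayers do not visibly superpose, and the default event rate keeps
overlap rare. Defaults: `v = 4.7` µm/min, `R_max = 450` µm, `D0 = 40`
min, `A0 = 1`.

*Taper exponents.* The observation that waves dissipate in both duration
and intensity fixes the taper's sign but not its shape. The default is
`α_D = α_A = 0.5`. A linear taper (`α = 1`) was considered and rejected
for the defaults on identifiability grounds: with `α_D = 1` the pulse
duration over the outer ~40 µm of the wave's true reach falls below one
frame interval, so no frame-sampled measurement — simulated or real —
could register activity there, and the observable extent would sit
systematically ~1.5 distance bins short of the configured `R_max`. With
`α = 0.5` the pulse at the outermost resolvable bin still spans at least
one frame, making the configured reach measurable. Both exponents remain
configurable, and the duration-decay recovery test runs with `α_D = 1`.

**Motion.** Active cells drift toward the wave source at
`migration_gain · E` µm/min (default gain 0.5), cells within
`recoil_radius` (20 µm) of a dying cell are displaced outward once by
`recoil_distance` at the event frame, and all cells receive isotropic
Gaussian jitter (s.d. 0.3 µm/frame). The magnitude of the initial recoil
is not quantified anywhere; the 2 µm default is a visual-scale guess and
is flagged as such. A pairwise relaxation pass keeps nuclei at least one
nuclear radius apart.

**Rendering.** Default calibration is 1.3 µm/px and 5 min/frame — fine
enough to resolve a 4.7 µm/min front between frames. The H2B channel is a
Gaussian blob per nucleus whose full width at half maximum equals the
nuclear diameter. The KTR channel gives each cell a cytoplasmic disk
(radius 9 µm) and a nuclear domain defined as the FWHM footprint of the
cell's own H2B blob, so the two channels agree about where the nucleus
ends. A cell with activity `E` has true ratio
`C/N(E) = (1 + (g − 1)E) / √g` with `g = ktr_partition` (default 2):
inactive cells sit at `1/√g < 1` (reporter nuclear), fully active cells
at `√g > 1` (reporter exported), and the contrast between `E = 0` and
`E = 1` is exactly `g`. This anchoring keeps the strict
`cytoplasm > nucleus` activity call away from the tie at ratio 1, where a
symmetric rendering would leave inactive cells. Gaussian intensity noise
(s.d. 2 on a base of 100) is added to all channels unless disabled.

**Determinism.** One seeded `numpy` generator is threaded through
placement, seeding, scheduling, motion and rendering noise; identical
config + seed reproduces bit-identical ground-truth tables.

## Segmentation and KTR measurement

Nuclei are segmented per frame by Gaussian smoothing (σ = 1 px), a global
Otsu threshold, and a watershed seeded at local intensity maxima
(minimum seed separation 3 px) — intensity seeding splits overlapping
blob pairs whose union is convex and therefore has no waist for a
distance-transform watershed. Each object is then trimmed to the pixels
at or above half its own raw peak intensity. This per-object FWHM
refinement matters quantitatively: a global threshold includes an
arbitrary amount of blob skirt (roughly doubling the mask area at
defaults), which dilutes the nuclear mean with perinuclear cytoplasm and
compressed the measured C/N fold change from 2.0 to ~1.33 in early
testing; with refinement the round-trip error is below 2%. Objects under
12 px are removed; border-touching nuclei are kept but flagged.

The cytoplasmic measurement is the mean KTR intensity over a two-pixel-
wide annulus: the nucleus dilated by a Euclidean disk of radius 2 px,
minus the nucleus, minus every *other* nucleus dilated by 1 px. Only
neighbouring nuclei can be excluded from image data; the annulus may
still mix in neighbouring cells' cytoplasm, an ambiguity real data shares.
Cells whose annulus comes up empty (pathological crowding) get a missing
ratio and a missing activity call but are not dropped. A cell is
ERK-active iff `cyto_mean > nuc_mean` strictly; ties are inactive. No
background subtraction is applied by default (the simulator renders zero
background); a threshold override exists for real data.

## Tracking and events

Detections are linked frame-to-frame by optimal one-to-one assignment
(Hungarian algorithm on squared displacement) under a hard gating radius
(default 15 µm); unmatched detections open new tracks, tracks unmatched
for more than `max_gap = 2` frames terminate, and interior gaps are
filled by linear interpolation and flagged. On ≤10-cell instances the
assignment provably equals the brute-force permutation optimum (tested).
Divisions are not handled; a division simply starts a new track.

Apoptotic events come from the caspase channel: connected regions above
half the channel maximum are reduced to intensity-weighted centroids and
merged across ≤2-frame, ≤30-µm windows; an event is anchored at its first
above-threshold frame. A channel whose maximum does not exceed the median
by ten standard deviations is considered signal-free (no events), which
keeps pure-noise channels from producing detections. A fallback for
caspase-free data (track terminations without nearby continuations) is
deliberately not implemented; the simulator always renders the channel.

## Wave kinematics

All movement statistics are referenced to the event: `dNuc` is the
Euclidean distance to the event position (the printed formula's stray
minus sign between the squared terms is resolved as the distance
formula, which its own text names), `Mov = dNuc_a − dNuc` is exactly zero
at the apoptosis frame and positive for approach, and `ΔMov` is its
per-frame difference. Kymographs sort cells by their distance at the
event frame, closest on top.

The wave estimator groups cells into 25 µm distance bins. Each bin's
onset is the first post-event frame where its mean C/N ratio exceeds its
own pre-event baseline (default: the 6 frames before the event) by
`k·σ_baseline` with `k = 2`, subject to a relative floor of 2% of the
baseline mean. The floor exists because the σ-rule alone is degenerate on
noiseless data (σ → 0) and because cell motion and pixel re-quantisation
give the per-bin mean a ~0.7% wiggle even without imaging noise; 2%
clears that wiggle while sitting far below the ≥15% rises of genuinely
reached bins at default wave parameters. Bin onsets are fitted by least
squares (distance against onset time) with one pass of outlier rejection
at two frame-interval residuals; the slope is the front speed, the
largest consistent bin centre is the extent, and the quoted
distance-over-period speed is also reported as `extent/total_duration`
for comparability with single-exemplar descriptions. No crossing in any
bin yields a "no wave detected" result, not an exception; fewer than
three onset bins leaves the speed undefined.

Cross-correlation between each cell's C/N series and its `ΔMov` series is
Pearson at every lag in ±`max_lag` frames on mean-centred,
variance-normalised series, ties broken toward the smaller |lag| (the
conservative direction for the claim that ERK precedes movement).
Positive lag means ERK leads. Zero-variance or too-short series are
excluded and counted; the population summary is the median lag plus a
sign test.

## Spatial patterning

ERK-active cells are clustered per frame with DBSCAN (Euclidean, µm);
`eps` defaults to 1.5× the frame's median nearest-nuclei distance
(scale-adaptive), `min_pts = 5`. Cluster boundaries are alpha shapes —
unions of Delaunay triangles with circumradius ≤ eps — because a convex
hull would bridge concave active regions. Heat maps count, per pixel
centre, the frames whose active-region polygons contain it; the count is
bounded by the frame count by construction and is checked against a
point-in-polygon oracle from an independent geometry library.

Nodes are detected from nuclear centroid density, not raw intensity: a
histogram KDE (bandwidth 40 µm on a 4 µm grid) is Otsu-thresholded, the
foreground is watershed-split at density maxima at least 2.5 bandwidths
apart, and each candidate region must pass a Poisson excess test — the
nuclei it contains must exceed the expectation from the field's median
density by at least a factor 2 **and** 4 Poisson standard deviations —
plus a 6,000 µm² minimum area. The excess test is what keeps uniform
fields empty: KDE texture on a uniform field is pure sampling noise with
peaks up to ~2–3× the median, which a plain contrast threshold cannot
separate from genuine 4–8× dense compartments at these cell counts. Node
boundaries are trimmed to the density contour at 40% of the
peak-over-background rise: the half-rise contour tracks the dense-disk
edge (verified on azimuthally averaged profiles), and the default sits
slightly below half because node interiors are several-fold denser than
the background, making a cell just outside the true edge far cheaper to
mislabel than one just inside. Compartment assignment is point-in-polygon
against these boundaries; every cell gets a label. Node spacing is the
nearest-neighbour distance between node centroids — the same statistic
reported for nuclei — since edge-to-edge spacing is not otherwise
defined; no buffer margin is applied around node boundaries when
localising events.

## PIV

Single-pass windowed normalised cross-correlation on the H2B channel
(window 32 px, 50% overlap, ±8 px search), sub-pixel refined by a
three-point Gaussian fit, converted to µm/min. A vector is invalid if its
window is flat, its correlation peak is weak (< 0.3), its peak lies on
the border of the searched range, or the search range was clipped by the
image edge — clipped windows can lock onto spurious interior peaks and
are never trusted. Convergence toward an event is the mean projection of
valid vectors onto the unit vector pointing at the event, positive for
approach; vectors are time-averaged across frame pairs by default, with
per-pair output available for time-integrated displacement. Whether
movie-long arrows should be time-averaged or integrated is ambiguous in
the source material; averaging is the default and both are computable.

## Benchmark fixtures and problem sizes

The named fixtures pin the generator to the study's printed set-points:
`fig3` (one event, 455 cells in a 1000×1000 µm field, speed 4.7 µm/min,
reach 450 µm, noiseless, 30 frames at 5 min), `fig3_noisy` (reach 447 µm,
default noise — the ensemble variant), `fig1` (2000×2000 µm, 25 nodes at
399 µm spacing), and the pharmacological presets `fig4_pma` (global
activation with dispersed nodes), `fig6_meki` (activity clamped to zero,
nodes enlarged 1.5×) and `fig3g_egfri` (migration gain zero). Presets
emulate perturbation *outcomes* as parameter regimes only; no signalling
biochemistry is modelled. These sizes keep a full fig3 cycle
(simulate → render → segment → track → estimate) around 20 s and the
complete benchmark script under ~3 minutes on one CPU.

## What passing the benchmarks does and does not show

The closed-loop recoveries show that the estimators are unbiased at
realistic geometry, density, contrast and sampling, and that the whole
chain — rendering, segmentation, annulus measurement, linking, binned
onset regression — composes without systematic error. They do not
exercise uneven illumination, photobleaching, focus drift, out-of-plane
extrusion, nuclear shape variability, reporter expression heterogeneity,
or segmentation in 3-D-crowded epithelia; real data will degrade the C/N
contrast and tracking continuity in ways the noiseless fixtures cannot
reveal. The extent estimator reports the largest 25 µm bin with a
consistent onset, so its resolution is one bin by construction; at
5-minute sampling the measured reach of a 450 µm wave lands at 437.5 µm,
and that bin-quantised shortfall is a property of any frame-sampled
measurement of a dissipating front, not of this implementation.

## Known limitations

- Radial symmetry is assumed throughout; no 2-D anisotropic wave
  reconstruction is attempted.
- The linking is not mitosis-aware, and no interactive curation exists.
- DBSCAN border points inherit the scan-order cluster of the library
  implementation; the equivalence tests treat border assignment as
  ambiguous, as the definition allows.
- The high/low expression gate in per-cell quantification is a fixed
  configurable threshold, not a mixture fit.
- Descriptive statistics only; no hypothesis testing is bundled.
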