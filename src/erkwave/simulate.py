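"""Agent-based simulator of an organoid monolayer with ERK trigger waves.

The model: nuclei live on a 2-D field partitioned into dense, crypt-like
"node" disks and a sparse non-node background.  Apoptotic events strike
(preferentially non-node) cells at a Poisson rate; each event launches a
radially propagating ERK activation wave.  A cell at distance ``d`` from
the event (measured at the event frame) activates at ``t_a + d/v`` with
amplitude ``A0 * (1 - d/R_max)**alpha_A`` for a duration
``D0 * (1 - d/R_max)**alpha_D``; cells beyond ``R_max`` never activate,
and overlapping waves combine by taking the maximum activity.  Active
cells drift toward the wave source at ``migration_gain * E`` µm/min;
cells adjacent to the dying cell recoil outward once at the event frame.

The simulator is the ground-truth oracle for the analysis modules: it
records true positions, activities, compartments, events and nodes, and
renders calibrated H2B / ERK-KTR / caspase image channels from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import ConfigError, SimConfig
from .stack import FrameStack

CHANNELS = ["H2B", "KTR", "CASP"]


@dataclass
class GroundTruth:
    """True per-cell tracks, activities and event/node tables.

    ``cells`` has one row per living cell per frame with columns
    ``cell_id, frame, x_um, y_um, E, compartment``; ``events`` one row per
    apoptotic event (``event_id, frame, x_um, y_um, cell_id``); ``nodes``
    one row per node disk (``node_id, x_um, y_um, radius_um``).
    """

    cells: pd.DataFrame
    events: pd.DataFrame
    nodes: pd.DataFrame
    config: SimConfig
    death_frames: dict[int, int] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(out / "cells.csv", index=False)
        self.events.to_csv(out / "events.csv", index=False)
        self.nodes.to_csv(out / "nodes.csv", index=False)
        self.config.to_yaml(out / "sim_config.yaml")


# ---------------------------------------------------------------------------
# placement


def place_nodes(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Place node centres on a jittered grid with the configured mean spacing.

    Returns an (n, 2) array of (x, y) centres in µm.  A field smaller than
    one spacing gets a single central node; ``n_nodes == 0`` returns an
    empty array.  No two centres end up closer than ``2 * node_radius``.
    """
    if config.n_nodes == 0:
        return np.empty((0, 2))
    w, h = config.field_size
    s = config.node_spacing_mean
    if w < 2 * config.node_radius or h < 2 * config.node_radius:
        raise ConfigError("field too small to hold a single node")
    nx, ny = int(w // s), int(h // s)
    if nx < 1 or ny < 1:
        return np.array([[w / 2.0, h / 2.0]])
    # centre the grid in the field
    x0 = (w - (nx - 1) * s) / 2.0
    y0 = (h - (ny - 1) * s) / 2.0
    gx, gy = np.meshgrid(x0 + s * np.arange(nx), y0 + s * np.arange(ny))
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    if config.node_jitter_um > 0:
        for _ in range(50):  # redraw jitter until min-distance holds
            jitter = rng.normal(0.0, config.node_jitter_um, size=centers.shape)
            jittered = centers + jitter
            if len(jittered) < 2:
                break
            dmin = cKDTree(jittered).query(jittered, k=2)[0][:, 1].min()
            if dmin >= 2 * config.node_radius:
                break
        else:
            jittered = centers  # fall back to the bare grid
        centers = jittered
    margin = config.node_radius
    centers[:, 0] = np.clip(centers[:, 0], margin, w - margin)
    centers[:, 1] = np.clip(centers[:, 1], margin, h - margin)
    if config.n_nodes is not None and config.n_nodes < len(centers):
        idx = rng.choice(len(centers), size=config.n_nodes, replace=False)
        centers = centers[np.sort(idx)]
    return centers


def seed_cells(
    config: SimConfig, node_centers: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Scatter nuclei at the node / non-node densities by dart throwing.

    Returns ``(positions, compartment)`` where positions is (n, 2) µm and
    compartment is an array of ``"node"`` / ``"non-node"`` labels.  Nuclei
    are rejected closer than ``1.5 * nucleus_radius`` to any accepted one.
    """
    w, h = config.field_size
    min_sep = 1.5 * config.nucleus_radius
    node_r = config.node_radius
    area_node = np.pi * node_r**2 * len(node_centers)
    area_total = w * h
    area_non = max(area_total - area_node, 0.0)
    n_node = int(round(config.node_density * area_node / 1e4))
    n_non = int(round(config.nonnode_density * area_non / 1e4))
    # feasibility: random sequential adsorption jams near 0.547 coverage
    for n, area, what in ((n_node, area_node, "node"), (n_non, area_non, "non-node")):
        if n > 0 and n * np.pi * (min_sep / 2) ** 2 > 0.5 * area:
            raise ConfigError(
                f"{what} density incompatible with the minimum nuclear spacing"
            )

    accepted: list[np.ndarray] = []
    labels: list[str] = []

    def in_node(p: np.ndarray) -> bool:
        if len(node_centers) == 0:
            return False
        return bool(
            (np.linalg.norm(node_centers - p[None, :], axis=1) < node_r).any()
        )

    def try_place(n_target: int, want_node: bool, centers: np.ndarray) -> None:
        placed, attempts = 0, 0
        max_attempts = 200 * max(n_target, 1)
        while placed < n_target and attempts < max_attempts:
            attempts += 1
            if want_node:
                c = centers[rng.integers(len(centers))]
                r = node_r * np.sqrt(rng.uniform())
                th = rng.uniform(0, 2 * np.pi)
                p = c + r * np.array([np.cos(th), np.sin(th)])
                p = np.clip(p, [0, 0], [w, h])
            else:
                p = rng.uniform([0, 0], [w, h])
                if in_node(p):
                    continue
            if accepted:
                d = np.linalg.norm(np.asarray(accepted) - p[None, :], axis=1)
                if (d < min_sep).any():
                    continue
            accepted.append(p)
            labels.append("node" if want_node else "non-node")
            placed += 1

    if len(node_centers) > 0 and n_node > 0:
        try_place(n_node, True, node_centers)
    try_place(n_non, False, node_centers)
    if not accepted:
        return np.empty((0, 2)), np.array([], dtype=object)
    return np.asarray(accepted), np.asarray(labels, dtype=object)


# ---------------------------------------------------------------------------
# dynamics


@dataclass
class _Wave:
    event_id: int
    frame: int
    x: float
    y: float
    cell_id: int
    # per-cell activation windows, keyed by cell_id
    t_on: dict[int, float] = field(default_factory=dict)
    dur: dict[int, float] = field(default_factory=dict)
    amp: dict[int, float] = field(default_factory=dict)


def _wave_windows(
    config: SimConfig,
    event_xy: np.ndarray,
    t_a: float,
    cell_ids: np.ndarray,
    positions: np.ndarray,
) -> tuple[dict[int, float], dict[int, float], dict[int, float]]:
    """Activation onset/duration/amplitude for every cell in reach."""
    d = np.linalg.norm(positions - event_xy[None, :], axis=1)
    r = config.wave_extent
    inside = d < r
    taper = np.clip(1.0 - d[inside] / r, 0.0, 1.0)
    t_on = t_a + d[inside] / config.wave_speed
    dur = config.duration_at_origin * taper**config.duration_decay_exp
    amp = config.amplitude_at_origin * taper**config.amplitude_decay_exp
    ids = cell_ids[inside]
    return (
        dict(zip(ids.tolist(), t_on.tolist())),
        dict(zip(ids.tolist(), dur.tolist())),
        dict(zip(ids.tolist(), amp.tolist())),
    )


def simulate(config: SimConfig, rng: Optional[np.random.Generator] = None) -> GroundTruth:
    """Run the full agent-based simulation and return the ground truth."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    w, h = config.field_size
    dt = config.frame_interval

    node_centers = place_nodes(config, rng)
    pos, compartment = seed_cells(config, node_centers, rng)
    n0 = len(pos)
    cell_ids = np.arange(n0)
    alive = np.ones(n0, dtype=bool)

    fixed = {}
    if config.fixed_events is not None:
        for f, x, y in config.fixed_events:
            fixed.setdefault(int(f), []).append((x, y))

    waves: list[_Wave] = []
    rows: list[tuple] = []
    event_rows: list[tuple] = []
    death_frames: dict[int, int] = {}
    pending_recoil = np.zeros((n0, 2))

    for frame in range(config.n_frames):
        t = frame * dt

        # --- apoptosis scheduling ---------------------------------------
        new_events: list[int] = []  # indices into cell arrays
        if config.fixed_events is not None:
            for x, y in fixed.get(frame, []):
                cand = np.flatnonzero(alive)
                if len(cand) == 0:
                    continue
                d = np.linalg.norm(pos[cand] - np.array([x, y]), axis=1)
                new_events.append(int(cand[np.argmin(d)]))
        elif config.apoptosis_rate > 0:
            for _ in range(rng.poisson(config.apoptosis_rate)):
                want_non = rng.uniform() < config.p_nonnode
                label = "non-node" if want_non else "node"
                cand = np.flatnonzero(alive & (compartment == label))
                if len(cand) == 0:  # fall back to any living cell
                    cand = np.flatnonzero(alive)
                if len(cand) == 0:
                    continue
                new_events.append(int(rng.choice(cand)))

        dying_now: list[int] = []
        for idx in new_events:
            if not alive[idx] or idx in dying_now:
                continue
            ev_xy = pos[idx].copy()
            wave = _Wave(
                event_id=len(waves), frame=frame, x=ev_xy[0], y=ev_xy[1],
                cell_id=int(cell_ids[idx]),
            )
            dying_now.append(idx)
            death_frames[int(cell_ids[idx])] = frame
            live = np.array([i for i in np.flatnonzero(alive)
                             if i not in dying_now])
            wave.t_on, wave.dur, wave.amp = _wave_windows(
                config, ev_xy, t, cell_ids[live], pos[live]
            )
            waves.append(wave)
            event_rows.append((wave.event_id, frame, ev_xy[0], ev_xy[1], wave.cell_id))
            # outward recoil of immediate neighbours, applied this frame
            if config.recoil_distance > 0:
                d = np.linalg.norm(pos[live] - ev_xy[None, :], axis=1)
                near = live[(d <= config.recoil_radius) & (d > 0)]
                vec = pos[near] - ev_xy[None, :]
                norm = np.linalg.norm(vec, axis=1, keepdims=True)
                pending_recoil[near] += config.recoil_distance * vec / norm

        # --- activity at this frame -------------------------------------
        # dying cells stay visible at their event frame (E = 0) and are
        # removed from all subsequent frames
        live = np.flatnonzero(alive)
        dying_set = set(dying_now)
        E = np.zeros(len(live))
        drive = np.full(len(live), -1)  # wave index driving each cell
        for wi, wave in enumerate(waves):
            for j, idx in enumerate(live):
                cid = int(cell_ids[idx])
                t_on = wave.t_on.get(cid)
                if t_on is None:
                    continue
                if t_on <= t <= t_on + wave.dur[cid] and wave.amp[cid] > E[j]:
                    E[j] = wave.amp[cid]
                    drive[j] = wi
        if config.global_activity is not None:
            E[:] = config.global_activity
            drive[:] = -1
        for j, idx in enumerate(live):
            if idx in dying_set:
                E[j] = 0.0
                drive[j] = -1

        for j, idx in enumerate(live):
            rows.append(
                (int(cell_ids[idx]), frame, pos[idx, 0], pos[idx, 1], E[j],
                 compartment[idx])
            )

        for idx in dying_now:
            alive[idx] = False
        if dying_set:
            keep = np.array([idx not in dying_set for idx in live])
            live, E, drive = live[keep], E[keep], drive[keep]

        # --- motion toward the wave source ------------------------------
        if frame < config.n_frames - 1:
            disp = np.zeros((len(live), 2))
            if config.migration_gain > 0:
                for j, idx in enumerate(live):
                    if drive[j] >= 0 and E[j] > 0:
                        wv = waves[drive[j]]
                        vec = np.array([wv.x, wv.y]) - pos[idx]
                        d = np.linalg.norm(vec)
                        if d > 1e-9:
                            step = config.migration_gain * E[j] * dt
                            disp[j] = vec / d * min(step, d)
            if config.jitter_sd > 0:
                disp += rng.normal(0.0, config.jitter_sd, size=disp.shape)
            disp += pending_recoil[live]
            pending_recoil[live] = 0.0
            pos[live] += disp
            pos[live, 0] = np.clip(pos[live, 0], 0, w)
            pos[live, 1] = np.clip(pos[live, 1], 0, h)
            _enforce_separation(pos, live, config.nucleus_radius)

    cells = pd.DataFrame(
        rows, columns=["cell_id", "frame", "x_um", "y_um", "E", "compartment"]
    )
    events = pd.DataFrame(
        event_rows, columns=["event_id", "frame", "x_um", "y_um", "cell_id"]
    )
    nodes = pd.DataFrame(
        {
            "node_id": np.arange(len(node_centers)),
            "x_um": node_centers[:, 0] if len(node_centers) else [],
            "y_um": node_centers[:, 1] if len(node_centers) else [],
            "radius_um": config.node_radius,
        }
    )
    return GroundTruth(cells=cells, events=events, nodes=nodes, config=config,
                       death_frames=death_frames)


def _enforce_separation(pos: np.ndarray, live: np.ndarray, min_sep: float) -> None:
    """Push apart any pair of living nuclei closer than ``min_sep`` (in place)."""
    if len(live) < 2:
        return
    for _ in range(3):
        tree = cKDTree(pos[live])
        pairs = tree.query_pairs(min_sep, output_type="ndarray")
        if len(pairs) == 0:
            return
        for i, j in pairs:
            a, b = live[i], live[j]
            vec = pos[b] - pos[a]
            d = np.linalg.norm(vec)
            if d < 1e-9:
                vec, d = np.array([1.0, 0.0]), 1.0
            push = (min_sep - d) / 2.0 + 1e-6
            pos[a] -= vec / d * push
            pos[b] += vec / d * push


# ---------------------------------------------------------------------------
# rendering


def _paint_disk(img: np.ndarray, cx: float, cy: float, r: float) -> tuple:
    """Anti-aliased disk coverage added into a scratch alpha patch.

    Returns (row slice, col slice, alpha patch); alpha in [0, 1].
    """
    h_px, w_px = img.shape
    lo_c = max(int(np.floor(cx - r - 1)), 0)
    hi_c = min(int(np.ceil(cx + r + 2)), w_px)
    lo_r = max(int(np.floor(cy - r - 1)), 0)
    hi_r = min(int(np.ceil(cy + r + 2)), h_px)
    if lo_c >= hi_c or lo_r >= hi_r:
        return None
    cols = np.arange(lo_c, hi_c)
    rws = np.arange(lo_r, hi_r)
    dd = np.hypot(cols[None, :] - cx, rws[:, None] - cy)
    alpha = np.clip(r + 0.5 - dd, 0.0, 1.0)
    return slice(lo_r, hi_r), slice(lo_c, hi_c), alpha


def _paint_gaussian(img: np.ndarray, cx: float, cy: float, sigma: float,
                    amp: float) -> Optional[tuple]:
    """Add a Gaussian blob; return its (row slice, col slice, unit profile)."""
    h_px, w_px = img.shape
    ext = 4.0 * sigma
    lo_c = max(int(np.floor(cx - ext)), 0)
    hi_c = min(int(np.ceil(cx + ext)) + 1, w_px)
    lo_r = max(int(np.floor(cy - ext)), 0)
    hi_r = min(int(np.ceil(cy + ext)) + 1, h_px)
    if lo_c >= hi_c or lo_r >= hi_r:
        return None
    cols = np.arange(lo_c, hi_c)
    rws = np.arange(lo_r, hi_r)
    d2 = (cols[None, :] - cx) ** 2 + (rws[:, None] - cy) ** 2
    profile = np.exp(-d2 / (2.0 * sigma**2))
    img[lo_r:hi_r, lo_c:hi_c] += amp * profile
    return slice(lo_r, hi_r), slice(lo_c, hi_c), profile


def render(gt: GroundTruth, config: Optional[SimConfig] = None,
           rng: Optional[np.random.Generator] = None) -> FrameStack:
    """Render H2B / KTR / CASP channels from the ground truth.

    The KTR channel implements the translocation-reporter contract: a cell
    with activity E has true cytoplasm/nucleus ratio
    ``cn(E) = (1 + (g - 1) E) / sqrt(g)`` (rendered as nuclear level
    ``base / sqrt(cn)`` and cytoplasmic level ``base * sqrt(cn)``), so an
    inactive cell sits at ``1/sqrt(g) < 1`` (reporter nuclear), a fully
    active cell at ``sqrt(g) > 1`` (reporter exported), and the fold
    change between E = 0 and E = 1 equals ``g = ktr_partition`` exactly.
    The nuclear KTR domain of each cell is the full-width-half-maximum
    footprint of its own H2B blob, so both channels agree on where the
    nucleus ends.  Dying nuclei shrink over two frames before
    disappearing; the caspase channel carries a bright spot at each event
    site around the event frame.
    """
    if config is None:
        config = gt.config
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 1)
    px = config.pixel_size
    w_px = int(round(config.field_size[0] / px))
    h_px = int(round(config.field_size[1] / px))
    n_bytes = config.n_frames * 3 * h_px * w_px * 4
    if n_bytes > config.max_render_bytes:
        raise MemoryError(
            f"requested stack needs {n_bytes / 1e9:.2f} GB, over the "
            f"configured budget of {config.max_render_bytes / 1e9:.2f} GB"
        )
    data = np.full((config.n_frames, 3, h_px, w_px), config.background,
                   dtype=np.float32)
    g = config.ktr_partition
    r_nuc = config.nucleus_radius / px
    r_cyto = config.cyto_radius / px
    sigma_h2b = r_nuc / 1.1774  # half-maximum of the blob falls at r_nuc

    cells_by_frame = dict(tuple(gt.cells.groupby("frame", sort=True)))
    events_by_cell = (
        gt.events.set_index("cell_id") if len(gt.events) else None
    )

    for frame in range(config.n_frames):
        h2b, ktr, casp = data[frame]
        sub = cells_by_frame.get(frame)
        shrink_rows = []
        if events_by_cell is not None:
            # dying nuclei: render shrinking remnants for two frames
            dying = gt.events[(gt.events["frame"] == frame - 1)
                              | (gt.events["frame"] == frame - 2)]
            for _, ev in dying.iterrows():
                factor = 0.6 if ev["frame"] == frame - 1 else 0.3
                shrink_rows.append((ev["x_um"], ev["y_um"], factor))
        if sub is None and not shrink_rows:
            continue
        cyto_layer = np.zeros_like(ktr)
        nuc_alpha = np.zeros_like(ktr)
        nuc_value = np.zeros_like(ktr)

        def paint_cell(x_um: float, y_um: float, E: float, scale: float) -> None:
            cx, cy = x_um / px, y_um / px
            cn = (1.0 + (g - 1.0) * np.clip(E, 0.0, 1.0)) / np.sqrt(g)
            n_val = config.ktr_base / np.sqrt(cn)
            c_val = config.ktr_base * np.sqrt(cn)
            hit = _paint_disk(ktr, cx, cy, r_cyto * scale)
            if hit is not None:
                rs, cs, alpha = hit
                np.maximum(cyto_layer[rs, cs], c_val * alpha,
                           out=cyto_layer[rs, cs])
            blob = _paint_gaussian(h2b, cx, cy, sigma_h2b * scale,
                                   config.h2b_amp)
            if blob is not None:
                # nuclear KTR domain = FWHM footprint of the cell's H2B blob
                rs, cs, profile = blob
                fp = profile >= 0.5 * profile.max()
                prev = nuc_alpha[rs, cs]
                take = np.where(fp, np.clip(1.0 - prev, 0.0, 1.0), 0.0)
                nuc_alpha[rs, cs] = prev + take
                nuc_value[rs, cs] += n_val * take

        if sub is not None:
            for x_um, y_um, E in zip(sub["x_um"], sub["y_um"], sub["E"]):
                paint_cell(x_um, y_um, E, 1.0)
        for x_um, y_um, factor in shrink_rows:
            paint_cell(x_um, y_um, 0.0, factor)

        ktr += cyto_layer * (1.0 - nuc_alpha) + nuc_value

        if len(gt.events):
            near = gt.events[np.abs(gt.events["frame"] - frame) <= 1]
            for _, ev in near.iterrows():
                rel = int(ev["frame"] - frame)  # -1, 0, +1 relative to event
                amp = {1: 0.3, 0: 1.0, -1: 0.7}[rel] * config.casp_amp
                _paint_gaussian(casp, ev["x_um"] / px, ev["y_um"] / px,
                                max(r_nuc * 0.8, 1.5), amp)

    if config.noise_sd > 0:
        data += rng.normal(0.0, config.noise_sd, size=data.shape).astype(np.float32)
        np.clip(data, 0.0, None, out=data)
    return FrameStack(data=data, channels=list(CHANNELS), pixel_size=px,
                      frame_interval=config.frame_interval)


def simulate_and_render(
    config: SimConfig, out_dir: Optional[str | Path] = None
) -> tuple[GroundTruth, FrameStack]:
    """Convenience wrapper: simulate, render, optionally write everything."""
    rng = np.random.default_rng(config.rng_seed)
    gt = simulate(config, rng)
    stack = render(gt, config, rng)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        gt.write(out)
        stack.save(out / "stack.ome.tif")
    return gt, stack
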