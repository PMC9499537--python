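"""End-to-end orchestration: simulate → segment → track → analyse → report.

Also houses the named benchmark fixtures — synthetic monolayers whose
generator parameters are pinned to the study's printed set-points (wave
speed ~4.7 µm/min over ~450 µm with ~455 analysed cells; ensemble wave
distance ~447 µm; node spacing ~399 µm) and the pharmacological presets
(global ERK activation, ERK-off with enlarged nodes, migration-off).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .config import ConfigError, PipelineConfig, SimConfig
from .patterning import (
    accumulate_heatmap,
    assign_compartments,
    cluster_erk_active,
    detect_nodes,
    localize_events,
    nearest_nuclei_distances,
)
from .piv import convergence_toward, piv_stack
from .segmentation import SegParams, segment_stack
from .simulate import GroundTruth, render, simulate
from .stack import FrameStack, StackError
from .tracking import detect_apoptosis_events, events_to_frame, link_tracks
from .waves import build_kymograph, compute_dnuc, compute_mov, estimate_wave

log = logging.getLogger("erkwave")

FIXTURE_NAMES = ("fig1", "fig3", "fig3_noisy", "fig4_pma", "fig6_meki",
                 "fig3g_egfri")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


def fixture_config(name: str, seed: int = 0) -> SimConfig:
    """Return the SimConfig of a named benchmark fixture.

    fig3
        Single apoptotic event at the field centre launching one noiseless
        wave (speed 4.7 µm/min, extent 450 µm) through ~455 uniformly
        seeded cells — the exemplar-wave scenario.
    fig3_noisy
        As fig3 but with default imaging noise and a 447 µm extent, for
        ensemble wave-distance recovery.
    fig1
        A 2000×2000 µm patterned monolayer with nodes on a jittered grid
        at 399 µm mean spacing (5×5 = 25 nodes).
    fig4_pma
        Global-activation preset: every cell fully ERK-active and node
        cells dispersed to a uniform density (phorbol-ester analogue).
    fig6_meki
        ERK-off preset: activity clamped to zero with enlarged nodes (MEK
        inhibitor analogue).
    fig3g_egfri
        As fig3 but with migration_gain = 0 (EGFR inhibitor analogue; the
        wave fires but no cell moves toward the dying cell).
    """
    if name == "fig3":
        return SimConfig(
            field_size=(1000.0, 1000.0),
            n_frames=30,
            n_nodes=0,
            nonnode_density=4.55,
            wave_speed=4.7,
            wave_extent=450.0,
            noise_sd=0.0,
            jitter_sd=0.15,
            fixed_events=[(6, 500.0, 500.0)],
            rng_seed=seed,
        )
    if name == "fig3_noisy":
        cfg = fixture_config("fig3", seed)
        cfg.wave_extent = 447.0
        cfg.noise_sd = 2.0
        return cfg
    if name == "fig1":
        return SimConfig(
            field_size=(2000.0, 2000.0),
            n_frames=1,
            node_spacing_mean=399.0,
            node_radius=70.0,
            node_density=12.0,
            nonnode_density=3.0,
            rng_seed=seed,
        )
    if name == "fig4_pma":
        return SimConfig(
            field_size=(1200.0, 1200.0),
            n_frames=2,
            node_spacing_mean=399.0,
            node_density=5.0,
            nonnode_density=5.0,
            global_activity=1.0,
            rng_seed=seed,
        )
    if name == "fig6_meki":
        return SimConfig(
            field_size=(1200.0, 1200.0),
            n_frames=2,
            node_spacing_mean=399.0,
            node_radius=105.0,
            node_density=12.0,
            nonnode_density=3.0,
            global_activity=0.0,
            rng_seed=seed,
        )
    if name == "fig3g_egfri":
        cfg = fixture_config("fig3", seed)
        cfg.migration_gain = 0.0
        return cfg
    raise ConfigError(
        f"unknown fixture {name!r}; valid names: {', '.join(FIXTURE_NAMES)}"
    )


def make_fixtures(name: str, seed: int = 0,
                  out_dir: Optional[str | Path] = None
                  ) -> tuple[GroundTruth, FrameStack]:
    """Simulate and render a named fixture, optionally writing it to disk."""
    cfg = fixture_config(name, seed)
    rng = np.random.default_rng(cfg.rng_seed)
    gt = simulate(cfg, rng)
    stack = render(gt, cfg, rng)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        gt.write(out)
        stack.save(out / "stack.ome.tif")
    return gt, stack


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return (and write) the report.

    Stages run in order simulate → segment → track → waves → nodes →
    [heatmap] → [piv]; each stage writes its intermediates under the
    output directory and is skipped when ``resume`` is set and its outputs
    already exist.  A stage failure raises :class:`PipelineError` naming
    the stage; inputs written so far are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}
    t_start = time.time()

    def timed(stage: str):
        class _T:
            def __enter__(self):
                self.t0 = time.time()
                log.info("stage %s started", stage)
                return self

            def __exit__(self, exc_type, exc, tb):
                report["stages"][stage] = {"seconds": time.time() - self.t0}
                if exc is None:
                    log.info("stage %s finished in %.1f s",
                             stage, time.time() - self.t0)
                return False

        return _T()

    # -- simulate / load -----------------------------------------------
    gt: Optional[GroundTruth] = None
    stack_path = out / "stack.ome.tif"
    with timed("input"):
        try:
            if config.sim is not None:
                if config.resume and stack_path.exists():
                    stack = FrameStack.load(stack_path)
                    gt = _load_ground_truth(out, config.sim)
                else:
                    cfg = config.sim
                    rng = np.random.default_rng(cfg.rng_seed)
                    gt = simulate(cfg, rng)
                    stack = render(gt, cfg, rng)
                    gt.write(out / "truth")
                    stack.save(stack_path)
            elif config.stack_path is not None:
                stack = FrameStack.load(config.stack_path)
            else:
                raise PipelineError("input", "neither a stack nor a sim config given")
        except StackError as exc:
            raise PipelineError("input", str(exc)) from exc
    report["pixel_size_um"] = stack.pixel_size
    report["frame_interval_min"] = stack.frame_interval
    report["n_frames"] = stack.n_frames

    # -- segmentation ---------------------------------------------------
    meas_path = out / "measurements.csv"
    with timed("segment"):
        seg_params = SegParams(**config.segmentation) if config.segmentation else SegParams()
        if config.resume and meas_path.exists():
            measurements = pd.read_csv(meas_path)
            label_maps = None
        else:
            measurements, label_maps = segment_stack(stack, seg_params)
            measurements.to_csv(meas_path, index=False)
            tifffile.imwrite(
                out / "labels.tif",
                np.stack([lm.labels.astype(np.uint16) for lm in label_maps]),
                photometric="minisblack",
            )

    # -- tracking + events ---------------------------------------------
    with timed("track"):
        tracks = link_tracks(measurements, **config.tracking)
        tracks.to_csv(out / "tracks.csv", index=False)
        events = detect_apoptosis_events(stack)
        events_to_frame(events).to_csv(out / "events.csv", index=False)
    report["n_tracks"] = int(tracks["track_id"].nunique()) if len(tracks) else 0
    report["n_events"] = len(events)

    # -- wave kinematics -------------------------------------------------
    with timed("waves"):
        wave_summaries = []
        for ev in events:
            try:
                with_d, _excluded = compute_dnuc(tracks, ev)
                with_mov = compute_mov(with_d)
                summary = estimate_wave(
                    with_mov, ev, frame_interval=stack.frame_interval,
                    **config.waves,
                )
            except ValueError as exc:
                log.warning("event %d skipped: %s", ev.event_id, exc)
                continue
            wave_summaries.append(summary)
            kymo = build_kymograph(with_mov, ev)
            for key in ("cn_ratio", "mov", "dmov"):
                if key in kymo:
                    pd.DataFrame(kymo[key], index=kymo["track_ids"],
                                 columns=kymo["frames"]).to_csv(
                        out / f"kymograph_event{ev.event_id}_{key}.csv")
            summary.bins.to_csv(out / f"wave_bins_event{ev.event_id}.csv",
                                index=False)
        report["waves"] = [s.to_dict() for s in wave_summaries]
        (out / "wave_summary.json").write_text(
            json.dumps(report["waves"], indent=2, default=_jsonable))

    # -- nodes / compartments -------------------------------------------
    with timed("nodes"):
        frame0 = measurements[measurements["frame"] == 0]
        node_section: dict = {"n_nodes": 0}
        if len(frame0) >= 2:
            centroids = frame0[["x_um", "y_um"]].to_numpy()
            field_size = (stack.shape_px[1] * stack.pixel_size,
                          stack.shape_px[0] * stack.pixel_size)
            nodes = detect_nodes(centroids, field_size, **config.nodes)
            comp = assign_compartments(frame0, nodes)
            annotated = frame0.copy()
            annotated["compartment"] = comp
            annotated.to_csv(out / "cells_compartments.csv", index=False)
            nodes.table.to_csv(out / "nodes.csv", index=False)
            nn = nearest_nuclei_distances(centroids)
            node_section = {
                "n_nodes": nodes.n_nodes,
                "total_node_area_um2": nodes.total_area_um2,
                "spacing_um": nodes.spacing.tolist(),
                "mean_spacing_um": (float(np.mean(nodes.spacing))
                                    if len(nodes.spacing) else None),
                "n_node_cells": int((comp == "node").sum()),
                "n_nonnode_cells": int((comp == "non-node").sum()),
                "nearest_nuclei_um": {
                    "mean": float(nn.mean()), "median": float(np.median(nn)),
                },
            }
            if events:
                node_section["event_localization"] = localize_events(
                    events_to_frame(events), nodes)
        report["nodes"] = node_section

    # -- cumulative ERK heat map ----------------------------------------
    if config.run_heatmap:
        with timed("heatmap"):
            polys_per_frame = []
            for f in range(stack.n_frames):
                sub = measurements[measurements["frame"] == f]
                _, polys = cluster_erk_active(sub)
                polys_per_frame.append(polys)
            heat = accumulate_heatmap(polys_per_frame, stack.shape_px,
                                      stack.pixel_size)
            tifffile.imwrite(out / "heatmap.tif", heat.astype(np.uint16))
            report["heatmap_max_frames"] = int(heat.max())

    # -- PIV --------------------------------------------------------------
    if config.run_piv and stack.n_frames >= 2:
        with timed("piv"):
            flow = piv_stack(stack, **config.piv)
            flow.to_csv(out / "flow.csv", index=False)
            conv = {}
            for ev in events:
                c = convergence_toward(flow, ev)
                conv[str(ev.event_id)] = c
            report["piv_convergence_um_min"] = conv

    report["total_seconds"] = time.time() - t_start
    (out / "report.json").write_text(json.dumps(report, indent=2,
                                                default=_jsonable))
    return report


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _load_ground_truth(out: Path, cfg: SimConfig) -> Optional[GroundTruth]:
    try:
        truth = out / "truth"
        return GroundTruth(
            cells=pd.read_csv(truth / "cells.csv"),
            events=pd.read_csv(truth / "events.csv"),
            nodes=pd.read_csv(truth / "nodes.csv"),
            config=cfg,
        )
    except FileNotFoundError:
        return None
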