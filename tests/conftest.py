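"""Shared fixtures: small synthetic monolayers exercised by many tests.

Everything is generated at test time from the simulator; sizes are kept
small so the full suite stays fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from erkwave import SimConfig, render, segment_stack, simulate
from erkwave.tracking import ApoptoticEvent


def small_wave_config(seed: int = 3, **overrides) -> SimConfig:
    """A compact single-wave scenario: ~70 cells, one event, noiseless."""
    defaults = dict(
        field_size=(400.0, 400.0),
        n_frames=20,
        n_nodes=0,
        nonnode_density=4.5,
        wave_speed=3.0,
        wave_extent=150.0,
        duration_at_origin=30.0,
        migration_gain=0.4,
        jitter_sd=0.1,
        noise_sd=0.0,
        fixed_events=[(5, 200.0, 200.0)],
        rng_seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def wave_truth():
    """Ground truth of the small single-wave scenario."""
    cfg = small_wave_config()
    return simulate(cfg, np.random.default_rng(cfg.rng_seed)), cfg


@pytest.fixture(scope="session")
def wave_run():
    """The small wave scenario pushed through render → segment → track."""
    from erkwave import link_tracks

    cfg = small_wave_config()
    rng = np.random.default_rng(cfg.rng_seed)
    gt = simulate(cfg, rng)
    stack = render(gt, cfg, rng)
    measurements, _maps = segment_stack(stack)
    tracks = link_tracks(measurements)
    ev = gt.events.iloc[0]
    event = ApoptoticEvent(event_id=0, frame=int(ev["frame"]),
                           x_um=float(ev["x_um"]), y_um=float(ev["y_um"]))
    return {
        "config": cfg,
        "gt": gt,
        "stack": stack,
        "measurements": measurements,
        "tracks": tracks,
        "event": event,
    }


@pytest.fixture(scope="session")
def patterned_truth():
    """Ground truth of a 2000×2000 µm node-patterned monolayer (no render)."""
    cfg = SimConfig(field_size=(2000.0, 2000.0), n_frames=1, rng_seed=7)
    return simulate(cfg, np.random.default_rng(cfg.rng_seed)), cfg
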