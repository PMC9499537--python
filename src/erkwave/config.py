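"""Configuration objects for the simulator and the analysis pipeline.

All lengths are in micrometres (µm), times in minutes, densities in cells
per 100×100 µm patch, intensities in arbitrary fluorescence units.  The
project-wide coordinate convention is: images are indexed (row, col),
0-based; x = col × pixel_size, y = row × pixel_size with the origin at the
top-left pixel centre; time = frame × frame_interval with frame 0-based.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value violates its contract."""


@dataclass
class SimConfig:
    """Parameters of the synthetic organoid-monolayer simulation.

    The defaults describe a confluent human colonic organoid monolayer with
    crypt-like "node" compartments of densely packed cells, sparse
    differentiated non-node regions, and apoptosis-triggered ERK trigger
    waves propagating radially at constant speed from each dying cell.

    Parameters
    ----------
    field_size : (width, height) of the simulated field, µm.
    pixel_size : rendered pixel size, µm/px.
    frame_interval : time between rendered frames, min.
    n_frames : number of frames simulated.
    node_spacing_mean : target mean nearest-neighbour distance between node
        centres, µm.
    node_radius : radius of each node disk, µm.
    n_nodes : number of nodes; ``None`` fills the field on a jittered grid
        at ``node_spacing_mean``, ``0`` requests a uniform (node-free) field.
    node_jitter_um : s.d. of the Gaussian jitter applied to grid node
        centres, µm.
    node_density, nonnode_density : cells per 100×100 µm patch inside and
        outside node disks.
    nucleus_radius : nuclear radius, µm.
    cyto_radius : outer radius of the rendered cytoplasmic KTR territory, µm.
    apoptosis_rate : expected apoptotic events per frame (Poisson).
    p_nonnode : probability that an apoptotic event strikes a non-node cell.
    wave_speed : radial ERK front speed v, µm/min.
    wave_extent : maximal radius R_max reached by a wave, µm.
    duration_at_origin : ERK pulse duration D0 at the wave origin, min.
    amplitude_at_origin : ERK activity amplitude A0 at the origin, in (0, 1].
    duration_decay_exp, amplitude_decay_exp : taper exponents; duration and
        amplitude fall as ``(1 - d / R_max) ** exp``.
    recoil_radius : radius around the dying cell whose occupants recoil, µm.
    recoil_distance : outward displacement of recoiling cells, µm.  The
        magnitude of this initial recoil is not quantified anywhere; the
        2 µm default is a visual-scale guess.
    migration_gain : drift speed toward the wave source per unit ERK
        activity, µm/min.
    jitter_sd : s.d. of per-frame isotropic positional jitter, µm.
    ktr_partition : fold-change g of the true cytoplasmic/nuclear KTR ratio
        between ERK-inactive (E=0) and fully active (E=1) cells.
    global_activity : if set, overrides every cell's ERK activity with this
        constant (used by the pharmacological presets).
    noise_sd : s.d. of Gaussian intensity noise added to rendered channels.
    h2b_amp, ktr_base, casp_amp, background : rendered intensity levels.
    fixed_events : optional explicit apoptosis schedule, a sequence of
        ``(frame, x_um, y_um)``; overrides ``apoptosis_rate``.
    max_render_bytes : refuse to render stacks larger than this.
    rng_seed : seed for the single generator threaded through all
        stochastic steps.
    """

    field_size: tuple[float, float] = (1000.0, 1000.0)
    pixel_size: float = 1.3
    frame_interval: float = 5.0
    n_frames: int = 30
    node_spacing_mean: float = 399.0
    node_radius: float = 70.0
    n_nodes: Optional[int] = None
    node_jitter_um: float = 12.0
    node_density: float = 24.0
    nonnode_density: float = 3.0
    nucleus_radius: float = 4.0
    cyto_radius: float = 9.0
    apoptosis_rate: float = 0.0
    p_nonnode: float = 0.8
    wave_speed: float = 4.7
    wave_extent: float = 450.0
    duration_at_origin: float = 40.0
    amplitude_at_origin: float = 1.0
    duration_decay_exp: float = 0.5
    amplitude_decay_exp: float = 0.5
    recoil_radius: float = 20.0
    recoil_distance: float = 2.0
    migration_gain: float = 0.5
    jitter_sd: float = 0.3
    ktr_partition: float = 2.0
    global_activity: Optional[float] = None
    noise_sd: float = 2.0
    h2b_amp: float = 300.0
    ktr_base: float = 100.0
    casp_amp: float = 600.0
    background: float = 0.0
    fixed_events: Optional[list[tuple[int, float, float]]] = None
    max_render_bytes: int = 2 * 1024**3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.field_size
        positive = {
            "field width": w,
            "field height": h,
            "pixel_size": self.pixel_size,
            "frame_interval": self.frame_interval,
            "n_frames": self.n_frames,
            "node_spacing_mean": self.node_spacing_mean,
            "node_radius": self.node_radius,
            "node_density": self.node_density,
            "nucleus_radius": self.nucleus_radius,
            "cyto_radius": self.cyto_radius,
            "wave_speed": self.wave_speed,
            "wave_extent": self.wave_extent,
            "duration_at_origin": self.duration_at_origin,
            "ktr_partition": self.ktr_partition,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ConfigError(f"{name} must be strictly positive, got {value!r}")
        for name, value in {
            "nonnode_density": self.nonnode_density,
            "apoptosis_rate": self.apoptosis_rate,
            "migration_gain": self.migration_gain,
            "jitter_sd": self.jitter_sd,
            "noise_sd": self.noise_sd,
            "recoil_distance": self.recoil_distance,
            "recoil_radius": self.recoil_radius,
        }.items():
            if value < 0:
                raise ConfigError(f"{name} must be non-negative, got {value!r}")
        if not 0.0 <= self.p_nonnode <= 1.0:
            raise ConfigError(f"p_nonnode must be in [0, 1], got {self.p_nonnode!r}")
        if not 0.0 < self.amplitude_at_origin <= 1.0:
            raise ConfigError(
                f"amplitude_at_origin must be in (0, 1], got {self.amplitude_at_origin!r}"
            )
        if self.wave_extent < self.wave_speed * self.frame_interval:
            raise ConfigError(
                "wave_extent must be at least wave_speed * frame_interval "
                "so the wave is observable for at least one frame"
            )
        if self.fixed_events is not None:
            self.fixed_events = [
                (int(f), float(x), float(y)) for f, x, y in self.fixed_events
            ]

    # -- serialisation --------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["field_size"] = list(self.field_size)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown SimConfig keys: {sorted(unknown)}")
        d = dict(d)
        if "field_size" in d:
            d["field_size"] = tuple(d["field_size"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration: paths, seed, per-stage parameters.

    Every parameter has a default, so an empty mapping is a valid config.
    Unknown keys at either level are rejected by name.
    """

    out_dir: str = "erkwave_out"
    stack_path: Optional[str] = None
    sim: Optional[SimConfig] = None
    seed: int = 0
    segmentation: dict[str, Any] = field(default_factory=dict)
    tracking: dict[str, Any] = field(default_factory=dict)
    waves: dict[str, Any] = field(default_factory=dict)
    nodes: dict[str, Any] = field(default_factory=dict)
    piv: dict[str, Any] = field(default_factory=dict)
    run_piv: bool = True
    run_heatmap: bool = False
    resume: bool = True

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict() if self.sim is not None else None
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        d = dict(d)
        if d.get("sim") is not None:
            d["sim"] = SimConfig.from_dict(d["sim"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
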