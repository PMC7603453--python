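"""Run configuration: a YAML-serializable bundle of every knob a pipeline
stage needs, with lossless round-tripping so a logged config reproduces
its run exactly."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

from .detectability import DetectabilityConfig
from .geometry import CArmGeometry
from .phantom import PhantomConfig, ScrewSpec

__all__ = ["RunConfig", "load_config", "save_config"]


def _to_plain(obj):
    """Recursively convert numpy scalars/tuples for YAML."""
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass
class RunConfig:
    """Everything a pipeline run needs, with reproducible defaults."""

    seed: int = 0
    # phantom
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    canonical: bool = True  # zero-width randomization bounds
    # geometry & physics
    geometry: CArmGeometry = field(default_factory=CArmGeometry)
    spectrum_preset: str = "poly5"
    photons_per_pixel: float = 1.0e5
    noise_photons_per_pixel: float | None = None  # None = noise-free
    # view grid for maps / datasets
    grid_phi_step_deg: float = 5.0
    grid_theta_min_deg: float = 45.0
    grid_theta_max_deg: float = 135.0
    # detectability
    detectability: DetectabilityConfig = field(default_factory=DetectabilityConfig)
    # planner
    lam: float = 0.6
    delta_phi_deg: float = 5.0
    planner_oracle: str = "cumulative"  # or "per-view"
    n_views: int = 40
    start_phi_deg: float = 0.0
    start_theta_deg: float = 90.0
    # reconstruction
    recon_shape: tuple[int, int, int] = (72, 72, 72)
    recon_spacing_mm: float = 1.3333333333333333
    recon_iterations: int = 30
    recon_detector_rows: int = 80
    recon_detector_cols: int = 104
    recon_pixel_pitch_mm: float = 1.86
    # surrogate
    train_seeds: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6, 7)
    test_seeds: tuple[int, ...] = (100, 101, 102, 103, 104)
    input_phi_step_deg: float = 10.0
    epochs: int = 300

    def to_dict(self) -> dict:
        return _to_plain(asdict(self))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "phantom" in data and isinstance(data["phantom"], dict):
            ph = dict(data["phantom"])
            if "screw" in ph and isinstance(ph["screw"], dict):
                ph["screw"] = ScrewSpec(**{
                    k: tuple(v) if isinstance(v, list) else v for k, v in ph["screw"].items()
                })
            for key in ("shape", "voxel_spacing_mm", "box_size_mm"):
                if key in ph and isinstance(ph[key], list):
                    ph[key] = tuple(ph[key])
            if "cylinder_centers_mm" in ph:
                ph["cylinder_centers_mm"] = tuple(tuple(c) for c in ph["cylinder_centers_mm"])
            data["phantom"] = PhantomConfig(**ph)
        if "geometry" in data and isinstance(data["geometry"], dict):
            geo = dict(data["geometry"])
            if "isocenter_offset_mm" in geo and isinstance(geo["isocenter_offset_mm"], list):
                geo["isocenter_offset_mm"] = tuple(geo["isocenter_offset_mm"])
            data["geometry"] = CArmGeometry(**geo)
        if "detectability" in data and isinstance(data["detectability"], dict):
            det = dict(data["detectability"])
            if isinstance(det.get("task_voxel"), list):
                det["task_voxel"] = tuple(det["task_voxel"])
            data["detectability"] = DetectabilityConfig(**det)
        for key in ("recon_shape", "train_seeds", "test_seeds"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @property
    def recon_geometry(self) -> CArmGeometry:
        """Reduced detector used for reconstruction experiments."""
        from dataclasses import replace

        return replace(
            self.geometry,
            detector_rows=self.recon_detector_rows,
            detector_cols=self.recon_detector_cols,
            pixel_pitch_mm=self.recon_pixel_pitch_mm,
        )


def save_config(path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))
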