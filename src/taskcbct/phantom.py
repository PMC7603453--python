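"""Procedural screw phantom and material attenuation lookup.

The canonical scene mirrors a semianthropomorphic bench phantom: a long
wooden box with two parallel titanium screws drilled through it and two
ballistic-gel cylinders standing in for soft tissue.  Object positions and
screw orientations can be randomized within configurable bounds to emulate
patient-to-patient variation; generation is a pure function of
(seed, config).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict

import numpy as np

__all__ = [
    "MATERIALS",
    "MATERIAL_NAMES",
    "ScrewSpec",
    "MaterialPhantom",
    "PhantomConfig",
    "make_screw",
    "make_phantom",
    "canonical_phantom",
    "attenuation",
    "save_phantom",
    "load_phantom",
]

MATERIALS = {"air": 0, "gel": 1, "wood": 2, "titanium": 3}
MATERIAL_NAMES = {v: k for k, v in MATERIALS.items()}

# Linear attenuation tables, mm^-1, on a 20-150 keV energy grid.
# Gel is water-equivalent (mass attenuation times unit density); wood is a
# low-density cellulose-like solid; titanium uses elemental Ti at
# 4.506 g/cm^3.  Air is treated as a vacuum surrogate (negligible mu).
_ENERGIES_KEV = np.array([20.0, 30.0, 40.0, 50.0, 60.0, 80.0, 100.0, 150.0])
_MU_TABLE_PER_MM = {
    "air": np.array([3.0e-13, 2.5e-13, 2.2e-13, 2.0e-13, 1.8e-13, 1.6e-13, 1.4e-13, 1.2e-13]),
    "gel": np.array([0.08096, 0.03756, 0.02683, 0.02269, 0.02059, 0.01837, 0.01707, 0.01505]),
    "wood": np.array([0.04700, 0.02250, 0.01640, 0.01400, 0.01280, 0.01150, 0.01070, 0.00945]),
    "titanium": np.array([7.1430, 2.2404, 0.9976, 0.5466, 0.3452, 0.1826, 0.1226, 0.0743]),
}


def attenuation(material: str | int, energy_keV) -> float | np.ndarray:
    """Linear attenuation coefficient in mm^-1, log-log interpolated.

    ``material`` is a name or integer label; ``energy_keV`` may be a scalar
    or array within the tabulated 20-150 keV range.
    """
    if isinstance(material, (int, np.integer)):
        material = MATERIAL_NAMES.get(int(material))
    if material not in _MU_TABLE_PER_MM:
        raise ValueError(f"unknown material: {material!r}")
    energy = np.asarray(energy_keV, dtype=float)
    if np.any(energy < _ENERGIES_KEV[0]) or np.any(energy > _ENERGIES_KEV[-1]):
        raise ValueError("energy outside the tabulated 20-150 keV range")
    mu = np.exp(
        np.interp(np.log(energy), np.log(_ENERGIES_KEV), np.log(_MU_TABLE_PER_MM[material]))
    )
    return float(mu) if np.isscalar(energy_keV) else mu


@dataclass(frozen=True)
class ScrewSpec:
    """Geometry of one titanium screw.

    The thread is a single-start helical ridge: the local radius grows by
    ``thread_depth_mm`` wherever the helical phase condition holds, so
    axial profiles along the screw surface carry a genuine 1/pitch spatial
    frequency.
    """

    length_mm: float = 40.0
    shaft_radius_mm: float = 2.5
    thread_pitch_mm: float = 3.0
    thread_depth_mm: float = 0.75
    head_radius_mm: float = 4.0
    tip_position_mm: tuple[float, float, float] = (0.0, -20.0, 0.0)
    axis: tuple[float, float, float] = (0.0, 1.0, 0.0)

    def __post_init__(self):
        for name in ("length_mm", "shaft_radius_mm", "thread_pitch_mm", "head_radius_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.thread_depth_mm < 0 or self.thread_depth_mm >= self.shaft_radius_mm:
            raise ValueError("thread_depth must be in [0, shaft_radius)")
        ax = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(ax)
        if n < 1e-12:
            raise ValueError("axis must be nonzero")
        object.__setattr__(self, "axis", tuple(ax / n))
        object.__setattr__(self, "tip_position_mm", tuple(float(x) for x in self.tip_position_mm))


@dataclass
class MaterialPhantom:
    """Labeled voxel grid (air/gel/wood/titanium) with world placement.

    ``origin_mm`` is the world coordinate of the center of voxel (0,0,0);
    axes are ordered (x, y, z).
    """

    labels: np.ndarray
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    screws: tuple[ScrewSpec, ...] = ()

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D grid")
        if not set(np.unique(self.labels)) <= set(MATERIALS.values()):
            raise ValueError("labels outside the material set")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def voxel_center(self, index) -> np.ndarray:
        return np.asarray(self.origin_mm) + np.asarray(index) * np.asarray(self.voxel_spacing_mm)

    def world_to_voxel(self, point_mm) -> np.ndarray:
        return (np.asarray(point_mm) - np.asarray(self.origin_mm)) / np.asarray(self.voxel_spacing_mm)

    def attenuation_volume(self, energy_keV: float = 60.0) -> np.ndarray:
        """Monoenergetic mu volume (mm^-1) for registration / ground truth."""
        mu = np.array([attenuation(m, energy_keV) for m in range(len(MATERIALS))])
        return mu[self.labels].astype(np.float32)

    def material_counts(self) -> dict[str, int]:
        return {
            name: int(np.count_nonzero(self.labels == label))
            for name, label in MATERIALS.items()
        }


def _screw_frame(spec: ScrewSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    w = np.asarray(spec.axis)
    helper = np.array([0.0, 0.0, 1.0]) if abs(w[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(helper, w)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return u, v, w


def make_screw(
    spec: ScrewSpec,
    shape: tuple[int, int, int],
    voxel_spacing_mm=(1.0, 1.0, 1.0),
    origin_mm=(0.0, 0.0, 0.0),
) -> np.ndarray:
    """Rasterize one screw into a boolean voxel mask.

    Voxels are titanium where the distance to the axis is within the local
    radius r(z, angle); the helical ridge adds ``thread_depth`` where
    |wrap(angle - 2*pi*z/pitch)| < pi/2.  A spherical head caps the far end.
    Raises if the screw does not fit inside the grid.
    """
    spacing = np.asarray(voxel_spacing_mm, dtype=float)
    origin = np.asarray(origin_mm, dtype=float)
    tip = np.asarray(spec.tip_position_mm)
    u, v, w = _screw_frame(spec)
    r_max = spec.shaft_radius_mm + spec.thread_depth_mm
    reach = max(r_max, spec.head_radius_mm)
    # bounding check: both end disks plus head must be inside the grid
    hi_world = origin + (np.asarray(shape) - 1) * spacing
    for z in (0.0, spec.length_mm):
        center = tip + z * w
        if np.any(center - reach < origin - spacing / 2) or np.any(
            center + reach > hi_world + spacing / 2
        ):
            raise ValueError("screw exceeds the phantom grid")

    # restrict rasterization to the screw's bounding box
    corners = [tip + z * w + s1 * reach * u + s2 * reach * v
               for z in (-spec.head_radius_mm, spec.length_mm + spec.head_radius_mm)
               for s1 in (-1, 1) for s2 in (-1, 1)]
    corners = np.array(corners)
    lo = np.maximum(np.floor((corners.min(axis=0) - origin) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((corners.max(axis=0) - origin) / spacing).astype(int) + 1,
                    np.asarray(shape))
    idx = np.meshgrid(*[np.arange(lo[k], hi[k]) for k in range(3)], indexing="ij")
    pts = origin + np.stack(idx, axis=-1) * spacing - tip
    z = pts @ w
    pu, pv = pts @ u, pts @ v
    r = np.hypot(pu, pv)
    angle = np.arctan2(pv, pu)
    phase = np.mod(angle - 2 * np.pi * z / spec.thread_pitch_mm + np.pi, 2 * np.pi) - np.pi
    local_r = spec.shaft_radius_mm + spec.thread_depth_mm * (np.abs(phase) < np.pi / 2)
    shaft = (z >= 0) & (z <= spec.length_mm) & (r <= local_r)
    head_center_z = spec.length_mm
    head = (pu**2 + pv**2 + (z - head_center_z) ** 2) <= spec.head_radius_mm**2
    mask = np.zeros(shape, dtype=bool)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = shaft | head
    return mask


@dataclass(frozen=True)
class PhantomConfig:
    """Scene layout and randomization bounds for :func:`make_phantom`."""

    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    # the rod runs along the rotation axis (z), like a patient's long axis:
    # out-of-plane tilting lengthens the path through it, so tilt carries a
    # cost unless it buys metal avoidance
    # square x-z cross-section: a 45-degree out-of-plane diagonal is longer
    # than any axis-aligned crossing, so extreme tilt costs path length
    box_size_mm: tuple[float, float, float] = (80.0, 40.0, 80.0)
    cylinder_radius_mm: float = 10.0
    cylinder_height_mm: float = 60.0
    cylinder_centers_mm: tuple = ((0.0, -34.0, 0.0), (0.0, 34.0, 0.0))
    screw_separation_mm: float = 12.0
    # screws sit at different heights (drilled at different levels), so the
    # in-plane view orthogonal to their axes crosses only one of them
    screw_z_offsets_mm: tuple[float, float] = (-8.0, 8.0)
    screw: ScrewSpec = field(default_factory=ScrewSpec)
    translation_bound_mm: float = 15.0
    screw_tilt_bound_deg: float = 20.0
    max_retries: int = 50

    @property
    def origin_mm(self) -> tuple[float, float, float]:
        return tuple(-(n - 1) / 2.0 * s for n, s in zip(self.shape, self.voxel_spacing_mm))


def _tilt_axis(axis: np.ndarray, tilt_a_deg: float, tilt_b_deg: float) -> np.ndarray:
    """Tilt a unit axis by two small rotations about perpendicular directions."""
    u = np.cross(np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([1.0, 0.0, 0.0]), axis)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    a, b = np.deg2rad(tilt_a_deg), np.deg2rad(tilt_b_deg)
    out = axis + np.tan(a) * u + np.tan(b) * v
    return out / np.linalg.norm(out)


def make_phantom(seed: int = 0, config: PhantomConfig | None = None) -> MaterialPhantom:
    """Generate the canonical two-screw scene with randomized placement.

    Deterministic for a fixed (seed, config).  Zero-width bounds
    (translation_bound_mm = 0, screw_tilt_bound_deg = 0) yield the
    documented canonical layout: wood box along x, two parallel screws
    along y separated in x, two gel cylinders along z on either side.
    Raises if the screws cannot be placed without intersecting after
    ``max_retries`` attempts.
    """
    cfg = config or PhantomConfig()
    rng = np.random.default_rng(seed)
    spacing = np.asarray(cfg.voxel_spacing_mm)
    origin = np.asarray(cfg.origin_mm)
    shape = cfg.shape
    idx = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    coords = origin + np.stack(idx, axis=-1) * spacing  # (nx,ny,nz,3) world mm

    labels = np.zeros(shape, dtype=np.uint8)

    def rand_shift():
        return rng.uniform(-cfg.translation_bound_mm, cfg.translation_bound_mm, size=3)

    # wood box
    box_c = rand_shift()
    half = np.asarray(cfg.box_size_mm) / 2.0
    box = np.all(np.abs(coords - box_c) <= half, axis=-1)
    labels[box] = MATERIALS["wood"]

    # gel cylinders (axis z)
    for center in cfg.cylinder_centers_mm:
        c = np.asarray(center) + rand_shift()
        d2 = (coords[..., 0] - c[0]) ** 2 + (coords[..., 1] - c[1]) ** 2
        cyl = (d2 <= cfg.cylinder_radius_mm**2) & (
            np.abs(coords[..., 2] - c[2]) <= cfg.cylinder_height_mm / 2.0
        )
        labels[cyl] = MATERIALS["gel"]

    # two screws, re-drawn until non-intersecting
    base_axis = np.asarray(ScrewSpec().axis)
    screws, masks = [], []
    for k, x_off in enumerate((-cfg.screw_separation_mm / 2, cfg.screw_separation_mm / 2)):
        base_tip = np.array(
            [x_off, -cfg.screw.length_mm / 2.0, cfg.screw_z_offsets_mm[k]]
        )
        placed = False
        for _ in range(cfg.max_retries):
            axis = _tilt_axis(
                base_axis,
                rng.uniform(-cfg.screw_tilt_bound_deg, cfg.screw_tilt_bound_deg),
                rng.uniform(-cfg.screw_tilt_bound_deg, cfg.screw_tilt_bound_deg),
            )
            tip = base_tip + rand_shift()
            spec = replace(cfg.screw, tip_position_mm=tuple(tip), axis=tuple(axis))
            try:
                mask = make_screw(spec, shape, spacing, origin)
            except ValueError:
                continue
            if k == 1 and np.any(mask & masks[0]):
                continue
            screws.append(spec)
            masks.append(mask)
            placed = True
            break
        if not placed:
            raise ValueError("could not place screws without overlap within bounds")
    for mask in masks:
        labels[mask] = MATERIALS["titanium"]

    return MaterialPhantom(
        labels=labels,
        voxel_spacing_mm=tuple(spacing),
        origin_mm=tuple(origin),
        screws=tuple(screws),
    )


def canonical_phantom(config: PhantomConfig | None = None) -> MaterialPhantom:
    """The deterministic reference layout (zero-width randomization bounds)."""
    cfg = config or PhantomConfig()
    cfg = replace(cfg, translation_bound_mm=0.0, screw_tilt_bound_deg=0.0)
    return make_phantom(seed=0, config=cfg)


def save_phantom(path, phantom: MaterialPhantom) -> None:
    """Write labels as NIfTI plus a JSON sidecar with materials and screws."""
    import nibabel as nib

    affine = np.diag([*phantom.voxel_spacing_mm, 1.0])
    affine[:3, 3] = phantom.origin_mm
    nib.save(nib.Nifti1Image(phantom.labels.astype(np.uint8), affine), str(path))
    sidecar = {
        "materials": MATERIALS,
        "voxel_spacing_mm": list(phantom.voxel_spacing_mm),
        "origin_mm": list(phantom.origin_mm),
        "screws": [asdict(s) for s in phantom.screws],
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_phantom(path) -> MaterialPhantom:
    import nibabel as nib

    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.uint8)
    with open(str(path) + ".json") as fh:
        sidecar = json.load(fh)
    screws = tuple(
        ScrewSpec(**{k: tuple(v) if isinstance(v, list) else v for k, v in s.items()})
        for s in sidecar["screws"]
    )
    return MaterialPhantom(
        labels=labels,
        voxel_spacing_mm=tuple(sidecar["voxel_spacing_mm"]),
        origin_mm=tuple(sidecar["origin_mm"]),
        screws=screws,
    )
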