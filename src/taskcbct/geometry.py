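"""C-arm pose parameterization and projection geometry.

A view is addressed by an in-plane angle ``phi`` (rotation along the
conventional circular orbit) and an out-of-plane angle ``theta`` (tilt of
the source--detector axis out of that plane).  ``theta`` is the polar angle
measured from the fixed C-arm rotation axis (world +z), so ``theta = 90``
reproduces the standard circular orbit.  Angles are degrees, world units
are millimetres, detector pixels are 0-based with the pixel-center
convention throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ViewPose",
    "CArmGeometry",
    "ProjectionMatrix",
    "RigidTransform",
    "grid_views",
    "pose_to_matrix",
    "apply_registration",
    "tilted_orbit_views",
    "angular_stats",
    "save_matrices",
    "load_matrices",
]

_RIGID_TOL = 1e-8


@dataclass(frozen=True)
class ViewPose:
    """One source position on the view sphere.

    ``phi_deg`` is canonicalized to [0, 360); ``theta_deg`` must lie in
    [0, 180] with 90 denoting the untilted circular-orbit plane.  ``t`` is
    an optional acquisition index.
    """

    phi_deg: float
    theta_deg: float
    t: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "phi_deg", float(self.phi_deg) % 360.0)
        object.__setattr__(self, "theta_deg", float(self.theta_deg))
        if not 0.0 <= self.theta_deg <= 180.0:
            raise ValueError(f"theta_deg={self.theta_deg} outside [0, 180]")


@dataclass(frozen=True)
class CArmGeometry:
    """Cone-beam acquisition geometry (distances in mm).

    The default detector is the desk-scale one: 120x155 pixels at 1.24 mm
    pitch, i.e. the full-size 480x620 flat panel at 0.31 mm pitch binned
    4x4, preserving the field of view.
    """

    source_to_isocenter_mm: float = 500.0
    source_to_detector_mm: float = 1000.0
    detector_rows: int = 120
    detector_cols: int = 155
    pixel_pitch_mm: float = 1.24
    isocenter_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if not self.source_to_detector_mm > self.source_to_isocenter_mm > 0:
            raise ValueError("require source_to_detector > source_to_isocenter > 0")
        if self.detector_rows <= 0 or self.detector_cols <= 0:
            raise ValueError("detector dimensions must be positive")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel pitch must be positive")

    @classmethod
    def full_size(cls, **kw) -> "CArmGeometry":
        """Full flat-panel geometry: 480x620 pixels at 0.31 mm pitch."""
        return cls(detector_rows=480, detector_cols=620, pixel_pitch_mm=0.31, **kw)

    def scaled_detector(self, factor: int) -> "CArmGeometry":
        """Bin the detector ``factor`` x ``factor``, preserving field of view."""
        return replace(
            self,
            detector_rows=self.detector_rows // factor,
            detector_cols=self.detector_cols // factor,
            pixel_pitch_mm=self.pixel_pitch_mm * factor,
        )

    @property
    def magnification(self) -> float:
        return self.source_to_detector_mm / self.source_to_isocenter_mm

    @property
    def principal_point(self) -> tuple[float, float]:
        """(u, v) = (col, row) of the detector center, 0-based pixel centers."""
        return ((self.detector_cols - 1) / 2.0, (self.detector_rows - 1) / 2.0)

    def source_position(self, pose: ViewPose) -> np.ndarray:
        """World position of the X-ray source for ``pose``."""
        phi = np.deg2rad(pose.phi_deg)
        theta = np.deg2rad(pose.theta_deg)
        direction = np.array(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
        )
        return np.asarray(self.isocenter_offset_mm) + self.source_to_isocenter_mm * direction


@dataclass(frozen=True)
class ProjectionMatrix:
    """Homogeneous 3x4 map from world mm to detector pixels (u=col, v=row)."""

    entries: np.ndarray

    def __post_init__(self):
        entries = np.asarray(self.entries, dtype=float)
        if entries.shape != (3, 4):
            raise ValueError("projection matrix must be 3x4")
        if np.linalg.matrix_rank(entries) != 3:
            raise ValueError("projection matrix must have rank 3")
        object.__setattr__(self, "entries", entries)

    def project(self, points_mm: np.ndarray) -> np.ndarray:
        """Project world points, shape (..., 3), to pixel coords (..., 2)."""
        pts = np.asarray(points_mm, dtype=float)
        scalar = pts.ndim == 1
        pts = np.atleast_2d(pts)
        hom = np.concatenate([pts, np.ones((*pts.shape[:-1], 1))], axis=-1)
        proj = hom @ self.entries.T
        pix = proj[..., :2] / proj[..., 2:3]
        return pix[0] if scalar else pix


@dataclass(frozen=True)
class RigidTransform:
    """Rigid world transform x -> R x + t (rotation 3x3, translation mm)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        rot = np.asarray(self.rotation, dtype=float)
        tra = np.asarray(self.translation, dtype=float).reshape(3)
        if rot.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if np.linalg.norm(rot @ rot.T - np.eye(3)) > 1e-6 or np.linalg.det(rot) < 0:
            raise ValueError("rotation must be orthonormal with det +1")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tra)

    @classmethod
    def from_euler_deg(
        cls, rx: float = 0.0, ry: float = 0.0, rz: float = 0.0,
        translation: Sequence[float] = (0.0, 0.0, 0.0),
    ) -> "RigidTransform":
        """Intrinsic x-y-z Euler rotations in degrees plus a translation."""
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("xyz", [rx, ry, rz], degrees=True).as_matrix()
        return cls(rot, np.asarray(translation, dtype=float))

    def matrix4(self) -> np.ndarray:
        out = np.eye(4)
        out[:3, :3] = self.rotation
        out[:3, 3] = self.translation
        return out

    def inverse(self) -> "RigidTransform":
        rot = self.rotation.T
        return RigidTransform(rot, -rot @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self o other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.asarray(points_mm, dtype=float)
        return pts @ self.rotation.T + self.translation


def grid_views(
    phi_start_deg: float,
    phi_end_deg: float,
    theta_min_deg: float,
    theta_max_deg: float,
    step_deg: float,
    phi_half_open: bool = True,
) -> list[ViewPose]:
    """Uniform (phi, theta) view grid.

    The phi range is half-open when ``phi_half_open`` (full rotations: the
    end angle coincides with the start and is not repeated); the theta range
    is always inclusive.  Grids are generated by integer index arithmetic so
    counts are exact; the step must divide both ranges.
    """
    if step_deg <= 0:
        raise ValueError("step_deg must be positive")
    phi_span = phi_end_deg - phi_start_deg
    theta_span = theta_max_deg - theta_min_deg
    if phi_span <= 0 or theta_span < 0:
        raise ValueError("empty angular range")
    n_phi_f = phi_span / step_deg
    n_theta_f = theta_span / step_deg
    if abs(n_phi_f - round(n_phi_f)) > 1e-9 or abs(n_theta_f - round(n_theta_f)) > 1e-9:
        raise ValueError("step_deg must divide both angular ranges exactly")
    n_phi = int(round(n_phi_f)) + (0 if phi_half_open else 1)
    n_theta = int(round(n_theta_f)) + 1
    poses = []
    for i in range(n_phi):
        for j in range(n_theta):
            poses.append(
                ViewPose(phi_start_deg + i * step_deg, theta_min_deg + j * step_deg)
            )
    return poses


def pose_to_matrix(geom: CArmGeometry, pose: ViewPose) -> ProjectionMatrix:
    """Build the 3x4 world-mm -> detector-pixel matrix for a pose.

    The source sits at spherical position (radius = source-to-isocenter
    distance, azimuth phi, polar theta about the rotation axis); the
    detector is perpendicular to the source--isocenter ray at the
    source-to-detector distance, so the isocenter of an offset-free
    geometry projects to the principal point.
    """
    iso = np.asarray(geom.isocenter_offset_mm, dtype=float)
    src = geom.source_position(pose)
    w = iso - src
    w = w / np.linalg.norm(w)  # ray direction, source -> isocenter
    axis = np.array([0.0, 0.0, 1.0])
    u = np.cross(axis, w)
    nu = np.linalg.norm(u)
    if nu < 1e-12:  # pole: ray parallel to rotation axis
        u = np.array([1.0, 0.0, 0.0])
    else:
        u = u / nu
    v = np.cross(w, u)
    f = geom.source_to_detector_mm / geom.pixel_pitch_mm
    cu, cv = geom.principal_point
    rot = np.stack([u, v, w])  # world -> camera
    k = np.array([[f, 0.0, cu], [0.0, f, cv], [0.0, 0.0, 1.0]])
    ext = np.concatenate([rot, (-rot @ src)[:, None]], axis=1)
    return ProjectionMatrix(k @ ext)


def apply_registration(p_flat: ProjectionMatrix, transform: RigidTransform) -> ProjectionMatrix:
    """Adjust a projection matrix by a rigid alignment transform.

    ``transform`` aligns the moving (tilted) acquisition onto the reference
    frame: it maps moved-frame coordinates to reference coordinates.
    Composing the matrix with the inverse transform yields the matrix that
    projects reference-frame points onto the images of the moved object, so
    multi-orbit projections integrate into one reference volume.
    """
    if not isinstance(transform, RigidTransform):
        raise TypeError("transform must be a RigidTransform")
    return ProjectionMatrix(p_flat.entries @ transform.inverse().matrix4())


def tilted_orbit_views(
    tilt_deg: float, swivel_deg: float, phi_samples: int | Iterable[float]
) -> list[ViewPose]:
    """(phi, theta) curve traced by a tilted/swiveled circular orbit.

    The untilted orbit lies in the equatorial plane (theta = 90).  Tilt
    rotates the orbit plane about the world x-axis, swivel about the world
    y-axis (swivel applied after tilt).  ``phi_samples`` is either a count
    of uniform samples over [0, 360) or an explicit list of orbit angles.
    """
    if abs(tilt_deg) >= 45 or abs(swivel_deg) >= 45:
        raise ValueError("|tilt| and |swivel| must each be < 45 degrees")
    if isinstance(phi_samples, (int, np.integer)):
        angles = np.arange(int(phi_samples)) * (360.0 / int(phi_samples))
    else:
        angles = np.asarray(list(phi_samples), dtype=float)
    t = np.deg2rad(tilt_deg)
    s = np.deg2rad(swivel_deg)
    rx = np.array(
        [[1, 0, 0], [0, np.cos(t), -np.sin(t)], [0, np.sin(t), np.cos(t)]]
    )
    ry = np.array(
        [[np.cos(s), 0, np.sin(s)], [0, 1, 0], [-np.sin(s), 0, np.cos(s)]]
    )
    rot = ry @ rx
    poses = []
    for idx, a in enumerate(angles):
        ar = np.deg2rad(a)
        d = rot @ np.array([np.cos(ar), np.sin(ar), 0.0])
        theta = np.rad2deg(np.arccos(np.clip(d[2], -1.0, 1.0)))
        phi = np.rad2deg(np.arctan2(d[1], d[0])) % 360.0
        poses.append(ViewPose(phi, theta, t=idx))
    return poses


def _pose_arrays(traj) -> tuple[np.ndarray, np.ndarray]:
    poses = getattr(traj, "poses", traj)
    phi = np.array([p.phi_deg for p in poses])
    theta = np.array([p.theta_deg for p in poses])
    return phi, theta


def angular_stats(traj_a, traj_b) -> tuple[float, float]:
    """Mean and population std of |theta_A - theta_B| over matched phi.

    Both trajectories must be sampled at identical phi values (they differ
    only in their out-of-plane component by construction).
    """
    phi_a, theta_a = _pose_arrays(traj_a)
    phi_b, theta_b = _pose_arrays(traj_b)
    if phi_a.shape != phi_b.shape or not np.allclose(phi_a, phi_b, atol=1e-9):
        raise ValueError("trajectories are not sampled at identical phi values")
    d = np.abs(theta_a - theta_b)
    return float(d.mean()), float(d.std())


def save_matrices(path, poses: Sequence[ViewPose], matrices: Sequence[ProjectionMatrix]) -> None:
    """NPZ archive: key ``P`` (n, 3, 4) plus ``phi_deg``/``theta_deg`` arrays."""
    np.savez(
        path,
        P=np.stack([m.entries for m in matrices]),
        phi_deg=np.array([p.phi_deg for p in poses]),
        theta_deg=np.array([p.theta_deg for p in poses]),
    )


def load_matrices(path) -> tuple[list[ViewPose], list[ProjectionMatrix]]:
    with np.load(path) as data:
        poses = [
            ViewPose(phi, theta, t=i)
            for i, (phi, theta) in enumerate(zip(data["phi_deg"], data["theta_deg"]))
        ]
        matrices = [ProjectionMatrix(p) for p in data["P"]]
    return poses, matrices
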