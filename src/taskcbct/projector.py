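"""Polyenergetic cone-beam forward projection (DRR), noise, normalization.

Rays are driven from the 3x4 projection matrix: the source is the camera
center, pixel rays come from the matrix pseudo-inverse, and each ray is
sampled uniformly between its entry and exit points of the volume bounding
box with nearest-voxel material lookup.  Per-material path lengths are
accumulated exactly (their sum equals the ray--grid intersection length),
which is what the polyenergetic Beer--Lambert sum needs:

    I = sum_E S(E) * exp(-sum_m mu_m(E) * l_m)

Noise is Poisson counting noise parameterized by unattenuated photons per
detector pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import CArmGeometry, ProjectionMatrix, ViewPose, pose_to_matrix
from .phantom import MATERIALS, MaterialPhantom, attenuation

__all__ = [
    "Spectrum",
    "ProjectionImage",
    "spectrum_preset",
    "forward_project_poly",
    "forward_project_lineintegral",
    "inject_noise",
    "log_normalize",
    "save_projection_stack",
    "load_projection_stack",
]

COUNT_FLOOR = 0.5  # counts; guards the log against photon starvation


@dataclass(frozen=True)
class Spectrum:
    """Discrete X-ray spectrum: photons per detector pixel (in air) per bin."""

    energies_keV: tuple[float, ...]
    fluence_weights: tuple[float, ...]

    def __post_init__(self):
        e = np.asarray(self.energies_keV, dtype=float)
        w = np.asarray(self.fluence_weights, dtype=float)
        if e.ndim != 1 or e.shape != w.shape or e.size == 0:
            raise ValueError("energies and weights must be matching 1D sequences")
        if np.any(np.diff(e) <= 0) and e.size > 1:
            raise ValueError("energies must be strictly ascending")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive total")
        object.__setattr__(self, "energies_keV", tuple(e))
        object.__setattr__(self, "fluence_weights", tuple(w))

    @property
    def total_fluence(self) -> float:
        return float(np.sum(self.fluence_weights))

    def scaled_to(self, photons_per_pixel: float) -> "Spectrum":
        """Rescale so the unattenuated expectation equals ``photons_per_pixel``."""
        factor = photons_per_pixel / self.total_fluence
        return Spectrum(self.energies_keV, tuple(w * factor for w in self.fluence_weights))


_SPECTRA = {
    # single-bin spectrum: no beam hardening, used for ground-truth scans
    "mono60": ([60.0], [1.0]),
    # minimal hardening spectrum for closed-form two-bin checks
    "poly2": ([40.0, 80.0], [0.5, 0.5]),
    # hardened bremsstrahlung-like preset (config, not a claimed tube model)
    "poly5": ([30.0, 50.0, 70.0, 90.0, 120.0], [0.15, 0.30, 0.30, 0.18, 0.07]),
}


def spectrum_preset(name: str, photons_per_pixel: float = 1.0e5) -> Spectrum:
    """Named spectrum preset scaled to a total unattenuated fluence."""
    if name not in _SPECTRA:
        raise ValueError(f"unknown spectrum preset {name!r}; have {sorted(_SPECTRA)}")
    e, w = _SPECTRA[name]
    return Spectrum(tuple(e), tuple(w)).scaled_to(photons_per_pixel)


@dataclass
class ProjectionImage:
    """Detector image bound to a pose and a 3x4 projection matrix.

    ``kind`` flags whether pixels hold intensity counts or line integrals.
    """

    pixels: np.ndarray
    pose: ViewPose
    matrix: ProjectionMatrix
    total_fluence: float
    kind: str = "intensity"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D detector grid")
        if self.kind not in ("intensity", "line_integral"):
            raise ValueError("kind must be 'intensity' or 'line_integral'")
        if self.kind == "intensity" and np.any(self.pixels < 0):
            raise ValueError("intensity pixels must be non-negative")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")


def pixel_rays(matrix: ProjectionMatrix, rows: int, cols: int, pixel_idx=None):
    """Source position and unit ray directions for detector pixels.

    The source is the camera center of the matrix; directions point from
    the source through each (row, col) pixel center.  ``pixel_idx`` is an
    optional (n, 2) array of (row, col) pairs; default is the full grid in
    C order.  Returns (source (3,), directions (n, 3)).
    """
    p = matrix.entries
    m = p[:, :3]
    m_inv = np.linalg.inv(m)
    src = -m_inv @ p[:, 3]
    if pixel_idx is None:
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        pixel_idx = np.stack([rr.ravel(), cc.ravel()], axis=1)
    pixel_idx = np.asarray(pixel_idx)
    hom = np.stack(
        [pixel_idx[:, 1], pixel_idx[:, 0], np.ones(len(pixel_idx))], axis=1
    ).astype(float)
    dirs = hom @ m_inv.T
    # m @ d = (u, v, 1): unit positive homogeneous depth, so d already points
    # from the source toward the imaged half-space (positive-depth convention
    # of pose_to_matrix, preserved by rigid adjustment)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return src, dirs


def ray_box_intersection(src, dirs, lo, hi):
    """Entry/exit parameters of rays with an axis-aligned box (slab method)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo - src) / dirs
        t2 = (hi - src) / dirs
    tmin = np.where(np.isnan(t1), -np.inf, np.minimum(t1, t2)).max(axis=1)
    tmax = np.where(np.isnan(t2), np.inf, np.maximum(t1, t2)).min(axis=1)
    # rays parallel to a slab outside of it never intersect
    parallel = np.abs(dirs) < 1e-12
    outside = parallel & ((src < lo) | (src > hi))
    tmax = np.where(outside.any(axis=1), -np.inf, tmax)
    tmin = np.maximum(tmin, 0.0)
    return tmin, np.maximum(tmax, tmin)


def _per_material_lengths(
    phantom: MaterialPhantom,
    matrix: ProjectionMatrix,
    rows: int,
    cols: int,
    step_mm: float | None = None,
    pixel_idx=None,
) -> np.ndarray:
    """Per-pixel, per-material intersection lengths, shape (n_pixels, 4)."""
    spacing = np.asarray(phantom.voxel_spacing_mm)
    origin = np.asarray(phantom.origin_mm)
    shape = np.asarray(phantom.shape)
    lo = origin - spacing / 2.0
    hi = origin + (shape - 0.5) * spacing
    if step_mm is None:
        step_mm = 0.5 * float(spacing.min())
    src, dirs = pixel_rays(matrix, rows, cols, pixel_idx)
    if np.all(src > lo) and np.all(src < hi):
        raise ValueError("source lies inside the phantom bounding box")
    tmin, tmax = ray_box_intersection(src, dirs, lo, hi)
    span = tmax - tmin
    n_samples = max(int(np.ceil(span.max() / step_mm)), 1)
    labels_flat = phantom.labels.ravel()
    n_pix = len(dirs)
    lengths = np.zeros((n_pix, len(MATERIALS)), dtype=np.float64)
    chunk = max(1, int(4e6) // n_samples)
    frac = (np.arange(n_samples, dtype=np.float32) + 0.5) / n_samples
    for start in range(0, n_pix, chunk):
        sl = slice(start, min(start + chunk, n_pix))
        t = tmin[sl, None] + span[sl, None] * frac[None, :]  # (c, S)
        pts = src[None, None, :] + t[..., None] * dirs[sl, None, :]
        ijk = np.rint((pts - origin) / spacing).astype(np.int32)
        valid = np.all((ijk >= 0) & (ijk < shape), axis=-1)
        flat = (ijk[..., 0] * shape[1] + ijk[..., 1]) * shape[2] + ijk[..., 2]
        lab = labels_flat[np.where(valid, flat, 0)]
        lab = np.where(valid, lab, 255)
        dt = (span[sl] / n_samples)[:, None]
        for mat in range(len(MATERIALS)):
            lengths[sl, mat] = ((lab == mat) * dt).sum(axis=1)
    return lengths


def forward_project_poly(
    phantom: MaterialPhantom,
    geom: CArmGeometry,
    pose: ViewPose,
    spectrum: Spectrum,
    step_mm: float | None = None,
) -> ProjectionImage:
    """Polyenergetic DRR: intensity counts per detector pixel."""
    matrix = pose_to_matrix(geom, pose)
    lengths = _per_material_lengths(
        phantom, matrix, geom.detector_rows, geom.detector_cols, step_mm
    )
    energies = np.asarray(spectrum.energies_keV)
    weights = np.asarray(spectrum.fluence_weights)
    mu = np.stack(
        [attenuation(m, energies) for m in range(len(MATERIALS))]
    )  # (n_mat, n_E)
    atten = lengths @ mu  # (n_pix, n_E)
    intensity = np.exp(-atten) @ weights
    pixels = intensity.reshape(geom.detector_rows, geom.detector_cols)
    return ProjectionImage(pixels, pose, matrix, spectrum.total_fluence, "intensity")


def forward_project_lineintegral(
    phantom: MaterialPhantom,
    geom: CArmGeometry,
    pose: ViewPose,
    energy_keV: float = 60.0,
    step_mm: float | None = None,
) -> ProjectionImage:
    """Monoenergetic line integrals: mu-weighted total path length per pixel."""
    matrix = pose_to_matrix(geom, pose)
    lengths = _per_material_lengths(
        phantom, matrix, geom.detector_rows, geom.detector_cols, step_mm
    )
    mu = np.array([attenuation(m, energy_keV) for m in range(len(MATERIALS))])
    pixels = (lengths @ mu).reshape(geom.detector_rows, geom.detector_cols)
    return ProjectionImage(pixels, pose, matrix, 1.0, "line_integral")


def inject_noise(img: ProjectionImage, photons_per_pixel: float, seed: int) -> ProjectionImage:
    """Poisson counting noise at a given unattenuated photons-per-pixel level.

    The image is rescaled so that the unattenuated expectation equals
    ``photons_per_pixel`` and every pixel is replaced by a Poisson draw
    with that mean; deterministic for a fixed seed.
    """
    if img.kind != "intensity":
        raise ValueError("noise injection requires an intensity image")
    if photons_per_pixel <= 0:
        raise ValueError("photons_per_pixel must be positive")
    mean = img.pixels * (photons_per_pixel / img.total_fluence)
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(mean).astype(np.float64)
    return ProjectionImage(noisy, img.pose, img.matrix, photons_per_pixel, "intensity")


def log_normalize(img: ProjectionImage, i0: float | None = None) -> ProjectionImage:
    """Convert intensity counts to line integrals: p = ln(I0 / max(I, floor))."""
    if img.kind != "intensity":
        raise ValueError("log_normalize expects an intensity image")
    if np.any(img.pixels < 0):
        raise ValueError("negative counts")
    i0 = img.total_fluence if i0 is None else float(i0)
    if i0 <= 0:
        raise ValueError("I0 must be positive")
    p = np.log(i0 / np.maximum(img.pixels, COUNT_FLOOR))
    return ProjectionImage(p, img.pose, img.matrix, i0, "line_integral")


def save_projection_stack(path, images: list[ProjectionImage]) -> None:
    """NPZ stack: ``pixels`` (n, rows, cols), ``phi_deg``, ``theta_deg``, ``P``."""
    np.savez(
        path,
        pixels=np.stack([im.pixels for im in images]),
        phi_deg=np.array([im.pose.phi_deg for im in images]),
        theta_deg=np.array([im.pose.theta_deg for im in images]),
        P=np.stack([im.matrix.entries for im in images]),
        total_fluence=np.array([im.total_fluence for im in images]),
        kind=np.array([im.kind for im in images]),
    )


def load_projection_stack(path) -> list[ProjectionImage]:
    with np.load(path) as d:
        return [
            ProjectionImage(
                d["pixels"][i],
                ViewPose(d["phi_deg"][i], d["theta_deg"][i], t=i),
                ProjectionMatrix(d["P"][i]),
                float(d["total_fluence"][i]),
                str(d["kind"][i]),
            )
            for i in range(len(d["pixels"]))
        ]


def export_tiff(path, images: list[ProjectionImage]) -> None:
    """Multi-page TIFF export for visual inspection."""
    import tifffile

    tifffile.imwrite(path, np.stack([im.pixels.astype(np.float32) for im in images]))
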