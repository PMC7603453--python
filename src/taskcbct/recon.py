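"""Iterative cone-beam reconstruction and multi-orbit fusion.

The tomographic system A x = p is solved by conjugate-gradient least
squares (CGLS) with a matched forward/backprojector pair: the forward
operator samples the volume along each pixel ray at a fixed step with
trilinear-free nearest-voxel gathers, and the backprojector is its exact
adjoint (scatter with the same indices and weights).  Adjoint consistency
is what guarantees the monotone residual decrease of CGLS.

Truncated projections are handled by masking detector pixels whose rays
leave the reconstructed field of view (forward projection of a centered
sphere), and multiple orbits acquired in different frames are fused by
adjusting their projection matrices with the rigid transform recovered by
normalized cross-correlation registration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize

from .geometry import CArmGeometry, ProjectionMatrix, RigidTransform, ViewPose, pose_to_matrix
from .projector import ProjectionImage, pixel_rays, ray_box_intersection

__all__ = [
    "ReconVolume",
    "ConeBeamOperator",
    "reconstruct",
    "truncation_mask",
    "register_rigid",
    "ncc",
]


@dataclass
class ReconVolume:
    """Reconstructed attenuation grid (effective mm^-1) with placement."""

    values: np.ndarray
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or not np.all(np.isfinite(self.values)):
            raise ValueError("volume must be a finite 3D grid")

    @property
    def shape(self):
        return self.values.shape

    def save(self, path) -> None:
        import nibabel as nib

        affine = np.diag([*self.voxel_spacing_mm, 1.0])
        affine[:3, 3] = self.origin_mm
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), affine), str(path))

    @classmethod
    def load(cls, path) -> "ReconVolume":
        import nibabel as nib

        img = nib.load(str(path))
        aff = img.affine
        return cls(
            np.asarray(img.dataobj, dtype=np.float32),
            tuple(np.diag(aff)[:3]),
            tuple(aff[:3, 3]),
        )


class ConeBeamOperator:
    """Matched cone-beam forward/backprojector for a fixed view set.

    Rays are sampled uniformly between their volume-box entry and exit at
    ``step_mm`` (default 0.7 x voxel); the forward model gathers
    nearest-voxel values times the sample length, the adjoint scatters with
    identical indices and weights, so <Ax, y> = <x, A'y> to rounding.
    Per-view sample indices are precomputed once (``cache=True``).
    """

    def __init__(
        self,
        vol_shape: tuple[int, int, int],
        voxel_spacing_mm,
        origin_mm,
        matrices: Sequence[ProjectionMatrix],
        det_rows: int,
        det_cols: int,
        step_mm: float | None = None,
        cache: bool = True,
    ):
        self.vol_shape = tuple(vol_shape)
        self.spacing = np.asarray(voxel_spacing_mm, dtype=np.float64)
        self.origin = np.asarray(origin_mm, dtype=np.float64)
        self.matrices = list(matrices)
        self.det_rows = int(det_rows)
        self.det_cols = int(det_cols)
        self.step_mm = float(step_mm) if step_mm else 0.7 * float(self.spacing.min())
        self.n_views = len(self.matrices)
        self.n_pix = self.det_rows * self.det_cols
        self._cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._use_cache = cache

    def _view_samples(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """(flat voxel indices (n_pix, S) with -1 outside, dt (n_pix,))."""
        if k in self._cache:
            return self._cache[k]
        shape = np.asarray(self.vol_shape)
        lo = self.origin - self.spacing / 2.0
        hi = self.origin + (shape - 0.5) * self.spacing
        src, dirs = pixel_rays(self.matrices[k], self.det_rows, self.det_cols)
        tmin, tmax = ray_box_intersection(src, dirs, lo, hi)
        span = (tmax - tmin).astype(np.float32)
        n_s = max(int(np.ceil(span.max() / self.step_mm)), 1)
        frac = ((np.arange(n_s, dtype=np.float32) + 0.5) / n_s)[None, :]
        t = tmin[:, None].astype(np.float32) + span[:, None] * frac
        pts = src[None, None, :].astype(np.float32) + t[..., None] * dirs[:, None, :].astype(np.float32)
        ijk = np.rint((pts - self.origin) / self.spacing).astype(np.int32)
        valid = np.all((ijk >= 0) & (ijk < shape), axis=-1)
        flat = (ijk[..., 0] * shape[1] + ijk[..., 1]) * shape[2] + ijk[..., 2]
        flat = np.where(valid, flat, np.int32(-1))
        dt = span / np.float32(n_s)
        out = (flat, dt)
        if self._use_cache:
            self._cache[k] = out
        return out

    def forward(self, volume: np.ndarray) -> np.ndarray:
        vol = np.ascontiguousarray(volume, dtype=np.float32).ravel()
        vol_ext = np.append(vol, np.float32(0.0))  # index -1 -> zero
        out = np.empty((self.n_views, self.det_rows, self.det_cols), dtype=np.float32)
        for k in range(self.n_views):
            flat, dt = self._view_samples(k)
            acc = vol_ext[flat].sum(axis=1) * dt
            out[k] = acc.reshape(self.det_rows, self.det_cols)
        return out

    def adjoint(self, projections: np.ndarray) -> np.ndarray:
        proj = np.asarray(projections, dtype=np.float32)
        if proj.shape != (self.n_views, self.det_rows, self.det_cols):
            raise ValueError("projection stack shape mismatch")
        nvox = int(np.prod(self.vol_shape))
        acc = np.zeros(nvox + 1, dtype=np.float64)
        for k in range(self.n_views):
            flat, dt = self._view_samples(k)
            w = (proj[k].ravel() * dt).astype(np.float64)
            weights = np.broadcast_to(w[:, None], flat.shape).ravel()
            idx = np.where(flat >= 0, flat, nvox).ravel()
            acc += np.bincount(idx, weights=weights, minlength=nvox + 1)
        return acc[:nvox].reshape(self.vol_shape).astype(np.float32)


def _as_stack(projections, matrices):
    """Normalize input to (stack, matrices); accepts ProjectionImage lists."""
    if len(projections) and isinstance(projections[0], ProjectionImage):
        imgs: list[ProjectionImage] = list(projections)
        bad = [i for i, im in enumerate(imgs) if im.kind != "line_integral"]
        if bad:
            raise ValueError("reconstruction expects line-integral projections")
        stack = np.stack([im.pixels for im in imgs]).astype(np.float32)
        mats = [im.matrix for im in imgs]
        return stack, mats
    stack = np.asarray(projections, dtype=np.float32)
    if matrices is None:
        raise ValueError("matrices required when passing a raw stack")
    return stack, list(matrices)


def reconstruct(
    projections,
    matrices: Sequence[ProjectionMatrix] | None = None,
    vol_shape: tuple[int, int, int] = (96, 96, 96),
    voxel_spacing_mm=(1.0, 1.0, 1.0),
    origin_mm=None,
    n_iter: int = 30,
    mask: np.ndarray | None = None,
    algorithm: str = "cgls",
    step_mm: float | None = None,
    return_residuals: bool = False,
):
    """CGLS (or SIRT) reconstruction from posed line-integral projections.

    ``projections`` is a list of line-integral :class:`ProjectionImage` or
    a raw (n, rows, cols) stack with explicit ``matrices``.  ``mask`` is an
    optional boolean stack (or single image) of pixels to keep; masked-out
    pixels are excluded from the data term.  Returns a
    :class:`ReconVolume` (and residual norms when requested).
    """
    stack, mats = _as_stack(projections, matrices)
    n_views, rows, cols = stack.shape
    if len(mats) != n_views:
        raise ValueError("number of matrices must match number of projections")
    spacing = np.broadcast_to(np.asarray(voxel_spacing_mm, dtype=float), (3,))
    if origin_mm is None:
        origin_mm = tuple(-(np.asarray(vol_shape) - 1) / 2.0 * spacing)
    op = ConeBeamOperator(vol_shape, spacing, origin_mm, mats, rows, cols, step_mm)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim == 2:
            mask = np.broadcast_to(mask, stack.shape)
        m = mask.astype(np.float32)
    else:
        m = None

    def apply_mask(p):
        return p if m is None else p * m

    residuals: list[float] = []
    if algorithm == "cgls":
        x = np.zeros(vol_shape, dtype=np.float32)
        r = apply_mask(stack.copy())
        s = op.adjoint(r)
        p_dir = s.copy()
        gamma = float((s.astype(np.float64) ** 2).sum())
        for _ in range(n_iter):
            residuals.append(float(np.linalg.norm(r)))
            if gamma == 0:
                break
            q = apply_mask(op.forward(p_dir))
            qq = float((q.astype(np.float64) ** 2).sum())
            if qq == 0:
                break
            alpha = gamma / qq
            x += np.float32(alpha) * p_dir
            r -= np.float32(alpha) * q
            s = op.adjoint(r)
            gamma_new = float((s.astype(np.float64) ** 2).sum())
            p_dir = s + np.float32(gamma_new / gamma) * p_dir
            gamma = gamma_new
        residuals.append(float(np.linalg.norm(r)))
    elif algorithm == "sirt":
        ones_p = apply_mask(np.ones_like(stack))
        row_sum = op.forward(np.ones(vol_shape, dtype=np.float32))
        col_sum = op.adjoint(ones_p)
        inv_row = np.where(row_sum > 1e-6, 1.0 / np.maximum(row_sum, 1e-6), 0.0).astype(np.float32)
        inv_col = np.where(col_sum > 1e-6, 1.0 / np.maximum(col_sum, 1e-6), 0.0).astype(np.float32)
        x = np.zeros(vol_shape, dtype=np.float32)
        for _ in range(n_iter):
            r = apply_mask(stack - op.forward(x))
            residuals.append(float(np.linalg.norm(r)))
            x += inv_col * op.adjoint(r * inv_row)
        residuals.append(float(np.linalg.norm(apply_mask(stack - op.forward(x)))))
    else:
        raise ValueError("algorithm must be 'cgls' or 'sirt'")

    vol = ReconVolume(x, tuple(spacing), tuple(np.asarray(origin_mm, dtype=float)))
    return (vol, residuals) if return_residuals else vol


def truncation_mask(
    geom: CArmGeometry,
    pose_or_matrix,
    sphere_radius_mm: float = 50.0,
) -> np.ndarray:
    """Detector mask: True where the pixel ray intersects a centered sphere.

    The sphere sits at the isocenter; forward projecting it and keeping
    only interior pixels suppresses truncation artifacts from structures
    outside the reconstructed field of view.
    """
    if sphere_radius_mm <= 0:
        raise ValueError("sphere radius must be positive")
    matrix = (
        pose_to_matrix(geom, pose_or_matrix)
        if isinstance(pose_or_matrix, ViewPose)
        else pose_or_matrix
    )
    src, dirs = pixel_rays(matrix, geom.detector_rows, geom.detector_cols)
    center = np.asarray(geom.isocenter_offset_mm, dtype=float)
    rel = center - src
    t_par = dirs @ rel
    rho2 = (rel**2).sum() - t_par**2
    mask = rho2 <= sphere_radius_mm**2
    return mask.reshape(geom.detector_rows, geom.detector_cols)


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation of two equally shaped arrays."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        raise ValueError("zero-variance input to NCC")
    return float(a @ b / denom)


def _resample_moving(moving: ReconVolume, fixed: ReconVolume, transform: RigidTransform) -> np.ndarray:
    """Sample the moving volume on the fixed grid through transform^{-1}.

    ``transform`` aligns moving to fixed (moved-frame -> reference), i.e.
    fixed(x) ~ moving(T^{-1} x).
    """
    rot_inv = transform.rotation.T
    s_f = np.asarray(fixed.voxel_spacing_mm)
    s_m = np.asarray(moving.voxel_spacing_mm)
    o_f = np.asarray(fixed.origin_mm)
    o_m = np.asarray(moving.origin_mm)
    a = (rot_inv * s_f[None, :]) / s_m[:, None]
    b = (rot_inv @ (o_f - transform.translation) - o_m) / s_m
    return ndimage.affine_transform(
        moving.values.astype(np.float32), a, offset=b,
        output_shape=fixed.shape, order=1, mode="constant", cval=0.0,
    )


def register_rigid(
    moving: ReconVolume,
    fixed: ReconVolume,
    init: RigidTransform | None = None,
    coarse_translation_mm: float = 4.0,
    maxiter: int = 6000,
) -> RigidTransform:
    """Rigid registration by derivative-free NCC maximization.

    Searches the 6 rigid parameters (Euler angles in degrees, translation
    in mm) with a coarse translation grid followed by Powell refinement.
    Returns the transform aligning ``moving`` onto ``fixed`` (so that
    resampling moving through the inverse reproduces fixed).
    """
    init = init or RigidTransform()
    from scipy.spatial.transform import Rotation

    p0 = np.concatenate([
        Rotation.from_matrix(init.rotation).as_euler("xyz", degrees=True),
        init.translation,
    ])

    def objective(p):
        t = RigidTransform.from_euler_deg(p[0], p[1], p[2], p[3:6])
        resampled = _resample_moving(moving, fixed, t)
        if resampled.std() == 0:
            return 1.0
        val = ncc(fixed.values, resampled)
        if not np.isfinite(val):
            raise ValueError("non-finite registration objective")
        return -val

    # coarse grid over translations to escape poor initialization
    best_p, best_f = p0.copy(), objective(p0)
    g = coarse_translation_mm
    if g > 0:
        for dx in (-g, 0, g):
            for dy in (-g, 0, g):
                for dz in (-g, 0, g):
                    p = p0.copy()
                    p[3:6] += (dx, dy, dz)
                    f = objective(p)
                    if f < best_f:
                        best_p, best_f = p, f
    res = optimize.minimize(
        objective, best_p, method="Powell",
        options={"xtol": 1e-3, "ftol": 1e-7, "maxfev": maxiter},
    )
    p = res.x if res.fun <= best_f else best_p
    return RigidTransform.from_euler_deg(p[0], p[1], p[2], p[3:6])
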