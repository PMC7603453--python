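"""View-dependent task-based detectability index.

The quantity planned against is the non-prewhitening observer detectability

    d^2 = [ sum |MTF|^2 |W|^2 df^3 ]^2 / sum NPS |MTF|^2 |W|^2 df^3

evaluated from the *local* modulation transfer function and noise power
spectrum of quadratically penalized-likelihood reconstruction at a task
voxel j.  Both follow from the local Fisher information of the views: each
view projects a unit impulse at j into the detector (footprint), weights it
pixel-wise by the expected noise-free counts, and backprojects it into a
patch around j; the patch's 3D DFT magnitude F gives

    MTF = F / (F + beta * R),      NPS = F / (F + beta * R)^2

with R the DFT magnitude of the quadratic first-order-neighborhood penalty
stencil and beta the regularization strength.  Views whose rays suffer long
titanium traversals carry collapsed weights and hence low detectability --
this is what makes the planner steer away from views along screw axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import CArmGeometry, ViewPose, pose_to_matrix
from .phantom import MATERIALS, MaterialPhantom, attenuation
from .projector import Spectrum, _per_material_lengths, pixel_rays, ray_box_intersection

__all__ = [
    "TaskFunction",
    "LocalTransfer",
    "DetectabilityConfig",
    "DetectabilityMap",
    "thread_task_function",
    "default_task_voxel",
    "penalty_grid",
    "local_fisher",
    "mtf_nps",
    "detectability_index",
    "detectability_map",
    "build_targets",
]

logger = logging.getLogger(__name__)

THETA_OFFSETS_DEG = tuple(range(-25, 30, 5))  # the 11 out-of-plane targets


@dataclass(frozen=True)
class TaskFunction:
    """Task-function magnitude |W_task| on a 3D DFT frequency grid."""

    magnitude: np.ndarray
    f_x: np.ndarray
    f_y: np.ndarray
    f_z: np.ndarray

    def __post_init__(self):
        mag = np.asarray(self.magnitude, dtype=float)
        if mag.ndim != 3 or np.any(mag < 0):
            raise ValueError("task magnitude must be a non-negative 3D grid")
        if mag[0, 0, 0] != 0:
            raise ValueError("detection task must vanish at DC")
        object.__setattr__(self, "magnitude", mag)

    @property
    def df3(self) -> float:
        """Frequency-bin volume of the Riemann sum (cycles^3/mm^3)."""
        return float(
            abs(self.f_x[1] - self.f_x[0])
            * abs(self.f_y[1] - self.f_y[0])
            * abs(self.f_z[1] - self.f_z[0])
        )


@dataclass(frozen=True)
class LocalTransfer:
    """Local MTF and NPS at the task location for a given view set."""

    mtf: np.ndarray
    nps: np.ndarray
    location: tuple[int, int, int]

    def __post_init__(self):
        mtf = np.asarray(self.mtf, dtype=float)
        nps = np.asarray(self.nps, dtype=float)
        if mtf.shape != nps.shape:
            raise ValueError("MTF and NPS grids must be congruent")
        if np.any(mtf < -1e-12) or np.any(mtf > 1 + 1e-12):
            raise ValueError("MTF must lie in [0, 1]")
        if np.any(nps < 0) or not (np.all(np.isfinite(mtf)) and np.all(np.isfinite(nps))):
            raise ValueError("NPS must be non-negative and finite")


@dataclass(frozen=True)
class DetectabilityConfig:
    """Parameters of the local detectability computation.

    ``beta`` is the quadratic penalty strength, stated per unit incident
    fluence (the effective penalty is beta times the total photons/pixel,
    so the MTF/NPS balance is invariant to the simulated exposure);
    ``roi_halfwidth_vox`` sets the local patch (2h+1 per axis) around the
    task voxel; ``task_voxel`` defaults to the mid-shaft point of the
    first screw.  ``mode`` selects per-view maps (each candidate scored
    from its own single-view Fisher information) or cumulative maps
    (marginal d^2 gain over the views acquired so far).
    """

    beta: float = 10.0
    roi_halfwidth_vox: int = 8
    task_voxel: tuple[int, int, int] | None = None
    mode: str = "per-view"
    task_center_freq_cycles_mm: float = 1.0 / 3.0
    footprint_pad_px: int = 3
    supersample: int = 2  # patch sub-lattice per voxel; keeps the smooth
    # blob/ridge pattern alias-free under view rotation
    fft_pad_factor: float = 1.5  # zero-pad the patch DFT to resolve the task band

    @property
    def patch_n(self) -> int:
        return 2 * self.roi_halfwidth_vox * self.supersample + 1

    @property
    def fft_n(self) -> int:
        return int(round(self.fft_pad_factor * self.patch_n))

    def __post_init__(self):
        if self.beta < 0 or not np.isfinite(self.beta):
            raise ValueError("beta must be finite and >= 0")
        if self.mode not in ("per-view", "cumulative"):
            raise ValueError("mode must be 'per-view' or 'cumulative'")


@dataclass
class DetectabilityMap:
    """d^2 values on a discrete (phi, theta) view grid."""

    d2: np.ndarray  # (n_phi, n_theta)
    phi_deg: np.ndarray
    theta_deg: np.ndarray

    def __post_init__(self):
        self.d2 = np.asarray(self.d2, dtype=float)
        self.phi_deg = np.asarray(self.phi_deg, dtype=float)
        self.theta_deg = np.asarray(self.theta_deg, dtype=float)
        if self.d2.shape != (len(self.phi_deg), len(self.theta_deg)):
            raise ValueError("d2 grid shape must be (n_phi, n_theta)")
        if np.any(self.d2 < 0) or not np.all(np.isfinite(self.d2)):
            raise ValueError("d2 must be non-negative and finite")

    def _index(self, phi: float, theta: float) -> tuple[int, int]:
        phi = phi % 360.0
        i = np.where(np.isclose(self.phi_deg, phi, atol=1e-6))[0]
        j = np.where(np.isclose(self.theta_deg, theta, atol=1e-6))[0]
        if len(i) != 1 or len(j) != 1:
            raise KeyError(f"pose (phi={phi}, theta={theta}) not on the map grid")
        return int(i[0]), int(j[0])

    def value_at(self, pose: ViewPose) -> float:
        i, j = self._index(pose.phi_deg, pose.theta_deg)
        return float(self.d2[i, j])

    def to_dataframe(self):
        import pandas as pd

        phi, theta = np.meshgrid(self.phi_deg, self.theta_deg, indexing="ij")
        return pd.DataFrame(
            {"phi_deg": phi.ravel(), "theta_deg": theta.ravel(), "d2": self.d2.ravel()}
        )

    def save(self, path) -> None:
        np.savez(path, d2=self.d2, phi_deg=self.phi_deg, theta_deg=self.theta_deg)

    @classmethod
    def load(cls, path) -> "DetectabilityMap":
        with np.load(path) as d:
            return cls(d["d2"], d["phi_deg"], d["theta_deg"])


def thread_task_function(
    patch_shape: tuple[int, int, int],
    voxel_spacing_mm,
    center_freq_cycles_mm: float = 1.0 / 3.0,
    rel_width: float = 0.5,
) -> TaskFunction:
    """Radial Gaussian band-pass centered at the screw-thread frequency.

    The detection task targets thread conspicuity, so |W_task| peaks at
    1/pitch cycles/mm with Gaussian width ``rel_width`` times the center
    frequency; the DC bin is forced to zero (band-pass detection task).
    """
    spacing = np.broadcast_to(np.asarray(voxel_spacing_mm, dtype=float), (3,))
    axes = [np.fft.fftfreq(n, d=s) for n, s in zip(patch_shape, spacing)]
    fx, fy, fz = np.meshgrid(*axes, indexing="ij")
    radius = np.sqrt(fx**2 + fy**2 + fz**2)
    sigma = rel_width * center_freq_cycles_mm
    mag = np.exp(-0.5 * ((radius - center_freq_cycles_mm) / sigma) ** 2)
    mag[0, 0, 0] = 0.0
    return TaskFunction(mag, axes[0], axes[1], axes[2])


def default_task_voxel(phantom: MaterialPhantom) -> tuple[int, int, int]:
    """Mid-shaft voxel of the first screw (the object whose placement the
    task verifies)."""
    if not phantom.screws:
        center = tuple(n // 2 for n in phantom.shape)
        return center
    s = phantom.screws[0]
    mid = np.asarray(s.tip_position_mm) + 0.5 * s.length_mm * np.asarray(s.axis)
    idx = np.rint(phantom.world_to_voxel(mid)).astype(int)
    return tuple(int(v) for v in idx)


def penalty_grid(patch_shape: tuple[int, int, int], neighbor_stride: int = 1) -> np.ndarray:
    """|DFT| of the quadratic first-order-neighborhood penalty stencil.

    The stencil is the 6-neighbor 3D Laplacian-like quadratic form (center
    6, face neighbors -1); its DFT magnitude vanishes at DC, so the penalty
    never biases the mean.  ``neighbor_stride`` places the neighbors on a
    supersampled patch lattice (stride = samples per voxel).
    """
    stencil = np.zeros(patch_shape)
    stencil[0, 0, 0] = 6.0
    for axis in range(3):
        for off in (neighbor_stride, -neighbor_stride):
            idx = [0, 0, 0]
            idx[axis] = off % patch_shape[axis]
            stencil[tuple(idx)] += -1.0
    return np.abs(np.fft.fftn(stencil))


def _expected_counts(
    phantom: MaterialPhantom, matrix, pixel_idx: np.ndarray, spectrum: Spectrum
) -> np.ndarray:
    """Noise-free polyenergetic counts at selected detector pixels.

    Rays are sampled at one voxel per step: the counts only weight the
    footprint, so sub-voxel ray accuracy buys nothing here."""
    step = float(np.min(phantom.voxel_spacing_mm))
    lengths = _per_material_lengths(phantom, matrix, 0, 0, step_mm=step, pixel_idx=pixel_idx)
    energies = np.asarray(spectrum.energies_keV)
    weights = np.asarray(spectrum.fluence_weights)
    mu = np.stack([attenuation(m, energies) for m in range(len(MATERIALS))])
    return np.exp(-(lengths @ mu)) @ weights


BLOB_SIGMA_VOX = 0.6  # Gaussian voxel-basis width, in voxels


class _PatchGeometry:
    """Precomputed task-patch lattice shared across views."""

    def __init__(self, phantom: MaterialPhantom, config: DetectabilityConfig):
        j = np.asarray(
            config.task_voxel if config.task_voxel is not None else default_task_voxel(phantom)
        )
        h = config.roi_halfwidth_vox
        shape = np.asarray(phantom.shape)
        if np.any(j - h < 0) or np.any(j + h >= shape):
            raise ValueError("task voxel ROI does not fit inside the volume")
        spacing = np.asarray(phantom.voxel_spacing_mm)
        if np.ptp(spacing) > 1e-9:
            raise ValueError("local Fisher patch requires isotropic voxels")
        self.vox = float(spacing[0])
        self.sigma = BLOB_SIGMA_VOX * self.vox
        self.h = h
        self.sub = config.supersample
        self.patch_shape = (config.patch_n,) * 3
        self.j_center = phantom.voxel_center(j)
        offs = np.arange(-h * self.sub, h * self.sub + 1) * (self.vox / self.sub)
        ox, oy, oz = np.meshgrid(offs, offs, offs, indexing="ij")
        rel = np.stack([ox, oy, oz], axis=-1).reshape(-1, 3)
        radius = np.sqrt((rel**2).sum(1))
        sigma_w = h * self.vox / 2.5
        self.window = np.exp(-0.5 * (radius / sigma_w) ** 2)
        self.sphere = radius <= h * self.vox
        self.centers_s = (self.j_center + rel)[self.sphere]
        self.window_s = self.window[self.sphere]
        self.line_norm = np.sqrt(2.0 * np.pi) * self.sigma


def view_patch(
    phantom: MaterialPhantom,
    geom: CArmGeometry,
    pose,
    config: DetectabilityConfig,
    spectrum: Spectrum,
    patch_geom: _PatchGeometry | None = None,
) -> np.ndarray:
    """One view's contribution to the local Fisher patch at the task voxel.

    Footprint (blob line integral at j) weighted by expected noise-free
    counts and backprojected onto the windowed spherical patch; returns the
    patch-shaped array (zeros if the footprint misses the detector)."""
    pg = patch_geom or _PatchGeometry(phantom, config)
    patch = np.zeros(pg.patch_shape, dtype=np.float64)
    matrix = pose_to_matrix(geom, pose) if isinstance(pose, ViewPose) else pose
    pj = matrix.project(pg.j_center)
    pad = config.footprint_pad_px + int(
        np.ceil(3 * pg.sigma * geom.magnification / geom.pixel_pitch_mm)
    )
    u_lo = max(int(np.floor(pj[0])) - pad, 0)
    u_hi = min(int(np.ceil(pj[0])) + pad, geom.detector_cols - 1)
    v_lo = max(int(np.floor(pj[1])) - pad, 0)
    v_hi = min(int(np.ceil(pj[1])) + pad, geom.detector_rows - 1)
    if u_lo > u_hi or v_lo > v_hi:
        logger.info(
            "impulse footprint off detector at phi=%s theta=%s",
            getattr(pose, "phi_deg", "?"), getattr(pose, "theta_deg", "?"),
        )
        return patch
    vv, uu = np.meshgrid(
        np.arange(v_lo, v_hi + 1), np.arange(u_lo, u_hi + 1), indexing="ij"
    )
    pixel_idx = np.stack([vv.ravel(), uu.ravel()], axis=1)
    src, dirs = pixel_rays(matrix, geom.detector_rows, geom.detector_cols, pixel_idx)

    rel_j = pg.j_center - src
    t_par = dirs @ rel_j
    rho2 = (rel_j**2).sum() - t_par**2
    a = pg.line_norm * np.exp(-0.5 * rho2 / pg.sigma**2)
    keep = a > a.max() * 1e-4  # rays beyond ~4.3 sigma carry no footprint
    if not np.any(keep) or np.all(t_par <= 0):
        logger.info("impulse footprint missed voxel j in view %s", pose)
        return patch
    a = a[keep]
    dirs_k = dirs[keep]
    w = _expected_counts(phantom, matrix, pixel_idx[keep], spectrum)

    rel_c = pg.centers_s - src
    t_c = rel_c @ dirs_k.T
    rho2_c = (rel_c**2).sum(1)[:, None] - t_c**2
    # evaluate the blob only within 4.5 sigma of each ray (relative error
    # < 4e-5 of the on-axis value)
    near = rho2_c < (4.5 * pg.sigma) ** 2
    ridge = np.zeros_like(rho2_c)
    ridge[near] = pg.line_norm * np.exp(-0.5 * rho2_c[near] / pg.sigma**2)
    deposit = pg.window_s * (ridge @ (w * a))
    flat = np.zeros(patch.size)
    flat[pg.sphere] = deposit
    return flat.reshape(pg.patch_shape)


def local_fisher(
    phantom: MaterialPhantom,
    geom: CArmGeometry,
    views,
    config: DetectabilityConfig,
    spectrum: Spectrum,
) -> np.ndarray:
    """Local Fisher-information spectrum F_j for a set of views.

    For each view the unit impulse at the task voxel j is forward projected
    (footprint), weighted pixel-wise by the expected noise-free counts, and
    backprojected; patches are accumulated over views and F_j is the DFT
    magnitude of the accumulated patch on the task frequency grid.  Views
    whose footprint misses the detector contribute zero (logged).

    The voxel basis is a rotationally symmetric Gaussian blob, so both the
    footprint (line integral of the blob at j) and the backprojected ridge
    (line integral of the blob at each patch voxel) have the closed form
    sqrt(2 pi) sigma exp(-rho^2 / 2 sigma^2) with rho the perpendicular
    ray-to-center distance; the patch is restricted to the inscribed sphere
    under a Gaussian localization window (sidelobe-free transform), so
    single-view information is invariant under view rotation.
    """
    pg = _PatchGeometry(phantom, config)
    patch = np.zeros(pg.patch_shape, dtype=np.float64)
    for pose in views:
        patch += view_patch(phantom, geom, pose, config, spectrum, pg)
    return fisher_spectrum(patch, config)


def fisher_spectrum(patch: np.ndarray, config: DetectabilityConfig) -> np.ndarray:
    """DFT magnitude of an accumulated local patch (zero-padded)."""
    n_fft = config.fft_n
    return np.abs(np.fft.fftn(patch, s=(n_fft, n_fft, n_fft), axes=(0, 1, 2)))


def mtf_nps(fisher: np.ndarray, penalty: np.ndarray, beta: float) -> LocalTransfer:
    """Fourier metrics of quadratically penalized-likelihood reconstruction.

    MTF = F/(F + beta R) and NPS = F/(F + beta R)^2 elementwise; where the
    denominator vanishes there is neither transfer nor noise (both 0).
    """
    fisher = np.asarray(fisher, dtype=float)
    penalty = np.asarray(penalty, dtype=float)
    if fisher.shape != penalty.shape:
        raise ValueError("Fisher and penalty grids must be congruent")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    denom = fisher + beta * penalty
    zero = denom <= 0
    if np.any(zero):
        logger.debug("%d frequencies with zero transfer", int(zero.sum()))
    safe = np.where(zero, 1.0, denom)
    mtf = np.where(zero, 0.0, fisher / safe)
    nps = np.where(zero, 0.0, fisher / safe**2)
    return LocalTransfer(mtf, nps, location=(0, 0, 0))


def detectability_index(transfer: LocalTransfer, task: TaskFunction) -> float:
    """Non-prewhitening observer d^2 as a Riemann sum over the frequency grid."""
    if transfer.mtf.shape != task.magnitude.shape:
        raise ValueError("transfer and task grids must be congruent")
    df3 = task.df3
    core = transfer.mtf**2 * task.magnitude**2
    num = (core.sum() * df3) ** 2
    den = (transfer.nps * core).sum() * df3
    if num == 0:
        return 0.0
    if den == 0:
        raise ValueError("inconsistent transfer: zero noise with nonzero signal")
    return float(num / den)


def _single_view_d2(phantom, geom, views, config, spectrum, task, penalty) -> float:
    fisher = local_fisher(phantom, geom, views, config, spectrum)
    transfer = mtf_nps(fisher, penalty, config.beta * spectrum.total_fluence)
    return detectability_index(transfer, task)


def detectability_map(
    phantom: MaterialPhantom,
    geom: CArmGeometry,
    candidate_views,
    spectrum: Spectrum,
    config: DetectabilityConfig | None = None,
    acquired_views=(),
    progress: bool = False,
) -> DetectabilityMap:
    """Ground-truth d^2 over a grid of candidate views.

    Per-view mode scores every candidate from its own single-view Fisher
    information; cumulative mode scores the marginal gain of adding the
    candidate to the already-acquired view set.
    """
    from dataclasses import replace as _replace

    cfg = config or DetectabilityConfig()
    if cfg.task_voxel is None:
        cfg = _replace(cfg, task_voxel=default_task_voxel(phantom))
    fft_shape = (cfg.fft_n,) * 3
    fine_spacing = np.asarray(phantom.voxel_spacing_mm) / cfg.supersample
    task = thread_task_function(fft_shape, fine_spacing, cfg.task_center_freq_cycles_mm)
    penalty = penalty_grid(fft_shape, neighbor_stride=cfg.supersample)
    phi_axis = np.unique(np.round([p.phi_deg for p in candidate_views], 6))
    theta_axis = np.unique(np.round([p.theta_deg for p in candidate_views], 6))
    d2 = np.zeros((len(phi_axis), len(theta_axis)))
    base = 0.0
    if cfg.mode == "cumulative" and len(acquired_views):
        base = _single_view_d2(phantom, geom, list(acquired_views), cfg, spectrum, task, penalty)
    iterator = candidate_views
    if progress:
        from tqdm import tqdm  # pragma: no cover - cosmetic

        iterator = tqdm(candidate_views)
    for pose in iterator:
        if cfg.mode == "per-view":
            val = _single_view_d2(phantom, geom, [pose], cfg, spectrum, task, penalty)
        else:
            val = (
                _single_view_d2(
                    phantom, geom, list(acquired_views) + [pose], cfg, spectrum, task, penalty
                )
                - base
            )
            val = max(val, 0.0)
        i = np.searchsorted(phi_axis, round(pose.phi_deg, 6))
        jx = np.searchsorted(theta_axis, round(pose.theta_deg, 6))
        d2[i, jx] = val
    return DetectabilityMap(d2, phi_axis, theta_axis)


class CumulativeOracle:
    """Planner predictor scoring candidates by their marginal d^2 gain.

    The observer index is defined over *all* views in a trajectory; this
    oracle keeps the accumulated Fisher patch of the views acquired so far
    and scores each of the 11 candidates by d^2(acquired + candidate) -
    d^2(acquired).  Redundant views (information already collected) earn
    vanishing gain, so planning on these scores trades per-view SNR
    against angular coverage.  The planner calls ``observe`` after every
    acquisition; the image argument is ignored (3D scene known).
    """

    def __init__(
        self,
        phantom: MaterialPhantom,
        geom: CArmGeometry,
        spectrum: Spectrum,
        config: DetectabilityConfig | None = None,
        delta_phi_deg: float = 5.0,
    ):
        from dataclasses import replace as _replace

        cfg = config or DetectabilityConfig()
        if cfg.task_voxel is None:
            cfg = _replace(cfg, task_voxel=default_task_voxel(phantom))
        self.cfg = cfg
        self.phantom = phantom
        self.geom = geom
        self.spectrum = spectrum
        self.delta_phi_deg = delta_phi_deg
        self._pg = _PatchGeometry(phantom, cfg)
        n = cfg.fft_n
        self._task = thread_task_function(
            (n, n, n),
            np.asarray(phantom.voxel_spacing_mm) / cfg.supersample,
            cfg.task_center_freq_cycles_mm,
        )
        self._penalty = penalty_grid((n, n, n), neighbor_stride=cfg.supersample)
        self._beta = cfg.beta * spectrum.total_fluence
        self._acc = np.zeros(self._pg.patch_shape)
        self._acc_d2 = 0.0
        self._patch_cache: dict[tuple[float, float], np.ndarray] = {}

    def _d2_of(self, patch: np.ndarray) -> float:
        transfer = mtf_nps(fisher_spectrum(patch, self.cfg), self._penalty, self._beta)
        return detectability_index(transfer, self._task)

    def _patch(self, pose: ViewPose) -> np.ndarray:
        key = (round(pose.phi_deg, 6), round(pose.theta_deg, 6))
        if key not in self._patch_cache:
            self._patch_cache[key] = view_patch(
                self.phantom, self.geom, pose, self.cfg, self.spectrum, self._pg
            )
        return self._patch_cache[key]

    def observe(self, pose: ViewPose) -> None:
        """Commit an acquired view to the accumulated information."""
        self._acc = self._acc + self._patch(pose)
        self._acc_d2 = self._d2_of(self._acc)

    def __call__(self, image, pose: ViewPose) -> np.ndarray:
        scale = self.delta_phi_deg / 5.0
        gains = []
        for delta in THETA_OFFSETS_DEG:
            theta = pose.theta_deg + delta * scale
            if not 0.0 <= theta <= 180.0:
                gains.append(0.0)
                continue
            cand = ViewPose(pose.phi_deg + self.delta_phi_deg, theta)
            gains.append(max(self._d2_of(self._acc + self._patch(cand)) - self._acc_d2, 0.0))
        return np.asarray(gains)


def build_targets(dmap: DetectabilityMap, current: ViewPose) -> np.ndarray:
    """The 11 training targets: d^2 at (phi+5, theta+delta), delta in
    {-25, ..., +25} step 5, ascending delta order."""
    values = [
        dmap.value_at(ViewPose(current.phi_deg + 5.0, current.theta_deg + delta))
        for delta in THETA_OFFSETS_DEG
    ]
    return np.asarray(values)
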