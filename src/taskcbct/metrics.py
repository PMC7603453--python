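"""Image-quality metrics for screw reconstructions.

Metal blooming is quantified by the full width at half maximum of
profiles perpendicular to the known screw axis; thread conspicuity by the
spectral magnitude at the thread frequency (1/pitch cycles/mm) of a
standardized patch along the screw; slice similarity by SSIM.  Trajectory
detectability is compared by the relative difference of summed map values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .detectability import DetectabilityMap
from .phantom import ScrewSpec
from .recon import ReconVolume

__all__ = [
    "MetricReport",
    "fwhm_profile",
    "screw_fwhm",
    "thread_patch",
    "thread_peak",
    "screw_thread_peak",
    "ssim_slice",
    "rel_d2_diff",
]

logger = logging.getLogger(__name__)


@dataclass
class MetricReport:
    """Bundle of reconstruction/trajectory quality figures."""

    fwhm_mm: float
    thread_peak: float
    ssim: float | None = None
    mean_abs_dtheta_deg: float | None = None
    rel_d2_diff_percent: float | None = None
    details: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.isfinite(self.fwhm_mm) or self.fwhm_mm <= 0:
            raise ValueError("fwhm_mm must be positive and finite")
        for name in ("thread_peak", "ssim", "mean_abs_dtheta_deg", "rel_d2_diff_percent"):
            v = getattr(self, name)
            if v is not None and not np.isfinite(v):
                raise ValueError(f"{name} must be finite")

    def to_dict(self) -> dict:
        return asdict(self)


def fwhm_profile(profile: np.ndarray, spacing_mm: float) -> float:
    """Full width at half maximum of a 1D profile, in mm.

    Half maximum is baseline + (peak - baseline)/2 with the baseline at the
    profile minimum; crossings are located by linear interpolation around
    the global maximum.  Raises if either crossing lies outside the
    profile (truncated peak).
    """
    p = np.asarray(profile, dtype=float)
    if p.ndim != 1 or len(p) < 3:
        raise ValueError("profile must be a 1D array of at least 3 samples")
    peak_idx = int(np.argmax(p))
    base = p.min()
    half = base + (p[peak_idx] - base) / 2.0

    def cross(idx_range):
        prev = peak_idx
        for i in idx_range:
            if p[i] < half:
                # linear interpolation between i and the previous sample
                frac = (p[prev] - half) / (p[prev] - p[i])
                return prev + frac * (i - prev)
            prev = i
        raise ValueError("profile truncated: no half-maximum crossing")

    left = cross(range(peak_idx - 1, -1, -1))
    right = cross(range(peak_idx + 1, len(p)))
    return float((right - left) * spacing_mm)


def _screw_frame(screw: ScrewSpec):
    w = np.asarray(screw.axis)
    helper = np.array([0.0, 0.0, 1.0]) if abs(w[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(helper, w)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return u, v, w


def _sample_line(vol: ReconVolume, start_mm, direction, length_mm, step_mm):
    n = int(round(length_mm / step_mm)) + 1
    t = (np.arange(n) - (n - 1) / 2.0) * step_mm
    pts = np.asarray(start_mm) + t[:, None] * np.asarray(direction)
    coords = (pts - np.asarray(vol.origin_mm)) / np.asarray(vol.voxel_spacing_mm)
    return ndimage.map_coordinates(
        vol.values.astype(np.float64), coords.T, order=1, mode="nearest"
    )


def screw_fwhm(
    vol: ReconVolume,
    screw: ScrewSpec,
    profile_length_mm: float = 10.0,
    step_mm: float = 0.25,
    axial_fractions=(0.35, 0.65),
) -> float:
    """Screw FWHM: profiles perpendicular to the screw axis through the
    shaft, averaged over two axial positions (quantifies blooming)."""
    u, _, w = _screw_frame(screw)
    tip = np.asarray(screw.tip_position_mm)
    widths = []
    for frac in axial_fractions:
        center = tip + frac * screw.length_mm * w
        profile = _sample_line(vol, center, u, profile_length_mm, step_mm)
        widths.append(fwhm_profile(profile, step_mm))
    return float(np.mean(widths))


def screw_profiles(
    vol: ReconVolume,
    screw: ScrewSpec,
    profile_length_mm: float = 10.0,
    step_mm: float = 0.25,
    axial_fractions=(0.35, 0.65),
):
    """Raw FWHM profiles as a tidy DataFrame (for export/inspection)."""
    import pandas as pd

    u, _, w = _screw_frame(screw)
    tip = np.asarray(screw.tip_position_mm)
    rows = []
    n = int(round(profile_length_mm / step_mm)) + 1
    offsets = (np.arange(n) - (n - 1) / 2.0) * step_mm
    for frac in axial_fractions:
        center = tip + frac * screw.length_mm * w
        values = _sample_line(vol, center, u, profile_length_mm, step_mm)
        for off, val in zip(offsets, values):
            rows.append({"axial_fraction": frac, "offset_mm": off, "value": val})
    return pd.DataFrame(rows)


def thread_patch(
    vol: ReconVolume,
    screw: ScrewSpec,
    step_mm: float = 0.5,
    margin_mm: float = 2.0,
    axial_trim_mm: float = 4.0,
) -> tuple[np.ndarray, float]:
    """2D patch through the screw axis containing the thread region.

    Rows run along the screw axis, columns across it (shaft plus
    ``margin_mm`` on either side).  Returns (patch, step_mm).
    """
    u, _, w = _screw_frame(screw)
    tip = np.asarray(screw.tip_position_mm)
    r_max = screw.shaft_radius_mm + screw.thread_depth_mm + margin_mm
    s_vals = np.arange(axial_trim_mm, screw.length_mm - axial_trim_mm + 1e-9, step_mm)
    r_vals = np.arange(-r_max, r_max + 1e-9, step_mm)
    pts = tip[None, None, :] + s_vals[:, None, None] * w + r_vals[None, :, None] * u
    coords = (pts - np.asarray(vol.origin_mm)) / np.asarray(vol.voxel_spacing_mm)
    patch = ndimage.map_coordinates(
        vol.values.astype(np.float64),
        coords.reshape(-1, 3).T, order=1, mode="nearest",
    ).reshape(len(s_vals), len(r_vals))
    return patch, step_mm


def thread_peak(
    patch: np.ndarray, pitch_mm: float, spacing_mm: float, axis: int = 0
) -> float:
    """Spectral magnitude at the thread frequency of a standardized patch.

    The patch is standardized to zero mean and unit variance; 1D spectra
    along the screw axis are averaged across the perpendicular direction
    and read out at the bin nearest 1/pitch cycles/mm.  A constant patch
    returns 0 (logged).
    """
    p = np.asarray(patch, dtype=float)
    if p.ndim != 2:
        raise ValueError("patch must be 2D")
    n_axis = p.shape[axis]
    if n_axis * spacing_mm < 2 * pitch_mm:
        raise ValueError("patch must span at least two thread pitches")
    std = p.std()
    if std == 0:
        logger.info("constant patch: thread peak undefined, returning 0")
        return 0.0
    p = (p - p.mean()) / std
    spec = np.abs(np.fft.rfft(p, axis=axis)) / n_axis
    mean_spec = spec.mean(axis=1 - axis)
    freqs = np.fft.rfftfreq(n_axis, d=spacing_mm)
    idx = int(np.argmin(np.abs(freqs - 1.0 / pitch_mm)))
    return float(mean_spec[idx])


def screw_thread_peak(vol: ReconVolume, screw: ScrewSpec, step_mm: float = 0.5) -> float:
    """Thread-frequency peak of the reconstruction around one screw."""
    patch, step = thread_patch(vol, screw, step_mm=step_mm)
    return thread_peak(patch, screw.thread_pitch_mm, step, axis=0)


def ssim_slice(a: np.ndarray, b: np.ndarray) -> float:
    """SSIM between two slices (7-pixel Gaussian window, K1=0.01, K2=0.03).

    The dynamic range is taken from the reference slice ``a``.
    """
    from skimage.metrics import structural_similarity

    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("slices must be congruent 2D arrays")
    data_range = float(a.max() - a.min())
    if data_range == 0:
        raise ValueError("reference slice has zero dynamic range")
    return float(
        structural_similarity(
            a, b, data_range=data_range,
            gaussian_weights=True, sigma=1.0, truncate=3.0,
            use_sample_covariance=False, K1=0.01, K2=0.03,
        )
    )


def rel_d2_diff(traj, reference_traj, dmap: DetectabilityMap) -> float:
    """Relative detectability shortfall of a trajectory vs a reference, %.

    100 * (sum d2_ref - sum d2_traj) / sum d2_ref over the map values at
    each trajectory's poses.
    """
    ref = float(sum(dmap.value_at(p) for p in reference_traj.poses))
    got = float(sum(dmap.value_at(p) for p in traj.poses))
    if ref == 0:
        raise ValueError("reference trajectory has zero summed detectability")
    return float(100.0 * (ref - got) / ref)
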