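"""Greedy online trajectory construction.

The in-plane angle advances by a fixed increment each step; the
out-of-plane step is chosen among the 11 candidate offsets by maximizing
the predicted detectability plus a cosine smoothness reward,

    i* = argmax_i [ lambda * (u . v_i) + p_hat_i ]

where u is the previous step direction in (delta-phi, delta-theta), v_i
the candidate direction, and p_hat the per-step min-max normalization of
the predictions to [0, 1].  The out-of-plane angle is doubly constrained:
absolute bounds (default [45, 135] degrees) and a +/-45 degree excursion
from the starting angle.  Because each decision depends only on the
current pose and previous direction, two trajectories that meet in the
same state merge and continue identically under a deterministic predictor.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .detectability import THETA_OFFSETS_DEG, DetectabilityMap, build_targets
from .geometry import ViewPose

__all__ = [
    "PlannerState",
    "Trajectory",
    "OracleMapPredictor",
    "next_view",
    "plan_trajectory",
    "circular_trajectory",
    "retrospective_select",
]


@dataclass(frozen=True)
class PlannerState:
    """Planner configuration plus the evolving (pose, direction) state."""

    current: ViewPose
    prev_direction: tuple[float, float] | None = None  # unit (dphi, dtheta)
    lam: float = 0.6
    delta_phi_deg: float = 5.0
    theta_abs_bounds: tuple[float, float] = (45.0, 135.0)
    theta_rel_bound_deg: float = 45.0
    start_theta_deg: float | None = None

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.delta_phi_deg <= 0:
            raise ValueError("delta_phi_deg must be positive")
        if self.start_theta_deg is None:
            object.__setattr__(self, "start_theta_deg", self.current.theta_deg)
        if self.prev_direction is not None:
            u = np.asarray(self.prev_direction, dtype=float)
            n = np.linalg.norm(u)
            if n < 1e-12:
                raise ValueError("prev_direction must be nonzero")
            object.__setattr__(self, "prev_direction", tuple(u / n))

    @property
    def theta_offsets(self) -> np.ndarray:
        """Candidate out-of-plane offsets, scaled so the maximum slope
        matches the 25/5 ratio of the training geometry."""
        return np.asarray(THETA_OFFSETS_DEG, dtype=float) * (self.delta_phi_deg / 5.0)


@dataclass
class Trajectory:
    """Ordered view poses with the per-step chosen scores."""

    poses: list[ViewPose]
    scores: list[float] = field(default_factory=list)

    def __post_init__(self):
        if not self.poses:
            raise ValueError("trajectory must contain at least one pose")

    @property
    def phi_deg(self) -> np.ndarray:
        return np.array([p.phi_deg for p in self.poses])

    @property
    def theta_deg(self) -> np.ndarray:
        return np.array([p.theta_deg for p in self.poses])

    def __len__(self) -> int:
        return len(self.poses)

    def summed_d2(self, dmap: DetectabilityMap) -> float:
        """Ground-truth detectability accumulated along the trajectory."""
        return float(sum(dmap.value_at(p) for p in self.poses))

    def to_csv(self, path_or_buf) -> None:
        """CSV with header ``t,phi_deg,theta_deg``, 6-decimal fixed format."""
        buf = io.StringIO()
        buf.write("t,phi_deg,theta_deg\n")
        for t, p in enumerate(self.poses):
            buf.write(f"{t},{p.phi_deg:.6f},{p.theta_deg:.6f}\n")
        text = buf.getvalue()
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        import pandas as pd

        df = pd.read_csv(path)
        poses = [
            ViewPose(row.phi_deg, row.theta_deg, t=int(row.t))
            for row in df.itertuples()
        ]
        return cls(poses)


class OracleMapPredictor:
    """Predictor adapter that reads exact values off a detectability map.

    Implements the same interface as the learned surrogate (a callable of
    the current image and pose returning the 11-vector) but ignores the
    image entirely.
    """

    def __init__(self, dmap: DetectabilityMap, delta_phi_deg: float = 5.0):
        self.dmap = dmap
        self.delta_phi_deg = delta_phi_deg

    def __call__(self, image, pose: ViewPose) -> np.ndarray:
        scale = self.delta_phi_deg / 5.0
        values = []
        for d in THETA_OFFSETS_DEG:
            theta = pose.theta_deg + d * scale
            try:
                values.append(
                    self.dmap.value_at(ViewPose(pose.phi_deg + self.delta_phi_deg, theta))
                )
            except (KeyError, ValueError):
                # candidate off the map (outside the theta band): no
                # detectability information; such candidates are excluded
                # by the planner's bounds anyway
                values.append(0.0)
        return np.asarray(values)


def _admissible(state: PlannerState, theta_new: float) -> bool:
    lo, hi = state.theta_abs_bounds
    if not lo <= theta_new <= hi:
        return False
    return abs(theta_new - state.start_theta_deg) <= state.theta_rel_bound_deg


def next_view(predictions: np.ndarray, state: PlannerState) -> tuple[ViewPose, int]:
    """Select the next pose from the 11 predicted detectabilities.

    Predictions are min-max normalized to [0, 1] per step; candidates whose
    out-of-plane angle violates either bound are excluded; the cosine term
    is omitted on the first step (no previous direction).  Ties resolve
    toward the smallest |offset| (smoothest continuation), then toward the
    more negative offset, so an uninformative prediction vector continues
    the current orbit.
    """
    p = np.asarray(predictions, dtype=float)
    offsets = state.theta_offsets
    if p.shape != offsets.shape:
        raise ValueError(f"expected {len(offsets)} predictions, got {p.shape}")
    if not np.all(np.isfinite(p)):
        raise ValueError("predictions must be finite")
    span = p.max() - p.min()
    p_hat = (p - p.min()) / span if span > 0 else np.zeros_like(p)
    theta_new = state.current.theta_deg + offsets
    ok = np.array([_admissible(state, t) for t in theta_new])
    if not np.any(ok):
        raise ValueError("no admissible candidate within the theta bounds")
    v = np.stack([np.full_like(offsets, state.delta_phi_deg), offsets], axis=1)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    score = p_hat.copy()
    if state.prev_direction is not None:
        score = score + state.lam * (v @ np.asarray(state.prev_direction))
    score[~ok] = -np.inf
    best = score.max()
    tied = np.isclose(score, best, rtol=0, atol=1e-12)
    idx = int(min(np.flatnonzero(tied), key=lambda i: (abs(offsets[i]), offsets[i])))
    pose = ViewPose(
        state.current.phi_deg + state.delta_phi_deg, theta_new[idx],
        t=(state.current.t + 1) if state.current.t is not None else None,
    )
    return pose, idx


def plan_trajectory(
    predictor: Callable[[object, ViewPose], np.ndarray],
    start: ViewPose,
    n_steps: int,
    lam: float = 0.6,
    delta_phi_deg: float = 5.0,
    theta_abs_bounds: tuple[float, float] = (45.0, 135.0),
    theta_rel_bound_deg: float = 45.0,
    acquire: Callable[[ViewPose], object] | None = None,
) -> Trajectory:
    """Iterate acquire -> predict -> select for ``n_steps`` views.

    ``predictor(image, pose)`` returns the 11 candidate detectabilities;
    ``acquire(pose)`` produces the image handed to the predictor (None for
    map-oracle predictors).  Deterministic for deterministic inputs.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    start = ViewPose(start.phi_deg, start.theta_deg, t=0)
    state = PlannerState(
        current=start, lam=lam, delta_phi_deg=delta_phi_deg,
        theta_abs_bounds=theta_abs_bounds, theta_rel_bound_deg=theta_rel_bound_deg,
        start_theta_deg=start.theta_deg,
    )
    poses = [start]
    scores: list[float] = []
    offsets = state.theta_offsets
    observe = getattr(predictor, "observe", None)
    if observe is not None:
        observe(start)  # stateful predictors track acquired views
    for _ in range(n_steps - 1):
        image = acquire(state.current) if acquire is not None else None
        predictions = predictor(image, state.current)
        pose, idx = next_view(predictions, state)
        scores.append(float(np.asarray(predictions, dtype=float)[idx]))
        direction = (state.delta_phi_deg, offsets[idx])
        state = replace(state, current=pose, prev_direction=direction)
        poses.append(pose)
        if observe is not None:
            observe(pose)
    return Trajectory(poses, scores)


def circular_trajectory(
    start: ViewPose, n_steps: int, delta_phi_deg: float = 5.0
) -> Trajectory:
    """Reference circular orbit: theta fixed at the start angle."""
    poses = [
        ViewPose(start.phi_deg + t * delta_phi_deg, start.theta_deg, t=t)
        for t in range(n_steps)
    ]
    return Trajectory(poses)


def _angular_distance(a: ViewPose, b: ViewPose) -> float:
    dphi = abs(a.phi_deg - b.phi_deg)
    dphi = min(dphi, 360.0 - dphi)
    return float(np.hypot(dphi, a.theta_deg - b.theta_deg))


def retrospective_select(target: ViewPose, available: Sequence):
    """Pick the nearest available posed projection to a planned target.

    ``available`` holds objects with a ``pose`` attribute (or ViewPose
    directly).  Returns (selected, remaining): the view minimizing the
    Euclidean (phi, theta) distance in degrees, removed from the pool so a
    view is never reused; ties break toward smaller |theta - 90|, then
    smaller phi.
    """
    items = list(available)
    if not items:
        raise ValueError("no available views to select from")

    def pose_of(item):
        return item if isinstance(item, ViewPose) else item.pose

    keys = [
        (
            round(_angular_distance(target, pose_of(it)), 9),
            abs(pose_of(it).theta_deg - 90.0),
            pose_of(it).phi_deg,
        )
        for it in items
    ]
    best = min(range(len(items)), key=lambda i: keys[i])
    selected = items.pop(best)
    return selected, items
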