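"""Learned stand-in for the detectability oracle.

A regression model maps the current (noisy) projection image to the 11
detectability values of the candidate next views, so trajectory planning
needs no 3D information at scan time.  Training pairs are built exactly as
the planner will consume them: for every admissible grid pose, a noisy
projection of a randomized phantom is the input and the 11 ground-truth
map values at (phi+5, theta+delta) are the targets, normalized per
detectability map to [0, 1] (the planner only needs relative values).

The regressor is a multilayer perceptron on block-pooled, standardized
log-projections; pooling plays the role of the convolutional feature
reduction at desk scale.  Splits are by phantom seed, never by pose, so
overlapping views cannot leak between train and test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .detectability import (
    DetectabilityConfig,
    DetectabilityMap,
    build_targets,
    detectability_map,
)
from .geometry import CArmGeometry, ViewPose, grid_views
from .phantom import PhantomConfig, make_phantom
from .projector import (
    ProjectionImage,
    Spectrum,
    forward_project_poly,
    inject_noise,
    log_normalize,
)

__all__ = [
    "DatasetConfig",
    "SurrogateDataset",
    "SurrogatePredictor",
    "build_dataset",
    "train_surrogate",
    "predict_detectability",
    "save_model",
    "load_model",
]

THETA_MARGIN_DEG = 25.0  # targets reach theta +/- 25: inputs need this margin


@dataclass(frozen=True)
class DatasetConfig:
    """Grid and noise protocol for surrogate training data."""

    phi_step_deg: float = 5.0  # detectability-map grid step
    input_phi_step_deg: float = 10.0  # azimuthal stride of training inputs
    theta_min_deg: float = 45.0
    theta_max_deg: float = 135.0
    noise_photons_per_pixel: float = 1.0e5
    pool_factor: int = 5  # block-mean pooling of the input images
    drr_step_mm: float | None = None  # ray sampling step of the input DRRs
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    detectability: DetectabilityConfig = field(default_factory=DetectabilityConfig)


@dataclass
class SurrogateDataset:
    """Training archive: pooled input images, 11-target vectors, metadata."""

    inputs: np.ndarray  # (n, h, w) standardized pooled log-projections
    targets: np.ndarray  # (n, 11), per-map normalized
    phi_deg: np.ndarray
    theta_deg: np.ndarray
    seed_ids: np.ndarray
    maps: dict  # seed -> DetectabilityMap (normalized), for evaluation
    config: DatasetConfig

    def split(self, test_seeds) -> tuple["SurrogateDataset", "SurrogateDataset"]:
        """Held-out split by phantom seed."""
        test_seeds = set(int(s) for s in test_seeds)
        te = np.isin(self.seed_ids, list(test_seeds))
        tr = ~te

        def take(mask):
            return SurrogateDataset(
                self.inputs[mask], self.targets[mask], self.phi_deg[mask],
                self.theta_deg[mask], self.seed_ids[mask],
                {s: m for s, m in self.maps.items() if (s in test_seeds) == (mask is te)},
                self.config,
            )

        return take(tr), take(te)

    def save(self, path) -> None:
        np.savez(
            path,
            inputs=self.inputs, targets=self.targets,
            phi_deg=self.phi_deg, theta_deg=self.theta_deg, seed_ids=self.seed_ids,
            map_seeds=np.array(sorted(self.maps)),
            map_d2=np.stack([self.maps[s].d2 for s in sorted(self.maps)]),
            map_phi=self.maps[next(iter(self.maps))].phi_deg,
            map_theta=self.maps[next(iter(self.maps))].theta_deg,
        )

    @classmethod
    def load(cls, path, config: DatasetConfig | None = None) -> "SurrogateDataset":
        with np.load(path) as d:
            maps = {
                int(s): DetectabilityMap(d["map_d2"][i], d["map_phi"], d["map_theta"])
                for i, s in enumerate(d["map_seeds"])
            }
            return cls(
                d["inputs"], d["targets"], d["phi_deg"], d["theta_deg"],
                d["seed_ids"], maps, config or DatasetConfig(),
            )


def _pool(image: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean pooling, cropping to a multiple of the factor."""
    h = (image.shape[0] // factor) * factor
    w = (image.shape[1] // factor) * factor
    return (
        image[:h, :w]
        .reshape(h // factor, factor, w // factor, factor)
        .mean(axis=(1, 3))
    )


def preprocess_projection(
    img: ProjectionImage | np.ndarray, pool_factor: int = 5
) -> np.ndarray:
    """Noisy intensity projection -> standardized pooled log-image."""
    if isinstance(img, ProjectionImage):
        if img.kind == "intensity":
            img = log_normalize(img)
        pixels = img.pixels
    else:
        pixels = np.asarray(img, dtype=float)
    pooled = _pool(pixels, pool_factor)
    std = pooled.std()
    return (pooled - pooled.mean()) / (std if std > 0 else 1.0)


def admissible_input_poses(cfg: DatasetConfig) -> list[ViewPose]:
    """Grid poses usable as training inputs: all 11 targets stay on-grid
    (25-degree interior margin in theta) and the azimuth matches the
    configured input stride."""
    map_views = grid_views(
        0.0, 360.0, cfg.theta_min_deg, cfg.theta_max_deg, cfg.phi_step_deg
    )
    stride = int(round(cfg.input_phi_step_deg / cfg.phi_step_deg))
    return [
        p
        for p in map_views
        if cfg.theta_min_deg + THETA_MARGIN_DEG
        <= p.theta_deg
        <= cfg.theta_max_deg - THETA_MARGIN_DEG
        and round(p.phi_deg / cfg.phi_step_deg) % stride == 0
    ]


def _normalized(dmap: DetectabilityMap) -> DetectabilityMap:
    lo, hi = dmap.d2.min(), dmap.d2.max()
    span = hi - lo if hi > lo else 1.0
    return DetectabilityMap((dmap.d2 - lo) / span, dmap.phi_deg, dmap.theta_deg)


def build_dataset(
    phantom_seeds,
    geom: CArmGeometry,
    spectrum: Spectrum,
    config: DatasetConfig | None = None,
    progress: bool = False,
) -> SurrogateDataset:
    """Simulate the paired clean/noisy training protocol for each phantom.

    Per seed: a randomized phantom, its per-view ground-truth detectability
    map on the full (phi, theta) grid (from clean physics), and one noisy
    projection per admissible input pose (theta within the 25-degree
    margin, azimuths at the configured stride).  Deterministic for fixed
    seeds.
    """
    cfg = config or DatasetConfig()
    inputs, targets, phis, thetas, seed_ids = [], [], [], [], []
    maps: dict[int, DetectabilityMap] = {}
    map_views = grid_views(
        0.0, 360.0, cfg.theta_min_deg, cfg.theta_max_deg, cfg.phi_step_deg
    )
    admissible = admissible_input_poses(cfg)
    for seed in phantom_seeds:
        seed = int(seed)
        phantom = make_phantom(seed=seed, config=cfg.phantom)
        dmap = _normalized(
            detectability_map(phantom, geom, map_views, spectrum, cfg.detectability)
        )
        maps[seed] = dmap
        for i, pose in enumerate(admissible):
            clean = forward_project_poly(
                phantom, geom, pose, spectrum, step_mm=cfg.drr_step_mm
            )
            noise_seed = int(
                np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31)
            )
            noisy = inject_noise(clean, cfg.noise_photons_per_pixel, noise_seed)
            inputs.append(preprocess_projection(noisy, cfg.pool_factor))
            targets.append(build_targets(dmap, pose))
            phis.append(pose.phi_deg)
            thetas.append(pose.theta_deg)
            seed_ids.append(seed)
    if not inputs:
        raise ValueError("no admissible training poses on the grid")
    return SurrogateDataset(
        np.stack(inputs).astype(np.float32),
        np.stack(targets).astype(np.float64),
        np.array(phis), np.array(thetas), np.array(seed_ids), maps, cfg,
    )


class SurrogatePredictor:
    """Planner-facing predictor: noisy projection image -> 11-vector."""

    def __init__(self, model, pool_factor: int = 5):
        self.model = model
        self.pool_factor = pool_factor

    def __call__(self, image, pose: ViewPose) -> np.ndarray:
        if image is None:
            raise ValueError("surrogate predictor requires a projection image")
        x = preprocess_projection(image, self.pool_factor).ravel()[None, :]
        if x.shape[1] != self.model.n_features_in_:
            raise ValueError(
                f"input has {x.shape[1]} features, model expects {self.model.n_features_in_}"
            )
        return np.asarray(self.model.predict(x)[0], dtype=float)


def _augment(inputs: np.ndarray, targets: np.ndarray, rng, max_rot_deg: float):
    """Small random in-plane rotations of the pooled images."""
    from scipy.ndimage import rotate

    out_x, out_y = [inputs], [targets]
    angles = rng.uniform(-max_rot_deg, max_rot_deg, size=len(inputs))
    rotated = np.stack(
        [
            rotate(img, ang, reshape=False, order=1, mode="nearest")
            for img, ang in zip(inputs, angles)
        ]
    )
    out_x.append(rotated.astype(np.float32))
    out_y.append(targets)
    return np.concatenate(out_x), np.concatenate(out_y)


def train_surrogate(
    dataset: SurrogateDataset,
    epochs: int = 300,
    seed: int = 0,
    hidden_layer_sizes: tuple[int, ...] = (256, 64),
    augment_rotation_deg: float = 3.0,
    alpha: float = 1.0e-3,
    learning_rate_init: float = 1.0e-3,
):
    """Fit the MLP regressor; returns (model, loss_history).

    Mean-squared-error objective on the per-map-normalized targets;
    augmentation adds one small-random-rotation copy of every input.
    Deterministic for a fixed seed.
    """
    from sklearn.neural_network import MLPRegressor

    if len(dataset.inputs) == 0:
        raise ValueError("empty dataset")
    x = dataset.inputs.reshape(len(dataset.inputs), -1).astype(np.float64)
    y = dataset.targets
    if augment_rotation_deg > 0:
        rng = np.random.default_rng(seed)
        xi, y = _augment(dataset.inputs, y, rng, augment_rotation_deg)
        x = xi.reshape(len(xi), -1).astype(np.float64)
    model = MLPRegressor(
        hidden_layer_sizes=hidden_layer_sizes,
        activation="relu",
        solver="adam",
        learning_rate_init=learning_rate_init,
        alpha=alpha,
        max_iter=epochs,
        random_state=seed,
        tol=0.0,
        n_iter_no_change=epochs,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warning at fixed epochs
        model.fit(x, y)
    return model, list(model.loss_curve_)


def predict_detectability(predictor, image, pose: ViewPose) -> np.ndarray:
    """Uniform entry point: works for the oracle adapter and the model."""
    out = np.asarray(predictor(image, pose), dtype=float)
    if out.shape != (11,) or not np.all(np.isfinite(out)):
        raise ValueError("predictor must return a finite 11-vector")
    return out


def save_model(path, model, pool_factor: int = 5) -> None:
    """Serialized weights plus a JSON preprocessing spec sidecar."""
    import joblib

    joblib.dump(model, path)
    spec = {"pool_factor": pool_factor, "standardize": "per-image zero mean unit variance"}
    with open(str(path) + ".json", "w") as fh:
        json.dump(spec, fh, indent=2)


def load_model(path) -> SurrogatePredictor:
    import joblib

    model = joblib.load(path)
    with open(str(path) + ".json") as fh:
        spec = json.load(fh)
    return SurrogatePredictor(model, pool_factor=spec["pool_factor"])
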