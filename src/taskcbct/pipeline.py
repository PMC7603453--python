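"""Stage-based pipeline orchestration with a reproducibility manifest.

Every stage reads its inputs from the artifact directory, writes its
outputs there, and records input/output SHA-256 hashes plus the resolved
configuration in ``manifest.json``.  Stages are deterministic functions of
(config, seed), so re-running a stage reproduces its artifacts
byte-for-byte; a stage whose upstream artifact is missing fails with an
error naming the stage to run first.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .config import RunConfig, save_config
from .detectability import DetectabilityMap
from .geometry import ViewPose
from .metrics import MetricReport
from .phantom import canonical_phantom, make_phantom, save_phantom, load_phantom
from .planner import (
    OracleMapPredictor,
    Trajectory,
    circular_trajectory,
    plan_trajectory,
)
from .projector import forward_project_poly, inject_noise, spectrum_preset
from .recon import ReconVolume, reconstruct
from .surrogate import (
    DatasetConfig,
    SurrogateDataset,
    SurrogatePredictor,
    build_dataset,
    load_model,
    save_model,
    train_surrogate,
)

__all__ = ["STAGES", "run_pipeline"]

STAGES = ("simulate", "map", "dataset", "train", "plan", "recon", "evaluate")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path):
        self.path = outdir / "manifest.json"
        self.data = json.loads(self.path.read_text()) if self.path.exists() else {}

    def record(self, stage: str, inputs: list[Path], outputs: list[Path], seed: int):
        self.data[stage] = {
            "seed": seed,
            "inputs": {p.name: _sha256(p) for p in inputs if p.exists()},
            "outputs": {p.name: _sha256(p) for p in outputs if p.exists()},
        }
        self.path.write_text(json.dumps(self.data, indent=2))


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path.name}: run the '{stage}' stage first"
        )
    return path


def run_pipeline(config: RunConfig, stages, outdir, retrospective: bool = False) -> Path:
    """Execute the requested pipeline stages into an artifact directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_config(outdir / "config.yaml", config)
    manifest = _Manifest(outdir)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}; valid: {STAGES}")
    spectrum = spectrum_preset(config.spectrum_preset, config.photons_per_pixel)

    phantom_path = outdir / "phantom.nii.gz"
    map_path = outdir / "map.npz"
    dataset_path = outdir / "dataset.npz"
    model_path = outdir / "model.joblib"
    traj_path = outdir / "trajectory.csv"
    scores_path = outdir / "scores.jsonl"
    volume_path = outdir / "volume.nii.gz"
    report_path = outdir / "report.json"

    if "simulate" in stages:
        phantom = (
            canonical_phantom(config.phantom)
            if config.canonical
            else make_phantom(config.seed, config.phantom)
        )
        save_phantom(phantom_path, phantom)
        manifest.record("simulate", [], [phantom_path], config.seed)

    if "map" in stages:
        from .experiments import compute_map

        phantom = load_phantom(_require(phantom_path, "simulate"))
        dmap = compute_map(phantom, config)
        dmap.save(map_path)
        dmap.to_dataframe().to_csv(outdir / "map.csv", index=False)
        manifest.record("map", [phantom_path], [map_path], config.seed)

    if "dataset" in stages:
        ds_cfg = DatasetConfig(
            phi_step_deg=config.grid_phi_step_deg,
            input_phi_step_deg=config.input_phi_step_deg,
            theta_min_deg=config.grid_theta_min_deg,
            theta_max_deg=config.grid_theta_max_deg,
            noise_photons_per_pixel=config.noise_photons_per_pixel or config.photons_per_pixel,
            pool_factor=1,
            drr_step_mm=1.0,
            phantom=config.phantom,
            detectability=config.detectability,
        )
        geom = config.geometry.scaled_detector(4)
        ds = build_dataset(
            list(config.train_seeds) + list(config.test_seeds), geom, spectrum, ds_cfg
        )
        ds.save(dataset_path)
        manifest.record("dataset", [], [dataset_path], config.seed)

    if "train" in stages:
        ds = SurrogateDataset.load(_require(dataset_path, "dataset"))
        train, _ = ds.split(config.test_seeds)
        model, losses = train_surrogate(train, epochs=config.epochs, seed=config.seed)
        save_model(model_path, model, pool_factor=1)
        (outdir / "loss_history.json").write_text(json.dumps(losses))
        manifest.record("train", [dataset_path], [model_path], config.seed)

    if "plan" in stages:
        start = ViewPose(config.start_phi_deg, config.start_theta_deg)
        if model_path.exists():
            predictor = load_model(model_path)
            geom = config.geometry.scaled_detector(4)
            phantom = load_phantom(_require(phantom_path, "simulate"))

            def acquire(pose):
                img = forward_project_poly(phantom, geom, pose, spectrum, step_mm=1.0)
                if config.noise_photons_per_pixel:
                    sub = int(
                        np.random.SeedSequence([config.seed, pose.t or 0])
                        .generate_state(1)[0] % (2**31)
                    )
                    img = inject_noise(img, config.noise_photons_per_pixel, sub)
                return img

        elif map_path.exists():
            predictor = OracleMapPredictor(DetectabilityMap.load(map_path), config.delta_phi_deg)
            acquire = None
        else:
            raise FileNotFoundError(
                "planning needs map.npz (run 'map') or model.joblib (run 'train')"
            )
        if retrospective:
            traj = _plan_retrospective(config, predictor, acquire, start)
        else:
            traj = plan_trajectory(
                predictor, start, config.n_views,
                lam=config.lam, delta_phi_deg=config.delta_phi_deg,
                theta_abs_bounds=(config.grid_theta_min_deg, config.grid_theta_max_deg),
                acquire=acquire,
            )
        traj.to_csv(traj_path)
        with open(scores_path, "w") as fh:
            for t, s in enumerate(traj.scores):
                fh.write(json.dumps({"t": t + 1, "score": s}) + "\n")
        manifest.record("plan", [map_path, model_path], [traj_path, scores_path], config.seed)

    if "recon" in stages:
        from .experiments import reconstruct_trajectory

        phantom = load_phantom(_require(phantom_path, "simulate"))
        traj = Trajectory.from_csv(_require(traj_path, "plan"))
        vol = reconstruct_trajectory(
            phantom, config.recon_geometry, traj, spectrum,
            config.noise_photons_per_pixel, config, config.seed,
        )
        vol.save(volume_path)
        manifest.record("recon", [phantom_path, traj_path], [volume_path], config.seed)

    if "evaluate" in stages:
        from .experiments import _volume_metrics

        from .metrics import screw_profiles

        phantom = load_phantom(_require(phantom_path, "simulate"))
        vol = ReconVolume.load(_require(volume_path, "recon"))
        entry = _volume_metrics(vol, phantom)
        report = MetricReport(fwhm_mm=entry["fwhm_mm"], thread_peak=entry["thread_peak"])
        report_path.write_text(json.dumps(report.to_dict(), indent=2))
        if phantom.screws:
            import pandas as pd

            frames = []
            for k, screw in enumerate(phantom.screws):
                df = screw_profiles(vol, screw)
                df.insert(0, "screw", k)
                frames.append(df)
            pd.concat(frames).to_csv(outdir / "profiles.csv", index=False)
        manifest.record("evaluate", [volume_path], [report_path], config.seed)

    return outdir


def _plan_retrospective(config: RunConfig, predictor, acquire, start: ViewPose) -> Trajectory:
    """Nearest-sampled-view planning over a synthetic multi-orbit pool.

    Emulates the calibrated-short-scan protocol: 17 tilted/swiveled orbits
    sample the view sphere; each planned target is replaced by the closest
    available sampled view, which is then removed from the pool.
    """
    from .geometry import tilted_orbit_views
    from .planner import PlannerState, next_view, retrospective_select
    from dataclasses import replace as _replace

    rng = np.random.default_rng(config.seed)
    pool: list[ViewPose] = []
    pool.extend(tilted_orbit_views(0.0, 0.0, 72))  # untilted reference orbit
    for _ in range(16):
        tilt = float(rng.uniform(-30, 30))
        swivel = float(rng.uniform(-20, 20))
        pool.extend(tilted_orbit_views(tilt, swivel, 72))
    state = PlannerState(
        current=start, lam=config.lam, delta_phi_deg=config.delta_phi_deg,
        theta_abs_bounds=(config.grid_theta_min_deg, config.grid_theta_max_deg),
    )
    poses = [start]
    offsets = state.theta_offsets
    for _ in range(config.n_views - 1):
        image = acquire(state.current) if acquire is not None else None
        predictions = predictor(image, state.current)
        target, idx = next_view(predictions, state)
        chosen, pool = retrospective_select(target, pool)
        direction = (config.delta_phi_deg, offsets[idx])
        state = _replace(state, current=target, prev_direction=direction)
        poses.append(chosen)
    return Trajectory(poses)
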