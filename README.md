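# taskcbct

Task-aware C-arm cone-beam CT (CBCT) trajectory planning, simulation and
reconstruction — a desk-scale toolkit for studying how *where you look*
affects metal-artifact severity around pedicle screws.

Intraoperative CBCT of spinal-fusion screws suffers from beam hardening
and photon starvation: views whose rays travel along a screw's long axis
are grossly inconsistent with the linear reconstruction model and seed
streaks and blooming.  Instead of correcting corrupted data after the
fact, this package adjusts the *acquisition*: it scores every candidate
source position (in-plane angle φ, out-of-plane angle θ) with the
non-prewhitening-observer detectability index

    d²(φ,θ) = [∭ |MTF|² |W_task|² df³]² / ∭ NPS |MTF|² |W_task|² df³

where the local MTF and NPS of penalized-likelihood reconstruction are
derived per view by forward projecting an impulse at the task location,
weighting by expected counts, and backprojecting (so metal-crossed views
collapse), and W_task is a band-pass at the screw-thread frequency.  A
greedy planner advances φ by a fixed increment and picks the θ step
maximizing `λ·(u·v_i) + p̂_i` (predicted detectability plus a cosine
smoothness reward, λ = 0.6) under absolute θ ∈ [45°, 135°] and ±45°
relative excursion constraints.  The predictions come either from the
analytic oracle (requires the 3D scene) or from a learned surrogate that
regresses the 11 candidate detectabilities from the current X-ray image
alone.  Planned scans are reconstructed with CGLS using a matched
cone-beam projector pair and compared against circular reference scans by
screw FWHM (blooming), thread-frequency peak (thread conspicuity), and
SSIM to an artifact-free ground truth.

The package is aimed at researchers in tomographic acquisition
optimization who want a self-contained, CPU-friendly sandbox: everything
(phantoms, spectra, projections, maps, trajectories) is generated
procedurally — no external data.

## Worked example

Plan a task-aware scan of the canonical two-screw phantom with the
analytic oracle, reconstruct it, and quantify screw quality:

```python
import numpy as np

from taskcbct.config import RunConfig
from taskcbct.experiments import compute_map, plan_task_aware, reconstruct_trajectory
from taskcbct.metrics import screw_fwhm
from taskcbct.phantom import canonical_phantom
from taskcbct.planner import circular_trajectory
from taskcbct.projector import spectrum_preset
from taskcbct.geometry import ViewPose

cfg = RunConfig()
phantom = canonical_phantom()
dmap = compute_map(phantom, cfg)               # d2 over the 72x19 view grid
traj = plan_task_aware(phantom, dmap, cfg)     # 40-view, 200-degree scan
circ = circular_trajectory(ViewPose(0, 90), 40)
print(f"summed d2: task {traj.summed_d2(dmap):.3g}  circular {circ.summed_d2(dmap):.3g}")

spectrum = spectrum_preset("poly5", 1e5)       # hardened 5-bin beam
vol = reconstruct_trajectory(phantom, cfg.recon_geometry, traj, spectrum, None, cfg)
fwhm = float(np.mean([screw_fwhm(vol, s) for s in phantom.screws]))
print(f"screw FWHM: {fwhm:.2f} mm")
```

Output (values from the shipped defaults):

```
summed d2: task 8.23e+06  circular 7.17e+06
screw FWHM: 5.28 mm
```

The planned trajectory collects ~15% more detectability than the circular
scan because it tilts away from θ = 90° around φ ≈ 90° — the azimuth where
rays run along the screws' axes — and the reconstructed screws bloom less
than in the circular reconstruction (≈ 5.7 mm circular against a
≈ 5.4 mm artifact-free ground truth at the same scale).

The same experiment runs from the shell:

```
taskcbct all --stages simulate,map,plan,recon,evaluate -o run/ --seed 0
```

which writes `trajectory.csv` (`t,phi_deg,theta_deg`), `volume.nii.gz`,
`report.json`, and a `manifest.json` of artifact hashes; any run is
reproducible from its logged `config.yaml` and seed alone.

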