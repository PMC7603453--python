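# Methods

`taskcbct` simulates task-aware C-arm cone-beam CT (CBCT) acquisition
planning at desk scale: it builds a screw phantom, scores every candidate
source position with a task-based detectability index, greedily plans a
non-circular source trajectory (from the analytic oracle or from a learned
surrogate that sees only the current X-ray image), reconstructs, and
quantifies metal-artifact reduction against a circular reference scan.
This note records the models, the defaults and why they were chosen, the
numerical decisions, and the limits of what the synthetic experiments can
show.

## View parameterization and geometry

A view is an in-plane angle φ (position along a conventional circular
orbit) and an out-of-plane angle θ (tilt of the source–detector axis out
of the orbit plane).  θ is the polar angle from the fixed rotation axis
(world +z); θ = 90° is the untilted orbit.  Angles are degrees, lengths
millimetres, detector pixels 0-based at pixel centers.  The projection
model is an ideal pinhole: source on the sphere of radius
`source_to_isocenter_mm`, detector perpendicular to the source–isocenter
ray at `source_to_detector_mm`, yielding a rank-3 3×4 matrix mapping world
coordinates to (column, row) pixels.  The default geometry is a
flat-panel C-arm at 500 mm source–isocenter / 1000 mm source–detector
distance with the central 480×620 panel region at 0.31 mm pitch binned
4×4 to 120×155 at 1.24 mm (full-size available via
`CArmGeometry.full_size()`).  Reconstruction experiments use a further
reduced 80×104 panel at 1.86 mm pitch so that the detector sampling
(≈0.93 mm at the isocenter) matches the 1.33 mm reconstruction voxel.

Multi-orbit acquisitions taken in different object poses are fused by
composing each orbit's matrices with the inverse of the rigid transform
that aligns its reconstruction to the reference volume
(`apply_registration`): a feature at position y in the moved frame sits at
x = T(y) in the reference frame, so `P @ T⁻¹` projects reference
coordinates onto the moved acquisition's images.

## Phantom

The canonical scene mirrors a semianthropomorphic bench phantom: a wooden
box (80×40×80 mm) whose long axis lies **along the rotation axis** — like
a patient's long axis, with a square x–z cross-section so a 45° diagonal
crossing is longer than any axis-aligned one and out-of-plane tilting
costs path length; two titanium screws (40 mm long, 2.5 mm shaft radius, 3 mm thread
pitch, 0.75 mm thread depth, single-start helical ridge with π/2 phase
half-width) drilled through the box along +y, separated 12 mm in x and
16 mm in z (drilled at different heights, so the in-plane view orthogonal
to their axes crosses only one screw); and two ballistic-gel cylinders
(10 mm radius, 60 mm tall) standing beside the box at y = ±34 mm.  The
screw-height offset matters: with coplanar screws the orthogonal view is
doubly attenuated and extreme tilts dominate the detectability map
everywhere, which degenerates planned trajectories into boundary rings.
Randomized scenes draw object translations within ±15 mm and screw-axis
tilts within ±20° (bounded retries enforce non-intersecting screws);
generation is a pure function of (seed, config).

Linear attenuation tables (mm⁻¹, 20–150 keV, log-log interpolated) embed
water-equivalent gel, a cellulose-like wood, elemental titanium at
4.506 g/cm³, and air as a vacuum surrogate (μ ~ 1e-13, so an all-air scene
transmits to 1e-9 relative accuracy).

## Forward projection and noise

The polyenergetic projector traces each detector pixel's ray from the
projection matrix (camera center + pseudo-inverse directions), samples the
labelled volume uniformly between the ray's bounding-box entry and exit
(default step 0.5 × voxel) with nearest-voxel lookup, and accumulates
per-material path lengths l_m whose sum equals the ray–grid intersection
length exactly.  Intensity is the spectrum-weighted Beer–Lambert sum
I = Σ_E S(E) exp(−Σ_m μ_m(E) l_m).  Spectrum presets: `mono60` (no beam
hardening; used for artifact-free ground truth), `poly2` (two bins,
closed-form checks), and `poly5`, a hardened five-bin bremsstrahlung-like
shape used for all experiments; the presets are package configuration, not
claimed tube spectra.  Poisson noise is parameterized by unattenuated
photons per detector pixel (the experiments use 5·10⁴, 1·10⁵ and 4·10⁵
photons/pixel); line integrals are p = ln(I₀ / max(I, 0.5))
with a 0.5-count floor guarding photon starvation, which is the physical
regime behind metal streaks.

## Detectability index

Candidate views are scored with the non-prewhitening observer index

    d² = [ΣΣΣ |MTF|² |W_task|² Δf³]² / ΣΣΣ NPS |MTF|² |W_task|² Δf³

computed from the *local* Fisher information of penalized-likelihood
reconstruction at a task voxel j.  Per view, the unit impulse at j is
forward projected (footprint a = A e_j), weighted pixel-wise by the
expected noise-free counts, backprojected into a patch around j, and the
patch's 3D DFT magnitude F gives MTF = F/(F + βR) and NPS = F/(F + βR)²
with R the DFT magnitude of the 6-neighbor quadratic penalty stencil.
Views with long titanium traversals collapse the count weights and hence
d² — the mechanism that steers planning away from views along the screws'
long axes.

Numerical realization: the voxel basis is a rotationally symmetric
Gaussian blob (σ = 0.6 voxel) whose line integrals have the closed form
√(2π)σ·exp(−ρ²/2σ²) (ρ = perpendicular ray distance), the patch
(half-width 8 voxels) is sampled on a 2× supersampled lattice under a
Gaussian localization window (σ = h/2.5) restricted to the inscribed
sphere, and the DFT is zero-padded 1.5×.  Each of these choices removes a
specific lattice artifact: cubic bases and sharp windows make single-view
d² ripple by 7–45 % under in-plane rotation, while this construction keeps
the per-view map of an all-air scene φ-constant to <1 %.  β defaults to 10
*per unit incident fluence* (the effective penalty is β × photons/pixel),
which keeps the MTF transition on the resolved information plane; much
larger values suppress the task band and reintroduce sampling ripple.
W_task is a radial Gaussian band-pass at the thread frequency (1/pitch =
1/3 cycles/mm, width half the center frequency, zero at DC), and the task
voxel defaults to the mid-shaft point of the first screw — the object
whose placement the task verifies.  (With the task voxel midway *between*
the screws, the impulse footprint's rays pass between the shafts for
views along the screw axes and the avoidance mechanism vanishes; the
between-screws choice remains available in the configuration.)

Ground-truth maps for *training labels* are per-view (each grid pose
scored from its own single-view Fisher information, matching one scalar
label per training projection).  The *oracle planner* in the end-to-end
comparison uses the cumulative form by default: candidates are scored by
the marginal d² gain of adding them to the views acquired so far, which
is the trajectory-level reading of the observer index (its MTF/NPS are
defined over all views in a trajectory).  The distinction matters: pure
per-view planning ignores angular-coverage complementarity and degenerates
into rings at the tilt bound, sacrificing tomographic completeness; the
marginal-gain oracle assigns redundant views vanishing gain and produces
varied orbits that reconstruct better.  Per-view oracle planning remains
available (`planner_oracle: per-view`).

## Planner

φ advances by a fixed Δφ (5° in simulation, menu rescaled for other Δφ so
the maximum slope matches the 25°/5° training ratio); θ moves by the
candidate offset δ ∈ {−25°,…,+25°} maximizing λ(u·v_i) + p̂_i, where u is
the previous direction in (Δφ, Δθ), v_i the candidate direction, λ = 0.6,
and p̂ the per-step min–max normalization of the 11 predicted
detectabilities (selection is an argmax over candidates — adding the
score directly to the angle would be dimensionally inconsistent — and the
normalization makes λ meaningful independent of the d² scale).  The cosine term is skipped at t = 0 (no previous direction), and
score ties resolve toward the smallest |δ| so an uninformative prediction
continues the current orbit.  θ is doubly constrained: absolute bounds
[45°, 135°] and ±45° excursion from the start.  Because each decision
depends only on (pose, previous direction), deterministic predictors give
the merge property: trajectories that meet in state continue identically.
Retrospective mode (the calibrated-real-data protocol) replaces each
planned target by the nearest available view from a pre-sampled
multi-orbit pool (17 tilted/swiveled orbits by default), removing it from
the pool; ties break toward smaller |θ−90|, then smaller φ.

## Surrogate

The learned stand-in for the oracle maps a noisy projection to the 11
next-view detectabilities.  Training data follow the paired protocol: per
phantom seed, a per-view map on the full 5° grid from clean physics, and
one noisy projection (10⁵ photons/pixel) per admissible input pose (25°
interior θ margin).  Targets are normalized per map to [0, 1] — the
planner needs only relative values.  The regressor is a scikit-learn
multilayer perceptron (two hidden layers, 256/64 ReLU units, Adam, MSE)
on 4×-binned, log-normalized, per-image standardized projections
(30×38); binning plays the role of convolutional feature reduction at
desk scale.  Splits are by phantom seed, never by pose.  Augmentation by
small random image rotations is available (default on, ±3°).

## Reconstruction and registration

CGLS on the linear system A x = p with a matched nearest-voxel ray-driven
projector pair (adjoint exact to rounding; matched pairs are what make
the residual decrease monotonically).  Desk defaults: 72³ volume at
1.33 mm (thread frequency 1/3 cycles/mm stays under the 0.375 cycles/mm
voxel Nyquist), 30 iterations, 200° short scan with 40 views; SIRT is
provided as a fallback.  Truncation is handled by masking pixels whose
rays miss a 50 mm sphere at the isocenter.  Rigid registration maximizes
normalized cross-correlation over the 6 rigid parameters with a coarse
translation grid followed by derivative-free Powell refinement (any derivative-free local maximizer serves here).

## Metrics

Screw FWHM: profiles perpendicular to the known screw axis through the
shaft at two axial positions (35 % and 65 % of the length), 10 mm long so
the neighboring screw stays outside, half-maximum above the profile
minimum, linear sub-sample interpolation, averaged per screw.  Thread
peak: a 2D patch through the screw axis (shaft ± 2 mm margin) is
standardized, 1D spectra along the axis are averaged across the
perpendicular direction and read at the bin nearest 1/pitch.  SSIM uses a
7-pixel Gaussian window (σ=1) with K₁=0.01, K₂=0.03 and the reference
slice's dynamic range.  Trajectory comparisons use per-φ |Δθ| statistics
(mean and population standard deviation) and the relative summed-d²
difference in percent.

In the end-to-end comparison the circular reference overshoots the
ground-truth thread peak — metal artifacts inject spurious content at the
thread frequency — so a bare "higher is better" reading would be wrong; the
meaningful statement, asserted by the test suite, is that the
task-aware arm lands *closer to the ground-truth value* (and at or below
the circular FWHM, with higher SSIM).  Two protocol details are desk-scale
adaptations: SSIM compares each arm against the monoenergetic noise-free
reconstruction of *its own* trajectory, because at 40 views per scan a
single shared reference is dominated by orbit-geometry (sparse-view)
differences rather than by the metal artifacts under study; and the SSIM
slice metric averages a 4 mm-spaced axial slab spanning both screw
heights, since the screws sit at different levels and no single axial
slice contains both.

## Problem sizes

Experiments are desk-scaled so the full suite runs on one CPU: 120×155
binned detector for maps, 80×104 for reconstruction, 72³ recon volume,
40-view 200° scans, 8 training + 5 held-out phantom seeds for the
surrogate with inputs every 10° of φ.  Full-size settings (620×480 panel,
200 views at Δφ = 1°, 300 iterations) remain available through the
configuration; all quality claims asserted by the tests are orderings and
tolerances that do not depend on the absolute scale.

## What the synthetic study does and does not show

The generator emulates the geometry and physics that drive metal
artifacts (polyenergetic hardening, photon starvation, view-dependent
metal path lengths) but not scatter, detector blur or lag, mechanical
sag/wobble, or anatomical complexity; "realistic noise" is Poisson
counting noise.  Passing tests therefore demonstrate the internal
consistency of the pipeline and the direction of the task-aware benefit
under ideal-geometry simulation — not clinical performance on real
anatomy, real detectors, or real screw hardware.

## Known limitations

- Per-view detectability ignores angular-coverage complementarity between
  views; cumulative mode exists but is quadratically more expensive and
  untested as a training label.
- The surrogate generalizes across randomized phantoms of the same family
  only; ±θ ambiguity of near-symmetric scenes is the dominant error mode.
- The NCC registration basin is a few degrees/millimetres wide; larger
  initial misalignments need a better global initializer than the coarse
  translation grid.
- Nearest-voxel recon projectors trade accuracy for speed; the matched
  adjoint keeps CGLS sound, but high-contrast edges show mild staircase
  texture at desk resolution.
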