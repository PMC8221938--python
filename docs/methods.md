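# Methods

## Model and conventions

refocal models the remote-focus path paraxially: a remote-focus unit whose
output plane carries a spherical wavefront of curvature `κ` (mm⁻¹) and a
central-ray tilt `(θx, θy)` (rad), an ideal thin objective of focal length
`f` (mm), and a flat interface into an immersion medium of index `n`.
Misalignment of the unit output from the telecentric plane (one focal
length before the objective) is described by three parameters: `Z_ERROR`
(axial, mm, signed) and `X_ERROR`, `Y_ERROR` (lateral, mm).  Units are
fixed throughout: optical lengths in mm, curvature in mm⁻¹, angles in rad;
focus and sample coordinates in µm.

Sign conventions, stated once and used everywhere:

* `z_RF` is measured from the natural focal plane (the focus of a planar,
  `κ = 0` input) and is negative below it; for a telecentric system
  `z_RF = −n f² κ`, so positive curvature focuses below the natural plane.
* The x and y axes are independent and governed by identical equations
  (no cross terms); all lateral statements hold per axis.
* In the ray-trace module a device physically displaced by `+Δ` in ray
  space corresponds to `X_ERROR = −Δ` in the closed-form model: the
  printed lateral-focus equation fixes the sign, and the adapter
  `sequence_for_system` encodes the mapping in one place.  Published
  focus-error magnitudes can therefore be reproduced while their signs may
  differ between instruments whose axis orientations are unknown.

Conjugate-plane singularities — `|κ Z_ERROR + 1| < 1e-9` (focus at
infinity) and `|z_CORR Z_ERROR + n f²| < 1e-9 mm²` (target conjugate to
the unit output) — raise typed errors rather than returning huge values;
they are physical, not numerical, limits.

## Ray oracle and relay reduction

`refocal.rays` is an independent check on the closed forms: it propagates a
fan of paraxial rays through an explicit element sequence (free space, thin
lenses with lateral offsets, the unit output, the immersion interface) and
intersects the fan.  In paraxial optics any two rays of the fan intersect
at the same point, so a 2-ray intersection is exact; the default fan of 5
is for conditioning diagnostics only.  The trace knows nothing of the
closed-form equations, which is what makes the agreement tests (to 1e-9
relative over thousands of random systems) meaningful.

A relayed path (unit → relay lenses → objective) is reduced by
`effective_misalignment` to the single-objective parameters: the relay
images the unit output plane to a conjugate plane with transverse
magnification `m`; lateral offsets scale by `m`, axial placement by `m²`.
The reduction is exact for any imaging relay provided the commanded drive
is transformed too (`κ → κ/m² + residual relay power`, `θ → θ/m` plus any
residual tilt) — `EffectiveModel.map_drive` applies this, and it is the
identity for a unit-magnification, tilt-free relay.  A relay that images
the unit output to infinity admits no finite reduction and is rejected.
Residual constant beam tilts shift the whole field independently of depth;
because the calibration protocol references every measurement to the
natural-plane image, such a tilt is *measured* as an extra lateral
misalignment `tilt × Z_ERROR`, exposed as `registered_system`.  Note that a
single 4f lens pair has `m = −1` and inverts the field; "insert a relay and
nothing changes" holds for an `m = +1` chain (e.g. two 4f pairs).

## Calibration

The bead-slide protocol: a thin layer of ~5 µm fluorescent beads is imaged
at commanded remote foci (±200 µm in 5 µm steps by default) while the
objective is mechanically counter-displaced, keeping every plane in focus.
The scan-angle-to-image mapping is calibrated at the natural plane
(`θ = x_image / f`), so a bead at natural-plane position `x_b` appears at

    x_app = x_b (κ Z_ERROR + 1) + f κ X_ERROR      (y analogous).

Bead natural-plane positions are nuisance parameters eliminated by reading
them off the `κ = 0` reference plane (the plane of smallest |κ| a bead
appears in), not fitted.  `f` and `n` are treated as known configuration.
The fit is two-stage:

1. closed-form initialization — per-plane linear regression of apparent
   vs reference position gives slopes `a_k ≈ κ_k Z + 1` and intercepts
   `b_k ≈ f κ_k X`; regressing `(a_k − 1)` and `b_k` on `κ_k` through the
   origin yields starting values;
2. joint least squares over all observations (the model is linear in
   `X, Y, Z` given the reference positions, so convergence is immediate;
   the generic nonlinear driver is used so a robust soft-L1 loss remains
   available).  Standard errors come from the Jacobian at the optimum.

Trajectories with residual RMS above 5× the median are excluded once and
the model refit; exclusions are reported.  Degenerate designs (a single
curvature, coincident beads, no trajectories) raise rather than returning
meaningless estimates — with one bead, magnification and skew terms are
confounded (both are proportional to `κ`).

`verify_compensation` implements the published quality measure: each
bead's displacement from its natural-plane position, the maximum (and
per-bead mean ± sd) over the stack, the skew angle of the most central
bead's trajectory (arctan of the fitted x-vs-z and y-vs-z slopes), and the
coefficient of variation of the model-predicted z-plane spacing.

## Synthetic data

The generator emulates the calibration experiment, not general microscopy:
beads are rendered as 2-D Gaussian spots (default σ = 1.5 px) because the
objective counter-displacement keeps every plane in focus — there is no
axial PSF, defocus, photobleaching or scattering model.  Noise is Poisson
shot noise plus Gaussian read noise (defaults: peak 1000 counts,
background 10, read σ = 2 — bright 5 µm beads track comfortably; the
protocol's precision is not photon-starved).  Apparent bead positions come
from the same observation model the fitter inverts, so noiseless
round-trip tests isolate the tracking and fitting machinery; what passing
tests do *not* show is robustness to model mismatch (aberrated PSFs,
non-paraxial distortion, focus-dependent brightness).

Localization noise is specified as the RMS 2-D localization error in µm
(per-axis σ = value/√2); the study-condition value of 0.1 µm matches the
precision of sub-pixel tracking of bright beads at ~0.5–1 µm pixel pitch.
The default study conditions — 25 beads with ≥20 µm separation across a
260 µm field, 81 planes spanning ±200 µm, truth misalignments
(2.3, 1.3, −69) mm at f = 12.5 mm, n = 1.33 — mirror the calibration
experiment of the acousto-optic-lens instrument this package emulates.
Rendering uses 384 px images at 1 µm/px so that the distorted field
(up to ~±170 µm apparent) stays inside the frame.

When re-acquisition after calibration is simulated, the *fitted* system
supplies the drives and scan mapping (`control_system`) while the truth
system supplies the physics, so residual fit error propagates into the
verification exactly as it would on an instrument.

## Tracking

Detection: difference-of-Gaussians band-pass, local maxima above both a
relative threshold (fraction of the brightest band-passed peak) and a 5×
robust-noise floor (so noise-only frames yield nothing), then sub-pixel
refinement — an iterative Gaussian-weighted centroid by default (weighting
matched to the spot suppresses background-noise lever arms; re-centering
the kernel removes its shrinkage bias), or a full 2-D Gaussian fit.  Both
localize to ≲0.05 px at shot-noise-limited peak SNR 20.

Linking: greedy nearest-neighbour between consecutive planes within a
distance gate, with gap closing up to a configurable number of missed
planes.  Calibration stacks are sparse and inter-plane drift is smooth
(≲2 µm/plane at the default schedule), so greedy linking equals the
optimal assignment whenever drift < gate/2 and bead spacing > 2×gate; the
test suite pins this against a brute-force Hungarian-algorithm oracle.
Ties are broken by smaller distance, then lower detection index, with a
warning.

## Numerical choices and limitations

* Tolerances: singularity guards at 1e-9 (mm scale); ray-fan collimation
  at 1e-12 rad; afocality/astigmatism consistency checks at 1e-9–1e-12.
* The precompensation is algebraically exact; round-trip accuracy is
  limited only by floating point (≲1e-12 relative).
* Higher-order distortions from input-beam divergence are out of scope; a
  fit of `n f²` from z-focus-error data is likewise not implemented — `f`
  and `n` are configuration, which mirrors how instruments are calibrated.
* The model is strictly paraxial and per-axis separable: no wave optics,
  PSF aberration, chromatic effects, or x–y cross terms.
* Published experimental drift/FOV/skew magnitudes from any particular
  instrument depend on its objective focal length; with `f` unknown they
  are reproduced qualitatively (same structure, same signs up to axis
  conventions), while all closed-form identities are reproduced exactly.
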