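# Methods

## Pressure gradient from measured velocities

The package estimates the intraventricular pressure-gradient field from the
Navier–Stokes momentum balance for an incompressible Newtonian fluid,

g = −ρ ∂v/∂t − ρ (v·∇)v + μ ∇²v   [N/m³],

evaluated voxelwise from the measured velocity with finite differences on
the rectilinear acquisition grid. Assumptions: laminar flow (no turbulence
model), Newtonian rheology, rigid grid, and velocities that are accurate to
the voxel scale. Gravity and other conservative body forces are absorbed
into the pressure and do not affect force or relative-pressure results.

**Stencils.** Interior voxels use centered differences (exact for
polynomials of degree ≤ 2 per axis, truncation error O(h²)); voxels at a
domain or validity boundary fall back to first-order one-sided differences;
voxels with no valid neighbour pair along some axis are flagged invalid and
excluded from integrals, with counts reported (a warning above 5% per
frame, an error at 100%). The Laplacian uses the 7-point stencil and is
simply omitted (not invalidating the voxel) where its full stencil is
unavailable — at these resolutions the viscous term is ~3 orders of
magnitude below the inertial terms, and it can be toggled off entirely for
term-wise diagnostics.

**Temporal derivative.** Centered in time with periodic wrap-around by
default: retrospectively ECG-gated acquisitions cover the full cardiac
cycle, so frame n−1 is physically adjacent to frame 0. A non-periodic mode
(one-sided at the first/last frame) is provided for phantom runs that do
not close a cycle.

**Field-then-mask order.** g is computed on the full imaged volume and the
segmentation mask is applied only at the integration stage. Stencils at the
blood-pool boundary therefore use real measured flow on both sides instead
of zero padding, avoiding spurious boundary gradients.

**Units.** Everything internal is SI (m, s, kg); file readers convert
(cm/s is the common stored unit for 4D flow) and every output carries its
unit in the header or key name.

## Anatomical directions and cardiac phases

The basal-apical axis is the normal of the atrioventricular plane, fitted
by total least squares (centroid + smallest-variance singular vector) to
operator-placed landmarks from long-axis views; TLS is used because
landmark error is isotropic in 3D, not confined to one coordinate. Sign
conventions, which the data themselves cannot fix, are resolved by two
required hint points: b̂ points apex → base (away from the apex hint), ŝ =
normalize(b̂ × n₃ch) lies in the 3-chamber plane and points septum →
lateral wall (toward the lateral hint), â = b̂ × ŝ completes a right-handed
triad. The RV triad uses the same construction (septal-freewall parallel to
the LV septal-lateral axis). The triad is orthonormal to 10⁻¹² by
construction regardless of input noise.

End-systole defaults to the first frame where aortic outflow has fallen
below 5% of its peak while transmitral inflow has not yet exceeded 5% of
its peak, when flux ROIs are configured; the 5% thresholds operationalise
"cessation" and "initiation" on sampled curves and are overridable. The
pipeline accepts an explicit end-systole frame, and when neither ROIs nor
an override are given it falls back to the minimum of the mask volume
curve (end-systole is the minimum-volume phase by definition), with a
warning. RMS, peaks and ratios are always computed per phase, never across
the whole cycle. Peak ties break to the earliest frame.

Curve resampling to an "average heartbeat" interpolates systole and
diastole separately on normalised phase time, so phase boundaries align
across subjects; linear interpolation keeps constant and piecewise-linear
curves exact.

## Preprocessing

**Background correction.** Eddy-current phase offsets are modelled as a
first-order polynomial a + bx + cy + dz per velocity component, fitted by
least squares over static-tissue voxels and subtracted everywhere. The fit
uses the time-averaged velocity by default (the offset is stationary over
the cycle; averaging maximises SNR); a per-frame mode exists. Degenerate
static masks (coplanar voxel clouds) are rejected with the offending axis
named. The correction is idempotent to round-off.

**Unwrapping.** Velocities beyond ±VENC alias by multiples of 2·VENC. The
unwrapper applies temporal continuity per voxel (shift each frame by the
multiple of 2·VENC that minimises the jump from the previous frame — valid
when true inter-frame changes are below VENC), then a spatial pass that
shifts voxels deviating from their valid 6-neighbour median by more than
VENC. Alias-free fields pass through unchanged, and every change is an
integer multiple of 2·VENC. A checkerboard-like field (more than 30% of
voxels proposed for flipping) is declared unresolvable: warning, spatial
pass skipped. Manual per-voxel overrides are accepted as
(frame, i, j, k, component, multiple) records.

**Mask alignment.** Segmentations drawn on the cine grid are mapped to the
velocity grid by a user-supplied rigid translation followed by
nearest-neighbour resampling — masks stay binary and voxel-count bookkeeping
stays exact; integer-voxel shifts on identical grids preserve counts
exactly, cross-grid resampling errs by at most a surface layer.

## Relative pressure reconstruction

The relative pressure solves ∇p = g in the least-squares sense on the
masked domain: with G the package's own discrete gradient restricted to
mask voxels (centered in the mask interior, one-sided at the mask
boundary), the solver minimises ‖Gp − g‖² via conjugate gradients on the
normal equations GᵀG p = Gᵀg, which are the discrete pressure Poisson
equation with a Neumann-type boundary closure. Two consequences drove this
choice over a face-based multigrid discretisation: (i) a gradient field
produced by G itself is inverted *exactly* (to solver tolerance), so
gradient → Poisson → gradient round trips close at the discrete level, and
(ii) ventricular problem sizes (≲10⁵ mask voxels) converge in a few hundred
CG iterations without preconditioning, so multigrid machinery adds nothing.
Convergence: relative residual < 10⁻⁸ by default, with the residual history
attached to any failure. Pressure is defined up to a constant; the gauge is
zero mean over the mask. Disconnected masks are solved per 6-connected
component, each gauge-fixed separately, with a warning. Manufactured
solutions converge at the expected O(h²) (relative RMS error 3.5·10⁻³ at
32³). Probing interpolates trilinearly with weights restricted to mask
voxels; points outside the mask report NaN rather than extrapolating.

## Agreement statistics

Two-method agreement uses the crossed random-effects model
m_ij = A + M_j + p_i + ε_ij (i = subjects, j = two methods) with
ICC = σ̃p²/(σ̃p² + σ̃M² + σ̃ε²). Variance components are estimated by maximum
likelihood (REML available by flag; component estimates differ slightly),
with the grand mean profiled out by GLS and all three components
constrained ≥ 0 (the method component, with only two levels, is weakly
identified and frequently lands on the zero boundary — this is correct
behaviour, not a failure). The likelihood is evaluated in closed form via
the orthogonal per-subject sum/difference transform, under which the
covariance splits into two exchangeable (aI + bJ) blocks with explicit
determinants and inverses; the optimiser is L-BFGS-B from three starting
points including near-boundary ones. Interpretation bands for ICC and R²:
poor 0.00–0.30, weak 0.31–0.50, moderate 0.51–0.70, strong 0.71–0.90, very
strong 0.91–1.00.

A note on null behaviour: with zero subject variance the ICC estimate
piles up at 0 but has sampling spread ~1/√n, so at n ≈ 20 a substantial
minority of estimates still exceed 0.1; concentration below 0.1 becomes
near-total only at hundreds of subjects. The tests assert exactly this.

Bland–Altman reports mean ± SD of differences (method 2 − method 1),
percent differences against the pairwise mean (zero-mean pairs excluded
with a warning), and 1.96·SD limits of agreement. Regression is OLS of
method 2 on method 1 with R² as the squared Pearson correlation. Incomplete
pairs are dropped with a reported count.

## Synthetic scenes and what they do and do not show

Each generator stores its ground truth inside the scene and audits itself
at build time (stored force vs. quadrature of the stored analytic g over
the voxelized mask, within 0.5%), so tests never re-derive truth through
the code under test. All generators are deterministic under a fixed seed.

* **Plug flow** — v = (0, 0, V(t)) with a sinusoidal drive (defaults: 0.3
  m/s peak, 2 s cycle, 40 frames, 3 mm voxels, ~100 ml spherical mask,
  chosen to mirror a typical whole-heart 4D flow protocol). Convective and
  viscous terms vanish; force = −ρV′(t)·Volume exactly, with Volume the
  voxelized mask volume. Drives with spectral content at or above the
  frame-rate Nyquist limit are rejected.
* **Rigid rotation** — v = ω(−y, x, 0): linear in space, quadratic
  convective term, so every centered stencil is exact and g = ρω²(x, y, 0)
  to round-off; the net force over an axis-centered mask cancels by
  symmetry.
* **Pulsatile nozzle** — an axisymmetric jet from a Stokes stream function
  (Poiseuille-profiled efflux through a 25 mm nozzle with a C²-matched
  Gaussian skirt and a translating vortex-ring-like axial envelope;
  defaults 57 bpm, 12.3 ml pulse volume, 0.21 m/s peak, matching a
  desk-scale pump phantom; the ejection time follows from the pulse-volume
  constraint PV = R²·v_peak·t_ej of the half-sine drive). The 3D velocity
  is emitted as the *discrete* centered-difference curl of the analytic
  vector potential: difference operators commute, so the discrete
  divergence vanishes to round-off rather than to truncation order. A
  central-plane 2D view with the through-plane component dropped mirrors a
  planar-velocimetry acquisition. This is a kinematic stand-in, not a
  Navier–Stokes solution: its force has no closed form and its validation
  is consistency- and convergence-based.
* **Ellipsoidal ventricle** — a half-ellipsoid blood pool (flat base,
  8 cm end-diastolic long axis, defaults EDV 175 ml, EF 0.60, 60 bpm,
  typical of healthy adults) whose long axis shortens with a C¹-periodic
  raised-cosine volume drive (end-systole at 35% of the cycle). The
  interior velocity is the affine field v_z = (z−z₀)·ċ/c (long-axis
  function with a fixed base; blood crosses the base), for which
  g_z = −ρ(c̈/c)(z−z₀) exactly; an optional uniform transverse jet adds a
  closed-form transverse force for ratio testing. The base plane sits
  between voxel layers to avoid a half-voxel volume bias.
* **Corruption** — injects, in order, a linear background plane, wrapping
  into [−VENC, +VENC], and seeded Gaussian noise, recording all injections
  so preprocessing can be tested as an exact inversion in the noiseless
  case.

What these scenes do **not** emulate: measurement noise spectra and
velocity-dependent phase noise, partial-volume and segmentation error,
intra-voxel dephasing, turbulence, respiratory motion, and realistic
intraventricular flow patterns (vortex rings, inflow jets). Passing tests
therefore demonstrate that the numerical chain is correct and convergent on
resolvable flows — not that in vivo accuracy matches any particular figure;
on real data the dominant error sources are acquisition- and
segmentation-side.

## Numerical choices and problem sizes

Tolerances: Poisson relative residual 10⁻⁸ (round-trip checks at 10⁻¹⁰);
orthonormality and gauge checks at 10⁻¹²; scene self-audit at 0.5%.
Validation problem sizes were chosen as the smallest that cleanly exhibit
each property: convergence studies use three refinements (12³→48³ spatial,
20→80 frames temporal; observed orders ≥ 1.97), manufactured Poisson
solutions run at 8³–32³, ICC recovery uses 500 simulations at n = 8 with
variance ratio 1:0.1:0.1 (population ICC 1/1.2 ≈ 0.833, recovered mean
within ±0.02), and the end-to-end CLI check uses the default plug-flow
scene. The ~0.4% plug-flow force error at 40 frames/cycle is the expected
sinc-factor attenuation of the centered temporal difference,
1 − sinc(2π/40); halving the frame duration quarters it.

Degenerate inputs are errors, not silent defaults: non-positive spacings or
frame counts, collinear landmarks, parallel plane normals, empty phases,
zero-variance agreement data, velocities outside ±VENC before unwrapping,
masks shifted off-grid, and fully invalid mask frames all raise with a
named cause.

## Known limitations

No turbulence modelling or non-Newtonian rheology; rigid translation only
for mask alignment (no deformable registration); no automatic static-tissue
detection or landmark placement; the energy- and momentum-consistency of
the nozzle scene is kinematic only; ICC confidence intervals are not
computed; DICOM ingestion is out of scope (NIfTI/HDF5 interchange only).
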