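# Methods

## The physical model

At the frequencies relevant to EEG and tES the head behaves quasi-
statically: the potential V in a conductor with conductivity field σ(x)
obeys current continuity, ∇·(σ∇V) = 0, with no current crossing the outer
(scalp–air) surface.  Injecting a known total current through one scalp
electrode and withdrawing it at a reference electrode defines a boundary-
value problem; the brain electric field is E = −∇V.  Because the mapping
from electrode currents to brain fields is linear, all of it is captured
by the *lead field*: for each cortical location i an M×3 matrix L_i whose
row m is the field produced at i by 1 mA injected at electrode m against
the reference.  By the reciprocity theorem the same matrix maps a dipole
at i to the potentials measured at the electrodes, so the tES forward
model and the EEG forward model are one object.

Assumptions inherited from this formulation: isotropic per-tissue
conductivities (no white-matter anisotropy, no layered skull), point-like
electrodes (one surface voxel per electrode; no sponge/gel modeling), and
purely ohmic, frequency-independent tissue.

## Discretization

The head is a voxel grid of integer tissue labels (background, scalp,
skull, CSF, gray matter, white matter, air).  A 7-point finite-volume
stencil is built over the conducting voxels: the conductance of the face
between two adjacent conducting voxels is the harmonic mean of their
conductivities times face area over pitch (for isotropic voxels of edge h
in metres this is σ_harm·h).  Harmonic averaging keeps the normal current
continuous across tissue interfaces; faces toward air or background get
zero conductance, which implements the insulated surface exactly.  The
resulting operator is symmetric with zero row sums, so charge is conserved
by construction.

Stimulation spreads the stated total current uniformly over the electrode
patch voxels; the ground patch is held at V = 0 (Dirichlet), making the
reduced system symmetric positive definite.  The two-step convention of
imposing a nominal current density and rescaling afterwards collapses into
a single solve at the stated current, which is equivalent by linearity.
Solves use Jacobi-preconditioned conjugate gradients at relative residual
1e−8 with an iteration cap of 100·√(unknowns); non-convergence raises an
error carrying the achieved residual and is never silently accepted.

E = −∇V at a cortical voxel uses central differences, falling back to
one-sided differences along axes where a neighbor is non-conducting.

Accuracy at the default resolutions (measured by `scripts/acceptance.py`
against the analytic series below, evaluation points within 80 % of the
sphere radius): relative RMS error falls from ≈3.6 % at 6 mm voxels to
≈2.6 % at 4 mm and ≈1.8 % at 2 mm.

## Analytic oracle

For a homogeneous sphere of radius R with insulated surface, point
injection at surface direction a and withdrawal at b gives

V(r) = I/(4πσR) Σ_{n≥1} ((2n+1)/n)(‖r‖/R)ⁿ [Pₙ(cos γₐ) − Pₙ(cos γ_b)],

with γ the angle between r and the electrode direction.  The series is
accumulated by the Legendre recurrence with early stopping when the newest
term falls below 1e−10 of the partial sum for two consecutive orders
(default cap 200 terms; a warning is emitted if the ratio test never
triggers).  Solver-versus-oracle comparisons use a phantom with all tissue
conductivities set equal, and subtract the mean of both potential sets
over the evaluation points before comparing, since the two solutions fix
their additive constants differently.  Only the single-sphere solution is
provided; multilayer radial profiles are deliberately out of scope.

## Phantoms and what they do and do not emulate

`make_sphere_head` labels each voxel by the distance of its centre from
the origin against strictly decreasing shell radii (defaults
92/86/80/78/70 mm — head-sized scalp, skull, CSF, gray matter shells over
a white-matter core).  There is no partial-volume handling; the rule is
deliberately simple enough to test against closed forms (shell nesting,
volume convergence).  An optional spherical air pocket can be carved out
of the skull.  Electrodes follow a deterministic golden-angle spiral
within a polar cap (default 160°, emulating extended coverage down toward
the neck while leaving the inferior pole free), each snapped to the
best-aligned exposed scalp-surface voxel; the most inferior electrode
serves as the ground ("Iz" by default).  Cortical sources are a uniform
stride over the sorted gray-matter voxels; normals are outward radial
directions pushed through the head's generating affine by the
inverse-transpose rule, which is exact for level-set surfaces and avoids a
meshing dependency.

`perturb_anatomy` resamples the labels under a 12-parameter affine
(nearest neighbor) and returns the exact transform, so correspondence and
localization experiments have ground truth.  Random perturbations draw
the linear part as I + U(−m, m) per entry and the translation as
U(−1, 1)·m·50 mm, so magnitudes 0.02–0.10 produce shape changes of a few
millimetres up to a centimetre on a head-sized sphere — comparable to its
millimetre-scale translations.  Nearest-neighbor resampling under strong
shear can strand single conducting voxels at the surface; the largest
6-connected conducting component is kept, mirroring the cleanup of
disconnected regions that real segmentation pipelines apply.

What passing tests on these phantoms shows: the solver, metrics, scan and
LP are internally correct and behave as the theory predicts under
controlled anatomical mismatch.  What it does not show: performance on
real heads with cortical folding, air sinuses, neck geometry, skull
layering or segmentation noise — sphere phantoms have none of these, and
their thin-shell geometry makes "deep" and "superficial" sources much
less distinct than in a real brain.

## Conductivities

The bundled default table assigns the classic three-compartment values:
scalp 0.33 S/m, skull 0.041 S/m, and all brain-side tissues (CSF, gray,
white) 0.33 S/m.  Finer per-tissue values (e.g. a distinct CSF
conductivity) are user-supplied via the YAML table; air and background
are always non-conducting.  `TissueConductivityTable.uniform` supports
the homogeneous-sphere oracle comparisons.

## Comparison methodology

Two head models of different anatomies are compared location-by-location.
The approximate anatomy's coordinates are mapped into the reference
head's native space by a chain of affine transforms — never resampling
lead-field values, only transforming coordinates — and each reference
location is matched to the exactly nearest transformed location (ties to
the lowest index).  Three matching routes are exercised by the pipeline:
identity (same anatomy, different discretization), the exact inverse of
the generating perturbation (ground-truth registration), and a
least-squares affine fitted to corresponding electrode positions (the
practical "individualized warp" route, implemented as a known-
correspondence fit rather than full surface warping).

Because native frames of different anatomies differ by (at least)
rotations, all lead-field measures are rotation invariant:

* **gain** G_i = 10·log₁₀(‖L_ref^i‖_F²/‖L_appr^i‖_F²).  Positive gain
  means the approximate model *underestimates* the field strength the
  reference model predicts (reference in the numerator); output headers
  document this orientation.
* **subspace correlation** 1 − θ_max/(π/2), where θ_max is the largest
  principal angle between the column spaces.  It is 1 for lead fields
  identical up to any invertible 3×3 mixing and 0 for orthogonal ones,
  and is invariant to scaling of either argument.  θ_max is computed by
  the sine route — orthonormal bases via SVD (rank tolerance
  max(dims)·eps relative to the largest singular value), then the largest
  singular value of Q_small − Q_large(Q_largeᵀQ_small) and an arcsin —
  because the cosine route loses half the floating-point digits near zero
  angle and cannot return exactly 1 for identical subspaces.
* EEG localization: the pseudo-EEG of a unit dipole along the cortical
  normal is scanned against every candidate location by the same
  principal-angle machinery (1-D versus 3-D subspace), exhaustively and
  noise-free, one source at a time; the estimate is mapped to the
  reference frame before measuring the Euclidean error.
* tES targeting: montages maximize the normal-direction field under the
  constraint that the total injected current (sum of positive entries,
  equivalently half the l1 norm given the zero-sum constraint) stays
  within 2 mA.  The LP is solved by HiGHS after variable splitting; since
  the objective is linear and the feasible set's vertices are bipolar
  pairs at the limit, an exhaustive pair enumeration provides an exact
  independent oracle, and both are exposed.  Approximate-model montages
  are applied to the reference lead field and scored by relErr at the
  target and the Jaccard overlap of peak masks.
* peak masks take field magnitudes strictly greater than that field's own
  75th percentile (linear-interpolation estimator, computed per field,
  not pooled); ties at the threshold are excluded, so masks hold 20–25 %
  of locations for continuous magnitudes.
* a single global least-squares scalar α = Σ⟨L_ref, L_appr⟩_F/Σ‖L_appr‖_F²
  brings lead fields of different electrical-model families to a common
  scale before targeting.  Note that the intensity-maximization LP is
  homogeneous in the lead-field scale, so on this pipeline the calibration
  changes reported field intensities but not the chosen montages.

## Default problem sizes and numerical choices

The bundled experiments use a 92 mm phantom at 4 mm voxels (≈51k
conducting unknowns), 32 electrodes (16-electrode subset for the
EEG-style comparisons, full set for targeting), and 500 cortical sources;
the solver-oracle comparison adds a 2 mm solve (≈408k unknowns).  These
sizes resolve all five shells while keeping a full pipeline run in the
minutes range on one CPU; the same code scales to finer grids unchanged.
Tie-breaks are deterministic everywhere (lowest index in nearest-point
matching, scan argmax, and bipolar enumeration), every random quantity is
a pure function of its seed, and the pipeline is byte-reproducible from
its configuration.

## Known limitations

* Voxel finite volumes, not adaptive tetrahedral finite elements: field
  evaluation right at tissue boundaries is first-order accurate.
* Electrodes are single surface voxels; contact impedance and electrode
  size effects are not modeled.
* The affine "warp" stand-in assumes known electrode correspondence and
  cannot express the nonlinear component of real surface warping.
* Only intensity-maximization targeting is implemented; focality-
  constrained and orientation-free variants are out of scope.
* The homogeneous-sphere oracle validates the solver only in the
  equal-conductivity regime; multilayer analytic checks are not included.
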