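# Methods

`tomopipe` re-creates, at desk scale and on synthetic data, the
computational chain by which a native membrane-protein complex is solved
from cryo-electron tomograms: simulated tilt-series acquisition, CTF
handling, weighted backprojection, missing-wedge-aware template matching,
constrained-PCA classification, iterative and gold-standard subtomogram
averaging, Fourier-shell-correlation (FSC) resolution estimation, and
atomic-model fitting with screw-axis analysis of a conformational change.
This note records the models, the parameters that matter, and the design
choices made where the problem was genuinely open.

## Conventions

Volumes are cubic with even edge; arrays are indexed `[x, y, z]` and the
rotation center is voxel `floor(n/2)` (the `fftshift` center). Euler angles
are intrinsic ZXZ in degrees (the common subtomogram-averaging convention);
rotations are active; interpolation is trilinear. The tilt axis is y; the
beam at tilt θ runs along `(sin θ, 0, cos θ)`, and a point `(x, y, z)`
projects to image coordinates `u = x cos θ − z sin θ`, `v = y`. Volumes are
stored as MRC2014 mode-2 files (reader/writer cross-checked against gemmi);
particle tables are TSV.

## The synthetic specimen

The generator emulates rough-ER vesicles densely decorated with
membrane-bound particles. One particle is a two-part Gaussian-blob
phantom, 270 Å across: a large cytosolic body (ribosome-like, six macro
lobes of σ ≈ 22 Å), a compact membrane-embedded foot (translocon-like,
three lobes of σ ≈ 16 Å), and 18 fine internal blobs of σ = 10 Å. The fine
blobs matter: without them the phantom's power spectrum dies by ~45 Å and
iterative alignment has nothing to improve on, which is unrepresentative of
a ribosome-sized particle sampled at 13 Å. Compositional heterogeneity is
modeled by optional sub-densities: an OST-like lumenal blob present in 55%
of particles and a tRNA-like blob in the intersubunit region present in
29% — the class abundances the classification stages must recover.
Conformers (e.g. a rotated "gate-open" foot) can be declared as per-domain
rigid offsets.

Scenes place particles on a vesicle shell (default radius 650 Å, membrane
thickness 45 Å rendered as a Gaussian shell) with the foot centered in the
membrane along the local normal (± 8° jitter), non-overlapping at one
particle diameter; unbound particles take uniform random poses; 10-nm gold
fiducials are bright compact spheres (4× particle peak density). Every
placement, pose, label, defocus and shift is recorded as ground truth.

Tilt series follow the modeled acquisition: −60°…+60° in 2° steps,
cumulative dose ~95 e/Å² (so the ±20° subset carries ~30 e/Å²), 300 kV,
Cs 2.7 mm, 7% amplitude contrast, 3–4 µm underfocus. Projections are
cubic-spline line integrals (central-slice-accurate to r > 0.99), CTF
multiplied in Fourier space (sign convention: positive at low frequency,
so images keep the specimen's contrast below the first zero), optionally
shifted by recorded stage jitter, with additive white Gaussian noise of
variance ∝ 1/dose. Detector MTF, beam-induced deformation and marker
occlusion are not modeled.

**What the generator does not emulate.** Real tomograms carry structured
background (crowding, carbon edges, ice gradients), non-white noise, and
CTF envelopes; the phantom is far smoother than a true macromolecule and
the membrane is a perfect sphere. Passing tests therefore demonstrate the
correctness and internal consistency of the algorithms under controlled
conditions, not their performance on real data.

### Fixture SNR and the angular-precision floor

Subtomogram-level SNR is defined as signal variance inside the particle
region over noise variance, both at the 13.1 Å working voxel. The
benchmark value is 1.0 — a level at which the particle is clearly visible
and classification is reliable, in the upper range of what heavily binned
tomographic data supports.

Alignment benchmarks must be read against a measured property of the
estimator: the per-particle angular scatter of discrete-grid constrained
matched filtering on a 32-voxel box is p50 ≈ 2–3°, p90 ≈ 4°, and it is
nearly independent of SNR (p90 4.6°/4.1°/3.8° at SNR 1/2/4) — a floor set
by the wedge-constrained score landscape and grid sampling, still ~2°
noise-free with a clean reference and full wedge. Refinement therefore
converges to within a few degrees of truth, not arbitrarily close; the
fraction of poses recovered within half the resolution-matched angular
step (~3.4° at the ~31 Å ceiling) is ~35% at these conditions. Reaching
sub-degree pose precision would require larger boxes or a continuous
(gradient-based) pose estimator, both outside the desk-scale envelope.

## Reconstruction

Weighted backprojection uses the analytic ramp `|k|` along the in-image
axis perpendicular to the tilt axis, then linear-interpolated smearing along
each viewing direction, scaled by π/(2·N). Two numerical choices:

* **Angular apodization.** The outermost two tilt images get raised-cosine
  quadrature weights. The extreme projections sit exactly on the wedge
  boundary, and their finite-box spectra otherwise ring perpendicular to
  the boundary, spilling several percent of the reconstruction's energy
  outside the sampled wedge; with the taper the ±20° reconstruction keeps
  > 98% of its Fourier energy inside its wedge at a small cost in boundary
  contrast.
* **Partial-field region.** Voxels whose rays leave the detector field for
  some tilts (the x–z corners and y borders) are only partially sampled.
  They are reconstructed as-is but excluded from template-matching peak
  extraction (`detection_valid_mask`), where their depressed local variance
  would otherwise inflate normalized scores.

Per-particle reconstruction recenters the projections on the particle
(crop-equivalent to the full tomogram to machine precision) and records the
tilt coverage actually used as the subtomogram's wedge.

Movie-frame alignment is an iterated expectation/maximization scheme
(correlate each frame against the sum of the others, subpixel parabola,
re-sum; zero-mean gauge). Defocus is estimated by strip-based periodogram
averaging: half-overlapping Hann-windowed strips parallel to the tilt axis,
radially averaged, background-removed by a wide Gaussian, and matched to
|CTF|² by grid search (the grid spacing is the reported error bound) plus
bounded refinement; a featureless spectrum returns quality 0. Phase
flipping multiplies by sign(CTF) per frequency, preserving amplitudes
exactly. Marker-based tilt alignment solves the linear model
`u = pₓ cos θ − p_z sin θ + sₓ`, `v = p_y + s_y` for per-image shifts and
3-D marker positions; the gauge freedom (a common marker translation is
absorbable into the shifts) is fixed by constraining the marker centroid to
the volume origin, so the simulator places marker sets with centroid there.
Rotations and magnification are deliberately not solved.

## Template matching

Orientations tile SO(3) as a Fibonacci sphere (one direction per increment-
sized cap) crossed with in-plane rotations at the same increment; 12.85°
gives ~8400 nodes, every node within one increment of a neighbor. For each
orientation the template (low-passed to 50 Å) is rotated, limited to the
tomogram's wedge support, made mean-free under the matching mask, and
correlated at all positions by FFT with Roseman-style local normalization;
the denominator is computed once from the unrotated spherical mask and
floored at 10⁻³ of its maximum. A slow real-space path (`normalized_cc_at`)
computes the identical quantity for cross-checking; the two agree to 1e-5.

Peak extraction is greedy with spherical suppression (default exclusion
radius one particle diameter, ties in lexicographic voxel order) inside the
trustworthy region. Because the coarse grid quantizes orientations — which
depresses a true match's score far more than a rotationally featureless
gold bead's — candidates are then re-scored by a local hill-climb
(alternating half-ball orientation polish and ±1-voxel moves until a local
maximum) and deduplicated. This two-stage matched filter is what separates
particles from fiducials by score; with single-stage matching the bead
plateau overlaps the weakest true particles.

## Subtomogram averaging

The constrained cross-correlation of two wedge-limited volumes is the
correlation over the Fourier region inside both wedges and the alignment
band, normalized by each volume's energy in that region (symmetric by
construction, DC excluded). Alignment searches a rotation-vector ball
around the current pose; for each candidate rotation the reference is
rotated into the subtomogram frame, wedge- and band-filtered, and the
translation read from the correlation peak with parabolic subpixel
refinement (shift radius capped at a quarter box); the returned score never
falls below the input pose's.

Averaging divides the Fourier sum of back-rotated subtomograms by the sum
of equally rotated wedge masks, floored at `max(10⁻³·N, 0.5)` — the
absolute term keeps voxels grazed by a fraction of one wedge from being
amplified beyond their information content. The output is mean-free.

Iterative refinement (conventional: one reference, FSC 0.5 between random
halves; gold-standard: fixed seeded halves, each aligned only against its
own average, FSC 0.143) uses the resolution-adaptive schedule: angular step
`max(1°, atan(res/diameter))` and band low-pass at the best resolution so
far. Three choices proved load-bearing at desk-scale N (~100 per half) and
are therefore defaults:

* **External first reference.** The first iteration aligns against a sharp
  external reference (the low-passed phantom; in the original workflow, an
  external single-particle map). The loop is bistable: seeded with the
  blurred average of the perturbed poses it settles into a self-consistent
  ~4.5°-error state in which reference blur and pose errors sustain each
  other.
* **Leave-one-out references.** From iteration 2 on, each particle aligns
  against its group average minus its own contribution. With a
  self-inclusive average, a 5°-wrong pose outscored the true pose for
  18/20 particles in a direct probe — at small N the particle's own
  misposed copy dominates the constrained score.
* **Half-step sampling, patience-2 stopping, final polish.** The search
  grid is sampled at half the schedule step so corrections below the step
  remain expressible; refinement stops only when the resolution has failed
  to improve on its best by one Fourier shell for two consecutive
  iterations (single-iteration stalls of the noisy per-iteration estimate
  are not convergence); and a last sweep at the minimum angular step
  (default 1°) polishes each pose against its leave-one-out reference.
  Candidate poses are re-scored at their parabola-refined fractional
  translation through an exact Fourier phase ramp — scoring them at
  integer voxels while the incumbent keeps its exact fractional shift is a
  systematic handicap that freezes refinement.

## Classification (constrained PCA)

Each aligned subtomogram is rotated to the reference frame; Fourier voxels
outside its rotated wedge are replaced by the current average's values
(wedge compensation, so wedge orientation cannot leak into the features);
the volume is band-limited, restricted to a focus mask, centered and
globally scale-normalized; PCA supplies the feature space and k-means (best
of 10 restarts, seeded, labels renumbered by class size) the labels. Round
masks follow the workflow: whole particle (membrane-bound vs junk),
translocon foot (OST occupancy), tRNA sites (translational state). The
pipeline's particle-vs-junk round keeps the class whose average correlates
best with the search template — an automated stand-in for the visual
curation the original procedure used. The pipeline's tRNA round uses k = 2
because the generator plants exactly two states; the original analysis used
three classes whose extra distinction (two translating sub-states) the
phantom does not model.

## Resolution and sharpening

FSC uses one-voxel shells, optional soft real-space masks, and linear
interpolation for the threshold crossing (0.5 conventional, 0.143
gold-standard, 0.33 cross-resolution); a curve that never crosses returns
the Nyquist bound flagged as such. No phase-randomization mask correction
is applied — masked FSC values are therefore mildly optimistic, a known
limitation. Local resolution slides a 20³ window (raised-cosine apodized
over its outer 20%) on a half-box stride and assigns the windowed FSC
crossing to the window center, nearest-node filled between grid points.
Sharpening multiplies amplitudes by `exp(−B·s²/4)` (Rosenthal–Henderson
convention; B = −500 Å² amplifies ~3.5× at s = 0.1 Å⁻¹) under a soft
low-pass at the stated resolution.

## Model fitting and screw analysis

Models are flat coordinate arrays with per-atom domain tags (PDB/mmCIF via
gemmi). Superposition is Kabsch with the proper-rotation correction. Rigid
fitting renders the model as one Gaussian per atom (σ = resolution/(π√2),
the `molmap` convention), seeds with a coarse orientation grid plus FFT
translation search, and polishes the six pose parameters by Nelder–Mead
(explicit 2°/1 Å initial simplex) on the real-space map correlation.
Domain-wise fitting subtracts the other domains' rendered, amplitude-matched
density from the target before fitting each domain. Helix repositioning
scans translations along the selection's first principal axis and reports
the full score profile. Flexible refinement is an elastic-restrained
surrogate, not molecular dynamics: atoms ascend the gradient of the
*residual* map (target minus currently rendered model — which makes a
model that explains the map an exact fixed point), restrained by harmonic
bonded-distance and displacement-from-start terms, with an annealed step.
Screw decomposition takes angle/axis from the rotation vector, splits the
translation into its axis-parallel part and a perpendicular part absorbed
into the axis-point solve `(I−R)c = t⊥`; reconstruction from the
parameters reproduces the transform to 1e-6 Å on probe points.

The benchmark conformational scenario builds a ten-helix channel analog
whose N-terminal half carries a 22° / 13.8 Å screw motion and whose last
helix shifts 13 Å along its axis — the printed geometry of the lateral-gate
opening — and recovers all three numbers by domain fitting, helix scanning
and screw decomposition, with flexible-refinement motions below 3 Å Cα
RMSD.

## Problem sizes

Benchmarks run on one CPU in minutes by construction: subtomograms 32³ at
13.1 Å (5× the modeled detector pixel), detection in 2×-binned 64³
tomograms at 21 Å (matching the workflow's own detection scale), scenes of
10–30 particles, 200 particles for refinement and 1000 for classification.
The pipeline's default configuration is the same machinery end to end on a
128³ scene. `scripts/validate_deposited.py` (network-required, not part of
the test suite) runs the deposited-structure comparison the synthetic
analog mirrors.

## Known limitations

Single-axis geometry only; shifts-only marker alignment; no SIRT, no dose
weighting, no CTF refinement, no maximum-likelihood alignment; no
mask-corrected FSC; the flexible-fitting surrogate has no force field and
cannot model large remodeling. The detection benchmark uses homogeneous
particles and no membrane — it probes the six-dimensional search; the
membrane, beads-as-false-positives and compositional heterogeneity are
exercised in the pipeline and classification rounds.
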