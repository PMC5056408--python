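# Methods

This note records the models, algorithms and numerical choices behind
`ctfm`, and what the synthetic benchmarks do and do not demonstrate.

## The measurement model

The substrate is a flat, ≈30 µm layer of very soft silicone (initial shear
modulus µ₀ ≈ 4.24 kPa) bonded to glass, carrying a printed triangular
lattice of fluorescent nanodiscs with known spacing `L0` (0.75–3 µm).  A
cell deforms the surface; one fluorescence image of the deformed lattice is
the entire measurement.  Three physical facts make the inverse problem
well-posed without regularization:

* each disc is a diffraction-limited point source localizable to a few
  nanometres;
* the load-free geometry is *known by construction* (equilateral triangles
  at `L0`), up to the printing-placement error;
* the substrate is homogeneous and well characterized up to large strains.

## Synthetic data (`lattice_sim`)

All validation uses simulated arrays because they retain per-disc ground
truth.  Conventions: lattice rows along x, odd rows shifted `L0/2`, row
pitch `L0·√3/2`; coordinates in µm; pixel centres at `(i+0.5)·pixel_size`;
8-bit images with spot peak 200 over a zero baseline (configurable),
isotropic Gaussian spots of s.d. 0.2 µm, additive Gaussian read noise of
s.d. 10 grey levels; 3D stacks add an axial Gaussian of s.d. 0.4 µm and
0.1 µm slice spacing.

**Printing error.** The printing process places discs with a positioning
error of 35 nm; we read this as the RMS *magnitude* of the 2D offset
(consistent with the independently quoted 30–45 nm positioning precision),
i.e. an isotropic Gaussian with per-axis s.d. 35/√2 ≈ 24.7 nm
(`ctfm.pipeline.PRINT_JITTER_SD`).  Reading 35 nm as the per-axis s.d.
would imply ~50 nm typical offsets and inflate every jitter-driven figure
by √2.  The `LatticeSpec.jitter_sd` parameter itself is a per-axis s.d.

**Standard deformation.** The built-in "cell" is a contractile dipole:
two Gaussian lobes (σ = 3 µm, separation 8 µm — the footprint of a pair of
strong adhesion regions) pulling towards each other with peak displacement
1.5 µm.  At `L0 = 1.5 µm` this compresses the core region by >50% (local
strains beyond 100%, as observed under real cells) while leaving the array
rim essentially load-free.  Narrower lobes at the same peak would push
neighbouring discs closer than the optical resolution and make any
assignment ill-posed.

What the generator does **not** model: photon-counting noise, PSF
asymmetries and aberrations, fiducial bleaching, unprinted or missing
discs, and substrate curvature.  Passing benchmarks therefore demonstrate
algorithmic correctness under idealized imaging, not robustness to every
experimental artefact.

## Detection

2D: threshold (Otsu by default) → 8-connected pixel islands →
intensity-weighted centroid per island.  Centroid weights are the grey
values *minus the threshold*: with raw weights the flat supra-threshold
pedestal pixel-locks the centroid (measured 3.7 nm bias noise-free, 9.6 nm
RMS at noise s.d. 10, versus 0.7/7.0 nm with subtraction).  Islands
containing several local maxima (two discs merged by deformation or dense
packing) are split by a marker-based watershed; the maxima are sought on a
σ = 1 px smoothed copy because read noise can fill the valley between two
merged spots.  Islands below 4 px are discarded.

Z: per disc, the stack intensity within a lateral radius of half the spot
size (0.717 µm) is summed per slice; a parabola fitted to the
log-intensity around the peak gives sub-slice resolution; discs peaking at
the first/last slice are flagged unreliable.  A least-squares plane fit
over all discs removes sample tilt (the plane absorbs only 3 d.o.f., so
genuine topography survives).

## Connectivity reconstruction (`meshing`)

Step 1 — regular regions: a disc is accepted when it has exactly six
neighbours within `L0 ± 250 nm` whose consecutive polar-angle gaps are
60° ± 10°.  Accepted discs receive integer axial lattice coordinates by
BFS from a seed in the largest connected regular component; edge
directions are classified against the global lattice orientation
(circular mean of neighbour angles modulo 60°), which makes the
construction invariant to rigid motions of the point set.

Step 2 — completion: the outer rim (which can never pass the six-neighbour
test) is extended greedily onto ring sites outside the regular hull;
deformation voids in the interior are filled by assigning discs to vacant
sites with a linear assignment on the squared distance to each site's
*predicted* deformed position (thin-plate-spline interpolation of the
displacement known at the already-meshed discs).  The result is polished by
exhaustive enumeration (voids ≤ 8 discs) or 2-swap descent on the package's
distortion functional: edge terms `(length − predicted length)²` plus
node-fidelity terms `|x − x_pred|²`.  A pure spring functional
`(length − L0)²` is *not* used as the optimization target: under >50%
compression the deformed edge lengths deviate from `L0` for every
assignment, making that cost degenerate (it mis-assigned ~40 discs per
array in development tests); it is recovered as the limit of the present
functional as the deformation vanishes.  Ties break deterministically
(lexicographic scan keeps the first optimum).  Missing discs are a hard
error: the method presumes a complete printed array.

## Reference recovery

Discs are point masses joined to their mesh neighbours by linear springs
of rest length `L0`; damped Newtonian dynamics is integrated with RK4
(Δt = 0.1·√(m/k)) until the maximum nodal force falls below `10⁻⁶·k·L0`.
A complete triangular mesh with all edges at `L0` is rigid, so the
steady state is the equilateral lattice, independent of `k`, `m`, `c`
(verified to <0.02 nm).  The default damping targets the slowest network
mode, `c = 4π√(km)/√n`; critical damping of the stiffest edge mode
converges to the same state ~10× slower.  Rigid-body position and
orientation are fixed afterwards by Procrustes alignment onto the observed
positions of the low-strain discs (all incident edges within 250 nm of
`L0`) — the cell's far field is load-free and defines the laboratory
frame.  We deliberately do **not** pin those discs at their observed
positions during relaxation: doing so would zero the apparent displacement
wherever the array is undeformed and hence hide the printing-jitter
contribution that sets the platform's real traction noise floor.

An information-theoretic consequence worth stating plainly: the printing
jitter lives in the *reference* configuration and is not observable from a
single deformed image, so the reconstructed reference cannot be closer to
the true printed positions than the jitter magnitude (~35 nm RMS).  The
measured reconstruction error of the full pipeline is ≈35–36 nm, i.e. the
algorithm itself contributes only a few nanometres beyond this floor.

## Substrate model (`material`)

Two-term Ogden in the convention
`W = Σᵢ 2µᵢ/αᵢ² (λ̄₁^αᵢ + λ̄₂^αᵢ + λ̄₃^αᵢ − 3) + κ/2 (J−1)²` with
µ₀ = µ₁+µ₂ and κ from ν = 0.49.  Under this convention the calibrated
parameters give E = 2(1+ν)µ₀ = 12.64 kPa, matching the bench-measured
~12.6 kPa; the classical `Σ µᵢ/αᵢ` convention would give 12.79 kPa, which
is how the convention was disambiguated.  Incompressible closed forms:
uniaxial `P(λ) = Σᵢ 2µᵢ/αᵢ (λ^(αᵢ−1) − λ^(−αᵢ/2−1))`, equibiaxial
`P(λ) = Σᵢ 2µᵢ/αᵢ (λ^(αᵢ−1) − λ^(−2αᵢ−1))`.  Fitting: multi-start
Levenberg–Marquardt around a neo-Hookean initial guess whose µ₀ comes from
the small-strain slope; both loading modes weighted equally.

## Traction reconstruction (`traction_fem`)

*Meshing.*  Tensor-product graded grid over the cuboid (disc bounding box
× substrate thickness), each hexahedron split into six tetrahedra with a
checkerboard-mirrored pattern (conforming and mirror-symmetric; a uniform
split direction left a percent-level directional bias in reaction sums).
In-plane spacing is `L0/5` where the measured displacement exceeds
~100 nm, grading geometrically (ratio 1.35) to `L0` elsewhere; vertically
the spacing is fine within `max(2·fine, L0)` of the surface — the decay
depth of the shortest lateral wavelength the markers carry — and relaxes
to `max(L0, h/8)` at depth.  In noise-only runs nothing exceeds the
refinement threshold and the rule yields uniform ~`L0` elements, which is
also the sampling at which the traction-noise figures are defined.

*Boundary conditions.*  Thin-plate-spline (`r² log r` + affine)
interpolation of the per-disc displacements to every top-surface node —
exact at the discs, exact for affine fields; bottom and lateral faces
fixed (bonding to glass; embedding in the surrounding substrate).  In the
2D pipeline the vertical surface displacement is prescribed as zero;
tangential loading then produces a nonzero *net* vertical reaction (the
suppressed Poisson bulge), which is why the force-balance check applies to
the in-plane components.

*Elements and incompressibility.*  Linear tetrahedra with the deviatoric
Ogden stress evaluated per element (spectral, on the right Cauchy–Green
eigenbasis) and the volumetric penalty evaluated on nodal-patch-averaged
volume changes (average-nodal-pressure formulation).  A pointwise penalty
— equivalent to element-constant-pressure hybrid linear tetrahedra —
locks severely at ν = 0.49: we measured ≈2× traction overestimation
against an independent linear layered-elasticity solution; patch
averaging brings the same benchmark to within ~7%.  For this reason no
separate mixed u–p element is provided: for constant-strain tetrahedra it
would condense back to the locking penalty form.

*Solver.*  The tangent at the undeformed state (element-wise finite
differences of the internal forces plus the closed-form volumetric patch
stiffness) is assembled and LU-factorized once per mesh and reused as a
quasi-Newton operator with the exact residual; a backtracking line search
guards against element inversion, re-linearized steps engage when the
contraction is slow, and the load is marched incrementally with adaptive
step control when a full-load solve fails.  Convergence: residual < 10⁻⁸
of its initial value.  At the benchmark strain levels (noise and
sensitivity runs, ≲5% strain) solves take one to a few iterations; fields
with peak displacements approaching `L0/3` (tens of percent strain)
converge but slowly, and still larger imposed fields whose gradients fold
the initial predictor may require manual load-step tuning — prescribed
fields should leave an undeformed margin at the domain boundary.
Tractions are nodal reactions divided by deformed tributary areas (one
third of each adjacent deformed surface facet), reported in Pa; forces in
nN (1 kPa·µm² = 1 nN).

*Independent cross-check.*  `ctfm.spectral` solves the small-strain layer
problem per in-plane wavevector by propagating the 6-component
displacement–traction state through the thickness (`expm` of the constant
system matrix; thickness capped at `12/k` per mode, error ~e⁻²⁴, to keep
the propagator conditioned).  It reproduces the uniform-shear and
uniform-compression closed forms to machine precision and provides the
10%-level check of the FEM on localized fields.

## Benchmarks and their scope

* **Detection precision**: 4–8 nm RMS across noise s.d. 0–10 (canonical
  conditions: `L0 = 1.5 µm`, 0.1 µm pixels); ~6.8 nm at noise 10.
* **Reference reconstruction**: ≈35 nm RMS against printed truth under the
  standard dipole — the printing-jitter floor (see above).
* **Traction noise vs spacing** (jitter only, no deformation, 9:10
  substrate, 30 µm thickness): ≈115 Pa at `L0 = 3 µm` (14×14 array) and
  ≈580 Pa at `L0 = 0.75 µm` (20×20 array), central analysis window inset
  `2·L0+1` from the domain edge, 3–5 replicates.  Array sizes are chosen
  so each run solves in seconds while the window still contains hundreds
  of surface nodes.
* **Sensitivity**: smallest amplitude of a contractile patch pair (radius
  2 µm, separation 6 µm) recoverable above the noise floor at standard
  conditions (`L0 = 1.5 µm`, 16×16).  Detection statistic: recovered
  traction projected onto the known applied pattern, averaged over the
  patch footprints (matched filter); floor: mean + 2 s.d. of the same
  statistic over noise-only runs.  A raw peak-versus-node-wise-floor rule
  is degenerate here — the regional noise peak alone exceeds such a floor —
  so the matched statistic is the package's operational definition.
  Result: 150–250 Pa depending on the seed.

All benchmark sizes (arrays of 14–24 discs per side, 5–10 replicates) are
the package's default desk-scale conditions; the statistics scale like
`1/√n` and were chosen so the complete characterization runs in minutes on
one CPU.

## Known limitations

* The pipeline assumes a complete, topologically intact printed array;
  missing or extra detections are hard errors, not recoverable states.
* Reference recovery is exact only up to the printing error, which is
  fundamental to single-image methods, and up to rigid alignment by the
  low-strain far field — a fully strained field of view has no anchor.
* The FEM's surface-traction estimator converges to ~5–10% of the
  independent linear reference at practical resolutions.  Pointwise
  (single-node) traction values converge only at first order in the
  element size — integral quantities (forces over regions, the RMS noise
  statistics) converge much faster and are the quantities the package's
  benchmarks report; peak values on coarse meshes are sampling-limited.
* Out-of-plane displacements enter as measured z-positions only; the
  relaxation itself is planar (the printed reference is flat).
* Adhesion segmentation with the automatic threshold is a reproducibility
  convenience; quantitative area statistics near the 0.5 µm² cutoff depend
  on that choice, and a manual threshold remains the faithful mode.
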