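# ctfm — reference-free traction force microscopy on printed nanodisc arrays

Cells pull and push on their surroundings, and traction force microscopy
(TFM) infers those stresses from the deformation of a compliant substrate.
Classical continuum TFM needs a second, *load-free* image — usually taken
after killing and removing the cell — to know where the fluorescent markers
started.  `ctfm` implements the reference-free alternative: the markers are
quantum-dot nanodiscs printed in a regular triangular lattice of known
spacing `L0` on a soft silicone layer, so the load-free configuration can be
reconstructed *computationally* from a single live image, and in- and
out-of-plane Cauchy tractions follow from a nonlinear hyperelastic
finite-element solve.  No regularization is involved anywhere: because the
markers are localized to a few nanometres, the inverse problem reduces to a
well-posed forward problem with Dirichlet data.

The pipeline (each stage is an importable module):

1. **`lattice_sim`** — in-silico ground truth: triangular arrays with
   printing jitter, imposed displacement fields, rendered images/stacks
   (Gaussian spots, s.d. 0.2 µm, plus read noise).  Every downstream claim
   is benchmarked against this generator.
2. **`detection`** — sub-pixel disc localization by intensity-weighted
   centroids of thresholded pixel islands (≈4–8 nm RMS at realistic noise),
   plus axial (z) localization from intensity profiles and a plane-fit tilt
   correction.
3. **`meshing`** — reconstruction of the triangular connectivity: a local
   six-neighbour test (distance ±250 nm, angles ±10°) meshes the
   low-distortion regions; strongly deformed *voids* are filled by optimal
   assignment of discs to vacant lattice sites.
4. **`reference_recovery`** — the meshed network, treated as point masses
   joined by pre-stretched springs of rest length `L0`, is relaxed by
   damped RK4 dynamics to its unique zero-energy state: the equilateral
   reference.  Per-disc displacements are `u = x − X`.
5. **`material`** — two-term Ogden hyperelasticity for the silicone
   substrate, `W = Σᵢ 2µᵢ/αᵢ² (λ₁^αᵢ + λ₂^αᵢ + λ₃^αᵢ − 3)`, with the
   calibrated 9:10 mixing-ratio parameters (µ₁ = 4.073 kPa, α₁ = 2.132,
   µ₂ = 0.167 kPa, α₂ = −0.600, ν = 0.49; E = 2(1+ν)(µ₁+µ₂) ≈ 12.6 kPa),
   closed-form uniaxial/equibiaxial stresses and parameter fitting.
6. **`traction_fem`** — graded tetrahedral meshing of the substrate cuboid,
   exact thin-plate-spline interpolation of the measured displacements onto
   the surface, and a finite-strain Newton solve (nearly incompressible
   Ogden, average-nodal-pressure elements); reaction forces over deformed
   tributary areas give the Cauchy traction field.
7. **`adhesion_analysis`** — focal-adhesion segmentation from a marker
   channel (background subtraction, CLAHE, LoG, threshold, > 0.5 µm² area
   filter) and per-adhesion force integration.

`ctfm.spectral` provides an independent Fourier-space linear-elastic layer
solution used to cross-check the FEM in the small-strain limit, and
`ctfm.pipeline` wires the stages together and hosts the benchmark
experiments (reference error, traction noise vs spacing, sensitivity).

## Worked example

A noise-only run quantifies the platform's detection floor (this is
`examples/04_traction_reconstruction.py`; see `examples/` for one script
per capability):

```text
$ python examples/04_traction_reconstruction.py
substrate model: 4284 nodes, 21216 tetrahedra
surface tractions at 238 nodes
RMS traction noise (central window): 221 Pa
peak |t|: 729 Pa
```

The 16×16 array at `L0 = 1.5 µm` carries only printing jitter (35 nm RMS
offsets) and imaging noise; the pipeline nevertheless reports ~220 Pa RMS of
spurious traction — the price of not having a reference image, and the
floor against which real cell tractions (kPa scale) are detected.  The same
experiment at `L0 = 3 µm` gives ≈115 Pa and at `L0 = 0.75 µm` ≈580 Pa:
spacing trades spatial resolution against force sensitivity.

A thin CLI mirrors the stages (`ctfm simulate`, `detect`, `mesh`, `relax`,
`fit-material`, `traction`, `adhesions`); run `ctfm --help`.

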