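"""End-to-end pipeline: image -> detection -> mesh -> reference -> tractions.

Also hosts the in-silico benchmark experiments used to characterize the
platform: reference-reconstruction error, traction noise from printing
jitter alone, and the minimum detectable traction (sensitivity sweep).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence
import logging

import numpy as np

from . import lattice_sim as sim
from .detection import DetectionParams, detect_xy, match_to_truth
from .lattice_sim import ImagingSpec, LatticeSpec, NanodiscArray, RenderedImage
from .meshing import MeshingParams, TriMesh, fill_voids, mesh_regular_regions
from .reference_recovery import (DisplacementField, SpringNetwork,
                                 displacements, recover_reference)
from .traction_fem import (FEASolver, SubstrateModel, TetMesh, TractionField,
                           build_mesh, forward_surface_displacement,
                           interpolate_bc, reconstruct_tractions)

logger = logging.getLogger(__name__)

#: Printing positioning error of the nanodrip process: 35 nm RMS *offset
#: magnitude* (the printed positioning precision is 30-45 nm), i.e. an
#: isotropic 2D Gaussian with per-axis s.d. 35/sqrt(2) nm.
PRINT_ERROR_UM = 0.035
PRINT_JITTER_SD = PRINT_ERROR_UM / np.sqrt(2.0)


@dataclass
class AnalysisResult:
    """Everything the inverse pipeline derives from one image."""

    detected: NanodiscArray
    mesh: TriMesh
    reference: np.ndarray
    disp: DisplacementField
    tractions: Optional[TractionField] = None


def analyze_image(image: RenderedImage, L0: float,
                  detection: Optional[DetectionParams] = None,
                  meshing: Optional[MeshingParams] = None,
                  anchor_tol: Optional[float] = None) -> AnalysisResult:
    """Detection, meshing and reference recovery for one 2D image."""
    det = detect_xy(image, detection or DetectionParams())
    arr = NanodiscArray(positions=det.positions.positions, L0=L0,
                        labels=det.positions.labels)
    mp = meshing or MeshingParams(L0=L0)
    mesh = fill_voids(mesh_regular_regions(arr, mp), arr, mp)
    net = SpringNetwork.from_mesh(arr, mesh)
    ref, _ = recover_reference(net, anchor_tol=anchor_tol)
    disp = displacements(arr, ref)
    return AnalysisResult(detected=arr, mesh=mesh, reference=ref, disp=disp)


def reconstruct_from_image(image: RenderedImage, L0: float,
                           model: Optional[SubstrateModel] = None,
                           solver: Optional[FEASolver] = None,
                           **analysis_kw) -> AnalysisResult:
    """Full inverse pipeline including the FEM traction solve."""
    res = analyze_image(image, L0, **analysis_kw)
    if model is None:
        model = SubstrateModel(L0=L0)
    tf, _ = reconstruct_tractions(res.disp, model, solver=solver)
    res.tractions = tf
    return res


# ---------------------------------------------------------------------------
# In-silico benchmark experiments
# ---------------------------------------------------------------------------

def standard_deformation(arr: NanodiscArray, peak: float = 1.5,
                         sigma: float = 3.0, separation: float = 8.0):
    """The default imposed deformation: a contractile dipole at the array
    centre, lobe width ``sigma`` um (a focal-adhesion-scale traction
    footprint), peak displacement ``peak`` um."""
    cen = arr.xy.mean(axis=0)
    return sim.contractile_dipole(centre=tuple(cen), separation=separation,
                                  sigma=sigma, peak=peak)


def ideal_extent(spec: LatticeSpec) -> tuple[float, float, float, float]:
    """Bounding box of the ideal (jitter-free) lattice, for mesh reuse."""
    return (0.0, (spec.cols - 1) * spec.L0 + spec.L0 / 2.0,
            0.0, (spec.rows - 1) * spec.L0 * np.sqrt(3.0) / 2.0)


def reference_error_experiment(n_arrays: int = 10, L0: float = 1.5,
                               rows: int = 24, cols: int = 24,
                               jitter_sd: float = PRINT_JITTER_SD,
                               peak: float = 1.5,
                               noise_sd: float = 10.0, seed: int = 0
                               ) -> dict:
    """Reference-reconstruction error of the full image pipeline.

    For each replicate: print a jittered lattice, impose the standard
    dipole deformation (max |u| = ``peak``), render with imaging noise,
    detect, mesh, relax; measure the reconstructed reference against the
    true printed positions.  Returns pooled RMS statistics in nm.
    """
    rng = np.random.default_rng(seed)
    sq_err = []
    for rep in range(n_arrays):
        s = int(rng.integers(2 ** 31 - 10))
        arr = sim.make_lattice(LatticeSpec(L0=L0, rows=rows, cols=cols,
                                           jitter_sd=jitter_sd, seed=s))
        deformed = sim.apply_deformation(arr, standard_deformation(arr, peak))
        img = sim.render_image(deformed, ImagingSpec(noise_sd=noise_sd),
                               seed=s + 1)
        res = analyze_image(img, L0)
        di, ti = match_to_truth(res.detected.positions, deformed.positions,
                                max_dist=0.45 * L0)
        if len(ti) < 0.99 * len(arr):
            raise RuntimeError(f"detection lost {len(arr) - len(ti)} discs")
        err = res.reference[di] - deformed.printed[ti]
        sq_err.append((err ** 2).sum(axis=1))
    pooled = np.concatenate(sq_err)
    return {"rms_nm": 1e3 * float(np.sqrt(pooled.mean())),
            "n_arrays": n_arrays, "n_discs": int(pooled.size)}


def _noise_solver(L0: float, spec: LatticeSpec, height: float,
                  fine: Optional[float] = None) -> FEASolver:
    # no high-displacement region in a noise-only run: the adaptive rule
    # gives uniform coarse (~L0) elements in-plane, fine only at the surface
    model = SubstrateModel(height=height, L0=L0, fine=fine)
    mesh = build_mesh(model, extent=ideal_extent(spec))
    return FEASolver(model, mesh)


def traction_noise_experiment(L0: float, rows: int, cols: int,
                              n_replicates: int = 3,
                              jitter_sd: float = PRINT_JITTER_SD,
                              noise_sd: float = 10.0, height: float = 30.0,
                              seed: int = 0, inset: Optional[float] = None,
                              solver: Optional[FEASolver] = None) -> dict:
    """Traction noise of the full pipeline with no true deformation.

    The printed jitter (and detection noise) masquerades as displacement,
    and the FEM converts it into spurious tractions; their RMS magnitude
    over the central analysis window is the noise floor of the platform
    at this disc spacing.  The window excludes a rim of ``inset`` um
    (default ``2 L0 + 1``) where the lateral constraints interact with
    the interpolated field.
    """
    spec0 = LatticeSpec(L0=L0, rows=rows, cols=cols, jitter_sd=jitter_sd)
    if solver is None:
        solver = _noise_solver(L0, spec0, height)
    if inset is None:
        inset = 2.0 * L0 + 1.0
    rng = np.random.default_rng(seed)
    rms = []
    for rep in range(n_replicates):
        s = int(rng.integers(2 ** 31 - 10))
        arr = sim.make_lattice(LatticeSpec(L0=L0, rows=rows, cols=cols,
                                           jitter_sd=jitter_sd, seed=s))
        img = sim.render_image(arr, ImagingSpec(noise_sd=noise_sd), seed=s + 1)
        res = analyze_image(img, L0)
        tf, _ = reconstruct_tractions(res.disp, solver.model, solver=solver)
        rms.append(tf.rms(tf.central_mask(inset)))
    return {"rms_Pa": float(np.mean(rms)), "per_replicate_Pa": rms,
            "n_replicates": n_replicates, "L0": L0}


@dataclass
class SensitivityResult:
    threshold_Pa: Optional[float]
    amplitudes_Pa: list
    recovered_peak_Pa: list
    noise_floor_Pa: float
    noise_peaks_Pa: list


def traction_patch_pair(centre: np.ndarray, separation: float, radius: float,
                        magnitude: float):
    """Two opposing circular tangential traction patches (contractile pair).

    Returns a function mapping surface (n, 2) xy to (n, 3) tractions in Pa:
    magnitude ``magnitude`` pointing towards the pair's midpoint inside
    each patch, zero outside - a minimal model of a pair of pulling
    adhesion sites.
    """
    c1 = centre + np.array([separation / 2.0, 0.0])
    c2 = centre - np.array([separation / 2.0, 0.0])

    def fn(xy: np.ndarray) -> np.ndarray:
        t = np.zeros((len(xy), 3))
        in1 = np.linalg.norm(xy - c1, axis=1) <= radius
        in2 = np.linalg.norm(xy - c2, axis=1) <= radius
        t[in1, 0] = -magnitude
        t[in2, 0] = magnitude
        return t

    return fn


def sensitivity_analysis(L0: float = 1.5, rows: int = 16, cols: int = 16,
                         jitter_sd: float = PRINT_JITTER_SD,
                         noise_sd: float = 10.0,
                         height: float = 30.0,
                         amplitudes_Pa: Sequence[float] = (400.0, 300.0,
                                                           250.0, 200.0,
                                                           150.0, 100.0),
                         n_noise: int = 6, patch_radius: float = 2.0,
                         patch_separation: float = 6.0, seed: int = 0
                         ) -> SensitivityResult:
    """Minimum traction magnitude recoverable above the pipeline noise floor.

    Localized tractions (a contractile patch pair) of decreasing magnitude
    are applied through a forward finite-element simulation; the resulting
    marker displacements are pushed through the complete inverse pipeline
    (render, detect, mesh, relax, FEM).  The detection statistic is the
    recovered traction projected onto the known applied pattern and
    averaged over the patch footprints (a matched filter: the applied
    signal accumulates coherently while isotropic noise averages towards
    zero); the noise floor is the mean plus two standard deviations of
    the same statistic measured on noise-only runs, so signal and noise
    are compared like for like.  The sensitivity is the smallest
    amplitude whose statistic exceeds the floor, scanning from the
    largest amplitude down until the first failure.
    """
    spec0 = LatticeSpec(L0=L0, rows=rows, cols=cols, jitter_sd=jitter_sd)
    x0, x1, y0, y1 = ideal_extent(spec0)
    centre = np.array([(x0 + x1) / 2.0, (y0 + y1) / 2.0])
    # displacements near the sensitivity limit are tens of nanometres, far
    # below the high-displacement refinement threshold: the adaptive sizing
    # rule gives the same uniform ~L0 in-plane mesh as the noise runs, so
    # signal and noise are measured on identical footing
    model = SubstrateModel(height=height, L0=L0)
    mesh = build_mesh(model, extent=(x0, x1, y0, y1))
    solver = FEASolver(model, mesh)
    rng = np.random.default_rng(seed)

    def matched_statistic(tf: TractionField) -> float:
        p = tf.points[:, :2]
        c1 = centre + np.array([patch_separation / 2.0, 0.0])
        c2 = centre - np.array([patch_separation / 2.0, 0.0])
        in1 = np.linalg.norm(p - c1, axis=1) <= patch_radius
        in2 = np.linalg.norm(p - c2, axis=1) <= patch_radius
        # applied pattern: -x in patch 1, +x in patch 2
        proj = np.concatenate([-tf.traction[in1, 0], tf.traction[in2, 0]])
        return float(proj.mean())

    def one_run(magnitude: float, s: int) -> TractionField:
        arr = sim.make_lattice(LatticeSpec(L0=L0, rows=rows, cols=cols,
                                           jitter_sd=jitter_sd, seed=s))
        if magnitude > 0:
            tfn = traction_patch_pair(centre, patch_separation, patch_radius,
                                      magnitude)
            interp, _ = forward_surface_displacement(model, mesh, tfn,
                                                     solver=solver)
            arr = sim.apply_deformation(
                arr, lambda pos: interp(pos[:, :2])[:, : pos.shape[1]])
        img = sim.render_image(arr, ImagingSpec(noise_sd=noise_sd), seed=s + 1)
        res = analyze_image(img, L0)
        tf, _ = reconstruct_tractions(res.disp, model, solver=solver)
        return tf

    noise_stats = []
    for _ in range(n_noise):
        tf = one_run(0.0, int(rng.integers(2 ** 31 - 10)))
        noise_stats.append(matched_statistic(tf))
    noise_arr = np.asarray(noise_stats)
    floor = float(noise_arr.mean() + 2.0 * noise_arr.std())

    amplitudes = sorted(amplitudes_Pa, reverse=True)
    peaks, threshold = [], None
    for amp in amplitudes:
        tf = one_run(amp, int(rng.integers(2 ** 31 - 10)))
        stat = matched_statistic(tf)
        peaks.append(stat)
        if stat > floor:
            threshold = amp
        else:
            break
    return SensitivityResult(threshold_Pa=threshold,
                             amplitudes_Pa=list(amplitudes[:len(peaks)]),
                             recovered_peak_Pa=peaks, noise_floor_Pa=floor,
                             noise_peaks_Pa=noise_stats)
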