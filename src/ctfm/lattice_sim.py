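"""In-silico nanodisc arrays and synthetic microscopy images.

The substrate carries a printed triangular (hexagonal-packing) array of
fluorescent quantum-dot nanodiscs with known spacing ``L0``.  This module
generates such arrays (optionally with Gaussian printing jitter), deforms
them with analytic displacement fields standing in for cell tractions, and
renders the 2D images / 3D stacks a fluorescence microscope would record:
isotropic Gaussian spots plus additive Gaussian read noise.

Every stage of the traction-reconstruction pipeline is validated against
this generator, because it retains per-disc ground truth (printed
positions, imposed displacements) that a real experiment never observes.

Conventions
-----------
* All coordinates are in micrometres, right-handed x-y frame.
* Lattice rows run along x; odd rows are shifted by ``L0/2``; row pitch is
  ``L0*sqrt(3)/2``.  The first node sits at the origin.
* Pixel centres are at ``(i + 0.5) * pixel_size`` relative to the image
  origin (0-based indices, x along columns, y along rows).
* Images default to 8-bit grey levels with a spot peak of 200, so that an
  additive noise s.d. of 10 grey levels matches the common 8-bit ImageJ
  convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional
import warnings

import numpy as np
import pandas as pd
import tifffile


class InvalidSpecError(ValueError):
    """Raised when a lattice or imaging specification violates its invariants."""


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of a printed nanodisc array.

    Parameters
    ----------
    L0 : float
        Reference inter-disc spacing in micrometres (typically 0.75-3).
    rows, cols : int
        Lattice extent; at least 3 each.
    jitter_sd : float
        Isotropic printing-position error s.d. per axis, micrometres
        (0.035 for the printing process emulated here).
    seed : int
        RNG seed for the jitter draw.
    """

    L0: float
    rows: int = 10
    cols: int = 10
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.L0) and self.L0 > 0):
            raise InvalidSpecError(f"L0 must be positive, got {self.L0}")
        if self.rows < 3 or self.cols < 3:
            raise InvalidSpecError("rows and cols must be >= 3")
        if self.jitter_sd < 0:
            raise InvalidSpecError("jitter_sd must be >= 0")


@dataclass(frozen=True)
class ImagingSpec:
    """Rendering parameters for synthetic fluorescence images.

    ``spot_sd`` is the s.d. of the rendered Gaussian spot (0.2 um emulates
    the microscope's convolution of a sub-diffraction nanodisc);
    ``noise_sd`` is additive Gaussian read noise in grey levels (10 by
    default).  ``z_sd`` controls the axial spot size for 3D stacks.
    """

    pixel_size: float = 0.1
    spot_sd: float = 0.2
    noise_sd: float = 10.0
    bit_depth: int = 8
    peak: float = 200.0
    baseline: float = 0.0     # camera offset added before noise
    pad: float = 1.0          # um of blank margin around the array bbox
    z_step: float = 0.1       # um between slices in a stack
    n_slices: int = 31
    z_sd: float = 0.4         # axial Gaussian s.d. (>= lateral)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise InvalidSpecError("pixel_size must be > 0")
        if self.spot_sd <= 0:
            raise InvalidSpecError("spot_sd must be > 0")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")

    @property
    def max_grey(self) -> int:
        return 2 ** self.bit_depth - 1


@dataclass
class NanodiscArray:
    """Positions of (simulated or detected) nanodiscs.

    ``positions`` is ``(n, 2)`` or ``(n, 3)`` in micrometres.  For
    simulated arrays, ``printed`` keeps the true printed (load-free)
    positions and ``u_true`` the imposed displacement per disc, so that
    reconstruction error can be measured exactly.
    """

    positions: np.ndarray
    L0: float
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]
    printed: Optional[np.ndarray] = None
    u_true: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("nanodisc positions must be finite")
        if self.labels is None:
            self.labels = np.arange(len(self.positions))
        self.labels = np.asarray(self.labels)
        if len(np.unique(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def xy(self) -> np.ndarray:
        return self.positions[:, :2]


@dataclass(frozen=True)
class RenderedImage:
    """A rendered image plus the mapping from pixels to micrometres."""

    data: np.ndarray
    pixel_size: float
    origin: np.ndarray  # (x, y) of the outer corner of pixel (0, 0), um

    def pixel_centres(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.data.shape[-2:]
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.pixel_size
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.pixel_size
        return xs, ys


def make_lattice(spec: LatticeSpec) -> NanodiscArray:
    """Generate a triangular lattice of nanodiscs, with optional printing jitter.

    With ``jitter_sd == 0`` every interior node has exactly six neighbours
    at distance ``L0``.  With jitter, i.i.d. isotropic Gaussian offsets are
    added per node; the jittered positions are the *printed* ground truth.
    """
    r, c = np.meshgrid(np.arange(spec.rows), np.arange(spec.cols), indexing="ij")
    x = c * spec.L0 + (r % 2) * spec.L0 / 2.0
    y = r * spec.L0 * np.sqrt(3.0) / 2.0
    pos = np.column_stack([x.ravel(), y.ravel()]).astype(float)
    if spec.jitter_sd > 0:
        rng = np.random.default_rng(spec.seed)
        pos = pos + rng.normal(0.0, spec.jitter_sd, size=pos.shape)
    return NanodiscArray(positions=pos, L0=spec.L0, printed=pos.copy(),
                         u_true=np.zeros_like(pos))


DisplacementFunction = Callable[[np.ndarray], np.ndarray]


def apply_deformation(arr: NanodiscArray, fn: DisplacementFunction) -> NanodiscArray:
    """Displace every disc by ``fn(positions)``; ground truth is retained.

    ``fn`` maps an ``(n, d)`` position array to ``(n, d)`` displacements in
    micrometres.  The returned array's ``u_true`` is measured from the
    printed positions, so chained deformations accumulate.
    """
    u = np.asarray(fn(arr.positions), dtype=float)
    if u.shape != arr.positions.shape:
        raise ValueError(f"displacement field shape {u.shape} != positions "
                         f"shape {arr.positions.shape}")
    if not np.all(np.isfinite(u)):
        raise ValueError("displacement field returned non-finite values")
    printed = arr.printed if arr.printed is not None else arr.positions.copy()
    new_pos = arr.positions + u
    return NanodiscArray(positions=new_pos, L0=arr.L0, labels=arr.labels.copy(),
                         printed=printed.copy(), u_true=new_pos - printed)


# ---------------------------------------------------------------------------
# Built-in displacement fields (invented plumbing standing in for the
# tractions a cell would impose; peak amplitudes are exact by construction).
# ---------------------------------------------------------------------------

def contractile_dipole(centre: tuple[float, float], separation: float,
                       sigma: float, peak: float,
                       axis: tuple[float, float] = (1.0, 0.0)) -> DisplacementFunction:
    """Two Gaussian lobes pulling material towards the dipole midpoint.

    Mimics the displacement footprint of a contractile cell: material near
    each pole moves towards the centre, with per-lobe amplitude ``peak``
    (so ``max |u| == peak`` when the lobes are well separated).
    """
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    cen = np.asarray(centre, dtype=float)
    p1 = cen + a * separation / 2.0
    p2 = cen - a * separation / 2.0

    def fn(pos: np.ndarray) -> np.ndarray:
        xy = pos[:, :2]
        g1 = np.exp(-np.sum((xy - p1) ** 2, axis=1) / (2 * sigma ** 2))
        g2 = np.exp(-np.sum((xy - p2) ** 2, axis=1) / (2 * sigma ** 2))
        u = peak * (g2[:, None] - g1[:, None]) * a[None, :]
        out = np.zeros_like(pos)
        out[:, :2] = u
        return out

    return fn


def radial_contraction(centre: tuple[float, float], sigma: float,
                       peak: float) -> DisplacementFunction:
    """Axisymmetric inward pull, max |u| = peak attained at r = sigma."""
    cen = np.asarray(centre, dtype=float)

    def fn(pos: np.ndarray) -> np.ndarray:
        d = pos[:, :2] - cen
        r = np.linalg.norm(d, axis=1)
        mag = peak * (r / sigma) * np.exp(0.5 - r ** 2 / (2 * sigma ** 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(r[:, None] > 0, d / np.maximum(r, 1e-300)[:, None], 0.0)
        out = np.zeros_like(pos)
        out[:, :2] = -mag[:, None] * unit
        return out

    return fn


def uniform_shear(gamma: float) -> DisplacementFunction:
    """Simple shear u_x = gamma * y."""

    def fn(pos: np.ndarray) -> np.ndarray:
        out = np.zeros_like(pos)
        out[:, 0] = gamma * pos[:, 1]
        return out

    return fn


def uniform_translation(vec) -> DisplacementFunction:
    v = np.asarray(vec, dtype=float)

    def fn(pos: np.ndarray) -> np.ndarray:
        out = np.zeros_like(pos)
        out[:, : len(v)] = v
        return out

    return fn


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _image_frame(arr: NanodiscArray, img: ImagingSpec):
    xy = arr.xy
    lo = xy.min(axis=0) - img.pad
    hi = xy.max(axis=0) + img.pad
    nx = int(np.ceil((hi[0] - lo[0]) / img.pixel_size))
    ny = int(np.ceil((hi[1] - lo[1]) / img.pixel_size))
    if min(nx, ny) * img.pixel_size < 3 * img.spot_sd:
        warnings.warn("image field of view smaller than 3 spot s.d.; spots "
                      "will be clipped", stacklevel=3)
    return np.asarray(lo), nx, ny


def _gaussian_spots(xy: np.ndarray, origin: np.ndarray, nx: int, ny: int,
                    pixel_size: float, spot_sd: float, peak: float) -> np.ndarray:
    """Sum of isotropic Gaussian spots sampled at pixel centres."""
    img = np.zeros((ny, nx))
    # render each spot only on a local window (6 sd) for speed
    half = int(np.ceil(4.0 * spot_sd / pixel_size)) + 1
    xs = origin[0] + (np.arange(nx) + 0.5) * pixel_size
    ys = origin[1] + (np.arange(ny) + 0.5) * pixel_size
    for x0, y0 in xy:
        ci = int((x0 - origin[0]) / pixel_size)
        ri = int((y0 - origin[1]) / pixel_size)
        c0, c1 = max(ci - half, 0), min(ci + half + 1, nx)
        r0, r1 = max(ri - half, 0), min(ri + half + 1, ny)
        if c0 >= c1 or r0 >= r1:
            continue
        gx = np.exp(-((xs[c0:c1] - x0) ** 2) / (2 * spot_sd ** 2))
        gy = np.exp(-((ys[r0:r1] - y0) ** 2) / (2 * spot_sd ** 2))
        img[r0:r1, c0:c1] += peak * gy[:, None] * gx[None, :]
    return img


def render_image(arr: NanodiscArray, img: ImagingSpec,
                 seed: Optional[int] = None) -> RenderedImage:
    """Render a 2D grey-scale image of the array.

    The image is the sum of isotropic Gaussian spots (s.d. ``spot_sd``,
    peak ``peak``) at the exact disc positions, plus additive Gaussian
    noise of s.d. ``noise_sd`` grey levels, clipped to the grey-level
    range and quantized to integers.
    """
    origin, nx, ny = _image_frame(arr, img)
    data = img.baseline + _gaussian_spots(arr.xy, origin, nx, ny,
                                          img.pixel_size, img.spot_sd,
                                          img.peak)
    if img.noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, img.noise_sd, size=data.shape)
    data = np.clip(np.rint(data), 0, img.max_grey)
    dtype = np.uint8 if img.bit_depth <= 8 else np.uint16
    return RenderedImage(data=data.astype(dtype), pixel_size=img.pixel_size,
                         origin=origin)


def render_stack(arr: NanodiscArray, img: ImagingSpec,
                 seed: Optional[int] = None) -> RenderedImage:
    """Render a 3D stack; each disc is an anisotropic 3D Gaussian.

    Slices are ``z_step`` apart, slice ``k`` at ``z = (k - (n-1)/2) *
    z_step`` so the stack is centred on z = 0.  Discs whose z lies outside
    the stack are clipped with a warning.
    """
    if img.n_slices < 3:
        raise InvalidSpecError("stacks need at least 3 slices")
    origin, nx, ny = _image_frame(arr, img)
    z = arr.positions[:, 2] if arr.positions.shape[1] > 2 else np.zeros(len(arr))
    zs = (np.arange(img.n_slices) - (img.n_slices - 1) / 2.0) * img.z_step
    if z.min() < zs[0] or z.max() > zs[-1]:
        warnings.warn("disc z outside stack range; axial profiles clipped",
                      stacklevel=2)
    stack = np.zeros((img.n_slices, ny, nx))
    for k, zk in enumerate(zs):
        w = np.exp(-((zk - z) ** 2) / (2 * img.z_sd ** 2))
        keep = w > 1e-4
        if not np.any(keep):
            continue
        plane = np.zeros((ny, nx))
        # per-disc axial weight scales the lateral Gaussian peak
        for (x0, y0), wk in zip(arr.xy[keep], w[keep]):
            plane += _gaussian_spots(np.array([[x0, y0]]), origin, nx, ny,
                                     img.pixel_size, img.spot_sd,
                                     img.peak * wk)
        stack[k] = plane
    stack = stack + img.baseline
    if img.noise_sd > 0:
        rng = np.random.default_rng(seed)
        stack = stack + rng.normal(0.0, img.noise_sd, size=stack.shape)
    stack = np.clip(np.rint(stack), 0, img.max_grey)
    dtype = np.uint8 if img.bit_depth <= 8 else np.uint16
    return RenderedImage(data=stack.astype(dtype), pixel_size=img.pixel_size,
                         origin=origin)


def stack_slice_z(img: ImagingSpec) -> np.ndarray:
    """z coordinate of every slice of a stack rendered with ``img``."""
    return (np.arange(img.n_slices) - (img.n_slices - 1) / 2.0) * img.z_step


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_tiff(path, image: RenderedImage) -> None:
    tifffile.imwrite(path, image.data)


def write_ground_truth(path, arr: NanodiscArray) -> None:
    """Ground-truth CSV: label,x,y,z,ux,uy,uz (um; z columns 0 for 2D)."""
    n = len(arr)
    pos = np.zeros((n, 3))
    pos[:, : arr.positions.shape[1]] = arr.positions
    u = np.zeros((n, 3))
    if arr.u_true is not None:
        u[:, : arr.u_true.shape[1]] = arr.u_true
    df = pd.DataFrame({
        "label": arr.labels,
        "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
        "ux": u[:, 0], "uy": u[:, 1], "uz": u[:, 2],
    })
    df.to_csv(path, index=False)
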