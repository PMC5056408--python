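"""Sub-pixel nanodisc localization.

In-plane positions are found by thresholding the image, identifying
8-connected supra-threshold pixel islands and taking the intensity-weighted
centroid of each island.  On well-sampled Gaussian spots this reaches a
localization precision of a few nanometres.  Axial (z) positions come from
an intensity profile along z within a small lateral window around each
disc, fitted with a parabola on the log-intensity near the peak
(equivalent to a Gaussian fit), followed by a least-squares plane fit to
remove sample tilt relative to the focal plane.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union
import warnings

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .lattice_sim import NanodiscArray, RenderedImage


class DetectionError(RuntimeError):
    pass


@dataclass(frozen=True)
class DetectionParams:
    """Parameters of the spot detector.

    ``threshold`` is a grey level or ``"auto"`` (Otsu).  ``spot_xy`` and
    ``spot_z`` are the lateral/axial spot sizes in micrometres used to
    size the z-profiling window and the merged-island splitting distance
    (defaults 0.717 / 1.434, the spot footprint of the quantum-dot discs
    at this magnification).  By default the centroid weights are the grey
    values minus the threshold (removes the pixel-locking bias the flat
    background pedestal would otherwise induce); set
    ``subtract_threshold=False`` for raw grey-value weights.
    """

    threshold: Union[float, str] = "auto"
    min_island_px: int = 4
    spot_xy: float = 0.717
    spot_z: float = 1.434
    subtract_threshold: bool = True
    split_merged: bool = True

    def __post_init__(self) -> None:
        if self.min_island_px < 1:
            raise ValueError("min_island_px must be >= 1")


@dataclass
class DetectionResult:
    positions: NanodiscArray
    mass: np.ndarray
    tilt_plane: Optional[tuple[float, float, float]] = None  # z = a x + b y + c
    unreliable_z: Optional[np.ndarray] = None


def _resolve_threshold(data: np.ndarray, params: DetectionParams) -> float:
    if params.threshold == "auto":
        return float(threshold_otsu(data))
    thr = float(params.threshold)
    if not (data.min() <= thr <= data.max()):
        raise DetectionError(f"threshold {thr} outside image grey range "
                             f"[{data.min()}, {data.max()}]")
    return thr


def detect_xy(image: RenderedImage, params: DetectionParams = DetectionParams()
              ) -> DetectionResult:
    """Locate discs in a 2D image by weighted centroids of pixel islands.

    Returns positions in micrometres (image frame).  Islands smaller than
    ``min_island_px`` are discarded.  Islands containing two or more local
    intensity maxima at least one spot radius apart are split by a
    marker-based watershed before the centroid step (two discs merged into
    one island by deformation).
    """
    data = np.asarray(image.data, dtype=float)
    if data.ndim != 2:
        raise DetectionError("detect_xy expects a single 2D image")
    if data.max() == data.min():
        raise DetectionError("flat image: no contrast to threshold")
    thr = _resolve_threshold(data, params)
    mask = data > thr
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        warnings.warn("no pixel island found above threshold", stacklevel=2)
        empty = NanodiscArray(positions=np.empty((0, 2)), L0=np.nan,
                              labels=np.empty(0, dtype=int))
        return DetectionResult(positions=empty, mass=np.empty(0))

    if params.split_merged:
        # peaks are sought on a lightly smoothed copy: read noise can fill
        # the valley between two discs merged into one island, hiding the
        # second maximum
        smooth = ndimage.gaussian_filter(data, sigma=1.0)
        min_dist = max(2, int(round(params.spot_xy / (2.5 * image.pixel_size))))
        peaks = peak_local_max(smooth, min_distance=min_dist, labels=labels,
                               threshold_abs=thr, exclude_border=False)
        markers = np.zeros_like(labels)
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i
        labels = watershed(-data, markers=markers, mask=mask)
        n = labels.max()

    sizes = ndimage.sum_labels(np.ones_like(data), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= params.min_island_px) + 1
    if keep.size == 0:
        warnings.warn("all islands below min_island_px", stacklevel=2)
        empty = NanodiscArray(positions=np.empty((0, 2)), L0=np.nan,
                              labels=np.empty(0, dtype=int))
        return DetectionResult(positions=empty, mass=np.empty(0))

    weights = data - thr if params.subtract_threshold else data
    mass = ndimage.sum_labels(weights, labels, index=keep)
    com = np.array(ndimage.center_of_mass(weights, labels, index=keep))  # (row, col)
    # pixel-centre convention: centre of pixel (r, c) is origin + (c+0.5, r+0.5)*ps
    x = image.origin[0] + (com[:, 1] + 0.5) * image.pixel_size
    y = image.origin[1] + (com[:, 0] + 0.5) * image.pixel_size
    pos = np.column_stack([x, y])
    order = np.lexsort((pos[:, 0], pos[:, 1]))
    arr = NanodiscArray(positions=pos[order], L0=np.nan,
                        labels=np.arange(len(keep)))
    return DetectionResult(positions=arr, mass=np.asarray(mass)[order])


def detect_z(stack: RenderedImage, xy_positions: np.ndarray, slice_z: np.ndarray,
             params: DetectionParams = DetectionParams()
             ) -> tuple[np.ndarray, np.ndarray]:
    """Per-disc z from the axial intensity profile at each xy position.

    For every disc, pixels within ``spot_xy / 2`` laterally are summed per
    slice; the peak of the profile is refined to sub-slice resolution with
    a parabolic fit to ``log`` intensity over the peak and its two
    neighbours.  Returns ``(z, unreliable)`` where ``unreliable`` flags
    discs whose profile peaks at the first or last slice.
    """
    data = np.asarray(stack.data, dtype=float)
    if data.ndim != 3 or data.shape[0] < 3:
        raise DetectionError("detect_z expects a stack with >= 3 slices")
    nz, ny, nx = data.shape
    xs, ys = (np.arange(nx) + 0.5) * stack.pixel_size + stack.origin[0], \
             (np.arange(ny) + 0.5) * stack.pixel_size + stack.origin[1]
    bg = np.median(data)
    radius = params.spot_xy / 2.0
    z_out = np.zeros(len(xy_positions))
    bad = np.zeros(len(xy_positions), dtype=bool)
    for i, (x0, y0) in enumerate(np.asarray(xy_positions)[:, :2]):
        csel = np.flatnonzero(np.abs(xs - x0) <= radius)
        rsel = np.flatnonzero(np.abs(ys - y0) <= radius)
        if csel.size == 0 or rsel.size == 0:
            bad[i] = True
            continue
        window = data[:, rsel[0]:rsel[-1] + 1, csel[0]:csel[-1] + 1]
        prof = window.sum(axis=(1, 2)) - bg * window.shape[1] * window.shape[2]
        k = int(np.argmax(prof))
        if k == 0 or k == nz - 1:
            z_out[i] = slice_z[k]
            bad[i] = True
            continue
        y3 = prof[k - 1:k + 2]
        y3 = np.log(np.maximum(y3, 1e-9 * y3.max() if y3.max() > 0 else 1e-9))
        denom = y3[0] - 2 * y3[1] + y3[2]
        delta = 0.0 if denom >= 0 else 0.5 * (y3[0] - y3[2]) / denom
        delta = float(np.clip(delta, -0.5, 0.5))
        z_out[i] = slice_z[k] + delta * (slice_z[1] - slice_z[0])
    return z_out, bad


def tilt_correct(positions: np.ndarray) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Remove sample tilt by subtracting a least-squares plane from z.

    ``positions`` is ``(n, 3)``.  Returns the corrected positions (same
    x, y; z minus the fitted plane ``z = a x + b y + c``) and ``(a, b, c)``.
    """
    p = np.asarray(positions, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3 or len(p) < 3:
        raise DetectionError("tilt_correct needs >= 3 points with x, y, z")
    A = np.column_stack([p[:, 0], p[:, 1], np.ones(len(p))])
    if np.linalg.matrix_rank(A) < 3:
        raise DetectionError("degenerate plane fit: points are collinear")
    coeff, *_ = np.linalg.lstsq(A, p[:, 2], rcond=None)
    corrected = p.copy()
    corrected[:, 2] = p[:, 2] - A @ coeff
    return corrected, (float(coeff[0]), float(coeff[1]), float(coeff[2]))


def match_to_truth(detected: np.ndarray, truth: np.ndarray,
                   max_dist: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Greedy nearest matching of detected to ground-truth positions.

    Helper for precision benchmarks: returns index arrays ``(det_idx,
    truth_idx)`` of mutual nearest neighbours within ``max_dist`` um.
    """
    from scipy.spatial import cKDTree
    det = np.asarray(detected)[:, :2]
    tru = np.asarray(truth)[:, :2]
    tree = cKDTree(tru)
    d, j = tree.query(det, distance_upper_bound=max_dist)
    ok = np.isfinite(d)
    # enforce one-to-one: keep closest detection per truth point
    best: dict[int, int] = {}
    for i in np.flatnonzero(ok):
        jj = int(j[i])
        if jj not in best or d[i] < d[best[jj]]:
            best[jj] = i
    truth_idx = np.array(sorted(best.keys()), dtype=int)
    det_idx = np.array([best[jj] for jj in truth_idx], dtype=int)
    return det_idx, truth_idx
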