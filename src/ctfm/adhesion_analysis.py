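"""Focal-adhesion segmentation and per-adhesion force integration.

Cells transmit traction mostly through focal adhesions, visible in a
second fluorescence channel (e.g. a paxillin marker) that the platform
can acquire simultaneously with the marker array.  This module segments
adhesions from such an image (background subtraction, CLAHE contrast
enhancement, Laplacian-of-Gaussian filtering, thresholding, area filter
> 0.5 um^2) and integrates the reconstructed traction field over each
adhesion footprint to report the force per adhesion (nN), plus the
out-of-plane/in-plane traction ratio statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import exposure, restoration
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .lattice_sim import RenderedImage
from .traction_fem import TractionField


@dataclass(frozen=True)
class AdhesionParams:
    """Segmentation parameters.

    ``threshold``: manual threshold on the filtered response, or "auto"
    (Otsu) - unattended runs need a reproducible default even though the
    reference procedure was thresholded by eye.  ``log_sigma`` is the
    Laplacian-of-Gaussian scale in um, ``rolling_ball_radius`` the
    background-subtraction radius in um, ``min_area`` the strict lower
    area bound in um^2 (adhesions of exactly this area are excluded).
    """

    threshold: Union[float, str] = "auto"
    log_sigma: float = 0.5
    rolling_ball_radius: float = 5.0
    clahe_clip: float = 0.01
    min_area: float = 0.5


@dataclass
class AdhesionSet:
    """Segmented adhesions, optionally annotated with forces."""

    masks: np.ndarray            # (ny, nx) int labels, 0 = background
    areas: np.ndarray            # um^2
    centroids: np.ndarray        # (n, 2) um
    pixel_size: float
    origin: np.ndarray
    mean_traction_Pa: Optional[np.ndarray] = None
    force_nN: Optional[np.ndarray] = None      # (n, 2 or 3) vectors

    def __len__(self) -> int:
        return len(self.areas)

    def to_frame(self) -> pd.DataFrame:
        d = {"id": np.arange(1, len(self) + 1), "area_um2": self.areas,
             "x_um": self.centroids[:, 0], "y_um": self.centroids[:, 1]}
        if self.mean_traction_Pa is not None:
            d["mean_traction_Pa"] = self.mean_traction_Pa
        if self.force_nN is not None:
            d["force_nN"] = np.linalg.norm(self.force_nN, axis=1)
            d["fx_nN"] = self.force_nN[:, 0]
            d["fy_nN"] = self.force_nN[:, 1]
            if self.force_nN.shape[1] > 2:
                d["fz_nN"] = self.force_nN[:, 2]
        return pd.DataFrame(d)


def segment_adhesions(image: RenderedImage,
                      params: AdhesionParams = AdhesionParams()) -> AdhesionSet:
    """Segment focal adhesions from a marker-channel image.

    Pipeline: rolling-ball background subtraction -> CLAHE -> LoG filter
    -> threshold (manual or Otsu) -> connected components -> strict area
    filter ``> min_area``.
    """
    data = np.asarray(image.data, dtype=float)
    ps = image.pixel_size
    # featureless-image guard: CLAHE equalizes local contrast, so running
    # the pipeline on a noise-only image would segment its own noise; an
    # image without any pixel well above the background noise level has no
    # adhesions to find
    sigma_bg = 1.4826 * np.median(np.abs(data - np.median(data))) + 1e-12
    if data.max() - np.median(data) < 6.0 * sigma_bg:
        warnings.warn("no adhesion above the area filter (featureless "
                      "image)", stacklevel=2)
        return AdhesionSet(masks=np.zeros(data.shape, dtype=int),
                           areas=np.empty(0), centroids=np.empty((0, 2)),
                           pixel_size=ps, origin=np.asarray(image.origin))
    if data.max() > data.min():
        bg = restoration.rolling_ball(
            data, radius=max(1, int(round(params.rolling_ball_radius / ps))))
        data = data - bg
        rng = data.max() - data.min()
        norm = (data - data.min()) / rng
        norm = exposure.equalize_adapthist(norm, clip_limit=params.clahe_clip)
        # negated LoG: bright blobs -> positive response
        resp = -ndimage.gaussian_laplace(norm, sigma=params.log_sigma / ps)
    else:
        resp = np.zeros_like(data)
    if params.threshold == "auto":
        if resp.max() == resp.min():
            thr = np.inf
        else:
            # Otsu, floored at mean + 2 s.d. so a featureless (pure-noise)
            # image does not segment its own noise
            thr = max(float(threshold_otsu(resp)),
                      float(resp.mean() + 2.0 * resp.std()))
    else:
        thr = float(params.threshold)
    mask = resp > thr
    labels = label(mask, connectivity=2)
    px_area = ps ** 2
    keep_labels = []
    for region in regionprops(labels):
        if region.area * px_area > params.min_area:
            keep_labels.append(region.label)
    if not keep_labels:
        warnings.warn("no adhesion above the area filter", stacklevel=2)
        return AdhesionSet(masks=np.zeros_like(labels), areas=np.empty(0),
                           centroids=np.empty((0, 2)), pixel_size=ps,
                           origin=np.asarray(image.origin))
    out = np.zeros_like(labels)
    areas, cents = [], []
    for new_id, lab in enumerate(keep_labels, start=1):
        sel = labels == lab
        out[sel] = new_id
        areas.append(sel.sum() * px_area)
        r, c = np.nonzero(sel)
        cents.append([image.origin[0] + (c.mean() + 0.5) * ps,
                      image.origin[1] + (r.mean() + 0.5) * ps])
    return AdhesionSet(masks=out, areas=np.array(areas),
                       centroids=np.array(cents), pixel_size=ps,
                       origin=np.asarray(image.origin))


def force_per_adhesion(adhesions: AdhesionSet,
                       tractions: TractionField) -> AdhesionSet:
    """Integrate the traction field over each adhesion footprint.

    The traction field is linearly interpolated to every mask pixel and
    summed times the pixel area; forces come out in nN (Pa um^2 * 1e-3).
    Raises if any mask pixel falls outside the traction-field domain.
    """
    interp = tractions.interpolator()
    ps = adhesions.pixel_size
    n = len(adhesions)
    forces = np.zeros((n, tractions.traction.shape[1]))
    mean_t = np.zeros(n)
    for i in range(1, n + 1):
        r, c = np.nonzero(adhesions.masks == i)
        xy = np.column_stack([adhesions.origin[0] + (c + 0.5) * ps,
                              adhesions.origin[1] + (r + 0.5) * ps])
        t = interp(xy)
        if np.any(np.isnan(t)):
            raise ValueError(f"adhesion {i} extends outside the traction "
                             "field domain")
        forces[i - 1] = t.sum(axis=0) * ps ** 2 * 1e-3
        mean_t[i - 1] = float(np.linalg.norm(t, axis=1).mean())
    return AdhesionSet(masks=adhesions.masks, areas=adhesions.areas,
                       centroids=adhesions.centroids,
                       pixel_size=ps, origin=adhesions.origin,
                       mean_traction_Pa=mean_t, force_nN=forces)


def oop_ratio(tractions: TractionField,
              noise_floor_Pa: float = 0.0) -> dict:
    """Out-of-plane/in-plane traction ratio per surface node.

    ``ratio = |t_z| / |(t_x, t_y)|`` where the in-plane magnitude exceeds
    ``noise_floor_Pa``; summary percentiles are reported.  Requires a
    3-component field.
    """
    t = tractions.traction
    if t.shape[1] < 3:
        raise ValueError("out-of-plane ratio requires a 3-component "
                         "traction field (z data missing)")
    ip = np.linalg.norm(t[:, :2], axis=1)
    sel = ip > noise_floor_Pa
    if not np.any(sel):
        return {"ratios": np.empty(0), "median": np.nan,
                "p10": np.nan, "p90": np.nan, "n": 0}
    ratios = np.abs(t[sel, 2]) / ip[sel]
    return {"ratios": ratios, "median": float(np.median(ratios)),
            "p10": float(np.percentile(ratios, 10)),
            "p90": float(np.percentile(ratios, 90)), "n": int(sel.sum())}


def write_adhesions_csv(path, adhesions: AdhesionSet) -> None:
    adhesions.to_frame().to_csv(path, index=False)
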