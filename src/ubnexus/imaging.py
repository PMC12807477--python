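"""Nuclear image quantification.

Segments nuclei from the DAPI channel, partitions each nucleus into the
NPM1-bright (nucleolar) and NPM1-dim (nucleoplasmic) compartments by
per-ROI Otsu thresholding, measures bright-object morphometry
(area, Crofton perimeter, circularity = 4*pi*A/P^2, aspect ratio =
minFeret/maxFeret via a rotating-calipers sweep of the convex hull), and
computes compartmental Pearson colocalization and per-nucleus intensity
statistics (MFI, SD).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy import stats as sps
from scipy.spatial import ConvexHull, QhullError
from skimage import measure
from skimage.filters import threshold_otsu

FERET_ANGULAR_STEP_DEG = 1.0   # caliper sweep resolution


@dataclass
class NucleusROI:
    mask: np.ndarray
    label: int
    area: int


@dataclass
class CompartmentMasks:
    bright: np.ndarray
    dim: np.ndarray
    degenerate: bool      # uniform NPM1 inside the ROI: no bright compartment


@dataclass
class ObjectShape:
    label: int
    area: float           # px^2
    perimeter: float      # px, Crofton estimate
    circularity: float    # 4*pi*A/P^2, clamped to <= 1
    aspect_ratio: float   # minFeret / maxFeret
    min_feret: float
    max_feret: float
    centroid: tuple[float, float]


def segment_nuclei(dapi: np.ndarray, min_area: int = 500) -> list[NucleusROI]:
    """Nuclear ROIs: global Otsu on DAPI, hole filling, size filter."""
    dapi = np.asarray(dapi, dtype=float)
    if dapi.size == 0 or dapi.max() == dapi.min():
        return []
    t = threshold_otsu(dapi)
    mask = ndi.binary_fill_holes(dapi > t)
    labels = measure.label(mask, connectivity=2)
    rois = []
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        rois.append(NucleusROI(mask=labels == region.label,
                               label=int(region.label),
                               area=int(region.area)))
    return rois


def bright_mask(npm1: np.ndarray, roi: NucleusROI) -> CompartmentMasks:
    """NPM1-bright/dim partition of a nucleus by per-ROI Otsu.

    The threshold is computed from the NPM1 values inside the ROI only
    ("relative thresholding within nuclei"); bright and dim masks
    partition the ROI exactly.  Uniform NPM1 yields a degenerate result
    with an empty bright mask.
    """
    vals = np.asarray(npm1, dtype=float)[roi.mask]
    if vals.size == 0 or vals.max() == vals.min():
        empty = np.zeros_like(roi.mask)
        return CompartmentMasks(bright=empty, dim=roi.mask.copy(), degenerate=True)
    t = threshold_otsu(vals)
    bright = roi.mask & (np.asarray(npm1, dtype=float) > t)
    return CompartmentMasks(bright=bright, dim=roi.mask & ~bright, degenerate=False)


def feret_diameters(coords: np.ndarray,
                    step_deg: float = FERET_ANGULAR_STEP_DEG) -> tuple[float, float]:
    """(minFeret, maxFeret) of a pixel coordinate set.

    Caliper widths are projection extents of the convex hull vertices,
    swept over directions at ``step_deg`` resolution; min and max over
    directions give the two Feret diameters.
    """
    pts = np.asarray(coords, dtype=float)
    if len(pts) == 0:
        raise ValueError("empty coordinate set")
    try:
        pts = pts[ConvexHull(pts).vertices]
    except (QhullError, IndexError):
        pass  # degenerate (collinear/single) point sets: use all points
    angles = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    proj = pts @ dirs.T
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.min()), float(widths.max())


def object_shapes(mask: np.ndarray, min_area: int = 5) -> list[ObjectShape]:
    """Shape descriptors of the connected bright objects in a mask."""
    labels = measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    shapes = []
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        perim = float(region.perimeter_crofton)
        area = float(region.area)
        circ = 4.0 * np.pi * area / perim ** 2 if perim > 0 else 1.0
        mn, mx = feret_diameters(region.coords)
        ar = mn / mx if mx > 0 else 1.0
        shapes.append(ObjectShape(
            label=int(region.label), area=area, perimeter=perim,
            circularity=float(min(circ, 1.0)),
            aspect_ratio=float(min(ar, 1.0)),
            min_feret=mn, max_feret=mx,
            centroid=(float(region.centroid[0]), float(region.centroid[1])),
        ))
    return shapes


def compartment_pearson(ch_a: np.ndarray, ch_b: np.ndarray,
                        bright: np.ndarray, dim: np.ndarray
                        ) -> tuple[float, float]:
    """Pearson r of two channels inside the bright and dim masks."""
    out = []
    for m in (bright, dim):
        a = np.asarray(ch_a, dtype=float)[m]
        b = np.asarray(ch_b, dtype=float)[m]
        if a.size < 3:
            raise ValueError("compartment mask must contain >= 3 pixels")
        if a.std() == 0 or b.std() == 0:
            raise ValueError("zero variance in a compartment")
        out.append(float(sps.pearsonr(a, b).statistic))
    return out[0], out[1]


def nucleus_intensity_stats(channel: np.ndarray,
                            roi: NucleusROI) -> tuple[float, float]:
    """(MFI, SD) of a channel inside one nucleus.

    SD is the population standard deviation across the ROI pixels — the
    per-nucleus signal-spread statistic used to score diffuse versus
    punctate distribution.
    """
    vals = np.asarray(channel, dtype=float)[roi.mask]
    if vals.size == 0:
        raise ValueError("empty ROI")
    return float(vals.mean()), float(vals.std(ddof=0))
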