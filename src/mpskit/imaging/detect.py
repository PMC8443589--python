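"""Scaffold detection on the nuclei-channel mosaic and fixed ROI placement."""

from __future__ import annotations

import logging

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from mpskit.errors import InputError
from mpskit.imaging.types import ROISet, ScaffoldDetection, SlideMosaic

log = logging.getLogger(__name__)


def detect_scaffolds(
    mosaic: SlideMosaic,
    expected_radius_px: float,
    radius_tolerance: float = 0.5,
) -> list[ScaffoldDetection]:
    """Locate circular scaffolds by smoothed-intensity thresholding.

    The mosaic is Gaussian-smoothed, Otsu-thresholded, and connected
    components whose equivalent radius lies within ``radius_tolerance`` of
    the expected radius are kept.  The score is the component's circularity
    (4 pi A / P^2), i.e. a match against a circular template of its own
    radius.  Detections are returned row-major by centre; an empty mosaic
    yields an empty list.
    """
    img = mosaic.pixels.astype(np.float64)
    if img.std() < 1e-9:
        return []
    sm = gaussian_filter(img, sigma=max(2.0, expected_radius_px / 10.0))
    thr = threshold_otsu(sm)
    mask = sm > thr
    labels = label(mask)
    detections: list[ScaffoldDetection] = []
    for region in regionprops(labels):
        radius = np.sqrt(region.area / np.pi)
        if not (
            (1 - radius_tolerance) * expected_radius_px
            <= radius
            <= (1 + radius_tolerance) * expected_radius_px
        ):
            continue
        perimeter = max(region.perimeter, 1e-9)
        circularity = min(1.0, 4.0 * np.pi * region.area / perimeter**2)
        detections.append(
            ScaffoldDetection(
                centre=(float(region.centroid[0]), float(region.centroid[1])),
                radius_px=float(radius),
                score=float(circularity),
            )
        )
    detections.sort(key=lambda d: (d.centre[0], d.centre[1]))
    log.info("detected %d scaffolds", len(detections))
    return detections


def place_rois(
    det: ScaffoldDetection,
    template: list[tuple[float, float]],
    roi_size_px: int,
    mosaic_shape: tuple[int, int] | None = None,
    scaffold_id: int = 0,
) -> ROISet:
    """Place the fixed ROI array on a detected scaffold.

    ROI centres are the scaffold centre plus each template offset; the same
    template is applied to every scaffold.  With ``mosaic_shape`` given, any
    ROI box (half-open, ``roi_size_px`` square) extending beyond the mosaic
    raises an input error naming the ROI index.
    """
    if not template:
        raise InputError("template must be non-empty")
    centres = [(det.centre[0] + dr, det.centre[1] + dc) for dr, dc in template]
    if mosaic_shape is not None:
        half = roi_size_px / 2.0
        for i, (r, c) in enumerate(centres):
            if (
                r - half < 0
                or c - half < 0
                or r + half > mosaic_shape[0]
                or c + half > mosaic_shape[1]
            ):
                raise InputError(f"ROI {i} exceeds mosaic bounds")
    return ROISet(scaffold_id=scaffold_id, centres=centres, roi_size_px=roi_size_px)
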