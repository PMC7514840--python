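"""Region morphology: 10 shape descriptors per mask, gland and lumen.

Descriptors are the classic region properties (area, convex area,
eccentricity and orientation of the second-moment ellipse, equivalent
diameter, extent, perimeter, solidity) plus two compactness measures:
``roundness = (equiv_diameter / 2) * perimeter / area`` and
``compactness = perimeter / area``.
"""

from __future__ import annotations

import logging

import numpy as np
from skimage import measure as skmeasure

from .schema import MORPH_NAMES
from ..utils import as_bool_mask

log = logging.getLogger(__name__)


def region_morphology(mask: np.ndarray) -> dict:
    """The 10 shape descriptors of a single-component binary mask.

    Orientation is reported in degrees from the x-axis (columns) to the
    major axis of the second-moment ellipse, in (-90, 90].  Multi-component
    input falls back to the largest component with a warning.
    """
    mask = as_bool_mask(np.asarray(mask))
    if not mask.any():
        raise ValueError("empty mask has no morphology")
    labels = skmeasure.label(mask, connectivity=2)
    props = skmeasure.regionprops(labels)
    if len(props) > 1:
        log.warning("mask has %d components; using the largest", len(props))
        props.sort(key=lambda p: p.area, reverse=True)
    p = props[0]
    area = float(p.area)
    perimeter = float(p.perimeter)
    equiv_diam = float(np.sqrt(4.0 * area / np.pi))
    # skimage orientation: angle from the row axis, (-pi/2, pi/2]; convert
    # to the x-axis (column) convention in (-90, 90]
    angle_x = 90.0 - np.degrees(p.orientation)
    if angle_x > 90.0:
        angle_x -= 180.0
    bbox_area = (p.bbox[2] - p.bbox[0]) * (p.bbox[3] - p.bbox[1])
    return {
        "area": area,
        "convex_area": float(p.area_convex),
        "eccentricity": float(p.eccentricity),
        "equiv_diameter": equiv_diam,
        "extent": area / bbox_area,
        "orientation": float(angle_x),
        "perimeter": perimeter,
        "solidity": float(p.solidity),
        "roundness": (equiv_diam / 2.0) * perimeter / area,
        "compactness": perimeter / area,
    }


def morphological_features(masks) -> tuple[dict, bool]:
    """The 20 morphological features: gland block then lumen block.

    Returns ``(values, lumen_valid)``; an empty lumen mask yields zeroed
    lumen features and ``lumen_valid=False``.
    """
    values = {}
    gland = region_morphology(masks.gland_mask)
    for nm in MORPH_NAMES:
        values[f"morph.gland.{nm}"] = gland[nm]
    lumen_valid = bool(masks.lumen_mask.any())
    if lumen_valid:
        lumen = region_morphology(masks.lumen_mask)
        for nm in MORPH_NAMES:
            values[f"morph.lumen.{nm}"] = lumen[nm]
    else:
        for nm in MORPH_NAMES:
            values[f"morph.lumen.{nm}"] = 0.0
    return values, lumen_valid
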