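"""Gland and lumen mask extraction from a segmented candidate crop.

The segmentation stage delivers two images per candidate: the RGB bounding
box and the same crop with non-gland pixels zeroed.  The gland mask is
recovered from the masked crop by Otsu-thresholding the summed colour
components, then area opening (4-connectivity, 20 px), hole filling, and
keeping the largest component.  The lumen mask is the part of the
patch-level lumen map lying inside the gland mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters as skfilters
from skimage import morphology as skmorph

from ..utils import as_bool_mask

log = logging.getLogger(__name__)


class InvalidCandidateError(ValueError):
    """Raised when a candidate yields no usable gland mask."""


@dataclass
class GlandCandidate:
    """One segmented gland candidate (bounding-box crop + masked variant)."""

    rgb_bbox: np.ndarray
    masked_rgb: np.ndarray
    bbox: tuple[int, int, int, int]  # row0, col0, row1, col1; half-open
    patient_id: str = "unknown"
    label: str = "unknown"
    candidate_id: str = ""

    def __post_init__(self):
        if self.rgb_bbox.shape != self.masked_rgb.shape:
            raise ValueError("rgb_bbox and masked_rgb must share dimensions")
        r0, c0, r1, c1 = self.bbox
        if (r1 - r0, c1 - c0) != self.rgb_bbox.shape[:2]:
            raise ValueError("bbox size inconsistent with crop shape")


@dataclass
class CandidateMasks:
    """Binary gland and lumen masks in bounding-box coordinates."""

    gland_mask: np.ndarray
    lumen_mask: np.ndarray

    def __post_init__(self):
        self.gland_mask = as_bool_mask(self.gland_mask)
        self.lumen_mask = as_bool_mask(self.lumen_mask)
        if self.gland_mask.shape != self.lumen_mask.shape:
            raise ValueError("gland and lumen masks must share dimensions")


def extract_masks(candidate: GlandCandidate, lumen_map: np.ndarray,
                  lam: int = 20, min_containment: float = 0.5) -> CandidateMasks:
    """Recover gland and lumen masks of one candidate.

    ``lumen_map`` is the binary lumen map cropped to the candidate's
    bounding box.  A lumen component is attributed to the candidate when at
    least ``min_containment`` of its pixels lie inside the gland mask; the
    kept components are clipped to the gland mask.
    """
    summed = candidate.masked_rgb.astype(np.int64).sum(axis=2)
    vals = np.unique(summed)
    if vals.size < 2:
        raise InvalidCandidateError("masked crop is constant; no gland to threshold")
    thresh = skfilters.threshold_otsu(summed)
    mask = summed > thresh
    mask = skmorph.remove_small_objects(mask, max_size=lam - 1, connectivity=1)
    mask = ndi.binary_fill_holes(mask)
    if not mask.any():
        raise InvalidCandidateError("gland mask empty after area opening")
    labels, n = ndi.label(mask, structure=np.ones((3, 3)))
    if n > 1:
        sizes = ndi.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        mask = labels == (int(np.argmax(sizes)) + 1)

    lumen_map = as_bool_mask(np.asarray(lumen_map))
    if lumen_map.shape != mask.shape:
        raise ValueError("lumen_map must be cropped to the candidate bounding box")
    lum_labels, n_lum = ndi.label(lumen_map, structure=np.ones((3, 3)))
    lumen = np.zeros_like(mask)
    for i in range(1, n_lum + 1):
        comp = lum_labels == i
        inside = (comp & mask).sum() / comp.sum()
        if inside >= min_containment:
            lumen |= comp
    lumen &= mask
    return CandidateMasks(gland_mask=mask, lumen_mask=lumen)
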