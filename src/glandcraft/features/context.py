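"""Contextual features: tissue-component relations around one candidate.

Nuclei "elements" are 8-connected components of the nuclei map; an element
counts as inside a region only if every one of its pixels lies inside.
The 20 features cover nuclei element/pixel counts and ratios inside the
bounding box and the gland, cytoplasm pixel counts and ratios, the
lumen-to-gland area ratio, the centroid-to-edge distance statistics of the
lumen, and the cytoplasm+nuclei occupancy of the toroid (gland minus
lumen) where the epithelial border is expected.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from ..utils import as_bool_mask, crop_bbox

_EIGHT = np.ones((3, 3), dtype=int)


def _safe_ratio(num: float, den: float, flags: dict, key: str) -> float:
    if den == 0:
        flags[key] = False
        return 0.0
    return num / den


def contextual_features(masks, maps, bbox=None) -> tuple[dict, dict]:
    """The 20 contextual features of one candidate.

    ``maps`` holds the patch-level component maps; when their shape differs
    from the candidate masks, ``bbox`` must be given so they can be cropped.
    Returns ``(values, valid_flags)``; ratios with zero denominators are 0
    and flagged invalid.
    """
    gland = as_bool_mask(masks.gland_mask)
    lumen = as_bool_mask(masks.lumen_mask)
    if not gland.any():
        raise ValueError("empty gland mask")

    def local(component):
        m = as_bool_mask(getattr(maps, component))
        if m.shape != gland.shape:
            if bbox is None:
                raise ValueError(
                    "maps are not in bbox coordinates and no bbox was given")
            m = crop_bbox(m, bbox)
        return m

    nuclei = local("nuclei")
    cyto = local("cytoplasm")

    flags: dict = {}
    values: dict = {}
    bbox_area = float(gland.size)
    gland_area = float(gland.sum())

    labels, n_elem = ndi.label(nuclei, structure=_EIGHT)
    nuclei_bb_num = float(n_elem)
    nuclei_bb_pix = float(nuclei.sum())
    gland_num = 0
    gland_pix = 0
    if n_elem:
        sizes = ndi.sum_labels(np.ones_like(labels), labels, range(1, n_elem + 1))
        inside = ndi.sum_labels(gland.astype(float), labels, range(1, n_elem + 1))
        fully_inside = inside == sizes
        gland_num = int(fully_inside.sum())
        gland_pix = int(sizes[fully_inside].sum())

    values["context.nuclei_bb_num"] = nuclei_bb_num
    values["context.nuclei_ratio_bb_num"] = _safe_ratio(
        nuclei_bb_num, bbox_area, flags, "context.nuclei_ratio_bb_num")
    values["context.nuclei_gland_num"] = float(gland_num)
    values["context.nuclei_ratio_gland_num"] = _safe_ratio(
        gland_num, gland_area, flags, "context.nuclei_ratio_gland_num")
    values["context.nuclei_ratio_gland_bb_num"] = _safe_ratio(
        gland_num, nuclei_bb_num, flags, "context.nuclei_ratio_gland_bb_num")
    values["context.nuclei_bb_pix"] = nuclei_bb_pix
    values["context.nuclei_ratio_bb_pix"] = _safe_ratio(
        nuclei_bb_pix, bbox_area, flags, "context.nuclei_ratio_bb_pix")
    values["context.nuclei_gland_pix"] = float(gland_pix)
    values["context.nuclei_ratio_gland_pix"] = _safe_ratio(
        gland_pix, gland_area, flags, "context.nuclei_ratio_gland_pix")
    values["context.nuclei_ratio_gland_bb_pix"] = _safe_ratio(
        gland_pix, nuclei_bb_pix, flags, "context.nuclei_ratio_gland_bb_pix")

    cyto_bb_pix = float(cyto.sum())
    cyto_gland_pix = float((cyto & gland).sum())
    values["context.cyto_bb_pix"] = cyto_bb_pix
    values["context.cyto_ratio_bb_pix"] = _safe_ratio(
        cyto_bb_pix, bbox_area, flags, "context.cyto_ratio_bb_pix")
    values["context.cyto_gland_pix"] = cyto_gland_pix
    values["context.cyto_ratio_gland_pix"] = _safe_ratio(
        cyto_gland_pix, gland_area, flags, "context.cyto_ratio_gland_pix")
    values["context.cyto_ratio_gland_bb_pix"] = _safe_ratio(
        cyto_gland_pix, cyto_bb_pix, flags, "context.cyto_ratio_gland_bb_pix")

    lumen_area = float(lumen.sum())
    values["context.ratio_lumen_gland_pix"] = _safe_ratio(
        lumen_area, gland_area, flags, "context.ratio_lumen_gland_pix")

    if lumen.any():
        edge = lumen & ~ndi.binary_erosion(lumen)
        er, ec = np.nonzero(edge)
        cr, cc = ndi.center_of_mass(lumen)
        dists = np.hypot(er - cr, ec - cc)
        values["context.mu_lumen_edge"] = float(dists.mean())
        values["context.sigma_lumen_edge"] = (
            float(dists.std(ddof=1)) if dists.size > 1 else 0.0)
    else:
        values["context.mu_lumen_edge"] = 0.0
        values["context.sigma_lumen_edge"] = 0.0
        flags["context.mu_lumen_edge"] = False
        flags["context.sigma_lumen_edge"] = False

    toroid = gland & ~lumen
    tor_area = float(toroid.sum())
    tor_cn = float((toroid & (cyto | nuclei)).sum())
    values["context.toroid_cn"] = tor_cn
    values["context.ratio_toroid_cn"] = _safe_ratio(
        tor_cn, tor_area, flags, "context.ratio_toroid_cn")
    return values, flags
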