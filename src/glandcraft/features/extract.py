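"""Assembly of the full 241-entry feature vector and cohort feature tables."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .context import contextual_features
from .fractal import fractal_features
from .masks import CandidateMasks, GlandCandidate, InvalidCandidateError, extract_masks
from .morphology import morphological_features
from .schema import feature_names
from .texture import texture_features
from ..utils import crop_bbox, derive_seed

log = logging.getLogger(__name__)

META_COLUMNS = ("candidate_id", "patient_id", "label")


@dataclass
class FeatureVector:
    """Ordered named 241-entry descriptor of one candidate."""

    values: np.ndarray
    names: tuple
    candidate_id: str = ""
    patient_id: str = ""
    label: str = "unknown"
    #: per-feature validity; False marks a degenerate quantity mapped to 0
    flags: dict = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


def extract_features(candidate: GlandCandidate, masks: CandidateMasks,
                     maps, use_masked_texture: bool = False) -> FeatureVector:
    """Compute the full descriptor of one candidate.

    Texture and fractal channels are taken from the unmasked bounding box by
    default (``use_masked_texture`` switches to the masked crop); morphology
    and context use the candidate masks and patch-level component maps.
    Non-finite entries are mapped to 0 and flagged.
    """
    texture_src = candidate.masked_rgb if use_masked_texture else candidate.rgb_bbox
    values: dict = {}
    flags: dict = {}

    morph, lumen_valid = morphological_features(masks)
    values.update(morph)
    if not lumen_valid:
        for key in morph:
            if key.startswith("morph.lumen."):
                flags[key] = False

    frac, frac_flags = fractal_features(texture_src)
    values.update(frac)
    flags.update({k: v for k, v in frac_flags.items() if not v})

    values.update(texture_features(texture_src))

    ctx, ctx_flags = contextual_features(masks, maps, bbox=candidate.bbox)
    values.update(ctx)
    flags.update(ctx_flags)

    names = feature_names()
    vec = np.array([values[nm] for nm in names], dtype=float)
    bad = ~np.isfinite(vec)
    if bad.any():
        for idx in np.nonzero(bad)[0]:
            flags[names[idx]] = False
        vec[bad] = 0.0
    return FeatureVector(values=vec, names=names,
                         candidate_id=candidate.candidate_id,
                         patient_id=candidate.patient_id,
                         label=candidate.label, flags=flags)


def candidate_from_truth(patch, cand) -> GlandCandidate:
    """Build a GlandCandidate from a phantom patch and its candidate truth."""
    rgb = crop_bbox(patch.rgb, cand.bbox)
    masked = rgb * cand.gland_mask[..., None].astype(rgb.dtype)
    return GlandCandidate(rgb_bbox=rgb, masked_rgb=masked, bbox=cand.bbox,
                          patient_id=cand.patient_id, label=cand.label,
                          candidate_id=cand.candidate_id)


def extract_table(cohort, seed: int = 0, use_truth_maps: bool = True,
                  map_config=None, use_masked_texture: bool = False) -> pd.DataFrame:
    """Feature table of a phantom cohort: one row per candidate.

    With ``use_truth_maps`` the generator's ground-truth component maps feed
    the contextual features and the lumen-mask extraction; otherwise the
    maps are estimated per patch with the k-means component-mapping
    pipeline.  Candidates whose gland mask cannot be recovered are skipped
    and logged.
    """
    from ..tissue import tissue_component_maps

    rows = []
    for patch in cohort.patches:
        if use_truth_maps:
            maps = patch.truth_maps
        else:
            maps = tissue_component_maps(
                patch.rgb, seed=derive_seed(seed, "maps", patch.patient_id,
                                            patch.patch_id),
                config=map_config)
        for cand in patch.candidates:
            gc = candidate_from_truth(patch, cand)
            try:
                masks = extract_masks(gc, crop_bbox(maps.lumen, cand.bbox))
                fv = extract_features(gc, masks, maps,
                                      use_masked_texture=use_masked_texture)
            except (InvalidCandidateError, ValueError) as exc:
                log.warning("skipping candidate %s: %s", cand.candidate_id, exc)
                continue
            row = {"candidate_id": fv.candidate_id, "patient_id": fv.patient_id,
                   "label": fv.label}
            row.update(zip(fv.names, fv.values))
            rows.append(row)
    return pd.DataFrame(rows)
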