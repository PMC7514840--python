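"""The ordered, named feature schema.

The descriptor of one candidate is a fixed-order vector of 241 named
scalars: 20 morphological + 15 fractal + 186 textural (126 GLCM + 60
LBP-family) + 20 contextual.  Names follow
``<family>.<channel?>.<offset?>.<name>`` and the order is stable across
versions; a JSON rendering can be written with :func:`write_schema_json`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

SCHEMA_VERSION = "1"

CHANNELS = ("cyan", "hematoxylin", "eosin")
GLCM_OFFSETS = {"deg0": (0, 2), "deg45": (-2, 2)}
HURST_ANGLES = (0, 30, 45, 60, 90)
LBP_BINS = 10

MORPH_NAMES = ("area", "convex_area", "eccentricity", "equiv_diameter",
               "extent", "orientation", "perimeter", "solidity",
               "roundness", "compactness")

GLCM_SCALARS = ("homogeneity", "contrast", "energy", "correlation", "entropy")

CONTEXT_NAMES = (
    "nuclei_bb_num", "nuclei_ratio_bb_num", "nuclei_gland_num",
    "nuclei_ratio_gland_num", "nuclei_ratio_gland_bb_num",
    "nuclei_bb_pix", "nuclei_ratio_bb_pix", "nuclei_gland_pix",
    "nuclei_ratio_gland_pix", "nuclei_ratio_gland_bb_pix",
    "cyto_bb_pix", "cyto_ratio_bb_pix", "cyto_gland_pix",
    "cyto_ratio_gland_pix", "cyto_ratio_gland_bb_pix",
    "ratio_lumen_gland_pix", "mu_lumen_edge", "sigma_lumen_edge",
    "toroid_cn", "ratio_toroid_cn",
)


@dataclass(frozen=True)
class FeatureEntry:
    name: str
    family: str  # morphology | fractal | texture | context
    subfamily: str = ""  # glcm | lbp for texture entries
    channel: str = ""
    offset: str = ""
    index: int = -1


@dataclass(frozen=True)
class FeatureSchema:
    version: str
    entries: tuple

    @property
    def names(self) -> tuple:
        return tuple(e.name for e in self.entries)

    def family_names(self, family: str, subfamily: str | None = None) -> tuple:
        return tuple(e.name for e in self.entries
                     if e.family == family
                     and (subfamily is None or e.subfamily == subfamily))

    def __len__(self) -> int:
        return len(self.entries)

    def to_json(self) -> str:
        payload = {
            "version": self.version,
            "entries": [vars(e) for e in self.entries],
        }
        return json.dumps(payload, indent=1)


def _build_entries() -> tuple:
    entries = []
    # morphology: gland block then lumen block
    for region in ("gland", "lumen"):
        for i, nm in enumerate(MORPH_NAMES):
            entries.append(FeatureEntry(f"morph.{region}.{nm}", "morphology",
                                        channel=region, index=i))
    # fractal: channel-major, angle-minor
    for ch in CHANNELS:
        for ang in HURST_ANGLES:
            entries.append(FeatureEntry(f"fractal.{ch}.hurst_{ang:02d}", "fractal",
                                        channel=ch, index=ang))
    # texture / GLCM: channel x offset x 21 scalars
    for ch in CHANNELS:
        for off in GLCM_OFFSETS:
            for nm in GLCM_SCALARS:
                entries.append(FeatureEntry(f"glcm.{ch}.{off}.{nm}", "texture",
                                            subfamily="glcm", channel=ch, offset=off))
            for j in range(1, 9):
                entries.append(FeatureEntry(f"glcm.{ch}.{off}.mean_{j}", "texture",
                                            subfamily="glcm", channel=ch,
                                            offset=off, index=j))
            for j in range(1, 9):
                entries.append(FeatureEntry(f"glcm.{ch}.{off}.std_{j}", "texture",
                                            subfamily="glcm", channel=ch,
                                            offset=off, index=j))
    # texture / LBP: channel x (riu2 histogram + LBPV histogram)
    for ch in CHANNELS:
        for k in range(LBP_BINS):
            entries.append(FeatureEntry(f"lbp.{ch}.hist_{k}", "texture",
                                        subfamily="lbp", channel=ch, index=k))
        for k in range(LBP_BINS):
            entries.append(FeatureEntry(f"lbpv.{ch}.hist_{k}", "texture",
                                        subfamily="lbp", channel=ch, index=k))
    # context
    for i, nm in enumerate(CONTEXT_NAMES):
        entries.append(FeatureEntry(f"context.{nm}", "context", index=i))
    return tuple(entries)


_SCHEMA = FeatureSchema(version=SCHEMA_VERSION, entries=_build_entries())

FAMILY_COUNTS = {
    "morphology": 20,
    "fractal": 15,
    "texture": 186,
    "context": 20,
}
TOTAL_FEATURES = 241

assert len(_SCHEMA) == TOTAL_FEATURES
for _fam, _n in FAMILY_COUNTS.items():
    assert len(_SCHEMA.family_names(_fam)) == _n


def feature_schema() -> FeatureSchema:
    """The versioned feature schema (singleton)."""
    return _SCHEMA


def feature_names() -> tuple:
    """All 241 feature names in schema order."""
    return _SCHEMA.names


def write_schema_json(path) -> None:
    """Write the schema as a versioned JSON file."""
    with open(path, "w") as fh:
        fh.write(_SCHEMA.to_json())
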