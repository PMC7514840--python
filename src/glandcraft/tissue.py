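"""Patch preprocessing and tissue-component mapping.

An H&E patch is decomposed into four binary component maps — lumen,
cytoplasm, stroma and nuclei — by clustering pixels of targeted colour
channels: the HSV saturation channel isolates the near-white lumens, the
CMYK cyan channel separates cytoplasm from stroma, and k-means in full RGB
space isolates the dark hematoxylin-stained nuclei.  Cluster label images
are binarised by intensity rank and cleaned with component-specific
morphological post-processing (area opening with a 20-px threshold plus a
radius-1 disk opening/dilation).

Hematoxylin and eosin stain channels are obtained by colour deconvolution:
optical density ``OD = -log10((I + 1) / 255)`` unmixed with the standard
Ruifrok–Johnston H&E stain matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage import color as skcolor
from skimage import morphology as skmorph
from skimage import transform as sktransform
from sklearn.cluster import KMeans

log = logging.getLogger(__name__)

#: Ruifrok–Johnston stain OD vectors (rows: hematoxylin, eosin, residual),
#: each row unit-normalised.
_STAIN_VECTORS = np.array([
    [0.65, 0.70, 0.29],
    [0.07, 0.99, 0.11],
    [0.27, 0.57, 0.78],
])
_STAIN_VECTORS = _STAIN_VECTORS / np.linalg.norm(_STAIN_VECTORS, axis=1, keepdims=True)
_UNMIX = np.linalg.inv(_STAIN_VECTORS)

#: Default intensity cutoff of the tissue test: a pixel counts as tissue if
#: min(R, G, B) falls below this value (background glass is near-white).
TISSUE_MIN_RGB = 220

#: Area-opening threshold (pixels) shared by all four component maps.
DEFAULT_LAMBDA = 20


@dataclass
class RGBPatch:
    """An 8-bit RGB patch with its offset inside the parent image."""

    pixels: np.ndarray
    origin: tuple[int, int] = (0, 0)
    patient_id: str | None = None

    def __post_init__(self):
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError("pixels must be an HxWx3 array")
        self.pixels = p


@dataclass
class ChannelSet:
    """Colour channels derived from one patch (possibly downscaled)."""

    s_hsv: np.ndarray
    c_cmyk: np.ndarray
    v_rgb: np.ndarray
    hematoxylin: np.ndarray
    eosin: np.ndarray
    scale: float = 1.0


@dataclass
class TissueComponentMaps:
    """Binary maps of the four H&E tissue components."""

    lumen: np.ndarray
    cytoplasm: np.ndarray
    stroma: np.ndarray
    nuclei: np.ndarray

    def as_dict(self):
        return {"lumen": self.lumen, "cytoplasm": self.cytoplasm,
                "stroma": self.stroma, "nuclei": self.nuclei}


def is_tissue(rgb: np.ndarray, cutoff: int = TISSUE_MIN_RGB) -> np.ndarray:
    """Boolean tissue test: non-background pixels have min(R,G,B) < cutoff."""
    return np.asarray(rgb).min(axis=2) < cutoff


def patch_image(image: np.ndarray, patch_size: int = 1024,
                min_tissue_fraction: float = 0.05,
                tissue_cutoff: int = TISSUE_MIN_RGB,
                patient_id: str | None = None) -> list[RGBPatch]:
    """Tile an RGB image into non-overlapping patches, row-major.

    Partial border tiles are dropped, as are tiles whose tissue fraction
    falls below ``min_tissue_fraction``.
    """
    if patch_size < 1:
        raise ValueError("patch_size must be >= 1")
    if not 0.0 <= min_tissue_fraction <= 1.0:
        raise ValueError("min_tissue_fraction must lie in [0, 1]")
    image = np.asarray(image)
    h, w = image.shape[:2]
    if h < patch_size or w < patch_size:
        log.warning("image (%dx%d) smaller than one %d-px patch; nothing to tile",
                    h, w, patch_size)
        return []
    patches = []
    for r0 in range(0, h - patch_size + 1, patch_size):
        for c0 in range(0, w - patch_size + 1, patch_size):
            tile = image[r0:r0 + patch_size, c0:c0 + patch_size]
            frac = is_tissue(tile, tissue_cutoff).mean()
            if frac >= min_tissue_fraction:
                patches.append(RGBPatch(pixels=tile, origin=(r0, c0),
                                        patient_id=patient_id))
    return patches


def cyan_channel(rgb: np.ndarray) -> np.ndarray:
    """CMYK cyan channel (after black-key correction), in [0, 1]."""
    x = np.asarray(rgb, dtype=float) / 255.0
    k = 1.0 - x.max(axis=2)
    denom = 1.0 - k
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (1.0 - x[..., 0] - k) / denom
    c[denom == 0] = 0.0  # pure black: cyan undefined, set to 0
    return np.clip(c, 0.0, 1.0)


def hed_channels(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(hematoxylin, eosin) concentration images by colour deconvolution."""
    od = -np.log10((np.asarray(rgb, dtype=float) + 1.0) / 255.0)
    conc = od @ _UNMIX
    return conc[..., 0], conc[..., 1]


def compute_channels(patch: RGBPatch | np.ndarray, downscale: float = 0.5) -> ChannelSet:
    """Compute the clustering/texture colour channels of a patch.

    When ``downscale < 1`` the RGB grid is rescaled first (bilinear), then
    all colour transforms are applied at the reduced resolution.
    """
    rgb = patch.pixels if isinstance(patch, RGBPatch) else np.asarray(patch)
    rgb = rgb.astype(float)
    if downscale < 1.0:
        rgb = sktransform.rescale(rgb / 255.0, downscale, order=1,
                                  channel_axis=2, anti_aliasing=False) * 255.0
    s_hsv = skcolor.rgb2hsv(rgb / 255.0)[..., 1]
    c = cyan_channel(rgb)
    hema, eos = hed_channels(rgb)
    return ChannelSet(s_hsv=s_hsv, c_cmyk=c, v_rgb=rgb / 255.0,
                      hematoxylin=hema, eosin=eos, scale=downscale)


@dataclass
class ClusterResult:
    """k-means labelling of one channel; labels 1..k ascend with intensity."""

    labels: np.ndarray
    centroids: np.ndarray
    k: int


def cluster_channel(channel: np.ndarray, k: int, seed: int,
                    name: str = "channel") -> ClusterResult:
    """k-means clustering of a scalar or colour channel.

    Labels are relabelled in ascending order of centroid mean intensity so
    label 1 is always the darkest cluster, making downstream binarisation
    invariant to k-means initialisation order.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    arr = np.asarray(channel, dtype=float)
    flat = arr.reshape(-1, 1) if arr.ndim == 2 else arr.reshape(-1, arr.shape[-1])
    n_distinct = np.unique(flat, axis=0).shape[0]
    if n_distinct < k:
        raise ValueError(
            f"channel {name!r} has only {n_distinct} distinct values; cannot form {k} clusters")
    km = KMeans(n_clusters=k, n_init=10, tol=1e-4, random_state=seed)
    raw = km.fit_predict(flat)
    order = np.argsort(km.cluster_centers_.mean(axis=1))
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    labels = remap[raw].reshape(arr.shape[:2])
    centroids = km.cluster_centers_[order]
    return ClusterResult(labels=labels, centroids=centroids, k=k)


def binarize_component(labelled: ClusterResult | np.ndarray,
                       rule: str | int = "min_label") -> np.ndarray:
    """Select one cluster of a labelled image as a binary map.

    ``min_label`` picks label 1 (the darkest cluster under the ascending
    relabelling), ``max_label`` the brightest; an integer picks that label.
    """
    labels = labelled.labels if isinstance(labelled, ClusterResult) else np.asarray(labelled)
    kmax = int(labels.max())
    if rule == "min_label":
        idx = 1
    elif rule == "max_label":
        idx = kmax
    else:
        idx = int(rule)
        if not 1 <= idx <= kmax:
            raise ValueError(f"label index {idx} outside 1..{kmax}")
    return labels == idx


_DISK1 = skmorph.disk(1)


def _area_open(mask: np.ndarray, lam: int, connectivity: int = 2) -> np.ndarray:
    """Keep connected components of area >= lam (8-connected by default)."""
    if lam <= 1:
        return mask.copy()
    return skmorph.remove_small_objects(mask.astype(bool), max_size=lam - 1,
                                        connectivity=connectivity)


def postprocess_map(mask: np.ndarray, component: str,
                    lam: int = DEFAULT_LAMBDA) -> np.ndarray:
    """Component-specific morphological cleanup of a raw binary map.

    lumen: area opening then radius-1 disk dilation; cytoplasm/stroma:
    radius-1 disk opening then area opening; nuclei: radius-1 disk dilation
    then area opening.
    """
    mask = np.asarray(mask).astype(bool)
    if component == "lumen":
        out = _area_open(mask, lam)
        out = skmorph.dilation(out, _DISK1)
    elif component in ("cytoplasm", "stroma"):
        out = skmorph.opening(mask, _DISK1)
        out = _area_open(out, lam)
    elif component == "nuclei":
        out = skmorph.dilation(mask, _DISK1)
        out = _area_open(out, lam)
    else:
        raise ValueError(f"unknown tissue component {component!r}")
    return out


@dataclass
class MapConfig:
    """Tunables of the component-mapping pipeline."""

    downscale: float = 0.5
    k_intensity: int = 3
    k_nuclei: int = 4
    lam: int = DEFAULT_LAMBDA
    #: which ascending-cyan cluster is cytoplasm / stroma (1..k_intensity)
    cyan_cytoplasm_cluster: int = 3
    cyan_stroma_cluster: int = 2
    #: lumen mode check: the darkest saturation centroid must be below this
    #: fraction of the next centroid, else the patch holds no lumen-like
    #: mode and the lumen map is empty (k-means would otherwise split a
    #: unimodal saturation distribution and return a spurious cluster)
    lumen_separation_ratio: float = 0.5


def tissue_component_maps(patch: RGBPatch | np.ndarray, seed: int,
                          config: MapConfig | None = None) -> TissueComponentMaps:
    """Full component-mapping pipeline for one patch.

    Clusters the saturation channel (k=3, darkest cluster = lumen), the cyan
    channel (k=3, cluster assignment per config) and the RGB grid (k=4,
    darkest cluster = nuclei), binarises, post-processes, and restores the
    maps to full patch resolution (nearest-neighbour).
    """
    config = config or MapConfig()
    rgb = patch.pixels if isinstance(patch, RGBPatch) else np.asarray(patch)
    channels = compute_channels(rgb, downscale=config.downscale)

    lum_cl = cluster_channel(channels.s_hsv, config.k_intensity, seed, name="s_hsv")
    c_dark, c_next = lum_cl.centroids.mean(axis=1)[:2]
    if c_dark < config.lumen_separation_ratio * c_next:
        lumen_raw = binarize_component(lum_cl, "min_label")
    else:
        lumen_raw = np.zeros(lum_cl.labels.shape, dtype=bool)
    lumen = postprocess_map(lumen_raw, "lumen", config.lam)

    cyan_cl = cluster_channel(channels.c_cmyk, config.k_intensity, seed, name="c_cmyk")
    cyto = postprocess_map(binarize_component(cyan_cl, config.cyan_cytoplasm_cluster),
                           "cytoplasm", config.lam)
    stroma = postprocess_map(binarize_component(cyan_cl, config.cyan_stroma_cluster),
                             "stroma", config.lam)

    nuc_cl = cluster_channel(channels.v_rgb, config.k_nuclei, seed, name="v_rgb")
    nuclei = postprocess_map(binarize_component(nuc_cl, "min_label"), "nuclei", config.lam)

    shape = rgb.shape[:2]
    maps = {}
    for name, m in (("lumen", lumen), ("cytoplasm", cyto),
                    ("stroma", stroma), ("nuclei", nuclei)):
        if m.shape != shape:
            m = sktransform.resize(m.astype(np.uint8), shape, order=0,
                                   preserve_range=True, anti_aliasing=False) > 0
        maps[name] = m
    return TissueComponentMaps(**maps)
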