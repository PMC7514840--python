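"""Textural descriptors: GLCM statistics and LBP/VAR/LBPV histograms.

GLCMs are computed at pixel offsets (0, 2) ("deg0") and (-2, 2) ("deg45")
on intensities uniformly quantised to 8 levels over [0, 255], symmetrised
by adding the transpose, and normalised to sum 1.  From each normalised
GLCM 21 scalars are taken: homogeneity, contrast, energy, correlation,
entropy, plus the 8 column means and 8 column standard deviations.

LBP uses the rotation-invariant uniform operator (P=8, R=1) with a circular
neighbourhood sampled by bilinear interpolation and the convention
s(0) = 1; uniform patterns map to their bit count 0..8, non-uniform ones to
9.  VAR is the biased variance of the same 8 neighbour samples.  The LBPV
histogram accumulates VAR per LBP label; both histograms are L1-normalised
by the number of interior pixels so candidates of different sizes are
comparable.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .schema import CHANNELS, GLCM_OFFSETS, GLCM_SCALARS, LBP_BINS

GLCM_LEVELS = 8


def quantize_255(channel: np.ndarray, levels: int = GLCM_LEVELS) -> np.ndarray:
    """Uniformly quantise an image to ``levels`` integer levels.

    Float inputs are assumed to lie in [0, 1] (clipped) and are scaled to
    [0, 255] first; integer inputs are taken as 8-bit.
    """
    arr = np.asarray(channel)
    if np.issubdtype(arr.dtype, np.floating):
        arr = np.clip(arr, 0.0, 1.0) * 255.0
    arr = np.clip(arr, 0, 255)
    q = (arr.astype(np.int64) * levels) // 256
    return np.clip(q, 0, levels - 1)


def glcm(channel: np.ndarray, offset: tuple[int, int],
         levels: int = GLCM_LEVELS) -> np.ndarray:
    """Symmetric, normalised grey-level co-occurrence matrix at one offset."""
    q = quantize_255(channel, levels)
    h, w = q.shape
    dr, dc = offset
    if h <= abs(dr) or w <= abs(dc):
        raise ValueError(f"crop {q.shape} smaller than offset span {offset}")
    r0 = max(0, -dr)
    r1 = h - max(0, dr)
    c0 = max(0, -dc)
    c1 = w - max(0, dc)
    a = q[r0:r1, c0:c1].ravel()
    b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
    counts = np.bincount(a * levels + b, minlength=levels * levels)
    counts = counts.reshape(levels, levels).astype(float)
    sym = counts + counts.T
    total = sym.sum()
    if total == 0:
        raise ValueError("empty co-occurrence matrix")
    return sym / total


def glcm_features(nglcm: np.ndarray) -> dict:
    """The 21 scalars of a normalised GLCM (keys without schema prefix)."""
    p = np.asarray(nglcm, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("nGLCM must be square")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("nGLCM is not normalised to sum 1")
    n = p.shape[0]
    i, j = np.mgrid[0:n, 0:n]
    out = {
        "homogeneity": float((p / (1.0 + np.abs(i - j))).sum()),
        "contrast": float(((i - j) ** 2 * p).sum()),
        "energy": float((p ** 2).sum()),
    }
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = (np.arange(n) * pi).sum()
    mu_j = (np.arange(n) * pj).sum()
    sd_i = np.sqrt(((np.arange(n) - mu_i) ** 2 * pi).sum())
    sd_j = np.sqrt(((np.arange(n) - mu_j) ** 2 * pj).sum())
    if sd_i * sd_j == 0:
        out["correlation"] = 0.0
    else:
        out["correlation"] = float(
            (((i - mu_i) * (j - mu_j) * p).sum()) / (sd_i * sd_j))
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p > 0, np.log(p), 0.0)
    out["entropy"] = float(-(p * logp).sum())
    col_mean = p.mean(axis=0)
    col_std = p.std(axis=0, ddof=1)
    for jj in range(n):
        out[f"mean_{jj + 1}"] = float(col_mean[jj])
        out[f"std_{jj + 1}"] = float(col_std[jj])
    return out


def _circular_samples(channel: np.ndarray, P: int = 8, R: float = 1.0) -> np.ndarray:
    """(P, H, W) stack of bilinear samples on the radius-R circle."""
    img = np.asarray(channel, dtype=float)
    h, w = img.shape
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    samples = np.empty((P,) + img.shape)
    for p in range(P):
        ang = 2.0 * np.pi * p / P
        rp = rows - R * np.sin(ang)
        cp = cols + R * np.cos(ang)
        samples[p] = ndi.map_coordinates(img, [rp, cp], order=1, mode="nearest")
    return samples


def lbp_riu2(channel: np.ndarray, P: int = 8, R: float = 1.0) -> np.ndarray:
    """Rotation-invariant uniform LBP label image (labels 0..P+1)."""
    img = np.asarray(channel, dtype=float)
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError("crop must be at least 3x3")
    samples = _circular_samples(img, P, R)
    s = (samples >= img[None]).astype(np.int8)
    transitions = np.abs(s - np.roll(s, 1, axis=0)).sum(axis=0)
    bits = s.sum(axis=0)
    labels = np.where(transitions <= 2, bits, P + 1)
    return labels.astype(np.int64)


def var_map(channel: np.ndarray, P: int = 8, R: float = 1.0) -> np.ndarray:
    """Rotation-invariant local variance of the P circular neighbours."""
    samples = _circular_samples(np.asarray(channel, dtype=float), P, R)
    return samples.var(axis=0)


def _interior(arr: np.ndarray, R: float = 1.0) -> np.ndarray:
    b = int(np.ceil(R))
    return arr[b:-b, b:-b]


def lbp_histogram(labels: np.ndarray, P: int = 8, normalise: bool = True,
                  border: float = 1.0) -> np.ndarray:
    """(P+2)-bin label histogram over interior pixels."""
    inner = _interior(np.asarray(labels), border)
    hist = np.bincount(inner.ravel(), minlength=P + 2).astype(float)
    if normalise and inner.size:
        hist /= inner.size
    return hist


def lbpv_histogram(labels: np.ndarray, var: np.ndarray, P: int = 8,
                   normalise: bool = True, border: float = 1.0) -> np.ndarray:
    """(P+2)-bin accumulation of VAR per LBP label over interior pixels."""
    labels = np.asarray(labels)
    var = np.asarray(var, dtype=float)
    if labels.shape != var.shape:
        raise ValueError("label and VAR images must share dimensions")
    inner_l = _interior(labels, border).ravel()
    inner_v = _interior(var, border).ravel()
    hist = np.bincount(inner_l, weights=inner_v, minlength=P + 2)
    if normalise and inner_l.size:
        hist /= inner_l.size
    return hist


def texture_features(rgb_bbox: np.ndarray, channels: dict | None = None) -> dict:
    """The 186 textural features of one candidate (126 GLCM + 60 LBP)."""
    if channels is None:
        from ..tissue import cyan_channel, hed_channels
        hema, eos = hed_channels(rgb_bbox)
        channels = {"cyan": cyan_channel(rgb_bbox), "hematoxylin": hema, "eosin": eos}
    values = {}
    for ch in CHANNELS:
        img = np.clip(np.asarray(channels[ch], dtype=float), 0.0, 1.0)
        for off_name, off in GLCM_OFFSETS.items():
            feats = glcm_features(glcm(img, off))
            for nm in GLCM_SCALARS:
                values[f"glcm.{ch}.{off_name}.{nm}"] = feats[nm]
            for j in range(1, 9):
                values[f"glcm.{ch}.{off_name}.mean_{j}"] = feats[f"mean_{j}"]
            for j in range(1, 9):
                values[f"glcm.{ch}.{off_name}.std_{j}"] = feats[f"std_{j}"]
    for ch in CHANNELS:
        img = np.clip(np.asarray(channels[ch], dtype=float), 0.0, 1.0) * 255.0
        labels = lbp_riu2(img)
        var = var_map(img)
        lh = lbp_histogram(labels)
        vh = lbpv_histogram(labels, var)
        for k in range(LBP_BINS):
            values[f"lbp.{ch}.hist_{k}"] = float(lh[k])
        for k in range(LBP_BINS):
            values[f"lbpv.{ch}.hist_{k}"] = float(vh[k])
    return values
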