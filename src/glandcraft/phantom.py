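"""Synthetic H&E gland-phantom generator.

Produces histology-like RGB patches containing three kinds of gland
candidates — artefacts (lumen-coloured blobs with no epithelial border),
benign glands (large, fusiform lumens ringed by cytoplasm and a dense,
multilayer band of epithelial nuclei) and Gleason-grade-3 glands (small,
near-circular lumens with a sparse nuclei band) — together with pixel-level
ground-truth component maps and per-candidate masks.  A cohort groups
patches by synthetic patient, with per-patient stain and geometry offsets,
so patient-wise cross-validation is meaningfully different from record-wise
splitting.

The module also synthesises exact 1-D fractional-Gaussian-noise (fGn) images
used as oracles for the Hurst-exponent estimator: each row is an independent
fGn sample whose power spectral density follows ``f**(1 - 2H)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage import draw as skdraw

CLASSES = ("artefact", "benign", "grade3")

#: Mean RGB per tissue component.  Chosen so that the k-means component
#: mapping separates the four components: lumen near-white (lowest HSV
#: saturation), nuclei dark blue-purple (darkest, highest CMYK cyan),
#: cytoplasm pale purple (blue-dominant, mid cyan), stroma pink.
DEFAULT_PALETTE = {
    "lumen": (247, 245, 247),
    "cytoplasm": (170, 150, 220),
    "stroma": (203, 159, 238),
    "nuclei": (110, 60, 150),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for a phantom cohort.

    Ranges are (low, high) tuples sampled uniformly per gland.  ``lumen_radius_px``
    is the geometric-mean semi-axis of the lumen ellipse; ``elongation`` the
    major/minor axis ratio; ``nuclei_density`` the fraction of the epithelial
    band perimeter covered by nuclei.
    """

    patch_size: int = 1024
    class_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    lumen_radius_px: dict = field(
        default_factory=lambda: {
            "artefact": (11.0, 22.0),
            "benign": (17.0, 28.0),
            "grade3": (7.0, 12.0),
        }
    )
    elongation: dict = field(
        default_factory=lambda: {
            "artefact": (1.0, 1.8),
            "benign": (1.6, 2.5),
            "grade3": (1.0, 1.25),
        }
    )
    cytoplasm_ring_px: tuple[float, float] = (8.0, 13.0)
    nuclei_density: dict = field(
        default_factory=lambda: {
            "artefact": (0.0, 0.0),
            "benign": (0.75, 0.95),
            "grade3": (0.25, 0.45),
        }
    )
    stain_palette: dict = field(default_factory=lambda: dict(DEFAULT_PALETTE))
    noise_sd: float = 5.0
    n_patients: int = 15
    patches_per_patient: int = 4
    glands_per_patch: int = 9
    seed: int = 0

    def __post_init__(self):
        mix = np.asarray(self.class_mix, dtype=float)
        if mix.shape != (3,) or not np.isclose(mix.sum(), 1.0) or (mix < 0).any():
            raise ValueError("class_mix must be 3 non-negative proportions summing to 1")
        for name, rng_map in (("lumen_radius_px", self.lumen_radius_px),
                              ("elongation", self.elongation),
                              ("nuclei_density", self.nuclei_density)):
            for cls in CLASSES:
                lo, hi = rng_map[cls]
                if hi < lo or lo < 0:
                    raise ValueError(f"{name}[{cls}] range ({lo}, {hi}) is invalid")
        dens = {c: np.mean(self.nuclei_density[c]) for c in CLASSES}
        if not (dens["artefact"] < dens["grade3"] < dens["benign"]):
            raise ValueError(
                "nuclei_density must be ordered artefact < grade3 < benign (class semantics)"
            )
        if self.max_gland_extent() * 1 > self.patch_size:
            raise ValueError("largest gland does not fit inside the patch")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")

    def max_gland_extent(self) -> int:
        """Conservative diameter (px) of the largest gland the spec can draw."""
        worst = 0.0
        for cls in CLASSES:
            r = self.lumen_radius_px[cls][1]
            e = self.elongation[cls][1]
            a = r * np.sqrt(e) * (1 + _PERTURB_BUDGET)
            band = self.cytoplasm_ring_px[1] + 2 * _NUCLEUS_RADIUS[1] + 2
            worst = max(worst, 2 * (a + band))
        return int(np.ceil(worst)) + 2 * _BBOX_MARGIN


# radial Fourier perturbation budget (sum of harmonic amplitudes)
_PERTURB_BUDGET = 0.12
_NUCLEUS_RADIUS = (2.3, 3.4)
_BBOX_MARGIN = 4
_MAX_PLACEMENT_TRIES = 50


from .tissue import TissueComponentMaps as TruthMaps  # noqa: E402  (shared container)


@dataclass
class CandidateTruth:
    """One generated gland candidate with its ground truth."""

    candidate_id: str
    patient_id: str
    label: str
    bbox: tuple[int, int, int, int]  # row0, col0, row1, col1; half-open
    gland_mask: np.ndarray  # bbox-local, bool
    lumen_mask: np.ndarray  # bbox-local, bool


@dataclass
class PhantomPatch:
    """A synthetic H&E patch with truth maps and candidate list."""

    rgb: np.ndarray
    truth_maps: TruthMaps
    candidates: list
    patient_id: str
    patch_id: str


def _perturbed_ellipse_outline(rng, center, radius, elong, rotation, n_pts=180,
                               amplitude=0.04):
    """Boundary points of a radially perturbed ellipse (row, col) arrays."""
    a = radius * np.sqrt(elong)
    b = radius / np.sqrt(elong)
    phi = np.linspace(0, 2 * np.pi, n_pts, endpoint=False)
    perturb = np.ones_like(phi)
    for k in range(2, 6):
        amp = rng.normal(0.0, amplitude)
        amp = np.clip(amp, -_PERTURB_BUDGET / 4, _PERTURB_BUDGET / 4)
        perturb += amp * np.cos(k * phi + rng.uniform(0, 2 * np.pi))
    x = a * np.cos(phi) * perturb
    y = b * np.sin(phi) * perturb
    cos_t, sin_t = np.cos(rotation), np.sin(rotation)
    rows = center[0] + (sin_t * x + cos_t * y)
    cols = center[1] + (cos_t * x - sin_t * y)
    return rows, cols


def _fill_outline(rows, cols, shape):
    rr, cc = skdraw.polygon(rows, cols, shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _draw_gland(rng, spec: PhantomSpec, label: str, center, shape):
    """Rasterise one candidate; returns (lumen, cyto, nuclei, gland) bool maps.

    Returns None if the geometry escapes the patch (caller resamples).
    """
    lo, hi = spec.lumen_radius_px[label]
    radius = rng.uniform(lo, hi)
    elo, ehi = spec.elongation[label]
    elong = rng.uniform(elo, ehi)
    rotation = rng.uniform(0, np.pi)
    amplitude = 0.06 if label == "artefact" else 0.035
    rows, cols = _perturbed_ellipse_outline(rng, center, radius, elong, rotation,
                                            amplitude=amplitude)
    lumen = _fill_outline(rows, cols, shape)
    if not lumen.any():
        return None

    if label == "artefact":
        pad = _BBOX_MARGIN
        rmin, rmax = rows.min() - pad, rows.max() + pad
        cmin, cmax = cols.min() - pad, cols.max() + pad
        if rmin < 0 or cmin < 0 or rmax >= shape[0] or cmax >= shape[1]:
            return None
        empty = np.zeros(shape, dtype=bool)
        return lumen, empty, empty, lumen.copy()

    ring = rng.uniform(*spec.cytoplasm_ring_px)
    # distance from lumen on a local window only (speed)
    r0 = max(int(rows.min() - ring - 12), 0)
    c0 = max(int(cols.min() - ring - 12), 0)
    r1 = min(int(rows.max() + ring + 12) + 1, shape[0])
    c1 = min(int(cols.max() + ring + 12) + 1, shape[1])
    window = lumen[r0:r1, c0:c1]
    dist = ndi.distance_transform_edt(~window)
    cyto = np.zeros(shape, dtype=bool)
    cyto[r0:r1, c0:c1] = (dist > 0) & (dist <= ring)

    density = rng.uniform(*spec.nuclei_density[label])
    nuclei = np.zeros(shape, dtype=bool)
    band_mid = ring + _NUCLEUS_RADIUS[1]
    layers = 2 if density > 0.7 else 1
    for layer in range(layers):
        offs = band_mid + layer * 2 * np.mean(_NUCLEUS_RADIUS) * 0.85
        perimeter = 2 * np.pi * (radius + offs)
        n_nuc = int(density * perimeter / (2 * np.mean(_NUCLEUS_RADIUS)))
        if n_nuc <= 0:
            continue
        angles = rng.uniform(0, 2 * np.pi, size=n_nuc)
        a = radius * np.sqrt(elong) + offs
        b = radius / np.sqrt(elong) + offs
        cos_t, sin_t = np.cos(rotation), np.sin(rotation)
        x = a * np.cos(angles)
        y = b * np.sin(angles)
        nr = center[0] + (sin_t * x + cos_t * y) + rng.normal(0, 0.6, n_nuc)
        nc = center[1] + (cos_t * x - sin_t * y) + rng.normal(0, 0.6, n_nuc)
        radii = rng.uniform(*_NUCLEUS_RADIUS, size=n_nuc)
        for j in range(n_nuc):
            rr, cc = skdraw.disk((nr[j], nc[j]), radii[j], shape=shape)
            nuclei[rr, cc] = True

    gland = lumen | cyto | nuclei
    pad = _BBOX_MARGIN
    rr_idx, cc_idx = np.nonzero(gland)
    if (rr_idx.min() < pad or cc_idx.min() < pad
            or rr_idx.max() >= shape[0] - pad or cc_idx.max() >= shape[1] - pad):
        return None
    nuclei &= ~lumen  # lumens stay lumen-coloured
    cyto &= ~(lumen | nuclei)
    return lumen, cyto, nuclei, gland


def _patient_effect(spec: PhantomSpec, patient_id: str, seed: int):
    """Per-patient stain offset and geometry scale, deterministic in inputs."""
    from .utils import derive_seed

    rng = np.random.default_rng(derive_seed(seed, "patient-effect", patient_id))
    palette = {}
    for comp, rgb in spec.stain_palette.items():
        shift = rng.integers(-3, 4, size=3)
        palette[comp] = tuple(int(np.clip(v + s, 0, 255)) for v, s in zip(rgb, shift))
    geom_scale = float(rng.uniform(0.92, 1.08))
    return palette, geom_scale


def generate_patch(spec: PhantomSpec, patient_id: str, seed: int,
                   labels: list | None = None,
                   patch_id: str = "patch0") -> PhantomPatch:
    """Generate one phantom patch deterministically from (spec, patient_id, seed).

    ``labels``, if given, fixes the class of each gland slot (used by
    :func:`generate_cohort` to guarantee cohort-level class balance);
    otherwise classes are drawn from ``spec.class_mix``.
    """
    from .utils import derive_seed

    rng = np.random.default_rng(derive_seed(seed, "patch", patient_id, patch_id))
    palette, geom_scale = _patient_effect(spec, patient_id, seed)
    size = spec.patch_size
    shape = (size, size)

    cell = spec.max_gland_extent()
    cell = int(np.ceil(cell * geom_scale)) + 2
    n_cells = size // cell
    if n_cells < 1:
        raise ValueError(
            f"gland geometry (extent {cell}px) cannot fit in a {size}px patch")
    n_slots = n_cells * n_cells
    n_glands = min(spec.glands_per_patch, n_slots)
    slot_order = rng.permutation(n_slots)[:n_glands]

    if labels is None:
        labels = list(rng.choice(CLASSES, size=n_glands, p=spec.class_mix))
    elif len(labels) != n_glands:
        raise ValueError(f"expected {n_glands} labels, got {len(labels)}")

    scaled = replace(
        spec,
        lumen_radius_px={c: (lo * geom_scale, hi * geom_scale)
                         for c, (lo, hi) in spec.lumen_radius_px.items()},
    )

    lumen_map = np.zeros(shape, dtype=bool)
    cyto_map = np.zeros(shape, dtype=bool)
    nuclei_map = np.zeros(shape, dtype=bool)
    candidates = []
    offset = (size - n_cells * cell) // 2
    for idx, (slot, label) in enumerate(zip(slot_order, labels)):
        gr, gc = divmod(int(slot), n_cells)
        base = (offset + gr * cell + cell / 2, offset + gc * cell + cell / 2)
        drawn = None
        for _ in range(_MAX_PLACEMENT_TRIES):
            jitter = rng.normal(0, cell / 16, size=2)
            center = (base[0] + jitter[0], base[1] + jitter[1])
            drawn = _draw_gland(rng, scaled, label, center, shape)
            if drawn is not None:
                break
        if drawn is None:
            raise RuntimeError(
                f"could not place a {label} gland after {_MAX_PLACEMENT_TRIES} tries; "
                "reduce gland sizes or enlarge the patch")
        lum, cyt, nuc, gland = drawn
        lumen_map |= lum
        cyto_map |= cyt
        nuclei_map |= nuc
        rr_idx, cc_idx = np.nonzero(gland)
        r0 = max(int(rr_idx.min()) - _BBOX_MARGIN, 0)
        c0 = max(int(cc_idx.min()) - _BBOX_MARGIN, 0)
        r1 = min(int(rr_idx.max()) + 1 + _BBOX_MARGIN, size)
        c1 = min(int(cc_idx.max()) + 1 + _BBOX_MARGIN, size)
        candidates.append(CandidateTruth(
            candidate_id=f"{patient_id}-{patch_id}-g{idx:02d}",
            patient_id=patient_id,
            label=label,
            bbox=(r0, c0, r1, c1),
            gland_mask=gland[r0:r1, c0:c1].copy(),
            lumen_mask=lum[r0:r1, c0:c1].copy(),
        ))

    stroma_map = ~(lumen_map | cyto_map | nuclei_map)
    rgb = np.empty(shape + (3,), dtype=float)
    rgb[...] = palette["stroma"]
    rgb[lumen_map] = palette["lumen"]
    rgb[cyto_map] = palette["cytoplasm"]
    rgb[nuclei_map] = palette["nuclei"]
    if spec.noise_sd > 0:
        rgb += rng.normal(0.0, spec.noise_sd, size=rgb.shape)
    rgb = np.clip(np.round(rgb), 0, 255).astype(np.uint8)

    truth = TruthMaps(lumen=lumen_map, cytoplasm=cyto_map,
                      stroma=stroma_map, nuclei=nuclei_map)
    return PhantomPatch(rgb=rgb, truth_maps=truth, candidates=candidates,
                        patient_id=patient_id, patch_id=patch_id)


@dataclass
class PhantomCohort:
    """Patches of a generated cohort, grouped by synthetic patient."""

    spec: PhantomSpec
    patches: list

    def iter_candidates(self):
        for patch in self.patches:
            for cand in patch.candidates:
                yield patch, cand

    @property
    def patient_ids(self):
        return sorted({p.patient_id for p in self.patches})


def _balanced_label_pool(rng, class_mix, total: int) -> list:
    """Exact largest-remainder class counts for ``total`` slots, shuffled."""
    mix = np.asarray(class_mix, dtype=float)
    base = np.floor(mix * total).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(mix * total - base))
    for i in range(rem):
        base[order[i % 3]] += 1
    pool = [CLASSES[i] for i in range(3) for _ in range(base[i])]
    rng.shuffle(pool)
    return pool


def generate_cohort(spec: PhantomSpec) -> PhantomCohort:
    """Generate a multi-patient cohort of phantom patches.

    Class labels are dealt from an exact largest-remainder pool per patient so
    cohort class counts track ``class_mix`` closely; every candidate carries
    its patient id.
    """
    from .utils import derive_seed

    patches = []
    for p in range(spec.n_patients):
        patient_id = f"pat{p:03d}"
        rng = np.random.default_rng(derive_seed(spec.seed, "labels", patient_id))
        # determine slot count per patch from one dry computation
        for q in range(spec.patches_per_patient):
            patch_id = f"patch{q:02d}"
            # number of glands actually drawn equals min(glands_per_patch, slots);
            # compute as generate_patch would
            cell = spec.max_gland_extent()
            _, geom_scale = _patient_effect(spec, patient_id, spec.seed)
            cell = int(np.ceil(cell * geom_scale)) + 2
            n_cells = spec.patch_size // cell
            n_glands = min(spec.glands_per_patch, n_cells * n_cells)
            labels = _balanced_label_pool(rng, spec.class_mix, n_glands)
            patches.append(generate_patch(spec, patient_id, spec.seed,
                                          labels=labels, patch_id=patch_id))
    return PhantomCohort(spec=spec, patches=patches)


def synthesize_fgn_image(H: float, rows: int, cols: int, seed: int) -> np.ndarray:
    """Synthesise an image whose rows are independent fGn samples.

    Each row is generated by exact frequency-domain shaping: a complex white
    Gaussian spectrum is multiplied by ``f**((1 - 2H) / 2)`` so the
    log–log power spectral density has slope ``1 - 2H``; the zero-frequency
    bin is nulled, making every row zero-mean.  ``H = 0.5`` reduces to white
    Gaussian noise.
    """
    if not (0.0 < H < 1.0):
        raise ValueError(f"Hurst exponent must lie in (0, 1), got {H}")
    if rows < 1 or cols < 4:
        raise ValueError("need at least 1 row and 4 columns")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(cols)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** ((1.0 - 2.0 * H) / 2.0)
    spectrum = (rng.normal(size=(rows, freqs.size))
                + 1j * rng.normal(size=(rows, freqs.size)))
    spectrum *= shaping
    img = np.fft.irfft(spectrum, n=cols, axis=1)
    img -= img.mean(axis=1, keepdims=True)
    sd = img.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return img / sd
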