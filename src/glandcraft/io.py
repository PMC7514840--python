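"""File-format handling: cohort export/import, tables and reports.

A cohort directory holds per-patch PNGs, 0/255 single-channel component-map
PNGs, paired candidate crops (`<id>_bbox.png` / `<id>_masked.png`) and one
`candidates.csv` with 0-based half-open bounding-box pixel coordinates.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .features.masks import GlandCandidate
from .utils import crop_bbox

log = logging.getLogger(__name__)

CSV_COLUMNS = ("candidate_id", "patient_id", "class", "x0", "y0", "x1", "y1")


def _save_png(path: Path, array: np.ndarray) -> None:
    arr = np.asarray(array)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    Image.fromarray(arr).save(path)


def _load_png(path: Path) -> np.ndarray:
    return np.asarray(Image.open(path))


def write_cohort(cohort, out_dir) -> Path:
    """Export a phantom cohort: patches, truth maps, crops and metadata CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for patch in cohort.patches:
        stem = f"{patch.patient_id}_{patch.patch_id}"
        _save_png(out / f"{stem}.png", patch.rgb)
        for comp, m in patch.truth_maps.as_dict().items():
            _save_png(out / f"{stem}_{comp}.png", m)
        for cand in patch.candidates:
            rgb = crop_bbox(patch.rgb, cand.bbox)
            masked = rgb * cand.gland_mask[..., None].astype(rgb.dtype)
            _save_png(out / f"{cand.candidate_id}_bbox.png", rgb)
            _save_png(out / f"{cand.candidate_id}_masked.png", masked)
            r0, c0, r1, c1 = cand.bbox
            rows.append({"candidate_id": cand.candidate_id,
                         "patient_id": cand.patient_id, "class": cand.label,
                         "x0": c0, "y0": r0, "x1": c1, "y1": r1})
    pd.DataFrame(rows, columns=list(CSV_COLUMNS)).to_csv(
        out / "candidates.csv", index=False)
    return out


def ingest_candidates(directory) -> list:
    """Load gland candidates from a cohort directory layout.

    Pairs `<id>_bbox.png` / `<id>_masked.png` are matched against
    `candidates.csv`; mismatched or incomplete pairs are rejected with a
    logged per-file error.
    """
    directory = Path(directory)
    csv_path = directory / "candidates.csv"
    if not csv_path.exists():
        log.warning("no candidates.csv in %s; returning empty list", directory)
        return []
    meta = pd.read_csv(csv_path)
    missing = set(CSV_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"candidates.csv is missing columns: {sorted(missing)}")
    candidates = []
    for _, row in meta.iterrows():
        cid = row["candidate_id"]
        bbox_path = directory / f"{cid}_bbox.png"
        masked_path = directory / f"{cid}_masked.png"
        if not bbox_path.exists() or not masked_path.exists():
            log.error("candidate %s: missing %s", cid,
                      bbox_path.name if not bbox_path.exists() else masked_path.name)
            continue
        rgb = _load_png(bbox_path)
        masked = _load_png(masked_path)
        if rgb.shape != masked.shape:
            log.error("candidate %s: crop size mismatch %s vs %s (%s, %s)",
                      cid, rgb.shape, masked.shape, bbox_path.name, masked_path.name)
            continue
        bbox = (int(row["y0"]), int(row["x0"]), int(row["y1"]), int(row["x1"]))
        try:
            candidates.append(GlandCandidate(
                rgb_bbox=rgb, masked_rgb=masked, bbox=bbox,
                patient_id=str(row["patient_id"]), label=str(row["class"]),
                candidate_id=str(cid)))
        except ValueError as exc:
            log.error("candidate %s rejected: %s", cid, exc)
    return candidates


def write_maps(maps, out_dir, stem: str, sidecar: dict | None = None) -> None:
    """Write component maps as 0/255 PNGs plus an optional JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for comp, m in maps.as_dict().items():
        _save_png(out / f"{stem}_{comp}.png", m)
    if sidecar is not None:
        (out / f"{stem}_maps.json").write_text(json.dumps(sidecar, indent=1))


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_selection(result, path) -> None:
    Path(path).write_text(json.dumps(result.to_json_dict(), indent=1, default=float))


def write_report(report, path) -> None:
    Path(path).write_text(json.dumps(report.to_json_dict(), indent=1, default=float))
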