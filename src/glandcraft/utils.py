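"""Small shared helpers: seed derivation and mask sanity checks."""

from __future__ import annotations

import hashlib

import numpy as np

MAX_SEED = 2**31 - 1


def derive_seed(root_seed: int, *tokens) -> int:
    """Derive a named child seed from a root seed.

    All randomness in the package flows from one root seed split into named
    per-stage streams; the same (root, tokens) pair always yields the same
    child seed, independent of call order.
    """
    payload = repr((int(root_seed),) + tuple(str(t) for t in tokens)).encode()
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:4], "big") % MAX_SEED


def as_bool_mask(arr: np.ndarray) -> np.ndarray:
    """Coerce a 0/1, 0/255 or boolean image to a boolean mask."""
    a = np.asarray(arr)
    if a.dtype == bool:
        return a
    return a > 0


def crop_bbox(image: np.ndarray, bbox: tuple[int, int, int, int]) -> np.ndarray:
    """Crop ``image`` to a (row0, col0, row1, col1) half-open bounding box."""
    r0, c0, r1, c1 = bbox
    return image[r0:r1, c0:c1]
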