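"""Directional Hurst-exponent fractal analysis of a candidate crop.

An image row is treated as a 1-D sample of fractional Brownian motion; its
first-difference increments form fractional Gaussian noise whose power
spectral density follows a power law ``f**(1 - 2H)``.  The estimator
differences each profile, averages the squared DFT magnitude over profiles,
and fits the log10 PSD against log10 frequency by least squares; the Hurst
exponent is ``H = (1 - slope) / 2``.

Directionality: profiles at 0deg are image rows and at 90deg image columns;
for oblique angles the crop is rotated by the negative angle with bilinear
interpolation and cropped to the largest inscribed axis-aligned rectangle
before taking rows, which preserves uniform sampling spacing.
"""

from __future__ import annotations

import numpy as np
from skimage import transform as sktransform

from .schema import CHANNELS, HURST_ANGLES

MIN_PROFILE_LEN = 16


def estimate_hurst_psd(profiles: np.ndarray) -> tuple[float, bool]:
    """Estimate H from a stack of profiles (rows); returns (H, valid).

    ``valid`` is False for degenerate input (zero increments everywhere or
    an estimate outside [0, 1]); the value is returned unclamped, with the
    all-degenerate case mapped to the sentinel 0.
    """
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    n = profiles.shape[1]
    if n < MIN_PROFILE_LEN:
        raise ValueError(
            f"profiles of length {n} are too short; need >= {MIN_PROFILE_LEN}")
    d = np.diff(profiles, axis=1)
    spectrum = np.fft.rfft(d, axis=1)
    psd = np.mean(np.abs(spectrum) ** 2, axis=0)
    m = d.shape[1]
    # positive frequencies up to Nyquist; zero-frequency bin excluded
    freqs = np.fft.rfftfreq(m)[1:]
    power = psd[1:]
    ok = power > 0
    if ok.sum() < 2:
        return 0.0, False
    slope = np.polyfit(np.log10(freqs[ok]), np.log10(power[ok]), 1)[0]
    h = (1.0 - slope) / 2.0
    return float(h), bool(0.0 <= h <= 1.0)


def _max_inscribed_rect(w: float, h: float, angle_rad: float) -> tuple[float, float]:
    """Width/height of the largest axis-aligned rectangle inside a rotated
    w x h rectangle (standard closed form)."""
    if w <= 0 or h <= 0:
        return 0.0, 0.0
    ang = abs(angle_rad) % np.pi
    if ang > np.pi / 2:
        ang = np.pi - ang
    sin_a, cos_a = np.sin(ang), np.cos(ang)
    if sin_a == 0:
        return w, h
    width_longer = w >= h
    side_long, side_short = (w, h) if width_longer else (h, w)
    if side_short <= 2.0 * sin_a * cos_a * side_long or abs(sin_a - cos_a) < 1e-10:
        x = 0.5 * side_short
        wr, hr = (x / sin_a, x / cos_a) if width_longer else (x / cos_a, x / sin_a)
    else:
        cos_2a = cos_a * cos_a - sin_a * sin_a
        wr = (w * cos_a - h * sin_a) / cos_2a
        hr = (h * cos_a - w * sin_a) / cos_2a
    return wr, hr


def directional_profiles(channel: np.ndarray, theta: float) -> np.ndarray:
    """Profiles of ``channel`` sampled along direction ``theta`` (degrees)."""
    channel = np.asarray(channel, dtype=float)
    if theta == 0:
        return channel
    if theta == 90:
        return channel.T
    rotated = sktransform.rotate(channel, -theta, resize=True, order=1)
    h0, w0 = channel.shape
    wr, hr = _max_inscribed_rect(w0, h0, np.deg2rad(theta))
    hh, ww = rotated.shape
    rr = max(int(np.floor(hr)) - 1, 1)
    cc = max(int(np.floor(wr)) - 1, 1)
    r0 = (hh - rr) // 2
    c0 = (ww - cc) // 2
    return rotated[r0:r0 + rr, c0:c0 + cc]


def hurst_exponent(channel: np.ndarray, theta: float) -> tuple[float, bool]:
    """Directional Hurst exponent of a grayscale crop; returns (H, valid)."""
    if theta not in HURST_ANGLES:
        raise ValueError(f"theta must be one of {HURST_ANGLES}")
    profiles = directional_profiles(channel, theta)
    return estimate_hurst_psd(profiles)


def fractal_features(rgb_bbox: np.ndarray, channels: dict | None = None) -> tuple[dict, dict]:
    """The 15 fractal features (3 channels x 5 directions) of one candidate.

    ``channels`` may supply precomputed {"cyan", "hematoxylin", "eosin"}
    grayscale crops; otherwise they are derived from ``rgb_bbox``.
    Returns ``(values, valid_flags)``.
    """
    if channels is None:
        from ..tissue import cyan_channel, hed_channels
        hema, eos = hed_channels(rgb_bbox)
        channels = {"cyan": cyan_channel(rgb_bbox), "hematoxylin": hema, "eosin": eos}
    values, flags = {}, {}
    for ch in CHANNELS:
        for ang in HURST_ANGLES:
            key = f"fractal.{ch}.hurst_{ang:02d}"
            try:
                h, ok = hurst_exponent(channels[ch], ang)
            except ValueError:
                # crop too small along this direction: sentinel 0, flagged
                h, ok = 0.0, False
            values[key] = h
            flags[key] = ok
    return values, flags
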