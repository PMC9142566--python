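"""Deterministic synthetic image fixtures.

Stand-ins for photographic test material: smooth gradients (maximally
compressible), flat-shape compositions, uniform noise (an incompressible
control) and "photo-like" images built from band-limited random fields,
which have the mix of smooth regions and level transitions that drives
realistic segment counts and restoration behaviour.
"""

from __future__ import annotations

import zlib

import numpy as np
from scipy import ndimage


def generate_fixture(kind: str, size: tuple[int, int], seed: int = 0) -> np.ndarray:
    """Deterministic (H, W, 3) uint8 image of the requested character."""
    h, w = size
    if h < 8 or w < 8:
        raise ValueError("fixtures are at least 8x8")
    rng = np.random.default_rng((seed, zlib.crc32(kind.encode())))
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    if kind == "gradient":
        r = 255.0 * xx / max(w - 1, 1)
        g = 255.0 * yy / max(h - 1, 1)
        b = 255.0 * (xx + yy) / max(h + w - 2, 1)
        img = np.stack([r, g, b], axis=2)
    elif kind == "shapes":
        base = np.stack(
            [
                120.0 + 60.0 * xx / max(w - 1, 1),
                90.0 + 80.0 * yy / max(h - 1, 1),
                np.full((h, w), 70.0),
            ],
            axis=2,
        )
        for _ in range(4):
            cy, cx = rng.integers(0, h), rng.integers(0, w)
            rad = int(rng.integers(min(h, w) // 8, min(h, w) // 3))
            color = rng.integers(0, 256, size=3)
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= rad**2
            base[disk] = color
        y0, x0 = rng.integers(0, h // 2), rng.integers(0, w // 2)
        base[y0 : y0 + h // 3, x0 : x0 + w // 3] = rng.integers(0, 256, size=3)
        img = base
    elif kind == "noise":
        img = rng.integers(0, 256, size=(h, w, 3)).astype(np.float64)
    elif kind == "photo-like":
        # photographic character: a shared luminance field (channels are
        # strongly correlated, as in low-saturation film imagery) plus a
        # weak per-channel chroma field and film-grain-like fine texture
        sigma = max(min(h, w) / 12.0, 1.5)
        luma = ndimage.gaussian_filter(rng.normal(size=(h, w)), sigma=sigma)
        grain = ndimage.gaussian_filter(rng.normal(size=(h, w)), sigma=0.8)
        base = luma + 0.30 * grain
        lo, hi = base.min(), base.max()
        base = (base - lo) / (hi - lo + 1e-12)
        img = np.empty((h, w, 3))
        for c in range(3):
            chroma = ndimage.gaussian_filter(rng.normal(size=(h, w)), sigma=sigma)
            img[:, :, c] = 255.0 * np.clip(
                base + 0.08 * chroma, 0.0, 1.0
            )
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


FIXTURE_KINDS = ("gradient", "shapes", "noise", "photo-like")
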