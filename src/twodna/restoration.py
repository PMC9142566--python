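"""Redundancy-free image restoration after oligo-channel decoding.

A lost or corrupted oligo discolours a contiguous run of pixels in a
single colour channel.  Because the three colour channels are stored in
separate oligos, errors are very unlikely to hit the same pixel in two
channels at once: the RGB decomposition behaves like a 3-repetition
code.  The detector exploits this by flagging, per pixel, the one
channel that disagrees strongly with the two (mutually consistent)
others; flags are then filtered along the Hilbert scan order, where
oligo damage is contiguous, to suppress isolated false positives.
Flagged pixels are masked and re-filled by classical biharmonic
inpainting, optionally followed by bilateral + adaptive-median
smoothing to blend quantization and fill artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.metrics import peak_signal_noise_ratio, structural_similarity
from skimage.restoration import denoise_bilateral, inpaint_biharmonic

from .image_codec import QUANT_LEVELS, HilbertOrder, QuantizedImage


@dataclass
class DiscolorationMask:
    """Per channel-pixel damage flags with provenance."""

    flags: np.ndarray  # (3, H, W) bool, union of both sources
    decoder: np.ndarray  # (3, H, W) bool: missing/conflict provenance
    statistical: np.ndarray  # (3, H, W) bool: cross-channel detection
    tau_agree: int
    tau_discolor: int


@dataclass
class PairwiseDifferenceStats:
    """Histograms of |R-G|, |R-B|, |G-B| in level units."""

    histograms: dict[str, np.ndarray]  # pair -> counts over 0..7

    @classmethod
    def from_levels(cls, levels: np.ndarray) -> "PairwiseDifferenceStats":
        r, g, b = (levels[i].astype(np.int16) for i in range(3))
        hists = {}
        for name, diff in (("RG", r - g), ("RB", r - b), ("GB", g - b)):
            hists[name] = np.bincount(np.abs(diff).ravel(), minlength=QUANT_LEVELS)
        return cls(histograms=hists)

    def tail_threshold(self, floor: int = 3, tail: float = 0.01) -> int:
        """Detection threshold read off the pairwise-difference histogram.

        On an intact image the histogram is concentrated at 0-1 level
        differences; channel damage adds a detached spike at larger
        differences.  The threshold is placed just past the point where
        the bulk has emptied: the smallest t >= ``floor`` whose
        *preceding* bin holds at most a ``tail`` fraction of all pairwise
        differences.  Anchoring the rule to the bulk (rather than to the
        total upper-tail mass) keeps a large damage spike from pushing
        the threshold past itself.  ``QUANT_LEVELS`` (detector inert)
        when the histogram never empties, as for saturated or noise-like
        imagery.
        """
        pooled = sum(self.histograms.values())
        total = pooled.sum()
        for t in range(floor, QUANT_LEVELS):
            if pooled[t - 1] <= tail * total:
                return t
        return QUANT_LEVELS


def _dilate_runs(
    flags_linear: np.ndarray, min_run: int, max_gap: int = 6
) -> np.ndarray:
    """Consolidate flags along the Hilbert order.

    Oligo damage discolours a *contiguous* Hilbert run, of which the
    per-pixel rule flags a scattered subset.  Gaps of up to ``max_gap``
    unflagged pixels between flags are closed (dilation along the run),
    and consolidated runs carrying fewer than ``min_run`` original flags
    are discarded as isolated false positives.
    """
    if not flags_linear.any():
        return flags_linear
    closed = ndimage.binary_closing(
        flags_linear, structure=np.ones(max_gap + 2, dtype=bool)
    )
    labels, n = ndimage.label(closed)
    if n == 0:
        return closed
    support = ndimage.sum_labels(flags_linear, labels, index=np.arange(1, n + 1))
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = support >= min_run
    return keep[labels]


def detect_discoloration(
    qimg: QuantizedImage,
    order: HilbertOrder,
    tau_agree: int = 1,
    tau_floor: int = 3,
    tail: float = 0.01,
    min_run: int = 4,
) -> DiscolorationMask:
    """Locate discoloured channel-pixels.

    The mask is the union of (a) decoder-provenance flags (missing or
    conflicting segments) and (b) statistical flags: channel X is
    implicated at a pixel when the other two channels agree within
    ``tau_agree`` levels while each differs from X by at least a
    threshold read off the upper tail of the pairwise-difference
    histograms.  Statistical flags are kept only in Hilbert-order runs
    of at least ``min_run`` pixels.
    """
    levels = qimg.levels.astype(np.int16)
    stats = PairwiseDifferenceStats.from_levels(levels)
    tau_d = stats.tail_threshold(floor=tau_floor, tail=tail)
    r, g, b = levels[0], levels[1], levels[2]
    d_rg, d_rb, d_gb = np.abs(r - g), np.abs(r - b), np.abs(g - b)
    statistical = np.zeros_like(qimg.missing_mask)
    # channel X flagged when the other two agree and both implicate X
    statistical[0] = (d_gb <= tau_agree) & (d_rg >= tau_d) & (d_rb >= tau_d)
    statistical[1] = (d_rb <= tau_agree) & (d_rg >= tau_d) & (d_gb >= tau_d)
    statistical[2] = (d_rg <= tau_agree) & (d_rb >= tau_d) & (d_gb >= tau_d)
    flat_idx = order.flat_index()
    for c in range(3):
        linear = statistical[c].ravel()[flat_idx]
        kept = _dilate_runs(linear, min_run)
        out = np.zeros(statistical[c].size, dtype=bool)
        out[flat_idx] = kept
        statistical[c] = out.reshape(statistical[c].shape)
    decoder = qimg.missing_mask | qimg.conflict_mask
    return DiscolorationMask(
        flags=decoder | statistical,
        decoder=decoder.copy(),
        statistical=statistical,
        tau_agree=tau_agree,
        tau_discolor=tau_d,
    )


def inpaint(image: np.ndarray, mask: DiscolorationMask | np.ndarray) -> np.ndarray:
    """Biharmonic fill of masked channel-pixels; unmasked pixels unchanged."""
    flags = mask.flags if isinstance(mask, DiscolorationMask) else np.asarray(mask)
    img = np.asarray(image)
    if flags.all():
        raise ValueError("fully masked image: nothing anchors the fill")
    if not flags.any():
        return img.copy()
    out = img.astype(np.float64).copy()
    for c in range(3):
        if not flags[c].any():
            continue
        filled = inpaint_biharmonic(out[:, :, c], flags[c])
        out[:, :, c] = np.where(flags[c], filled, out[:, :, c])
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _adaptive_median_channel(channel: np.ndarray, max_window: int = 7) -> np.ndarray:
    """Classic adaptive median: the window grows 3 -> max until the local
    median is not an extreme; a pixel is replaced only when it is itself a
    local extreme at that window."""
    src = channel.astype(np.int16)
    out = src.copy()
    undecided = np.ones(src.shape, dtype=bool)
    for w in range(3, max_window + 1, 2):
        med = ndimage.median_filter(src, size=w)
        lo = ndimage.minimum_filter(src, size=w)
        hi = ndimage.maximum_filter(src, size=w)
        med_ok = (med > lo) & (med < hi)
        is_extreme = (src <= lo) | (src >= hi)
        decide = undecided & med_ok
        out[decide & is_extreme] = med[decide & is_extreme]
        undecided &= ~med_ok
        if not undecided.any():
            break
    # windows exhausted: replace still-undecided extremes with the last median
    out[undecided & is_extreme] = med[undecided & is_extreme]
    return np.clip(out, 0, 255).astype(np.uint8)


def smooth(
    image: np.ndarray,
    sigma_spatial: float = 3.0,
    sigma_range: float = 30.0,
    max_window: int = 7,
) -> np.ndarray:
    """Bilateral filter followed by adaptive median smoothing.

    ``sigma_range`` is in 8-bit intensity units.  Both stages are
    deterministic and leave a constant image unchanged.
    """
    img = np.asarray(image).astype(np.float64) / 255.0
    bil = denoise_bilateral(
        img,
        sigma_color=sigma_range / 255.0,
        sigma_spatial=sigma_spatial,
        channel_axis=-1,
        mode="edge",
    )
    bil8 = np.clip(np.rint(bil * 255.0), 0, 255).astype(np.uint8)
    out = np.empty_like(bil8)
    for c in range(3):
        out[:, :, c] = _adaptive_median_channel(bil8[:, :, c], max_window=max_window)
    return out


def psnr(a: np.ndarray, b: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if np.array_equal(a, b):
        return math.inf
    return float(peak_signal_noise_ratio(a, b, data_range=255))


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Mean structural similarity over channels (7x7 windows, standard constants)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    return float(
        structural_similarity(a, b, data_range=255, channel_axis=-1, win_size=7)
    )


def restore(
    image: np.ndarray,
    qimg: QuantizedImage,
    order: HilbertOrder,
    do_smooth: bool = True,
    **detect_kwargs,
) -> tuple[np.ndarray, DiscolorationMask]:
    """Full restoration: detect -> inpaint -> (optional) smooth."""
    mask = detect_discoloration(qimg, order, **detect_kwargs)
    out = inpaint(image, mask) if mask.flags.any() else image.copy()
    if do_smooth:
        out = smooth(out)
    return out, mask
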