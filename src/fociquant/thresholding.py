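"""Intensity statistics and the two binarization operators.

Nucleus segmentation uses global Otsu thresholding on the marker channel,
restricted to pixels at or above a user-chosen background cut-off; focus
segmentation uses an adaptive Gaussian-C local threshold on the damage
channel.  Both operators are implemented here directly so their behaviour
is fully specified and testable against brute-force oracles:

* Otsu's criterion is evaluated in exact integer arithmetic.  For a
  candidate threshold ``t`` splitting the (floored) histogram into classes
  with pixel counts ``W0, W1`` and intensity sums ``S0, S1``, the
  between-class variance is proportional to ``(S0*W1 - S1*W0)^2 / (W0*W1)``;
  candidates are compared by cross-multiplication, so ties are broken
  deterministically at the smallest threshold with no floating-point noise.

* The adaptive operator compares each pixel against the Gaussian-weighted
  mean of its ``block_size`` x ``block_size`` neighbourhood, rounded to the
  nearest integer, minus a constant offset ``C``.  Rounding the local mean
  to integer matches the 8-bit convention of this operator family and makes
  the mask an exact, reproducible function of the input.  Borders are
  mirror-reflected (edge pixel not repeated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate1d

from .batchio import GrayImage
from .errors import EmptyBatchError, InvalidParameterError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntensityHistogram:
    """Pooled 256-bin pixel-intensity histogram over a batch of images."""

    counts: np.ndarray  # shape (256,), int64
    n_images: int
    n_pixels: int


def batch_intensity_histogram(images: list[GrayImage]) -> IntensityHistogram:
    """Pooled intensity histogram: counts[i] = number of pixels of value i
    summed over all images of the batch."""
    if not images:
        raise EmptyBatchError("cannot histogram an empty image batch")
    counts = np.zeros(256, dtype=np.int64)
    n_pixels = 0
    for img in images:
        counts += np.bincount(img.pixels.ravel(), minlength=256)
        n_pixels += img.pixels.size
    return IntensityHistogram(counts=counts, n_images=len(images), n_pixels=n_pixels)


def suggest_cutoff(hist: IntensityHistogram) -> int:
    """Suggest a minimal background cut-off from the pooled histogram.

    The dominant intensity ``d`` (the fullest bin, smallest index on ties)
    is taken as the background mode.  The suggestion is the absolute
    difference between the mean intensity of all pixels and the mean
    intensity after excluding the dominant bin, rounded to the nearest
    integer and clamped to [0, 255].  For a background-dominated
    fluorescence batch this lands near the intensity scale separating
    background from signal.
    """
    counts = np.asarray(hist.counts, dtype=np.int64)
    n = int(counts.sum())
    if n == 0:
        raise EmptyBatchError("histogram has no pixels")
    intensities = np.arange(256, dtype=np.int64)
    d = int(np.argmax(counts))
    mu_all = float((counts * intensities).sum()) / n
    n_excl = n - int(counts[d])
    if n_excl == 0:
        mu_excl = mu_all
    else:
        mu_excl = float((counts * intensities).sum() - d * int(counts[d])) / n_excl
    suggestion = int(np.floor(abs(mu_excl - mu_all) + 0.5))
    return min(max(suggestion, 0), 255)


def _otsu_from_counts(counts: list[int], floor: int) -> int | None:
    """Exact-arithmetic Otsu sweep over the histogram restricted to
    intensities >= floor.  Returns the smallest maximizing threshold, or
    None when no two-class split exists."""
    total_w = sum(counts[floor:])
    total_s = sum(i * c for i, c in enumerate(counts) if i >= floor)
    best_t: int | None = None
    best_num = 0  # best score as exact fraction best_num / best_den
    best_den = 1
    w0 = 0
    s0 = 0
    for t in range(floor, 256):
        w0 += counts[t]
        s0 += t * counts[t]
        w1 = total_w - w0
        if w0 == 0 or w1 == 0:
            continue
        s1 = total_s - s0
        num = (s0 * w1 - s1 * w0) ** 2
        den = w0 * w1
        # score = num/den; strict > keeps the smallest maximizer on ties
        if best_t is None or num * best_den > best_num * den:
            best_t, best_num, best_den = t, num, den
    return best_t


def otsu_threshold(image: GrayImage, floor: int = 0) -> tuple[int, np.ndarray]:
    """Global Otsu threshold with a background floor.

    Pixels below ``floor`` are treated as background: they are excluded from
    the Otsu histogram and can never enter the foreground.  Returns
    ``(threshold, mask)`` where ``mask`` is a boolean array of pixels with
    value strictly above the threshold.  When the pixels at or above the
    floor all share a single value but a background class below the floor
    exists, the cut-off itself already is the separation and those pixels
    are returned as foreground.  A degenerate image (constant, or entirely
    below the floor) yields an empty mask and threshold 255 with a logged
    warning, so one blank frame never aborts a batch.
    """
    if not 0 <= floor <= 255:
        raise InvalidParameterError(f"floor must be in [0, 255], got {floor}")
    pixels = image.pixels
    counts = np.bincount(pixels.ravel(), minlength=256).tolist()
    occupied_above = [i for i in range(floor, 256) if counts[i] > 0]
    if len(occupied_above) == 1 and floor > 0 and sum(counts[:floor]) > 0:
        # The user's cut-off already separated a (single-valued) signal
        # class from background; Otsu has nothing left to split, so the
        # remaining pixels are the foreground.
        return floor, pixels >= floor
    t = _otsu_from_counts(counts, floor)
    if t is None:
        logger.warning(
            "degenerate image %s: no intensity split at or above floor %d; "
            "returning empty mask",
            image.source_name or "<unnamed>",
            floor,
        )
        return 255, np.zeros_like(pixels, dtype=bool)
    threshold = max(t, floor)
    mask = (pixels > threshold) & (pixels >= floor)
    return threshold, mask


def gaussian_kernel_1d(block_size: int) -> np.ndarray:
    """Normalised 1-D Gaussian weights for a given odd window size.

    sigma follows the conventional size-to-sigma rule of the operator
    family: ``0.3 * ((block_size - 1) * 0.5 - 1) + 0.8``.
    """
    if block_size < 3 or block_size % 2 == 0:
        raise InvalidParameterError(
            f"block_size must be odd and >= 3, got {block_size}"
        )
    sigma = 0.3 * ((block_size - 1) * 0.5 - 1) + 0.8
    half = (block_size - 1) // 2
    x = np.arange(-half, half + 1, dtype=np.float64)
    g = np.exp(-(x**2) / (2.0 * sigma**2))
    return g / g.sum()


def adaptive_gaussian_mask(
    image: GrayImage, block_size: int = 11, c_offset: int = 2
) -> np.ndarray:
    """Adaptive Gaussian-C local threshold.

    A pixel is foreground iff its value exceeds the Gaussian-weighted mean
    of its neighbourhood (rounded to the nearest integer) minus
    ``c_offset``.  Note the operator's flat-field artifact: on a perfectly
    constant image every pixel is foreground when ``c_offset`` > 0 and
    background when ``c_offset`` <= 0.
    """
    g = gaussian_kernel_1d(block_size)
    f = image.pixels.astype(np.float64)
    local = correlate1d(f, g, axis=0, mode="mirror")
    local = correlate1d(local, g, axis=1, mode="mirror")
    t = np.floor(local + 0.5) - float(c_offset)
    return image.pixels.astype(np.float64) > t
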