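"""Refinement segmentation: strip the dark shadow border from grains.

Coarse segmentation keeps a dark rim of shadow pixels around each
grain.  In the red-channel histogram of the foreground pixels the rim
and the bright grain core form two separate modes; the valley between
them is a natural threshold ``d`` below which foreground pixels are
reclassified as background.

Locating that valley on the raw histogram is unreliable, so the
histogram is first smoothed with a wide Gaussian (101 symmetric taps,
sigma 7.5 bins) and then summarised by a least-squares quintic trend
line.  A quintic has at most four interior critical points, so between
its two dominant maxima there is a single interior minimum -- the
valley.  If the trend line has fewer than two interior maxima the
histogram is unimodal and refinement is skipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial
from scipy.ndimage import convolve1d

__all__ = [
    "Histogram256",
    "QuinticFit",
    "RefinementResult",
    "red_histogram",
    "gaussian_smooth_histogram",
    "fit_quintic",
    "find_threshold",
    "refine",
]

#: A histogram over the 256 red values; counts may be fractional after smoothing.
Histogram256 = np.ndarray


@dataclass(frozen=True)
class QuinticFit:
    """Least-squares 5th-degree polynomial trend of a histogram.

    ``coef`` holds the coefficients in ascending power order
    (``coef[5]`` multiplies ``x**5``), valid on the bin domain [0, 255].
    """

    coef: np.ndarray

    def __call__(self, x) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(x, dtype=np.float64), self.coef)


@dataclass(frozen=True)
class RefinementResult:
    """Outcome of the valley search on the quintic trend line.

    ``threshold_d`` is the red value separating shadow rim from grain
    core, or ``None`` when the trend line is not bimodal (refinement is
    then a no-op).  ``peak_a < valley_c < peak_b`` whenever present.
    """

    threshold_d: int | None
    peak_a: int | None = None
    peak_b: int | None = None
    valley_c: int | None = None


def red_histogram(img: np.ndarray, mask: np.ndarray) -> Histogram256:
    """Histogram of the red component over the foreground pixels.

    Raises ``ValueError`` on an empty mask: with no foreground there is
    nothing to refine.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("red_histogram: mask selects no foreground pixels")
    red = np.asarray(img)[..., 0][mask]
    return np.bincount(red.ravel(), minlength=256).astype(np.float64)


def gaussian_kernel(size: int = 100, sigma: float = 7.5) -> np.ndarray:
    """Unit-sum discrete Gaussian ``exp(-x^2 / 2 sigma^2)``.

    A nominal ``size`` of 100 is realised as a symmetric 101-tap kernel
    on ``x = -50..50`` (an even tap count has no centre tap).
    """
    half = size // 2
    x = np.arange(-half, half + 1, dtype=np.float64)
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def gaussian_smooth_histogram(
    h: Histogram256, size: int = 100, sigma: float = 7.5
) -> Histogram256:
    """Smooth a 256-bin histogram with the unit-sum Gaussian kernel.

    The boundary is handled by symmetric reflection, which for a
    unit-sum symmetric kernel preserves both the total mass of the
    histogram and constant histograms exactly.
    """
    h = np.asarray(h, dtype=np.float64)
    return convolve1d(h, gaussian_kernel(size, sigma), mode="reflect")


def fit_quintic(h: Histogram256) -> QuinticFit:
    """Least-squares quintic over the 256 ``(bin, count)`` pairs."""
    h = np.asarray(h, dtype=np.float64)
    x = np.arange(h.size, dtype=np.float64)
    poly = Polynomial.fit(x, h, deg=5).convert()
    coef = np.zeros(6)
    coef[: poly.coef.size] = poly.coef
    return QuinticFit(coef=coef)


def find_threshold(fit: QuinticFit) -> RefinementResult:
    """Valley of the quintic trend between its two dominant maxima.

    The polynomial is evaluated on the integer bins 0..255; interior
    strict local maxima are collected and the two with the largest
    value are kept.  The threshold is the argmin of the trend strictly
    between them.  With fewer than two interior maxima the histogram is
    treated as unimodal and no threshold is returned.
    """
    y = fit(np.arange(256))
    interior = np.arange(1, 255)
    is_max = (y[interior] > y[interior - 1]) & (y[interior] > y[interior + 1])
    peaks = interior[is_max]
    if peaks.size < 2:
        return RefinementResult(threshold_d=None)
    top_two = peaks[np.argsort(y[peaks])[-2:]]
    lo, hi = int(top_two.min()), int(top_two.max())
    between = np.arange(lo + 1, hi)
    valley = int(between[np.argmin(y[between])])
    return RefinementResult(threshold_d=valley, peak_a=lo, peak_b=hi, valley_c=valley)


def refine(
    img: np.ndarray, mask: np.ndarray, result: RefinementResult
) -> np.ndarray:
    """Remove foreground pixels whose red value is below the threshold.

    Anti-extensive: the output foreground is always a subset of the
    input foreground.  Without a threshold the mask is returned
    unchanged (as a copy).
    """
    mask = np.asarray(mask, dtype=bool)
    if result.threshold_d is None:
        return mask.copy()
    red = np.asarray(img)[..., 0]
    return mask & ~(red < result.threshold_d)
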