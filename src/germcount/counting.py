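"""Grain counting from the area distribution curve.

After refinement every connected foreground region holds one grain or
a cluster of touching grains.  The areas of the ``m`` regions, sorted
ascending, form the *area distribution curve*: tiny noise regions at
the front, then a stable plateau of single-grain areas, then the jumps
of two-, three-, four-grain clusters.

Turning point A (start of the plateau) is found from the discrete
Laplacian of the lightly smoothed curve: at the noise-to-plateau jump
the Laplacian swings positive then negative, and A is the first index
whose neighbourhood rises back through zero.  Turning point B (end of
the plateau) is the last index before the sorted areas start growing
by more than 20% over a window of three.  The candidate single-grain
areas between A and B are scored exhaustively: the optimal area
``s_opt`` minimises the summed relative deviation ``sum_j |1 - s_j /
s_i|``.  Each region then contributes ``floor(s / s_opt)`` grains,
plus one more when the fractional part exceeds 0.4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as _sk_label

__all__ = [
    "RegionTable",
    "AreaCurve",
    "GrainCountResult",
    "label_regions",
    "build_area_curve",
    "find_point_a",
    "find_point_b",
    "optimal_grain_area",
    "count_region",
    "count_grains",
]


@dataclass
class RegionTable:
    """Connected foreground regions of a binary mask.

    ``label_image`` holds 0 for background and 1..n for the regions;
    ``areas[i]`` is the pixel count of region ``labels[i]``.
    """

    label_image: np.ndarray
    labels: np.ndarray
    areas: np.ndarray
    bboxes: list[tuple[slice, slice]]

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class AreaCurve:
    """Ascending-sorted region areas with their smoothed curve and Laplacian."""

    areas: np.ndarray          # sorted ascending (raw)
    smoothed: np.ndarray       # after the 3-tap Gaussian
    laplacian: np.ndarray      # g(x) = f(x+1) + f(x-1) - 2 f(x); endpoints 0
    region_labels: np.ndarray  # region label at each sorted index
    index_a: int | None = None
    index_b: int | None = None

    @property
    def s_a(self) -> int:
        return int(self.areas[self.index_a])

    @property
    def s_b(self) -> int:
        return int(self.areas[self.index_b])


@dataclass
class GrainCountResult:
    """Total grain count with the per-region breakdown."""

    s_opt: int
    n_grain: int
    per_region_counts: dict[int, int]
    noise_labels: set[int] = field(default_factory=set)


def label_regions(mask: np.ndarray, connectivity: int = 8) -> RegionTable:
    """8-connected (default) labelling of the foreground with areas and boxes."""
    mask = np.asarray(mask, dtype=bool)
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    lab = _sk_label(mask, connectivity=2 if connectivity == 8 else 1)
    n = int(lab.max())
    if n == 0:
        return RegionTable(lab, np.empty(0, int), np.empty(0, int), [])
    areas = np.bincount(lab.ravel(), minlength=n + 1)[1:]
    boxes = ndimage.find_objects(lab)
    return RegionTable(lab, np.arange(1, n + 1), areas.astype(int), boxes)


def _smooth3(values: np.ndarray, sigma: float) -> np.ndarray:
    """3-tap unit-sum Gaussian smoothing with truncated-kernel edges."""
    x = np.asarray(values, dtype=np.float64)
    if x.size < 2:
        return x.copy()
    k = np.exp(-np.array([1.0, 0.0, 1.0]) / (2.0 * sigma**2))
    num = np.convolve(x, k, mode="same")
    den = np.convolve(np.ones_like(x), k, mode="same")
    return num / den


def build_area_curve(
    table: RegionTable, smooth_len: int = 3, smooth_sigma: float = 0.65
) -> AreaCurve:
    """Sort the region areas ascending, smooth them, take the Laplacian."""
    if len(table) < 1:
        raise ValueError("build_area_curve: no regions")
    if smooth_len != 3:
        raise ValueError("only the 3-tap smoothing window is supported")
    order = np.argsort(table.areas, kind="stable")
    areas = table.areas[order]
    f = _smooth3(areas, smooth_sigma)
    g = np.zeros_like(f)
    if f.size >= 3:
        g[1:-1] = f[2:] + f[:-2] - 2.0 * f[1:-1]
    return AreaCurve(
        areas=areas,
        smoothed=f,
        laplacian=g,
        region_labels=table.labels[order],
    )


def find_point_a(curve: AreaCurve) -> int:
    """First index where the Laplacian rises through zero (turning point A).

    Searches for the smallest interior ``i`` with ``g(i-1) < 0``,
    ``g(i-1) < g(i)``, ``g(i+1) > 0`` and ``g(i+1) > g(i)``.  Falls back
    to 0 (no noise regions) when the pattern never occurs or the curve
    is shorter than 3.
    """
    g = curve.laplacian
    for i in range(1, g.size - 1):
        if g[i - 1] < 0 and g[i - 1] < g[i] and g[i + 1] > 0 and g[i + 1] > g[i]:
            return i
    return 0


def find_point_b(
    curve: AreaCurve,
    a: int,
    ratio_threshold: float = 1.2,
    convention: str = "stable",
    on_smoothed: bool = False,
) -> int:
    """End of the single-grain plateau (turning point B).

    Scanning ``i`` upward from A on the sorted areas, the plateau ends
    at the first ``i`` with ``s[i+3] / s[i] > ratio_threshold``.  Under
    the default ``"stable"`` convention B is that ``i`` (the last point
    of the stable run); ``"jump"`` instead returns ``i + 3``.  If the
    condition never fires every region holds a single grain and the
    last index is taken as B.
    """
    s = curve.smoothed if on_smoothed else curve.areas.astype(np.float64)
    m = s.size
    for i in range(a, m - 3):
        if s[i + 3] / s[i] > ratio_threshold:
            return i if convention == "stable" else min(i + 3, m - 1)
    return m - 1


def optimal_grain_area(candidates: np.ndarray) -> int:
    """Exhaustively score the candidate areas; return the minimiser.

    ``s_opt`` is the candidate ``s_i`` minimising
    ``sum_j |1 - s_j / s_i|``; ties go to the smallest index (the
    strict "<" update of the exhaustive search).
    """
    c = np.asarray(candidates, dtype=np.float64)
    if c.size == 0:
        raise ValueError("optimal_grain_area: no candidate single-grain areas")
    errors = np.abs(1.0 - c[None, :] / c[:, None]).sum(axis=1)
    return int(np.asarray(candidates)[int(np.argmin(errors))])


def count_region(s: int, s_opt: int, fraction_threshold: float = 0.4) -> int:
    """Number of grains in one region: ``floor(s/s_opt)``, plus 1 when the
    fractional part strictly exceeds ``fraction_threshold``.

    Integer inputs are handled in exact rational arithmetic so that a
    fractional part landing exactly on the threshold never rounds up.
    """
    if s_opt <= 0:
        raise ValueError("count_region: s_opt must be positive")
    if (
        isinstance(s, (int, np.integer))
        and isinstance(s_opt, (int, np.integer))
        and float(fraction_threshold) == 0.4
    ):
        q, r = divmod(int(s), int(s_opt))
        return q + (1 if 5 * r > 2 * int(s_opt) else 0)
    q = s / s_opt
    fl = math.floor(q)
    return fl + (1 if q - fl > fraction_threshold else 0)


def count_grains(
    curve: AreaCurve,
    table: RegionTable,
    s_opt: int,
    fraction_threshold: float = 0.4,
    index_a: int = 0,
    exclude_noise_regions: bool = False,
) -> GrainCountResult:
    """Sum the per-region grain counts into the total ``n_grain``.

    Every region passes through :func:`count_region`; genuine noise
    regions are tiny and contribute 0 on their own.  Regions sorted
    below turning point A are additionally flagged as noise, and with
    ``exclude_noise_regions=True`` they are forced to contribute 0.
    """
    noise = set(int(l) for l in curve.region_labels[:index_a])
    counts: dict[int, int] = {}
    for lab, area in zip(table.labels, table.areas):
        lab = int(lab)
        if exclude_noise_regions and lab in noise:
            counts[lab] = 0
        else:
            counts[lab] = count_region(int(area), s_opt, fraction_threshold)
    return GrainCountResult(
        s_opt=int(s_opt),
        n_grain=int(sum(counts.values())),
        per_region_counts=counts,
        noise_labels=noise,
    )
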