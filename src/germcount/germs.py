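"""Germ detection and germinated-grain counting.

A germinated grain shows a white germ (radicle) protruding from the
yellow grain body.  Candidate germs are the bright connected regions
outside the grain foreground (gray value strictly above 160).  Two
filters remove non-germs:

* **area**: a real germ has ``s_opt/50 < s_bud < s_opt/3`` (both
  strict) relative to the single-grain area -- smaller blobs are
  droplets or specular noise, larger ones are reflections or whole
  white grains;
* **contact geometry**: a germ must touch a grain, and the length
  ``l`` of the germ boundary in contact with grain foreground must be
  small relative to the germ circumference ``p`` (``l/p < 0.4``).  A
  bright patch that is mostly embedded in a grain is an incompletely
  emerged germ, not a counted one.

Each accepted candidate counts one germinated grain (a germ touched by
the loop breaks on its first adjacent grain), so two germs that merge
into a single connected region count once -- a documented limitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .imaging import to_gray

__all__ = [
    "GermCandidate",
    "GerminationReport",
    "germ_mask",
    "extract_candidates",
    "filter_by_area",
    "measure_contact",
    "measure_candidates",
    "count_germinated",
]

_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-neighbourhood
_SQUARE = ndimage.generate_binary_structure(2, 2)  # 8-neighbourhood


@dataclass
class GermCandidate:
    """One candidate germ region with its contact geometry.

    ``perimeter`` (p) is the inner-boundary pixel count (pixels of the
    region with at least one 4-neighbour outside it) and
    ``intersection_length`` (l) the number of those boundary pixels
    with at least one 8-neighbour in grain foreground, so ``0 <= l <=
    p`` and ``l/p`` is a well-defined contact fraction.
    """

    label: int
    area: int
    perimeter: int | None = None
    intersection_length: int | None = None
    adjacent_grain_ids: frozenset[int] = frozenset()
    accepted: bool | None = None
    reason: str | None = None

    @property
    def lp_ratio(self) -> float | None:
        if self.perimeter in (None, 0):
            return None
        return self.intersection_length / self.perimeter


@dataclass
class GerminationReport:
    """Grain count, germinated count and their ratio, with a full audit."""

    n_grain: int
    n_bud: int
    germination_rate: float | None
    rate_defined: bool
    candidates: list[GermCandidate] = field(default_factory=list)


def germ_mask(
    img: np.ndarray, grain_mask: np.ndarray, gray_threshold: int = 160
) -> np.ndarray:
    """Bright pixels outside the (refined) grain foreground.

    The comparison is strict: a gray value exactly at the threshold is
    excluded.
    """
    gray = to_gray(img)
    return (~np.asarray(grain_mask, dtype=bool)) & (gray > gray_threshold)


def extract_candidates(mask: np.ndarray) -> tuple[np.ndarray, list[GermCandidate]]:
    """Label the germ mask (8-connectivity) into candidate regions."""
    lab, n = ndimage.label(np.asarray(mask, dtype=bool), structure=_SQUARE)
    if n == 0:
        return lab, []
    areas = np.bincount(lab.ravel(), minlength=n + 1)[1:]
    cands = [GermCandidate(label=i + 1, area=int(a)) for i, a in enumerate(areas)]
    return lab, cands


def filter_by_area(
    candidates: list[GermCandidate],
    s_opt: int,
    area_lo_divisor: float = 50.0,
    area_hi_divisor: float = 3.0,
) -> list[GermCandidate]:
    """Keep candidates with ``s_opt/50 < s_bud < s_opt/3`` (both strict).

    Rejected candidates are returned too, marked with their reason, so
    the report can audit every bright region.
    """
    if s_opt <= 0:
        raise ValueError("filter_by_area: s_opt must be positive")
    out = []
    for c in candidates:
        if not (c.area > s_opt / area_lo_divisor):
            out.append(replace(c, accepted=False, reason="area-too-small"))
        elif not (c.area < s_opt / area_hi_divisor):
            out.append(replace(c, accepted=False, reason="area-too-large"))
        else:
            out.append(c)
    return out


def measure_contact(
    candidate_mask: np.ndarray,
    grain_mask: np.ndarray,
    grain_labels: np.ndarray | None = None,
) -> tuple[int, int, frozenset[int]]:
    """Contact geometry of one candidate region against the grain foreground.

    Returns ``(p, l, adjacent_grain_ids)`` where ``p`` counts the
    candidate's inner-boundary pixels (4-neighbourhood test, image
    border counts as outside), ``l`` counts boundary pixels with an
    8-neighbour in grain foreground, and the id set holds the labels of
    the grain regions so touched (empty when ``grain_labels`` is not
    supplied or nothing is touched).
    """
    cand = np.asarray(candidate_mask, dtype=bool)
    grain = np.asarray(grain_mask, dtype=bool)
    interior = ndimage.binary_erosion(cand, structure=_CROSS, border_value=0)
    boundary = cand & ~interior
    p = int(boundary.sum())
    near_grain = ndimage.binary_dilation(grain, structure=_SQUARE)
    contact = boundary & near_grain
    l = int(contact.sum())
    ids: frozenset[int] = frozenset()
    if grain_labels is not None and l > 0:
        touch = ndimage.binary_dilation(contact, structure=_SQUARE) & grain
        ids = frozenset(int(v) for v in np.unique(grain_labels[touch]) if v > 0)
    return p, l, ids


def measure_candidates(
    germ_labels: np.ndarray,
    candidates: list[GermCandidate],
    grain_mask: np.ndarray,
    grain_labels: np.ndarray | None = None,
) -> list[GermCandidate]:
    """Fill in p, l and adjacency for every candidate (bbox-local for speed)."""
    grain = np.asarray(grain_mask, dtype=bool)
    slices = ndimage.find_objects(germ_labels)
    out = []
    for c in candidates:
        sl = slices[c.label - 1]
        sl = tuple(
            slice(max(s.start - 2, 0), min(s.stop + 2, dim))
            for s, dim in zip(sl, germ_labels.shape)
        )
        local = germ_labels[sl] == c.label
        p, l, ids = measure_contact(
            local,
            grain[sl],
            grain_labels[sl] if grain_labels is not None else None,
        )
        out.append(
            replace(c, perimeter=p, intersection_length=l, adjacent_grain_ids=ids)
        )
    return out


def count_germinated(
    candidates: list[GermCandidate],
    n_grain: int,
    ratio_max: float = 0.4,
) -> GerminationReport:
    """Count germinated grains among the measured candidates.

    A candidate counts one germinated grain when it passed the area
    filter, touches at least one grain (``l >= 1``) and has
    ``l/p < ratio_max`` (strict).  The germination rate is
    ``n_bud / n_grain``; with no grains the rate is undefined and
    flagged.
    """
    audited: list[GermCandidate] = []
    n_bud = 0
    for c in candidates:
        if c.accepted is False:  # already rejected by the area filter
            audited.append(c)
            continue
        if c.intersection_length is None or c.perimeter is None:
            raise ValueError("count_germinated: candidate not measured")
        if c.intersection_length < 1:
            audited.append(replace(c, accepted=False, reason="not-adjacent"))
        elif not (c.intersection_length / c.perimeter < ratio_max):
            audited.append(replace(c, accepted=False, reason="contact-too-long"))
        else:
            audited.append(replace(c, accepted=True, reason="germ"))
            n_bud += 1
    rate = n_bud / n_grain if n_grain > 0 else None
    return GerminationReport(
        n_grain=int(n_grain),
        n_bud=int(n_bud),
        germination_rate=rate,
        rate_defined=n_grain > 0,
        candidates=audited,
    )
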