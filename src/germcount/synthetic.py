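"""Seeded generator of synthetic grain scenes with exact ground truth.

The generator emulates the acquisition protocol the pipeline targets:
grains soaking in a dark, low-reflection container photographed from
above.  Each scene is rendered from geometric primitives so that every
pipeline stage sees the structure it was designed for:

* near-black background with mild Gaussian pixel noise;
* grains as yellow ellipses (aspect ratio ~2.5:1, typical of rice)
  whose core colour sits firmly in the clipped colour-difference
  branch, surrounded by a darker shadow rim whose red value falls in a
  separate histogram mode -- this exercises the refinement threshold;
* adhesion clusters: chains of grains lying side by side whose cores
  overlap by a few pixels, so the refined region stays connected and
  must be counted by area division;
* germs as white elliptical protrusions at one grain tip, drawn so
  that by construction the germ area falls inside the accepted band
  relative to the single-grain area and the contact fraction ``l/p``
  stays below 0.4;
* white reflection blobs and droplets that violate the area band or
  touch no grain, exercising the rejection paths.

Rendering is alias-free by default (hard-edged primitives), so the
ground-truth masks and counts are exact; an anti-aliased mode (2x
supersampling) exists for robustness tests with tolerances.  All
randomness flows from ``SceneSpec.seed`` and scenes are bit-identical
across runs.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["SceneSpec", "GroundTruth", "generate_scene", "generate_adversarial"]

ADVERSARIAL_KINDS = (
    "droplet-on-edge",
    "intertwined-germs",
    "germ-under-grain",
    "overlapping-grains",
)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic grain scene.

    Defaults describe a routine assessment scene: a few dozen grains,
    ±10% area jitter, 30% of grains in touching clusters of 2-4, and a
    high germination fraction, on an auto-sized canvas.
    """

    seed: int = 0
    n_grains: int = 40
    image_size: tuple[int, int] | None = None  # (H, W); None -> auto
    scale: float = 1.0

    # grain geometry (core ellipse semi-axes, pixels, before scale/jitter)
    core_axes: tuple[float, float] = (26.0, 10.5)
    area_jitter: float = 0.10          # relative area jitter, +/-
    rim_width: float = 2.0             # shadow border drawn outside the core

    # adhesion
    adhesion_fraction: float = 0.30
    cluster_sizes: tuple[int, ...] = (2, 3, 4)
    core_penetration: float = 3.0      # overlap of neighbouring cores, px

    # germination
    germination_fraction: float = 0.70
    germ_area_fraction: float = 0.12   # target s_bud / s_0, inside (1/50, 1/3)
    germ_aspect: float = 2.0
    germ_overlap: float = 5.0          # how far the germ footprint reaches into the grain

    # colours (RGB)
    background_rgb: tuple[int, int, int] = (10, 10, 10)
    background_noise_sigma: float = 3.0
    core_rgb: tuple[int, int, int] = (235, 205, 40)
    core_red_jitter: int = 5
    rim_rgb: tuple[int, int, int] = (85, 70, 32)
    rim_red_jitter: int = 5
    germ_rgb: tuple[int, int, int] = (250, 250, 250)

    # noise objects
    n_reflections: int = 2
    reflection_area_fraction: float = 0.60  # of the single-grain area (too big)
    n_droplets: int = 2
    droplet_area_fraction: float = 0.010    # of the single-grain area (too small)
    n_specks: int = 0                       # tiny grain-coloured regions
    speck_size: tuple[int, int] = (2, 3)

    antialias: bool = False
    max_attempts: int = 400


@dataclass
class GroundTruth:
    """Exact per-scene truth recorded while rendering."""

    n_grains: int
    n_germinated: int
    grain_label_image: np.ndarray      # 0 background, 1..n per-grain core pixels
    germ_label_image: np.ndarray       # 0 background, grain id of the owning grain
    cluster_multiplicities: list[int]  # one entry per placed cluster (singles -> 1)
    germinated_grain_ids: list[int]

    @property
    def germination_rate(self) -> float | None:
        return self.n_germinated / self.n_grains if self.n_grains else None

    def summary(self) -> dict:
        return {
            "n_grains": self.n_grains,
            "n_germinated": self.n_germinated,
            "germination_rate": self.germination_rate,
            "cluster_multiplicities": list(self.cluster_multiplicities),
        }


# ---------------------------------------------------------------------------
# geometry helpers


def _ellipse_pixels(cy, cx, a, b, theta, shape):
    """Row/col index arrays of the pixels inside a rotated ellipse.

    ``a`` is the semi-axis along ``theta`` (measured from the +x axis),
    ``b`` the perpendicular one.  Pixel centres are tested, clipped to
    the image bounds.
    """
    h, w = shape
    r = max(a, b) + 1.5
    y0, y1 = max(int(cy - r), 0), min(int(cy + r) + 2, h)
    x0, x1 = max(int(cx - r), 0), min(int(cx + r) + 2, w)
    if y0 >= y1 or x0 >= x1:
        return np.empty(0, int), np.empty(0, int)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = xx - cx
    dy = yy - cy
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return yy[inside], xx[inside]


def _radius_along(a, b, theta, phi):
    """Distance from centre to the ellipse boundary in direction ``phi``."""
    d = phi - theta
    return (a * b) / math.hypot(b * math.cos(d), a * math.sin(d))


@dataclass
class _Grain:
    cy: float
    cx: float
    a: float          # core semi-major
    b: float          # core semi-minor
    theta: float
    core_red: int
    rim_red: int
    germ_dir: int | None = None   # +1 / -1 along the major axis, None = no germ


class _Renderer:
    """Accumulates primitives on a canvas and tracks occupancy and truth."""

    def __init__(self, spec: SceneSpec, shape: tuple[int, int], rng: np.random.Generator):
        self.spec = spec
        self.shape = shape
        self.rng = rng
        h, w = shape
        bg = np.array(spec.background_rgb, dtype=np.float64)
        noise = rng.normal(0.0, spec.background_noise_sigma, size=(h, w, 3))
        self.img = np.clip(np.round(bg[None, None, :] + noise), 0, 255).astype(np.uint8)
        self.occupancy = np.zeros(shape, dtype=bool)
        self.grain_labels = np.zeros(shape, dtype=np.int32)
        self.germ_labels = np.zeros(shape, dtype=np.int32)
        self.cluster_multiplicities: list[int] = []
        self.germinated: list[int] = []
        self.n_grains = 0

    # -- low-level paint ----------------------------------------------------
    def _paint(self, ys, xs, rgb):
        self.img[ys, xs] = rgb
        self.occupancy[ys, xs] = True

    def free(self, ys, xs, margin: int = 3) -> bool:
        """True when the pixel set, dilated by ``margin``, avoids occupancy."""
        if ys.size == 0:
            return False
        h, w = self.shape
        y0 = max(int(ys.min()) - margin, 0)
        y1 = min(int(ys.max()) + margin + 1, h)
        x0 = max(int(xs.min()) - margin, 0)
        x1 = min(int(xs.max()) + margin + 1, w)
        probe = np.zeros((y1 - y0, x1 - x0), dtype=bool)
        probe[ys - y0, xs - x0] = True
        probe = ndimage.binary_dilation(probe, iterations=margin)
        return not (probe & self.occupancy[y0:y1, x0:x1]).any()

    # -- primitives ---------------------------------------------------------
    def draw_grains(self, grains: list[_Grain]) -> list[int]:
        """Paint a touching group: all shadow rims first, then all cores.

        Painting rims before any core keeps the overlap zone between
        neighbouring cores core-coloured, so a refined cluster stays a
        single connected region.
        """
        w = self.spec.rim_width
        for g in grains:
            rim_y, rim_x = _ellipse_pixels(
                g.cy, g.cx, g.a + w, g.b + w, g.theta, self.shape
            )
            self._paint(rim_y, rim_x, (g.rim_red, self.spec.rim_rgb[1], self.spec.rim_rgb[2]))
        gids = []
        for g in grains:
            core_y, core_x = _ellipse_pixels(g.cy, g.cx, g.a, g.b, g.theta, self.shape)
            self._paint(core_y, core_x, (g.core_red, self.spec.core_rgb[1], self.spec.core_rgb[2]))
            self.n_grains += 1
            gid = self.n_grains
            self.grain_labels[core_y, core_x] = gid
            gids.append(gid)
        return gids

    def draw_grain(self, g: _Grain) -> int:
        return self.draw_grains([g])[0]

    def draw_germ(self, g: _Grain, gid: int, ga: float, gb: float) -> None:
        """White germ at the grain tip; never covers core pixels."""
        sign = g.germ_dir or 1
        phi = g.theta if sign > 0 else g.theta + math.pi
        dist = g.a + ga - self.spec.germ_overlap * (self.spec.scale)
        cy = g.cy + math.sin(phi) * dist
        cx = g.cx + math.cos(phi) * dist
        ys, xs = _ellipse_pixels(cy, cx, ga, gb, phi, self.shape)
        keep = self.grain_labels[ys, xs] == 0
        ys, xs = ys[keep], xs[keep]
        self._paint(ys, xs, self.spec.germ_rgb)
        self.germ_labels[ys, xs] = gid
        self.germinated.append(gid)

    def draw_blob(self, cy, cx, a, b, theta, rgb):
        ys, xs = _ellipse_pixels(cy, cx, a, b, theta, self.shape)
        self._paint(ys, xs, rgb)

    def truth(self) -> GroundTruth:
        return GroundTruth(
            n_grains=self.n_grains,
            n_germinated=len(self.germinated),
            grain_label_image=self.grain_labels,
            germ_label_image=self.germ_labels,
            cluster_multiplicities=self.cluster_multiplicities,
            germinated_grain_ids=sorted(self.germinated),
        )


# ---------------------------------------------------------------------------
# scene assembly


def _cluster_plan(spec: SceneSpec, rng: np.random.Generator) -> list[int]:
    """Multiset of placement-unit sizes (1 = isolated grain)."""
    n = spec.n_grains
    target = int(round(spec.adhesion_fraction * n))
    sizes: list[int] = []
    remaining = target
    while remaining >= 2:
        k = int(rng.choice(spec.cluster_sizes))
        k = min(k, remaining)
        if k < 2:
            break
        sizes.append(k)
        remaining -= k
    sizes.extend([1] * (n - sum(sizes)))
    return sizes


def _jittered_axes(spec: SceneSpec, rng: np.random.Generator) -> tuple[float, float]:
    factor = math.sqrt(1.0 + rng.uniform(-spec.area_jitter, spec.area_jitter))
    return (
        spec.core_axes[0] * factor * spec.scale,
        spec.core_axes[1] * factor * spec.scale,
    )


def _build_cluster(
    spec: SceneSpec, rng: np.random.Generator, size: int
) -> list[_Grain]:
    """A chain of ``size`` grains lying side by side, cores overlapping."""
    theta0 = rng.uniform(0.0, math.pi)
    side = 1 if rng.random() < 0.5 else -1
    grains: list[_Grain] = []
    cy = cx = 0.0
    prev: _Grain | None = None
    for _ in range(size):
        a, b = _jittered_axes(spec, rng)
        theta = theta0 + (rng.uniform(-0.15, 0.15) if size > 1 else 0.0)
        core_red = int(spec.core_rgb[0] + rng.integers(-spec.core_red_jitter, spec.core_red_jitter + 1))
        rim_red = int(spec.rim_rgb[0] + rng.integers(-spec.rim_red_jitter, spec.rim_red_jitter + 1))
        if prev is not None:
            # offset perpendicular to the chain orientation
            phi = theta0 + side * math.pi / 2.0
            gap = (
                _radius_along(prev.a, prev.b, prev.theta, phi)
                + _radius_along(a, b, theta, phi)
                - spec.core_penetration * spec.scale
            )
            cy = prev.cy + math.sin(phi) * gap
            cx = prev.cx + math.cos(phi) * gap
        g = _Grain(cy, cx, a, b, theta, core_red, rim_red)
        grains.append(g)
        prev = g
    return grains


def _germ_axes(spec: SceneSpec, grain: _Grain, rng: np.random.Generator):
    s0 = math.pi * grain.a * grain.b
    area = spec.germ_area_fraction * s0 * (1.0 + rng.uniform(-0.15, 0.15))
    ga = math.sqrt(area * spec.germ_aspect / math.pi)
    return ga, ga / spec.germ_aspect


def _auto_canvas(spec: SceneSpec) -> tuple[int, int]:
    a = (spec.core_axes[0] + spec.rim_width + 8.0) * spec.scale
    n_units = max(spec.n_grains, 1)
    pitch = 4.0 * a
    side = int(max(448 * spec.scale, math.ceil(math.sqrt(n_units) * pitch)))
    return side, side


def _collect_pixels(spec: SceneSpec, grains, germs, shape):
    """Footprint (incl. rims and germ boxes) of a unit before committing it."""
    ys_all, xs_all = [], []
    w = spec.rim_width
    for g in grains:
        ys, xs = _ellipse_pixels(g.cy, g.cx, g.a + w, g.b + w, g.theta, shape)
        ys_all.append(ys)
        xs_all.append(xs)
    for (g, ga, gb) in germs:
        sign = g.germ_dir or 1
        phi = g.theta if sign > 0 else g.theta + math.pi
        dist = g.a + ga - spec.germ_overlap * spec.scale
        cy = g.cy + math.sin(phi) * dist
        cx = g.cx + math.cos(phi) * dist
        ys, xs = _ellipse_pixels(cy, cx, ga, gb, phi, shape)
        ys_all.append(ys)
        xs_all.append(xs)
    return np.concatenate(ys_all), np.concatenate(xs_all)


def _in_bounds(ys, xs, shape, border=2):
    h, w = shape
    return (
        ys.size > 0
        and ys.min() >= border
        and xs.min() >= border
        and ys.max() < h - border
        and xs.max() < w - border
    )


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a scene and its exact ground truth.

    Deterministic for a fixed ``spec`` (including the seed).  Raises
    ``RuntimeError`` when a unit cannot be placed within
    ``spec.max_attempts`` rejection-sampling attempts (the spec asks
    for more grains than the canvas can hold).
    """
    if spec.antialias:
        return _generate_antialiased(spec)

    rng = np.random.default_rng(spec.seed)
    shape = spec.image_size or _auto_canvas(spec)
    ren = _Renderer(spec, shape, rng)

    sizes = _cluster_plan(spec, rng)
    n_germ = int(round(spec.germination_fraction * spec.n_grains))
    # assign germs to a random subset of grain slots, decided up front
    germ_slots = set(rng.choice(spec.n_grains, size=n_germ, replace=False).tolist())

    slot = 0
    h, w = shape
    for size in sizes:
        placed = False
        for _ in range(spec.max_attempts):
            grains = _build_cluster(spec, rng, size)
            for i, g in enumerate(grains):
                if (slot + i) in germ_slots:
                    g.germ_dir = 1 if rng.random() < 0.5 else -1
            germs = []
            for g in grains:
                if g.germ_dir is not None:
                    ga, gb = _germ_axes(spec, g, rng)
                    germs.append((g, ga, gb))
            # translate the unit to a random position
            oy = rng.uniform(0, h)
            ox = rng.uniform(0, w)
            for g in grains:
                g.cy += oy
                g.cx += ox
            ys, xs = _collect_pixels(spec, grains, germs, shape)
            if _in_bounds(ys, xs, shape) and ren.free(ys, xs):
                gids = ren.draw_grains(grains)
                germ_gids = [
                    gid for g2, gid in zip(grains, gids) if g2.germ_dir is not None
                ]
                for (g, ga, gb), gid in zip(germs, germ_gids):
                    ren.draw_germ(g, gid, ga, gb)
                ren.cluster_multiplicities.append(size)
                placed = True
                break
            for g in grains:  # undo the translation for the next attempt
                g.cy -= oy
                g.cx -= ox
        if not placed:
            raise RuntimeError(
                f"generate_scene: could not place a cluster of {size} grain(s) "
                f"after {spec.max_attempts} attempts; canvas too small for spec"
            )
        slot += size

    _place_noise(spec, rng, ren)
    return ren.img, ren.truth()


def _place_noise(spec: SceneSpec, rng: np.random.Generator, ren: _Renderer) -> None:
    s0 = math.pi * spec.core_axes[0] * spec.core_axes[1] * spec.scale**2
    h, w = ren.shape

    def try_place(draw_fn, footprint_fn):
        for _ in range(spec.max_attempts):
            cy = rng.uniform(0, h)
            cx = rng.uniform(0, w)
            ys, xs = footprint_fn(cy, cx)
            if _in_bounds(ys, xs, ren.shape) and ren.free(ys, xs):
                draw_fn(cy, cx)
                return
        raise RuntimeError("generate_scene: could not place a noise object")

    for _ in range(spec.n_reflections):
        area = spec.reflection_area_fraction * s0
        a = math.sqrt(area * 1.8 / math.pi)
        b = a / 1.8
        th = rng.uniform(0, math.pi)
        try_place(
            lambda cy, cx, a=a, b=b, th=th: ren.draw_blob(cy, cx, a, b, th, spec.germ_rgb),
            lambda cy, cx, a=a, b=b, th=th: _ellipse_pixels(cy, cx, a, b, th, ren.shape),
        )

    for _ in range(spec.n_droplets):
        r = max(math.sqrt(spec.droplet_area_fraction * s0 / math.pi), 1.1)
        try_place(
            lambda cy, cx, r=r: ren.draw_blob(cy, cx, r, r, 0.0, spec.germ_rgb),
            lambda cy, cx, r=r: _ellipse_pixels(cy, cx, r, r, 0.0, ren.shape),
        )

    # specks: identical tiny grain-coloured rectangles (constant area keeps
    # the noise run of the area curve flat)
    sh, sw = spec.speck_size
    for _ in range(spec.n_specks):
        def footprint(cy, cx, sh=sh, sw=sw):
            y0, x0 = int(cy), int(cx)
            yy, xx = np.mgrid[y0 : y0 + sh, x0 : x0 + sw]
            keep = (yy < h) & (xx < w)
            return yy[keep], xx[keep]

        def draw(cy, cx, sh=sh, sw=sw):
            ys, xs = footprint(cy, cx)
            ren._paint(ys, xs, spec.core_rgb)

        try_place(draw, footprint)


def _generate_antialiased(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """2x supersampled rendering, block-averaged down; truth by majority."""
    big = dataclasses.replace(
        spec,
        antialias=False,
        scale=spec.scale * 2.0,
        image_size=None if spec.image_size is None else (spec.image_size[0] * 2, spec.image_size[1] * 2),
        background_noise_sigma=spec.background_noise_sigma,
    )
    img2, truth2 = generate_scene(big)
    h2, w2 = img2.shape[:2]
    h2 -= h2 % 2
    w2 -= w2 % 2
    img = (
        img2[:h2, :w2]
        .reshape(h2 // 2, 2, w2 // 2, 2, 3)
        .astype(np.float64)
        .mean(axis=(1, 3))
        .round()
        .astype(np.uint8)
    )

    def down_labels(lab):
        lab = lab[:h2, :w2]
        blocks = lab.reshape(h2 // 2, 2, w2 // 2, 2)
        out = np.zeros((h2 // 2, w2 // 2), dtype=lab.dtype)
        counts = (blocks > 0).sum(axis=(1, 3))
        out_vals = blocks.max(axis=(1, 3))
        out[counts >= 2] = out_vals[counts >= 2]
        return out

    truth = GroundTruth(
        n_grains=truth2.n_grains,
        n_germinated=truth2.n_germinated,
        grain_label_image=down_labels(truth2.grain_label_image),
        germ_label_image=down_labels(truth2.germ_label_image),
        cluster_multiplicities=truth2.cluster_multiplicities,
        germinated_grain_ids=truth2.germinated_grain_ids,
    )
    return img, truth


# ---------------------------------------------------------------------------
# adversarial scenes


def generate_adversarial(kind: str, seed: int = 0) -> tuple[np.ndarray, GroundTruth]:
    """Render one of the documented failure-mode scenes.

    ``kind`` is one of ``droplet-on-edge`` (a bright droplet stuck to a
    grain edge passes every germ test -> false-positive germ),
    ``intertwined-germs`` (two germs merge into one connected region ->
    counted once), ``germ-under-grain`` (most of the germ hidden under
    the grain, visible sliver below the area band -> missed germ) and
    ``overlapping-grains`` (two heavily overlapping grains -> area
    division undercounts).  Scene geometry is deterministic (the seed
    only feeds the background noise) and the ground truth records the
    *actual* counts, so tests can assert the direction of the induced
    error without depending on placement luck.
    """
    if kind not in ADVERSARIAL_KINDS:
        raise ValueError(
            f"unknown adversarial scenario {kind!r}; expected one of {ADVERSARIAL_KINDS}"
        )
    spec = SceneSpec(seed=seed, n_grains=8, adhesion_fraction=0.0,
                     n_reflections=0, n_droplets=0)
    rng = np.random.default_rng(seed)
    shape = (420, 860)
    ren = _Renderer(spec, shape, rng)
    a, b = spec.core_axes
    s0 = math.pi * a * b

    # eight horizontal grains on a 2x4 grid; the first three germinate
    centres = [(110 + 200 * r, 130 + 200 * c) for r in range(2) for c in range(4)]
    if kind == "intertwined-germs":
        # bring grains 5 and 6 close enough that facing germs will merge
        centres[4] = (310, 130)
        centres[5] = (310, 200)
    if kind == "overlapping-grains":
        # grain 6 overlaps grain 5 by well over half its area
        centres[5] = (centres[4][0], centres[4][1] + 0.5 * a)

    grains = [
        _Grain(cy, cx, a, b, 0.0, spec.core_rgb[0], spec.rim_rgb[0])
        for cy, cx in centres
    ]
    if kind == "overlapping-grains":
        gids = ren.draw_grains(grains)  # one two-pass group so the overlap stays core
    else:
        gids = []
        for g in grains:
            gids.append(ren.draw_grain(g))
    ren.cluster_multiplicities = [1] * len(grains)

    def normal_germ(idx: int, sign: int) -> None:
        g = grains[idx]
        g.germ_dir = sign
        ga, gb = _germ_axes(spec, g, rng)
        ren.draw_germ(g, gids[idx], ga, gb)

    for idx in range(3):
        normal_germ(idx, +1)

    if kind == "droplet-on-edge":
        # believable-germ-sized droplet touching grain 5's right edge
        g = grains[4]
        r = math.sqrt(0.08 * s0 / math.pi)
        ys, xs = _ellipse_pixels(g.cy, g.cx + g.a + r - 2.0, r, r, 0.0, shape)
        keep = ren.grain_labels[ys, xs] == 0
        ren._paint(ys[keep], xs[keep], spec.germ_rgb)
        # truth: not a germ, germ_labels untouched
    elif kind == "intertwined-germs":
        normal_germ(4, +1)   # germ pointing right ...
        normal_germ(5, -1)   # ... meets the germ pointing left
    elif kind == "germ-under-grain":
        # grain 5 germinated, but only a sliver of germ is visible
        g = grains[4]
        sliver = max(int(s0 / 80.0), 4)
        x = int(g.cx + g.a) + 1
        ys_l, xs_l = [], []
        n = 0
        while n < sliver:
            for dy in (0, 1):
                yy = int(g.cy) + dy
                if ren.grain_labels[yy, x] == 0:
                    ys_l.append(yy)
                    xs_l.append(x)
                    n += 1
            x += 1
        ys, xs = np.array(ys_l), np.array(xs_l)
        ren._paint(ys, xs, spec.germ_rgb)
        ren.germ_labels[ys, xs] = gids[4]
        ren.germinated.append(gids[4])
    # overlapping-grains needs no extra drawing: the truth simply holds
    # one more grain than area division can recover

    return ren.img, ren.truth()


# ---------------------------------------------------------------------------
# file output (used by the CLI `synth` subcommand)


def write_scene(img: np.ndarray, truth: GroundTruth, out_dir: str | os.PathLike, stem: str = "scene") -> None:
    """Write ``<stem>.png`` and ``<stem>.truth.json`` into ``out_dir``."""
    from PIL import Image

    os.makedirs(out_dir, exist_ok=True)
    Image.fromarray(img, mode="RGB").save(os.path.join(out_dir, f"{stem}.png"))
    with open(os.path.join(out_dir, f"{stem}.truth.json"), "w") as fh:
        json.dump(truth.summary(), fh, indent=2)
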