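"""Coarse grain segmentation in clipped colour-difference space.

Yellow grain pixels have large ``R-B`` and ``G-B`` differences, while
both the near-black background and the white germs/reflections have
differences close to zero.  Each pixel is mapped to a feature pair
``(r_b, g_b)`` where the difference is clipped to 30 once it reaches 60
-- this compresses the illumination-dependent spread of the grain
cluster so that darker border pixels are not pulled toward the
background.  A two-centre k-means with fixed initial centres ``(0, 0)``
and ``(40, 40)`` then labels every pixel; the cluster whose final
centre lies farther from the origin is the grain foreground.  The fixed
initialisation makes the whole segmentation deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["compute_color_features", "kmeans_two_clusters", "coarse_segment"]

DEFAULT_CENTERS = ((0.0, 0.0), (40.0, 40.0))


def compute_color_features(
    img: np.ndarray, clip_delta: int = 60, clip_value: int = 30
) -> np.ndarray:
    """Per-pixel ``(r_b, g_b)`` features as an ``(H, W, 2)`` int16 array.

    ``r_b = clip_value`` wherever ``R - B >= clip_delta`` and ``R - B``
    (possibly negative) elsewhere; identically for ``g_b`` with
    ``G - B``.  No lower clip is applied: negative differences only push
    pixels toward the background centre.
    """
    img = np.asarray(img)
    r = img[..., 0].astype(np.int16)
    g = img[..., 1].astype(np.int16)
    b = img[..., 2].astype(np.int16)
    rb = r - b
    gb = g - b
    rb = np.where(rb >= clip_delta, np.int16(clip_value), rb)
    gb = np.where(gb >= clip_delta, np.int16(clip_value), gb)
    return np.stack([rb, gb], axis=-1)


def kmeans_two_clusters(
    features: np.ndarray,
    centers: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_CENTERS,
    max_iter: int = 100,
) -> np.ndarray:
    """Two-centre Lloyd clustering of the feature image; returns the grain mask.

    Squared-Euclidean distances; pixels equidistant from both centres go
    to the first (background) cluster.  Iteration stops when the
    assignments no longer change, or after ``max_iter`` rounds.  An
    empty cluster keeps its previous centre, so monochrome images simply
    collapse onto the nearer initial centre.  The foreground is the
    cluster whose *final* centre is farther from the origin.
    """
    features = np.asarray(features)
    shape = features.shape[:-1]
    pts = features.reshape(-1, 2)

    # Cluster the unique feature values (weighted) -- equivalent to
    # per-pixel Lloyd but independent of image size.  Integer features
    # (the usual case: colour differences in [-255, 255]) are packed
    # into one int32 code so the unique pass stays fast.
    if np.issubdtype(pts.dtype, np.integer):
        codes = (pts[:, 0].astype(np.int32) + 256) * 1024 + (pts[:, 1].astype(np.int32) + 256)
        ucodes, inverse, counts = np.unique(codes, return_inverse=True, return_counts=True)
        uniq = np.column_stack([ucodes // 1024 - 256, ucodes % 1024 - 256]).astype(np.float64)
    else:
        uniq, inverse, counts = np.unique(
            pts.astype(np.float64), axis=0, return_inverse=True, return_counts=True
        )
    w = counts.astype(np.float64)
    c = np.array(centers, dtype=np.float64)

    labels = _assign(uniq, c)
    for _ in range(max_iter):
        for k in (0, 1):
            sel = labels == k
            wk = w[sel].sum()
            if wk > 0:  # empty cluster keeps its stale centre
                c[k] = (uniq[sel] * w[sel, None]).sum(axis=0) / wk
        new_labels = _assign(uniq, c)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels

    foreground = int(np.argmax((c**2).sum(axis=1)))
    return (labels[inverse] == foreground).reshape(shape)


def _assign(pts: np.ndarray, centers: np.ndarray) -> np.ndarray:
    d0 = ((pts - centers[0]) ** 2).sum(axis=1)
    d1 = ((pts - centers[1]) ** 2).sum(axis=1)
    # ties go to the first (background) cluster
    return (d1 < d0).astype(np.int8)


def coarse_segment(
    img: np.ndarray,
    clip_delta: int = 60,
    clip_value: int = 30,
    centers: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_CENTERS,
    max_iter: int = 100,
) -> np.ndarray:
    """Coarse binary grain mask of an RGB image (feature map + k-means)."""
    feats = compute_color_features(img, clip_delta=clip_delta, clip_value=clip_value)
    return kmeans_two_clusters(feats, centers=centers, max_iter=max_iter)
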