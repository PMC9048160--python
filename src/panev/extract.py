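"""Maximum-contour post-processing and needle-trajectory fitting.

The network output may contain isolated outliers next to the needle response;
since only a single in-plane needle is assumed, the connected component with
the largest boundary-pixel count is kept and the needle trajectory is the
pixel pair of that mask at maximal Euclidean separation (the tip being the
deeper endpoint).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import LineSegment, ReconImage

EIGHT_CONN = np.ones((3, 3), dtype=bool)
FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def boundary_pixel_count(component: np.ndarray) -> int:
    """Pixels of the component with at least one 4-neighbour outside it."""
    interior = ndimage.binary_erosion(component, structure=FOUR_CONN,
                                      border_value=0)
    return int(np.count_nonzero(component & ~interior))


def select_max_contour(img: ReconImage | np.ndarray,
                       threshold: float = 0.1) -> np.ndarray:
    """Binarise at ``threshold * max`` and keep the largest-boundary component.

    8-connectivity; an all-zero image yields an empty mask (a valid outcome).
    Ties are broken toward the lowest component label.
    """
    pixels = img.pixels if isinstance(img, ReconImage) else np.asarray(img, float)
    if np.any(pixels < 0):
        raise ValueError("select_max_contour expects a non-negative image")
    peak = pixels.max()
    mask = np.zeros(pixels.shape, dtype=bool)
    if peak <= 0:
        return mask
    binary = pixels >= threshold * peak
    labels, n = ndimage.label(binary, structure=EIGHT_CONN)
    if n == 0:
        return mask
    best_label, best_count = 0, -1
    for lbl, sl in enumerate(ndimage.find_objects(labels), start=1):
        comp = labels[sl] == lbl
        count = boundary_pixel_count(comp)
        if count > best_count:
            best_label, best_count = lbl, count
    mask[labels == best_label] = True
    return mask


def _hull_points(points: np.ndarray) -> np.ndarray:
    """Convex hull vertices of an (n, 2) integer point set (fallback: all)."""
    from scipy.spatial import ConvexHull, QhullError

    if len(points) < 3:
        return points
    try:
        hull = ConvexHull(points)
    except QhullError:  # collinear input
        return points
    return points[hull.vertices]


def fit_needle_line(mask: np.ndarray) -> LineSegment | None:
    """Fit the trajectory as the maximally separated pixel pair of the mask.

    Returns ``None`` (no needle detected) for an empty or single-pixel mask.
    The search runs on convex-hull vertices, which contain the diametral pair.
    """
    points = np.argwhere(mask)
    if len(points) < 2:
        return None
    hull = _hull_points(points.astype(float))
    diff = hull[:, None, :] - hull[None, :, :]
    d2 = (diff ** 2).sum(axis=-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    if d2[i, j] == 0:
        return None
    a, b = hull[i], hull[j]
    tip, far = (a, b) if a[0] >= b[0] else (b, a)  # tip = deeper endpoint
    return LineSegment(p0=tuple(tip), p1=tuple(far))


def extract_needle(img: ReconImage | np.ndarray,
                   threshold: float = 0.1) -> LineSegment | None:
    """Max-contour selection followed by line fitting; None if no needle."""
    return fit_needle_line(select_max_contour(img, threshold))
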