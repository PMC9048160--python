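"""Image-quality and detection metrics: SNR, modified Hausdorff distance,
and sequence-level detection-rate accounting.

* ``mhd`` is the modified Hausdorff distance between two point sets: the
  maximum of the two directed mean nearest-neighbour distances.  Pixels can
  be converted to mm via the image pixel size (70 um/px by default).
* ``snr`` is S / sigma with S the mean amplitude sampled along the rasterised
  needle segment and sigma the standard deviation over a large rectangular
  background region that excludes the (dilated) needle.
* ``evaluate_sequence`` mirrors per-frame detection accounting on video
  sequences: true positives are needle-present frames whose detection lies
  within an MHD threshold of the label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.spatial import cKDTree
from skimage.draw import line as draw_line

from .core import LineSegment, ReconImage


class UndefinedSNR(ValueError):
    """The background region is degenerate (zero variance)."""


# --------------------------------------------------------------------------
# modified Hausdorff distance
# --------------------------------------------------------------------------

def directed_mean_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Mean over points of A of the distance to the nearest point of B."""
    tree = cKDTree(b)
    d, _ = tree.query(a, k=1)
    return float(np.mean(d))


def mhd(a, b) -> float:
    """Modified Hausdorff distance between two non-empty point sets (pixels)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("point sets must be non-empty")
    return max(directed_mean_distance(a, b), directed_mean_distance(b, a))


def segment_points(segment: LineSegment) -> np.ndarray:
    """Bresenham rasterisation of a segment into an (n, 2) pixel point set."""
    r0, c0 = (int(round(v)) for v in segment.p0)
    r1, c1 = (int(round(v)) for v in segment.p1)
    rr, cc = draw_line(r0, c0, r1, c1)
    return np.column_stack([rr, cc])


def mhd_segments(seg_a: LineSegment, seg_b: LineSegment,
                 pixel_size_um: float | None = None) -> float:
    """MHD between two rasterised segments, optionally converted to mm."""
    d = mhd(segment_points(seg_a), segment_points(seg_b))
    if pixel_size_um is not None:
        d = d * pixel_size_um * 1e-3
    return d


# --------------------------------------------------------------------------
# SNR
# --------------------------------------------------------------------------

def largest_background_rectangle(excluded: np.ndarray,
                                 min_size: int = 32) -> tuple:
    """Maximal-area axis-aligned rectangle avoiding the excluded mask.

    Histogram-stack dynamic programming over rows; only rectangles with both
    sides >= ``min_size`` qualify.  Returns (r0, c0, r1, c1) with exclusive
    upper bounds.  Raises ValueError when no admissible rectangle exists.
    """
    excluded = np.asarray(excluded, dtype=bool)
    h, w = excluded.shape
    heights = np.zeros(w, dtype=int)
    best = None  # (area, r0, c0, r1, c1)
    for r in range(h):
        heights = np.where(excluded[r], 0, heights + 1)
        stack = []  # (start_col, height)
        for c in range(w + 1):
            cur = heights[c] if c < w else 0
            start = c
            while stack and stack[-1][1] >= cur:
                sc, sh = stack.pop()
                width = c - sc
                if sh >= min_size and width >= min_size:
                    area = sh * width
                    if best is None or area > best[0]:
                        best = (area, r - sh + 1, sc, r + 1, c)
                start = sc
            stack.append((start, cur))
    if best is None:
        raise ValueError(
            f"no background rectangle of at least {min_size}x{min_size} exists")
    return best[1:]


def needle_mask(shape: tuple, segment: LineSegment, margin: int) -> np.ndarray:
    """Pixels within ``margin`` of the rasterised segment (sidelobe guard)."""
    mask = np.zeros(shape, dtype=bool)
    pts = segment_points(segment)
    keep = ((pts[:, 0] >= 0) & (pts[:, 0] < shape[0])
            & (pts[:, 1] >= 0) & (pts[:, 1] < shape[1]))
    pts = pts[keep]
    mask[pts[:, 0], pts[:, 1]] = True
    if margin > 0 and mask.any():
        mask = distance_transform_edt(~mask) <= margin
    return mask


def snr(img: ReconImage | np.ndarray, needle: LineSegment,
        margin: int = 20, min_rect: int = 32) -> float:
    """S / sigma: mean amplitude along the needle segment over the standard
    deviation of the largest needle-free background rectangle."""
    pixels = img.pixels if isinstance(img, ReconImage) else np.asarray(img, float)
    pts = segment_points(needle)
    if (pts[:, 0].min() < 0 or pts[:, 0].max() >= pixels.shape[0]
            or pts[:, 1].min() < 0 or pts[:, 1].max() >= pixels.shape[1]):
        raise ValueError("needle segment must lie inside the image")
    s = float(np.mean(pixels[pts[:, 0], pts[:, 1]]))
    excl = needle_mask(pixels.shape, needle, margin)
    r0, c0, r1, c1 = largest_background_rectangle(excl, min_size=min_rect)
    sigma = float(np.std(pixels[r0:r1, c0:c1]))
    if sigma == 0:
        raise UndefinedSNR("background region has zero variance")
    return s / sigma


# --------------------------------------------------------------------------
# sequence-level detection accounting
# --------------------------------------------------------------------------

@dataclass
class MetricsReport:
    frames_with_needle: int = 0
    frames_without_needle: int = 0
    true_positives: int = 0
    false_positives: int = 0
    missed: int = 0
    tp_rate_pct: float = 0.0
    fp_rate_pct: float = 0.0
    per_frame_mhd: list = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "frames_with_needle": self.frames_with_needle,
            "frames_without_needle": self.frames_without_needle,
            "true_positives": self.true_positives,
            "false_positives": self.false_positives,
            "missed": self.missed,
            "true_positive_rate_pct": self.tp_rate_pct,
            "false_positive_rate_pct": self.fp_rate_pct,
        }


def evaluate_sequence(frames, labels, detector, mhd_threshold: float = 10.0,
                      fp_denominator: str = "without") -> MetricsReport:
    """Per-frame detection accounting against observer labels.

    ``labels`` is a sequence of (present: bool, segment | None); ``detector``
    maps a frame to a segment or ``None``.  A true positive is a labelled
    frame whose detection has MHD <= ``mhd_threshold`` (pixels) to the label;
    any detection on a needle-free frame is a false positive.  The
    false-positive denominator is the needle-free frame count by default
    (``fp_denominator="all"`` uses every frame).
    """
    if len(frames) != len(labels):
        raise ValueError("labels and frames must have equal length")
    if fp_denominator not in ("without", "all"):
        raise ValueError("fp_denominator must be 'without' or 'all'")
    rep = MetricsReport()
    for frame, (present, ref) in zip(frames, labels):
        detection = detector(frame)
        if present:
            rep.frames_with_needle += 1
            if detection is not None:
                d = mhd_segments(detection, ref)
                rep.per_frame_mhd.append(d)
                if d <= mhd_threshold:
                    rep.true_positives += 1
                else:
                    rep.missed += 1
            else:
                rep.missed += 1
        else:
            rep.frames_without_needle += 1
            if detection is not None:
                rep.false_positives += 1
    if rep.frames_with_needle:
        rep.tp_rate_pct = 100.0 * rep.true_positives / rep.frames_with_needle
    denom = (rep.frames_without_needle if fp_denominator == "without"
             else len(frames))
    if denom:
        rep.fp_rate_pct = 100.0 * rep.false_positives / denom
    return rep


def paired_summary(conventional: dict, enhanced: dict) -> dict:
    """Median SNR/MHD of two evaluation arms plus improvement factors."""
    out = {"conventional": conventional, "enhanced": enhanced}
    if conventional.get("median_snr") and enhanced.get("median_snr"):
        out["snr_improvement"] = enhanced["median_snr"] / conventional["median_snr"]
    if conventional.get("median_mhd") and enhanced.get("median_mhd"):
        out["mhd_reduction"] = conventional["median_mhd"] / enhanced["median_mhd"]
    return out
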