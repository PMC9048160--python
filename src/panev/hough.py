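"""Standard Hough transform (SHT) line detector, the comparison baseline.

The line parameterisation is ``r = x sin(theta) + y cos(theta)`` with
``x`` = column index and ``y`` = row index, theta in [0, 180) degrees —
kept in this (transposed-looking) form deliberately so the accumulator maths
matches the convention the rest of the package documents.  Every foreground
pixel votes once per theta bin, so the accumulator total equals
``n_foreground * n_theta_bins``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ConfigError, LineSegment


@dataclass
class HoughAccumulator:
    matrix: np.ndarray          # votes, indexed [r_bin, theta_bin]
    r_values: np.ndarray        # bin-centre r (pixels), signed
    theta_values: np.ndarray    # bin-centre theta (degrees)


@dataclass(frozen=True)
class HoughLine:
    r: float
    theta: float
    votes: int


def hough_accumulate(binary: np.ndarray, r_res: float = 1.0,
                     theta_res: float = 1.0) -> HoughAccumulator:
    """Vote every foreground pixel of a binarised image into (r, theta) bins."""
    binary = np.asarray(binary, dtype=bool)
    if binary.ndim != 2:
        raise ConfigError("binary image must be 2D")
    if r_res <= 0 or theta_res <= 0:
        raise ConfigError("resolutions must be positive")
    h, w = binary.shape
    diag = int(np.ceil(np.hypot(h, w)))
    r_values = np.arange(-diag, diag + r_res / 2, r_res)
    theta_values = np.arange(0.0, 180.0, theta_res)
    acc = np.zeros((len(r_values), len(theta_values)), dtype=np.int64)

    ys, xs = np.nonzero(binary)
    if ys.size:
        t = np.radians(theta_values)
        r = xs[:, None] * np.sin(t)[None, :] + ys[:, None] * np.cos(t)[None, :]
        r_idx = np.round((r + diag) / r_res).astype(np.int64)
        np.clip(r_idx, 0, len(r_values) - 1, out=r_idx)
        t_idx = np.broadcast_to(np.arange(len(theta_values)), r_idx.shape)
        np.add.at(acc, (r_idx.ravel(), t_idx.ravel()), 1)
    return HoughAccumulator(matrix=acc, r_values=r_values,
                            theta_values=theta_values)


def detect_lines(acc: HoughAccumulator, n_peaks: int = 1,
                 min_separation: int = 5) -> list:
    """Greedy local-maxima extraction in descending vote order.

    Accepted peaks suppress bins within a Chebyshev distance of
    ``min_separation`` bins; fewer peaks than requested is a valid result.
    ``min_separation=0`` recovers the raw top-n bins.
    """
    if n_peaks < 1:
        raise ConfigError("n_peaks must be >= 1")
    votes = acc.matrix.astype(np.float64).copy()
    lines = []
    for _ in range(n_peaks):
        best = int(votes.argmax())
        ri, ti = np.unravel_index(best, votes.shape)
        if votes[ri, ti] <= 0:
            break
        lines.append(HoughLine(r=float(acc.r_values[ri]),
                               theta=float(acc.theta_values[ti]),
                               votes=int(acc.matrix[ri, ti])))
        r0 = max(ri - min_separation, 0)
        r1 = ri + min_separation + 1
        t0 = max(ti - min_separation, 0)
        t1 = ti + min_separation + 1
        votes[r0:r1, t0:t1] = -1
        if min_separation == 0:
            votes[ri, ti] = -1
    return lines


def line_support_segment(binary: np.ndarray, line: HoughLine,
                         tol: float = 2.0) -> LineSegment | None:
    """Extreme supporting pixels of a detected line, as a segment.

    Foreground pixels within ``tol`` pixels of the line are projected onto
    the line direction and the two extremes become the endpoints; ``None``
    when fewer than two pixels support the line.
    """
    ys, xs = np.nonzero(np.asarray(binary, dtype=bool))
    if ys.size == 0:
        return None
    t = np.radians(line.theta)
    dist = np.abs(xs * np.sin(t) + ys * np.cos(t) - line.r)
    keep = dist <= tol
    if keep.sum() < 2:
        return None
    ys, xs = ys[keep], xs[keep]
    # direction along the line: (-cos t, sin t) in (x, y)
    proj = -xs * np.cos(t) + ys * np.sin(t)
    i0, i1 = int(np.argmin(proj)), int(np.argmax(proj))
    a = (float(ys[i0]), float(xs[i0]))
    b = (float(ys[i1]), float(xs[i1]))
    if a == b:
        return None
    tip, far = (a, b) if a[0] >= b[0] else (b, a)
    return LineSegment(p0=tip, p1=far)


def detect_needle_sht(image: np.ndarray, threshold: float = 0.2,
                      r_res: float = 1.0, theta_res: float = 1.0,
                      tol: float = 2.0) -> LineSegment | None:
    """Threshold, accumulate, take the strongest line, return its segment.

    The pre-binarisation threshold (default 0.2 x max) and bin resolutions
    are the detector's sensitive hyperparameters; all are surfaced here.
    """
    image = np.asarray(image, dtype=float)
    peak = image.max()
    if peak <= 0:
        return None
    binary = image >= threshold * peak
    acc = hough_accumulate(binary, r_res=r_res, theta_res=theta_res)
    lines = detect_lines(acc, n_peaks=1)
    if not lines:
        return None
    return line_support_segment(binary, lines[0], tol=tol)
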