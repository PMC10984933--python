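"""Exact two-change-point piecewise-linear least squares.

The sorted log10 particle-size curve of a mixed population (debris,
single cells, aggregates) shows three regimes: a concave rise, a flat
plateau, and a convex tail. We locate the two regime boundaries by
minimizing the summed ordinary-least-squares residuals of three
independent line fits over *all* admissible boundary pairs, so the
result is the exact optimum rather than a heuristic approximation.
The regressor is the rank index of the sorted series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SegmentFit", "ChangePointFit", "fit_change_points"]


@dataclass(frozen=True)
class SegmentFit:
    """OLS line fit of one segment [start, stop) of the rank-indexed curve."""

    start: int
    stop: int
    slope: float
    intercept: float
    rss: float


@dataclass(frozen=True)
class ChangePointFit:
    """Optimal segmentation into [0, i1), [i1, i2), [i2, n).

    ``total_rss`` is the minimum over all admissible (i1, i2) of the sum
    of the three per-segment OLS residual sums of squares; ties are
    broken toward the smallest i1, then the smallest i2.
    """

    i1: int
    i2: int
    segments: tuple[SegmentFit, SegmentFit, SegmentFit]
    total_rss: float
    n: int


def _prefix_sums(y: np.ndarray):
    x = np.arange(len(y), dtype=float)

    def pre(a):
        return np.concatenate(([0.0], np.cumsum(a)))

    return pre(x), pre(y), pre(x * x), pre(y * y), pre(x * y)


def _segment_rss(a, b, sums):
    """Vectorized OLS RSS of segments [a, b); a, b broadcastable int arrays."""
    Sx, Sy, Sxx, Syy, Sxy = sums
    m = (b - a).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        sx = Sx[b] - Sx[a]
        sy = Sy[b] - Sy[a]
        varx = (Sxx[b] - Sxx[a]) - sx * sx / m
        vary = (Syy[b] - Syy[a]) - sy * sy / m
        cov = (Sxy[b] - Sxy[a]) - sx * sy / m
        rss = vary - np.where(varx > 0, cov * cov / np.where(varx > 0, varx, 1.0), 0.0)
    # guard tiny negative round-off
    return np.maximum(rss, 0.0)


def _segment_fit(y: np.ndarray, a: int, b: int) -> SegmentFit:
    x = np.arange(a, b, dtype=float)
    seg = y[a:b]
    if b - a == 1:
        return SegmentFit(a, b, 0.0, float(seg[0]), 0.0)
    xm, ym = x.mean(), seg.mean()
    varx = float(((x - xm) ** 2).sum())
    slope = float(((x - xm) * (seg - ym)).sum() / varx) if varx > 0 else 0.0
    intercept = float(ym - slope * xm)
    resid = seg - (slope * x + intercept)
    return SegmentFit(a, b, slope, intercept, float((resid**2).sum()))


def fit_change_points(series, min_seg: int = 5) -> ChangePointFit:
    """Fit three line segments with two change points to a sorted series.

    Parameters
    ----------
    series
        A :class:`~ecmquant.aggregates.SizeSeries` or any object with a
        ``values`` attribute holding the sorted log10 areas (a bare
        array is accepted too).
    min_seg
        Minimum number of points per segment; keeps every OLS fit
        well-posed. Default 5.

    Returns
    -------
    ChangePointFit
        Exact least-squares optimum over all admissible (i1, i2).
    """
    y = np.asarray(getattr(series, "values", series), dtype=float)
    n = y.size
    if min_seg < 2:
        raise ValueError("min_seg must be >= 2 for a well-posed line fit")
    if n < 3 * min_seg:
        raise ValueError(
            f"series too short for change-point fitting: need at least "
            f"{3 * min_seg} points (3*min_seg), got {n}"
        )
    sums = _prefix_sums(y)

    i1 = np.arange(min_seg, n - 2 * min_seg + 1)
    i2 = np.arange(2 * min_seg, n - min_seg + 1)
    A = i1[:, None]
    B = i2[None, :]

    rss1 = _segment_rss(np.zeros_like(i1), i1, sums)[:, None]
    rss3 = _segment_rss(i2, np.full_like(i2, n), sums)[None, :]
    rss2 = _segment_rss(A, B, sums)
    total = rss1 + rss2 + rss3
    total = np.where(B - A >= min_seg, total, np.inf)

    # C-order argmin: first occurrence => smallest i1, then smallest i2
    flat = int(np.argmin(total))
    bi1 = int(i1[flat // len(i2)])
    bi2 = int(i2[flat % len(i2)])

    segs = (
        _segment_fit(y, 0, bi1),
        _segment_fit(y, bi1, bi2),
        _segment_fit(y, bi2, n),
    )
    return ChangePointFit(
        i1=bi1, i2=bi2, segments=segs, total_rss=float(sum(s.rss for s in segs)), n=n
    )
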