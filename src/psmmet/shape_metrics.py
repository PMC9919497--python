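"""Per-cell aspect ratio and its pseudo-colour encoding.

The aspect ratio (AR) — the longest over the shortest dimension of a cell
outline — is the elongation proxy for epithelialization used throughout
the pipeline.  The default estimator is the fitted-ellipse (second-moment)
axis ratio: the eigenvalue ratio of the polygon's area covariance matrix,
computed analytically from the vertices via Green's theorem.  This matches
the standard FIJI "AR" shape descriptor and is exactly invariant under
rigid motion and uniform scaling.  A Feret (caliper) ratio is available as
an alternative because the two estimators disagree on concave cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon
from shapely import minimum_rotated_rectangle

from .outline_io import CellOutline, OutlineError

_DEGENERATE_RTOL = 1e-12


@dataclass(frozen=True)
class AspectRatioRecord:
    """Fitted-ellipse axes and their ratio for one cell."""

    cell_id: str
    aspect_ratio: float
    major_axis_px: float
    minor_axis_px: float
    centroid: tuple[float, float]


def polygon_moments(vertices: np.ndarray):
    """Area, centroid and central second moments of a simple polygon.

    Green's-theorem closed forms over the vertex list; the result is exact
    for polygons (no rasterization).  Works for either vertex orientation.

    Returns
    -------
    area : float (positive)
    centroid : (2,) ndarray
    cov : (2, 2) ndarray
        Area covariance matrix, i.e. normalized central second moments
        ``[[<xx>, <xy>], [<xy>, <yy>]]``.
    """
    v = np.asarray(vertices, dtype=float)
    # work in vertex-mean-centred coordinates: keeps every product at the
    # polygon's own scale regardless of where it sits in the image
    ref = v.mean(axis=0)
    x, y = v[:, 0] - ref[0], v[:, 1] - ref[1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = 0.5 * cross.sum()  # signed
    if a == 0:
        raise ValueError("degenerate polygon: zero area")
    cx = ((x + x1) * cross).sum() / (6.0 * a)
    cy = ((y + y1) * cross).sum() / (6.0 * a)
    # second moments in centroid-centred coordinates: no parallel-axis
    # subtraction, so no cancellation for polygons far from the origin
    x, y = x - cx, y - cy
    x1, y1 = x1 - cx, y1 - cy
    cross = x * y1 - x1 * y
    sxx = ((x * x + x * x1 + x1 * x1) * cross).sum() / 12.0
    syy = ((y * y + y * y1 + y1 * y1) * cross).sum() / 12.0
    sxy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() / 24.0
    cov = np.array([[sxx, sxy], [sxy, syy]]) / a
    return abs(a), ref + [cx, cy], cov


def aspect_ratio(
    outline: CellOutline, method: str = "ellipse"
) -> AspectRatioRecord:
    """Aspect ratio of a cell outline.

    ``method="ellipse"`` (default) uses the axes of the ellipse with the
    same normalized second moments as the polygon: axis lengths are
    ``4 * sqrt(eigenvalue)`` of the area covariance.  ``method="feret"``
    uses the maximum caliper diameter over the minimum rotated-rectangle
    width.

    Raises
    ------
    OutlineError
        For degenerate (zero-area or collinear) polygons, naming the cell.
    """
    try:
        area, centroid, cov = polygon_moments(outline.vertices)
    except ValueError as exc:
        raise OutlineError(f"{outline.cell_id}: {exc}") from exc
    if method == "ellipse":
        eigvals = np.linalg.eigvalsh(cov)  # ascending
        lo, hi = float(eigvals[0]), float(eigvals[1])
        if lo <= _DEGENERATE_RTOL * max(hi, 1.0):
            raise OutlineError(f"{outline.cell_id}: degenerate (collinear) polygon")
        major, minor = 4.0 * np.sqrt(hi), 4.0 * np.sqrt(lo)
    elif method == "feret":
        poly = Polygon(outline.vertices)
        hull = np.asarray(poly.convex_hull.exterior.coords)
        diffs = hull[:, None, :] - hull[None, :, :]
        major = float(np.sqrt((diffs**2).sum(-1)).max())
        rect = np.asarray(minimum_rotated_rectangle(poly).exterior.coords)
        sides = np.sqrt(((rect[1:] - rect[:-1]) ** 2).sum(-1))
        minor = float(sides.min())
        if minor <= 0:
            raise OutlineError(f"{outline.cell_id}: degenerate (collinear) polygon")
    else:
        raise ValueError(f"unknown AR method {method!r}")
    return AspectRatioRecord(
        cell_id=outline.cell_id,
        aspect_ratio=major / minor,
        major_axis_px=major,
        minor_axis_px=minor,
        centroid=(float(centroid[0]), float(centroid[1])),
    )


def ar_colormap(ar: float, breaks) -> int:
    """Pseudo-colour bin index for an aspect ratio.

    Bins are half-open ``[b_i, b_{i+1})``; values at or above the last
    break saturate into the top bin.

    >>> ar_colormap(3.5, [1, 2, 3, 4, 5, 6, 7])
    2
    """
    breaks = np.asarray(breaks, dtype=float)
    if breaks.ndim != 1 or len(breaks) < 2 or np.any(np.diff(breaks) <= 0):
        raise ValueError("breaks must be a strictly increasing 1-D sequence")
    if breaks[0] < 1.0:
        raise ValueError("first break must be >= 1")
    if ar < 1.0:
        raise ValueError(f"aspect ratio {ar} < 1 is impossible")
    idx = int(np.searchsorted(breaks, ar, side="right")) - 1
    return min(max(idx, 0), len(breaks) - 2)


def measure_cells(outlines, method: str = "ellipse"):
    """Aspect ratios for many outlines as a :class:`pandas.DataFrame`.

    Degenerate cells are skipped with a log entry rather than aborting the
    batch.
    """
    import logging

    import pandas as pd

    rows = []
    log = logging.getLogger(__name__)
    for o in outlines:
        try:
            rec = aspect_ratio(o, method=method)
        except OutlineError as exc:
            log.warning("skipping cell: %s", exc)
            continue
        rows.append(
            {
                "cell_id": rec.cell_id,
                "embryo_id": o.embryo_id,
                "plane": o.plane,
                "structure": o.structure,
                "domain": o.domain,
                "somite_index": o.somite_index,
                "aspect_ratio": rec.aspect_ratio,
                "major_axis_px": rec.major_axis_px,
                "minor_axis_px": rec.minor_axis_px,
                "centroid_x": rec.centroid[0],
                "centroid_y": rec.centroid[1],
            }
        )
    return pd.DataFrame(rows)
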