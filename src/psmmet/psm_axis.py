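"""Axis straightening, 0-100% position normalization and domain assignment.

The rostro-caudal position of a cell is expressed as a percentage of the
PSM length of the same embryo: the posterior tip of the PSM is 0% and the
PSM-somite border is 100%.  Positions above 100% denote somites (reported
as 100% + 10% per somite index, a plotting convention only).

Straightening is orthogonal projection of each cell centroid onto a
midline polyline, followed by linear rescaling of cumulative arc length to
0-100% per embryo.  Domain assignment classifies each cell as a surface
cell (its outline intersects a one-cell-deep band inset from the tissue
boundary) or core, and partitions the surface by side (sagittal) or by
four 90-degree sectors about the section centroid (transverse).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import Polygon

from .outline_io import CellOutline

logger = logging.getLogger(__name__)

# fixed tie-break priority at sector corners (deterministic)
SECTOR_PRIORITY = ("dorsal", "medial", "ventral", "lateral")


@dataclass
class AxisModel:
    """A PSM midline from the posterior tip (0%) to the border (100%)."""

    midline: np.ndarray  # (n, 2) polyline, posterior first

    def __post_init__(self) -> None:
        self.midline = np.asarray(self.midline, dtype=float)
        if self.midline.ndim != 2 or len(self.midline) < 2:
            raise ValueError("midline must be a polyline of >= 2 points")
        seg = np.diff(self.midline, axis=0)
        self._seg_len = np.sqrt((seg**2).sum(axis=1))
        if np.any(self._seg_len <= 0):
            raise ValueError("midline has zero-length segments")
        self.arc_length_table = np.concatenate([[0.0], np.cumsum(self._seg_len)])
        self.total_psm_length_px = float(self.arc_length_table[-1])

    def project(self, point) -> tuple[float, float]:
        """Arc length and signed offset of the orthogonal projection.

        In image coordinates (y down) with the midline running posterior
        to anterior, a positive offset is the upper — by convention
        dorsal — side.  Projections equidistant to two non-adjacent
        segments take the smaller arc length.
        """
        p = np.asarray(point, dtype=float)
        a = self.midline[:-1]
        d = np.diff(self.midline, axis=0)
        t = np.clip(((p - a) * d).sum(axis=1) / (self._seg_len**2), 0.0, 1.0)
        proj = a + t[:, None] * d
        dist2 = ((p - proj) ** 2).sum(axis=1)
        best = int(np.argmin(dist2))  # argmin takes the first = smaller arc
        arc = self.arc_length_table[best] + t[best] * self._seg_len[best]
        # beyond the rostral end: extrapolate along the last segment
        if best == len(d) - 1 and t[best] == 1.0:
            u = d[best] / self._seg_len[best]
            arc += max(0.0, float((p - self.midline[-1]) @ u))
        u = d[best] / self._seg_len[best]
        off = p - proj[best]
        signed = float(u[1] * off[0] - u[0] * off[1])
        return float(arc), signed


@dataclass
class DomainGeometry:
    """Section geometry needed to assign cells to tissue domains.

    ``surface_band_depth_px`` operationalizes "a single layer of cells":
    a cell is a surface cell iff its outline comes within this depth of
    the outer boundary.  ``sector_rotation_deg`` rotates the four sector
    boundaries of a transverse section; ``medial_side`` says which image
    side faces the neural tube.
    """

    outer_boundary: np.ndarray  # (n, 2) closed polygon
    surface_band_depth_px: float
    sector_rotation_deg: float = 0.0
    medial_side: str = "left"
    dorsal_up: bool = True
    rostral_direction: tuple[float, float] = (1.0, 0.0)  # sagittal somites

    def __post_init__(self) -> None:
        self.outer_boundary = np.asarray(self.outer_boundary, dtype=float)
        if self.surface_band_depth_px <= 0:
            raise ValueError("surface band depth must be > 0")
        self._poly = Polygon(self.outer_boundary)
        if not self._poly.is_valid:
            raise ValueError("outer boundary is not a simple polygon")


def straighten(
    cells: Sequence[CellOutline], axis: AxisModel
) -> "pd.DataFrame":
    """Normalized axis position and transverse offset per cell.

    Returns a DataFrame with columns ``cell_id``, ``position_percent``
    (0 at the posterior tip, 100 at the PSM-somite border; somite cells
    are reported at 100 + 10 per somite index) and ``transverse_offset_px``
    (signed perpendicular distance, positive dorsal).
    """
    import pandas as pd

    from .shape_metrics import polygon_moments

    rows = []
    for cell in cells:
        _, centroid, _ = polygon_moments(cell.vertices)
        arc, offset = axis.project(centroid)
        if cell.structure == "somite":
            position = 100.0 + 10.0 * int(cell.somite_index)
        else:
            position = 100.0 * arc / axis.total_psm_length_px
        rows.append(
            {
                "cell_id": cell.cell_id,
                "position_percent": position,
                "transverse_offset_px": offset,
            }
        )
    return pd.DataFrame(rows)


def _band_distance(poly: Polygon, geom: DomainGeometry) -> float:
    return poly.distance(geom._poly.exterior)


def _sector_of(angle_deg: float, geom: DomainGeometry) -> str:
    """Transverse sector label for a centroid direction angle (degrees,
    measured from +x, y downward).  Sectors are closed 90-degree wedges;
    corners resolve in the fixed order dorsal > medial > ventral > lateral.
    """
    up = -90.0 if geom.dorsal_up else 90.0
    centers = {
        "dorsal": up,
        "ventral": -up,
        "medial": 180.0 if geom.medial_side == "left" else 0.0,
    }
    centers["lateral"] = centers["medial"] - 180.0
    rot = geom.sector_rotation_deg
    for name in SECTOR_PRIORITY:
        delta = (angle_deg - centers[name] - rot + 180.0) % 360.0 - 180.0
        if abs(delta) <= 45.0:
            return name
    raise AssertionError("sector wedges cover the circle")  # pragma: no cover


def _sagittal_label(cell_poly: Polygon, geom: DomainGeometry, somite: bool) -> str:
    """Surface label for a sagittal section.

    PSM strips split dorsal/ventral by the image side of the nearest
    boundary point; somite sections use four 45-degree-rotated quadrants
    (dorsal/ventral/anterior/posterior) about the section centroid.
    """
    c = geom._poly.centroid
    p = cell_poly.centroid
    dx, dy = p.x - c.x, p.y - c.y
    if somite:
        rx, ry = geom.rostral_direction
        along = dx * rx + dy * ry
        up = (-dy if geom.dorsal_up else dy) * np.hypot(rx, ry)
        # quadrants rotated 45 degrees: dorsal/ventral win on |up| > |along|
        if abs(up) >= abs(along):
            return "dorsal" if up >= 0 else "ventral"
        return "anterior" if along > 0 else "posterior"
    up = -dy if geom.dorsal_up else dy
    return "dorsal" if up >= 0 else "ventral"


def assign_domains(
    cells: Sequence[CellOutline],
    geom: DomainGeometry,
    plane: str,
) -> list[CellOutline]:
    """Fill in the ``domain`` of every cell (cells are modified in place).

    A cell is a surface cell iff its outline intersects the band of depth
    ``geom.surface_band_depth_px`` inset from the outer boundary; all
    other cells are core.  Sagittal sections split the surface into
    dorsal/ventral (PSM) or dorsal/ventral/anterior/posterior (somites);
    transverse sections into dorsal/medial/ventral/lateral sectors.

    Raises
    ------
    ValueError
        If a cell centroid lies outside the outer boundary.
    """
    cx, cy = geom._poly.centroid.x, geom._poly.centroid.y
    for cell in cells:
        poly = Polygon(cell.vertices)
        centroid = poly.centroid
        if not geom._poly.covers(centroid):
            raise ValueError(
                f"{cell.cell_id}: centroid outside the outer boundary"
            )
        if _band_distance(poly, geom) > geom.surface_band_depth_px:
            cell.domain = "core"
            continue
        if plane == "transverse":
            angle = np.degrees(np.arctan2(centroid.y - cy, centroid.x - cx))
            cell.domain = _sector_of(angle, geom)
        elif plane == "sagittal":
            cell.domain = _sagittal_label(poly, geom, cell.structure == "somite")
        else:
            raise ValueError(f"unknown plane {plane!r}")
    return list(cells)


def default_band_depth(cells: Sequence[CellOutline]) -> float:
    """Median cell minor-axis length: the default surface-band depth."""
    from .shape_metrics import aspect_ratio

    minors = [aspect_ratio(c).minor_axis_px for c in cells]
    return float(np.median(minors))
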