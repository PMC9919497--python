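"""Readers and writers for every external format the pipeline touches.

Three input families are supported:

* manually traced **cell outlines** (closed 2-D polygons in pixel
  coordinates), either as an ImageJ ROI zip or as a plain CSV vertex table;
* **polarity-marker intensity slices** (single-channel TIFF stacks with a
  sidecar table giving per-slice axis positions);
* **time-lapse distance tables** recording segmented-mesoderm length,
  labelled-front-to-border distance, PSM length and cumulative somite count
  per time point.

Pixel coordinates are 0-based with y increasing downward (image
convention).  Physical calibration (``microns_per_pixel``) lives in the run
configuration, not in the outline files.
"""

from __future__ import annotations

import logging
import struct
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

logger = logging.getLogger(__name__)

PLANES = ("sagittal", "transverse")
STRUCTURES = ("psm", "somite")
DOMAINS = (
    "dorsal",
    "ventral",
    "medial",
    "lateral",
    "anterior",
    "posterior",
    "core",
    "unassigned",
)
MARKERS = ("GM130", "PAR3", "PKCzeta", "ZO1", "Ncad", "synthetic")

TIMELAPSE_COLUMNS = (
    "t_minutes",
    "segmented_length_um",
    "dii_front_to_border_um",
    "psm_length_um",
    "somite_count",
)


class OutlineError(ValueError):
    """A cell outline violates its geometric invariants."""


@dataclass
class CellOutline:
    """One manually outlined cell: a simple closed polygon plus context.

    ``domain`` may be ``"unassigned"`` on input — domain assignment is a
    pipeline stage (:mod:`psmmet.psm_axis`), not an input requirement.
    ``somite_index`` (s0..s5) must be present iff ``structure == "somite"``.
    """

    cell_id: str
    embryo_id: str
    plane: str
    vertices: np.ndarray  # (n, 2) float, open ring (closure implied)
    domain: str = "unassigned"
    structure: str = "psm"
    somite_index: int | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)

    def validate(self) -> None:
        """Raise :class:`OutlineError` if any invariant is violated."""
        if self.plane not in PLANES:
            raise OutlineError(f"{self.cell_id}: unknown plane {self.plane!r}")
        if self.structure not in STRUCTURES:
            raise OutlineError(
                f"{self.cell_id}: unknown structure {self.structure!r}"
            )
        if self.domain not in DOMAINS:
            raise OutlineError(f"{self.cell_id}: unknown domain {self.domain!r}")
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise OutlineError(f"{self.cell_id}: vertices must be (n, 2)")
        if len(self.vertices) < 3:
            raise OutlineError(
                f"{self.cell_id}: polygon needs >= 3 vertices, "
                f"got {len(self.vertices)}"
            )
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            raise OutlineError(f"{self.cell_id}: polygon is self-intersecting")
        if poly.area <= 0:
            raise OutlineError(f"{self.cell_id}: polygon area is zero")
        if (self.structure == "somite") != (self.somite_index is not None):
            raise OutlineError(
                f"{self.cell_id}: somite_index must be present iff "
                f"structure == 'somite'"
            )

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass
class IntensitySlice:
    """One transverse optical re-slice of a polarity-marker stack.

    ``apical_reference`` marks the tissue-centre side: the apical pole of
    an epithelializing surface cell points inward, toward this point.
    Axis positions above 100% denote somites.
    """

    embryo_id: str
    marker: str
    axis_position_percent: float
    pixels: np.ndarray  # (h, w) nonnegative intensities
    psm_mask: np.ndarray  # (h, w) bool
    apical_reference: tuple[float, float]
    pixel_size_um: float = 1.0

    def validate(self) -> None:
        if self.marker not in MARKERS:
            raise ValueError(f"unknown marker {self.marker!r}")
        if not 0.0 <= self.axis_position_percent <= 130.0:
            raise ValueError("axis position must be in [0, 130]%")
        if self.pixels.shape != self.psm_mask.shape:
            raise ValueError("mask must match the pixel grid")
        if not self.psm_mask.any():
            raise ValueError("psm_mask is empty")
        if (self.pixels < 0).any():
            raise ValueError("intensities must be nonnegative")


@dataclass(frozen=True)
class TimepointRecord:
    """One time-lapse measurement: three distances plus the somite tally."""

    t_minutes: float
    segmented_length_um: float
    dii_front_to_border_um: float
    psm_length_um: float
    somite_count: int

    def validate(self) -> None:
        if self.t_minutes < 0:
            raise ValueError("t_minutes must be >= 0")
        if self.segmented_length_um < 0 or self.dii_front_to_border_um < 0:
            raise ValueError("distances must be >= 0")
        if self.psm_length_um <= 0:
            raise ValueError("psm_length_um must be > 0")
        if self.somite_count < 0:
            raise ValueError("somite_count must be >= 0")


@dataclass
class RejectedRecord:
    """Audit entry for an input record that failed validation."""

    cell_id: str
    reason: str


# ---------------------------------------------------------------------------
# CSV outline dialect
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["cell_id", "embryo_id", "plane", "structure", "domain", "x", "y"]


def _outline_from_rows(rows: pd.DataFrame) -> CellOutline:
    first = rows.iloc[0]
    somite_index = None
    if "somite_index" in rows.columns and pd.notna(first["somite_index"]):
        somite_index = int(first["somite_index"])
    return CellOutline(
        cell_id=str(first["cell_id"]),
        embryo_id=str(first["embryo_id"]),
        plane=str(first["plane"]),
        vertices=rows[["x", "y"]].to_numpy(dtype=float),
        domain=str(first["domain"]),
        structure=str(first["structure"]),
        somite_index=somite_index,
    )


def read_outlines(
    path: str | Path,
    dialect: str = "csv",
    *,
    return_report: bool = False,
    **roi_defaults,
):
    """Read cell outlines from ``path``.

    Parameters
    ----------
    dialect
        ``"csv"`` — one row per vertex with columns
        ``(cell_id, embryo_id, plane, structure, domain, x, y)`` and an
        optional ``somite_index`` column; ``"roi_zip"`` — an ImageJ ROI zip
        of polygon/freehand ROIs (cell ids taken from entry names; embryo,
        plane, structure and domain supplied via ``roi_defaults`` because
        the .roi format cannot carry them).
    return_report
        Also return the list of :class:`RejectedRecord` for records that
        failed validation.  Malformed records are always logged and never
        silently dropped.
    """
    path = Path(path)
    if dialect == "csv":
        raw = _read_outlines_csv(path)
    elif dialect == "roi_zip":
        raw = _read_outlines_roizip(path, **roi_defaults)
    else:
        raise ValueError(f"unknown outline dialect {dialect!r}")

    outlines: list[CellOutline] = []
    rejected: list[RejectedRecord] = []
    seen: set[str] = set()
    for outline in raw:
        try:
            if outline.cell_id in seen:
                raise OutlineError(f"{outline.cell_id}: duplicate cell_id")
            outline.validate()
        except OutlineError as exc:
            logger.warning("rejected outline %s: %s", outline.cell_id, exc)
            rejected.append(RejectedRecord(outline.cell_id, str(exc)))
            continue
        seen.add(outline.cell_id)
        outlines.append(outline)
    if return_report:
        return outlines, rejected
    return outlines


def _read_outlines_csv(path: Path) -> list[CellOutline]:
    # round_trip parsing: coordinates written by write_outlines re-read
    # bit-identically
    table = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _CSV_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    # groupby(sort=False) preserves both file order and vertex order
    for _, rows in table.groupby("cell_id", sort=False):
        out.append(_outline_from_rows(rows))
    return out


def write_outlines(
    outlines: Sequence[CellOutline], path: str | Path, dialect: str = "csv"
) -> None:
    path = Path(path)
    if dialect == "csv":
        frames = []
        for o in outlines:
            df = pd.DataFrame(o.vertices, columns=["x", "y"])
            df.insert(0, "cell_id", o.cell_id)
            df.insert(1, "embryo_id", o.embryo_id)
            df.insert(2, "plane", o.plane)
            df.insert(3, "structure", o.structure)
            df.insert(4, "domain", o.domain)
            df["somite_index"] = o.somite_index
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    elif dialect == "roi_zip":
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            for o in outlines:
                zf.writestr(f"{o.cell_id}.roi", _encode_roi(o.vertices))
    else:
        raise ValueError(f"unknown outline dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Minimal ImageJ .roi codec (polygon ROIs, sub-pixel resolution)
# ---------------------------------------------------------------------------
# Layout (big-endian): "Iout" magic, version, type byte, integer bounding
# box, n coordinates; int16 vertex offsets at byte 64, followed by float32
# absolute coordinates when the SUB_PIXEL_RESOLUTION option bit is set.
# Coordinates therefore round-trip at float32 precision.

_ROI_MAGIC = b"Iout"
_ROI_VERSION = 227
_ROI_TYPE_POLYGON = 0
_ROI_TYPE_FREEHAND = 7
_OPT_SUBPIXEL = 128


def _encode_roi(vertices: np.ndarray) -> bytes:
    v = np.asarray(vertices, dtype=np.float32)
    n = len(v)
    left, top = int(np.floor(v[:, 0].min())), int(np.floor(v[:, 1].min()))
    right, bottom = int(np.ceil(v[:, 0].max())), int(np.ceil(v[:, 1].max()))
    header = bytearray(64)
    header[0:4] = _ROI_MAGIC
    struct.pack_into(">h", header, 4, _ROI_VERSION)
    header[6] = _ROI_TYPE_POLYGON
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n)
    struct.pack_into(">h", header, 52, _OPT_SUBPIXEL)  # options
    xi = np.round(v[:, 0]).astype(">i2") - left
    yi = np.round(v[:, 1]).astype(">i2") - top
    return (
        bytes(header)
        + xi.tobytes()
        + yi.tobytes()
        + v[:, 0].astype(">f4").tobytes()
        + v[:, 1].astype(">f4").tobytes()
    )


def _decode_roi(blob: bytes) -> np.ndarray:
    if blob[:4] != _ROI_MAGIC:
        raise ValueError("not an ImageJ ROI (bad magic)")
    roi_type = blob[6]
    if roi_type not in (_ROI_TYPE_POLYGON, _ROI_TYPE_FREEHAND):
        raise ValueError(f"unsupported ROI type {roi_type} (polygons only)")
    top, left, _bottom, _right = struct.unpack_from(">4h", blob, 8)
    (n,) = struct.unpack_from(">h", blob, 16)
    (options,) = struct.unpack_from(">h", blob, 52)
    base = 64
    if options & _OPT_SUBPIXEL and len(blob) >= base + 4 * n + 8 * n:
        off = base + 4 * n
        x = np.frombuffer(blob, dtype=">f4", count=n, offset=off)
        y = np.frombuffer(blob, dtype=">f4", count=n, offset=off + 4 * n)
        return np.column_stack([x, y]).astype(float)
    x = np.frombuffer(blob, dtype=">i2", count=n, offset=base).astype(float) + left
    y = (
        np.frombuffer(blob, dtype=">i2", count=n, offset=base + 2 * n).astype(float)
        + top
    )
    return np.column_stack([x, y])


def _read_outlines_roizip(
    path: Path,
    embryo_id: str = "unknown",
    plane: str = "sagittal",
    structure: str = "psm",
    domain: str = "unassigned",
    somite_index: int | None = None,
) -> list[CellOutline]:
    out = []
    with zipfile.ZipFile(path) as zf:
        for name in zf.namelist():
            if not name.lower().endswith(".roi"):
                continue
            vertices = _decode_roi(zf.read(name))
            out.append(
                CellOutline(
                    cell_id=Path(name).stem,
                    embryo_id=embryo_id,
                    plane=plane,
                    vertices=vertices,
                    structure=structure,
                    domain=domain,
                    somite_index=somite_index,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Time-lapse tables
# ---------------------------------------------------------------------------


def read_timelapse(path: str | Path) -> list[TimepointRecord]:
    """Read a five-column time-lapse distance table, sorted by time.

    Raises
    ------
    ValueError
        If a row shows the cumulative somite count decreasing, naming the
        offending row, or if timepoints are duplicated.
    """
    table = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TIMELAPSE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    table = table.sort_values("t_minutes", kind="stable").reset_index(drop=True)
    if table["t_minutes"].duplicated().any():
        raise ValueError(f"{path}: duplicate timepoints")
    counts = table["somite_count"].to_numpy()
    drops = np.nonzero(np.diff(counts) < 0)[0]
    if drops.size:
        row = int(drops[0]) + 1
        raise ValueError(
            f"{path}: somite_count decreases at row {row} "
            f"({counts[row - 1]} -> {counts[row]})"
        )
    records = [
        TimepointRecord(
            t_minutes=float(r.t_minutes),
            segmented_length_um=float(r.segmented_length_um),
            dii_front_to_border_um=float(r.dii_front_to_border_um),
            psm_length_um=float(r.psm_length_um),
            somite_count=int(r.somite_count),
        )
        for r in table.itertuples()
    ]
    for rec in records:
        rec.validate()
    return records


def write_timelapse(records: Iterable[TimepointRecord], path: str | Path) -> None:
    df = pd.DataFrame([r.__dict__ for r in records], columns=list(TIMELAPSE_COLUMNS))
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Intensity stacks (TIFF + sidecar table)
# ---------------------------------------------------------------------------


def write_intensity_stack(
    slices: Sequence[IntensitySlice], directory: str | Path
) -> None:
    """Write slices as ``intensity.tif`` + ``mask.tif`` + ``slices.csv``."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        directory / "intensity.tif",
        np.stack([s.pixels.astype(np.float32) for s in slices]),
    )
    tifffile.imwrite(
        directory / "mask.tif",
        np.stack([s.psm_mask.astype(np.uint8) for s in slices]),
    )
    pd.DataFrame(
        {
            "embryo_id": [s.embryo_id for s in slices],
            "marker": [s.marker for s in slices],
            "axis_position_percent": [s.axis_position_percent for s in slices],
            "apical_x": [s.apical_reference[0] for s in slices],
            "apical_y": [s.apical_reference[1] for s in slices],
            "pixel_size_um": [s.pixel_size_um for s in slices],
        }
    ).to_csv(directory / "slices.csv", index=False)


def read_intensity_stack(directory: str | Path) -> list[IntensitySlice]:
    import tifffile

    directory = Path(directory)
    pixels = tifffile.imread(directory / "intensity.tif")
    masks = tifffile.imread(directory / "mask.tif").astype(bool)
    meta = pd.read_csv(directory / "slices.csv")
    if pixels.ndim == 2:  # single-slice stacks collapse on read
        pixels = pixels[None]
        masks = masks[None]
    slices = []
    for i, row in meta.iterrows():
        s = IntensitySlice(
            embryo_id=str(row.embryo_id),
            marker=str(row.marker),
            axis_position_percent=float(row.axis_position_percent),
            pixels=np.asarray(pixels[i], dtype=float),
            psm_mask=masks[i],
            apical_reference=(float(row.apical_x), float(row.apical_y)),
            pixel_size_um=float(row.pixel_size_um),
        )
        s.validate()
        slices.append(s)
    return slices
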