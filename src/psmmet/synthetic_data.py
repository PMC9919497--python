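"""Synthetic input generator with known ground truth.

The generator emulates the three input families the pipeline consumes —
cell-outline fields, polarity-marker intensity stacks and time-lapse
distance tracks — with parameters that state the biology the pipeline is
meant to recover: surface-domain aspect ratios rising as a sigmoid of
axis position with onsets ordered dorsal (40%) < medial (55%) < ventral =
lateral (70%); a mesenchymal core whose aspect ratio never changes;
per-marker apical-enrichment onsets with marker-specific domain
orderings; and constant-interval somitogenesis with a biphasic
slow-then-constant advection of labelled cells along the PSM.

Cells are ellipse-polygons (24 vertices) — enough to exercise moments,
surface banding and fitting, with no pretence of realistic cell shapes.
Aspect-ratio noise is multiplicative lognormal (AR is >= 1 and
right-skewed); intensity noise is additive Gaussian.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .outline_io import CellOutline, IntensitySlice, TimepointRecord
from .psm_axis import AxisModel, DomainGeometry
from .profile_fitting import logistic4

TRANSVERSE_DOMAINS = ("dorsal", "medial", "ventral", "lateral")
SAGITTAL_DOMAINS = ("dorsal", "ventral")

# default onset truths: AR rises first dorsally, then medially, then
# ventrally and laterally together; the core never elongates
DEFAULT_AR_TRUTH = {
    "dorsal": (1.5, 6.0, 40.0, 0.3),
    "medial": (1.5, 6.0, 55.0, 0.3),
    "ventral": (1.5, 6.0, 70.0, 0.3),
    "lateral": (1.5, 6.0, 70.0, 0.3),
}

# per-marker apical-enrichment onset positions (% PSM) per domain
DEFAULT_MARKER_ONSETS = {
    "PKCzeta": {"dorsal": 40.0, "ventral": 50.0, "medial": 65.0, "lateral": 100.0},
    "PAR3": {"lateral": 50.0, "ventral": 60.0, "medial": 70.0, "dorsal": 80.0},
    "ZO1": {"dorsal": 85.0, "medial": 95.0, "lateral": 100.0, "ventral": 110.0},
    "GM130": {"ventral": 65.0, "medial": 70.0, "dorsal": 80.0, "lateral": 95.0},
    "Ncad": {"dorsal": 60.0, "medial": 90.0, "ventral": 90.0, "lateral": 90.0},
}


@dataclass
class SyntheticTruth:
    """Ground-truth parameters that fully determine the generated data."""

    ar_truth: dict = field(default_factory=lambda: dict(DEFAULT_AR_TRUTH))
    core_ar_mean: float = 2.2
    ar_sigma: float = 0.15  # lognormal sigma on AR
    marker_onsets: dict = field(
        default_factory=lambda: {m: dict(d) for m, d in DEFAULT_MARKER_ONSETS.items()}
    )
    delta_amplitude: float = 30.0  # upper asymptote of apical-basal delta
    delta_slope: float = 0.3
    intensity_baseline: float = 50.0
    intensity_sigma: float = 5.0
    cells_per_domain: int = 600
    slices: int = 40
    breakpoint_h: float = 10.0
    slow_phase_rate: float = 1.0  # % PSM / h
    fast_phase_rate: float = 6.0
    interval_min: float = 68.0
    timelapse_noise_frac: float = 0.03  # of concurrent PSM length
    timelapse_dt_min: float = 20.0
    timelapse_duration_min: float = 1500.0
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        data = json.loads(Path(path).read_text())
        # JSON has no tuples; restore them so equality round-trips
        data["ar_truth"] = {k: tuple(v) for k, v in data["ar_truth"].items()}
        return cls(**data)


@dataclass
class SyntheticField:
    """A generated outline field plus everything needed to analyse it."""

    cells: list
    truth_table: pd.DataFrame  # cell_id, domain_true, position_percent, ar_true
    geometry: DomainGeometry
    axis: AxisModel | None
    truth: SyntheticTruth


def _ellipse_polygon(center, semi_major, semi_minor, angle_rad, n=24):
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    pts = np.column_stack([semi_major * np.cos(t), semi_minor * np.sin(t)])
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    rot = np.array([[c, -s], [s, c]])
    return pts @ rot.T + np.asarray(center)


def _draw_ar(rng, truth: SyntheticTruth, domain: str, x: np.ndarray):
    if domain == "core":
        base = np.full_like(x, truth.core_ar_mean)
    else:
        a, b, x0, k = truth.ar_truth[domain]
        base = logistic4(x, a, b, x0, k)
    if truth.ar_sigma > 0:
        base = base * np.exp(rng.normal(0.0, truth.ar_sigma, size=x.shape))
    return np.maximum(base, 1.02)


# transverse ring geometry (px)
_RING_RADIUS = 200.0
_BAND_DEPTH = 12.0
_MINOR_SEMI = 4.0
# sagittal strip geometry (px)
_STRIP_LENGTH = 1000.0
_STRIP_HEIGHT = 150.0
_STRIP_XPAD = 30.0

_SECTOR_CENTER_DEG = {"dorsal": -90.0, "lateral": 0.0, "ventral": 90.0, "medial": 180.0}


def generate_outline_field(
    truth: SyntheticTruth, plane: str = "transverse"
) -> SyntheticField:
    """Generate a field of ellipse-polygon cells with known truth labels.

    Surface cells sit inside a one-cell surface band (a ring for
    transverse sections, the top/bottom strip edges for sagittal ones)
    with their long axis tangent to the surface; core cells fill the
    interior with random orientation.  Axis positions are uniform on
    [0, 100]%; per-cell aspect ratios follow the domain's sigmoid truth
    times lognormal noise.
    """
    rng = np.random.default_rng(truth.seed)
    domains = TRANSVERSE_DOMAINS if plane == "transverse" else SAGITTAL_DOMAINS
    cells: list[CellOutline] = []
    rows = []
    n = truth.cells_per_domain

    for domain in (*domains, "core"):
        x_pct = rng.uniform(0.0, 100.0, size=n)
        ar = _draw_ar(rng, truth, domain, x_pct)
        if plane == "transverse":
            centers, angles = _place_transverse(rng, domain, n)
        else:
            centers, angles = _place_sagittal(rng, domain, n, x_pct)
        for i in range(n):
            cid = f"{plane[:3]}_{domain}_{i:04d}"
            verts = _ellipse_polygon(
                centers[i], _MINOR_SEMI * ar[i], _MINOR_SEMI, angles[i]
            )
            cells.append(
                CellOutline(
                    cell_id=cid,
                    embryo_id="synthetic",
                    plane=plane,
                    vertices=verts,
                    domain=domain,
                    structure="psm",
                )
            )
            rows.append(
                {
                    "cell_id": cid,
                    "domain_true": domain,
                    "position_percent": float(x_pct[i]),
                    "ar_true": float(ar[i]),
                }
            )

    if plane == "transverse":
        theta = np.linspace(0.0, 2.0 * np.pi, 96, endpoint=False)
        boundary = _RING_RADIUS * np.column_stack([np.cos(theta), np.sin(theta)])
        axis = None
    else:
        boundary = np.array(
            [
                [-_STRIP_XPAD, 0.0],
                [_STRIP_LENGTH + _STRIP_XPAD, 0.0],
                [_STRIP_LENGTH + _STRIP_XPAD, _STRIP_HEIGHT],
                [-_STRIP_XPAD, _STRIP_HEIGHT],
            ]
        )
        axis = AxisModel(
            np.array([[0.0, _STRIP_HEIGHT / 2], [_STRIP_LENGTH, _STRIP_HEIGHT / 2]])
        )
    geometry = DomainGeometry(
        outer_boundary=boundary, surface_band_depth_px=_BAND_DEPTH
    )
    return SyntheticField(
        cells=cells,
        truth_table=pd.DataFrame(rows),
        geometry=geometry,
        axis=axis,
        truth=truth,
    )


def _place_transverse(rng, domain, n):
    if domain == "core":
        # uniform over the interior disc, clear of the surface band
        r_max = _RING_RADIUS - _BAND_DEPTH - 4.0 * _MINOR_SEMI
        r = r_max * np.sqrt(rng.uniform(0.0, 1.0, size=n))
        phi = rng.uniform(-np.pi, np.pi, size=n)
        centers = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
        angles = rng.uniform(0.0, np.pi, size=n)
        return centers, angles
    c = np.radians(_SECTOR_CENTER_DEG[domain])
    phi = rng.uniform(c - np.pi / 4, c + np.pi / 4, size=n)
    r = _RING_RADIUS - _BAND_DEPTH / 2.0
    centers = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    return centers, phi + np.pi / 2.0  # long axis tangent to the ring


def _place_sagittal(rng, domain, n, x_pct):
    x_px = x_pct / 100.0 * _STRIP_LENGTH
    if domain == "dorsal":
        y = np.full(n, _BAND_DEPTH / 2.0)
        return np.column_stack([x_px, y]), np.zeros(n)
    if domain == "ventral":
        y = np.full(n, _STRIP_HEIGHT - _BAND_DEPTH / 2.0)
        return np.column_stack([x_px, y]), np.zeros(n)
    margin = _BAND_DEPTH + 4.0 * _MINOR_SEMI
    y = rng.uniform(margin, _STRIP_HEIGHT - margin, size=n)
    return np.column_stack([x_px, y]), rng.uniform(0.0, np.pi, size=n)


# ---------------------------------------------------------------------------
# Intensity stacks
# ---------------------------------------------------------------------------

_GRID = 120
_DISC_RADIUS = 45.0
_INTENSITY_BAND = 10.0


def delta_truth(truth: SyntheticTruth, marker: str, domain: str, x):
    """Ground-truth apical-basal delta for a marker/domain at position x."""
    x0 = truth.marker_onsets[marker][domain]
    return logistic4(x, 0.0, truth.delta_amplitude, x0, truth.delta_slope)


def generate_intensity_stack(
    truth: SyntheticTruth, marker: str = "PKCzeta"
) -> tuple[list[IntensitySlice], DomainGeometry]:
    """Generate transverse intensity slices for one marker.

    Each slice is a disc-masked grid at one axis position: a uniform
    baseline, plus the marker's truth delta added to the apical (inner)
    half of the surface band sector by sector, plus Gaussian noise.
    Positions run 0-120% so post-somite onsets (>100%) are observable.
    """
    rng = np.random.default_rng(truth.seed + 1)
    yy, xx = np.mgrid[0:_GRID, 0:_GRID].astype(float)
    center = (_GRID - 1) / 2.0
    rr = np.hypot(xx - center, yy - center)
    mask = rr <= _DISC_RADIUS
    band = mask & (rr > _DISC_RADIUS - _INTENSITY_BAND)
    apical = band & (rr <= _DISC_RADIUS - _INTENSITY_BAND / 2.0)
    angle = np.degrees(np.arctan2(yy - center, xx - center))

    geom = DomainGeometry(
        outer_boundary=_disc_boundary(center),
        surface_band_depth_px=_INTENSITY_BAND,
    )
    positions = np.linspace(0.0, 120.0, truth.slices)
    slices = []
    for pos in positions:
        img = np.full((_GRID, _GRID), truth.intensity_baseline)
        for domain in TRANSVERSE_DOMAINS:
            c = _SECTOR_CENTER_DEG[domain]
            in_sector = (np.abs((angle - c + 180.0) % 360.0 - 180.0) <= 45.0)
            img[apical & in_sector] += delta_truth(truth, marker, domain, pos)
        if truth.intensity_sigma > 0:
            img = img + rng.normal(0.0, truth.intensity_sigma, img.shape)
        slc = IntensitySlice(
            embryo_id="synthetic",
            marker=marker,
            axis_position_percent=float(pos),
            pixels=np.clip(img, 0.0, None),
            psm_mask=mask,
            apical_reference=(center, center),
        )
        slices.append(slc)
    return slices, geom


def _disc_boundary(center, n=96):
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return center + _DISC_RADIUS * np.column_stack([np.cos(t), np.sin(t)])


# ---------------------------------------------------------------------------
# Time-lapse tracks
# ---------------------------------------------------------------------------


def generate_timelapse(truth: SyntheticTruth) -> list[TimepointRecord]:
    """Generate a time-lapse distance track with biphasic advection.

    The labelled front advances at ``slow_phase_rate`` until
    ``breakpoint_h`` and at ``fast_phase_rate`` after it (percent of the
    concurrent PSM length per hour, capped at the border).  The somite
    count increments every ``interval_min``; the PSM shortens slowly; the
    front-to-border distance carries Gaussian noise scaled to the PSM
    length.
    """
    rng = np.random.default_rng(truth.seed + 2)
    t_min = np.arange(0.0, truth.timelapse_duration_min + 0.5, truth.timelapse_dt_min)
    t_h = t_min / 60.0
    pos = np.clip(
        truth.slow_phase_rate * np.minimum(t_h, truth.breakpoint_h)
        + truth.fast_phase_rate * np.maximum(t_h - truth.breakpoint_h, 0.0),
        0.0,
        100.0,
    )
    psm_len = 1800.0 - 10.0 * t_h
    dii = (100.0 - pos) / 100.0 * psm_len
    if truth.timelapse_noise_frac > 0:
        dii = dii + rng.normal(0.0, truth.timelapse_noise_frac * psm_len)
    dii = np.clip(dii, 0.0, None)
    segmented = 400.0 + 55.0 * t_h
    somites = np.floor(t_min / truth.interval_min).astype(int)
    return [
        TimepointRecord(
            t_minutes=float(t_min[i]),
            segmented_length_um=float(segmented[i]),
            dii_front_to_border_um=float(dii[i]),
            psm_length_um=float(psm_len[i]),
            somite_count=int(somites[i]),
        )
        for i in range(len(t_min))
    ]


# ---------------------------------------------------------------------------
# Complete fixture directories
# ---------------------------------------------------------------------------


def write_fixture_dir(truth: SyntheticTruth, directory: str | Path) -> None:
    """Emit a complete on-disk fixture: outline CSVs + ROI zip, one marker
    intensity stack, the time-lapse table and the truth JSON."""
    from . import outline_io

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for plane in ("sagittal", "transverse"):
        fieldset = generate_outline_field(truth, plane)
        outline_io.write_outlines(
            fieldset.cells, directory / f"outlines_{plane}.csv", "csv"
        )
        fieldset.truth_table.to_csv(
            directory / f"truth_{plane}.csv", index=False
        )
    outline_io.write_outlines(
        generate_outline_field(truth, "sagittal").cells[:50],
        directory / "outlines_sagittal.roi.zip",
        "roi_zip",
    )
    slices, _ = generate_intensity_stack(truth, "PKCzeta")
    outline_io.write_intensity_stack(slices, directory / "stack_PKCzeta")
    outline_io.write_timelapse(
        generate_timelapse(truth), directory / "timelapse.csv"
    )
    truth.to_json(directory / "truth.json")
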