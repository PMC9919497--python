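"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from psmmet import CellOutline


def rasterized_ar(vertices: np.ndarray, supersample: int = 10) -> float:
    """Brute-force aspect-ratio oracle: rasterize the polygon on a grid
    ``supersample`` times finer than pixels and take the eigenvalue ratio
    of the pixel-cloud covariance.  Independent of the analytic
    polygon-moment path it checks."""
    from skimage.draw import polygon as draw_polygon

    v = np.asarray(vertices, dtype=float) * supersample
    v = v - v.min(axis=0) + 2.0
    rr, cc = draw_polygon(v[:, 1], v[:, 0])
    pts = np.column_stack([cc, rr]).astype(float)
    cov = np.cov(pts.T)
    eig = np.linalg.eigvalsh(cov)
    return float(np.sqrt(eig[1] / eig[0]))


def star_polygon(rng: np.random.Generator, n_vertices: int = 12,
                 r_lo: float = 15.0, r_hi: float = 45.0) -> np.ndarray:
    """A random simple (star-shaped, generally concave) polygon.

    Angle gaps are bounded away from zero so the origin stays interior
    and no edge sweeps more than 180 degrees: the polygon is always
    simple."""
    gaps = rng.uniform(0.5, 1.0, n_vertices)
    angles = 2 * np.pi * np.cumsum(gaps) / gaps.sum() + rng.uniform(0, 2 * np.pi)
    radii = rng.uniform(r_lo, r_hi, n_vertices)
    return np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])


def make_outline(vertices, cell_id="c0", **kw) -> CellOutline:
    defaults = dict(embryo_id="e0", plane="sagittal")
    defaults.update(kw)
    return CellOutline(cell_id=cell_id, vertices=np.asarray(vertices, float),
                       **defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture
def square_outline():
    return make_outline([[0, 0], [10, 0], [10, 10], [0, 10]])
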