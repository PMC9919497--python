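"""Apical-basal polarity-marker quantification on transverse re-slices.

Each transverse optical slice carries a PSM cross-section mask.  The
surface band of the mask (one cell layer deep) is partitioned into the
four sectors dorsal/medial/ventral/lateral — the same rules as
:mod:`psmmet.psm_axis` — and each sector band is split into an apical
half (inner, toward the tissue centre) and a basal half (outer) at the
midpoint of the local band thickness, measured along the inward normal
via the Euclidean distance transform.  The polarity index per domain is
the apical minus basal mean pixel intensity; a constant image background
cancels exactly in the subtraction.  The mesenchymal core is never
analysed — apical and basal cannot be defined for unpolarized cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .outline_io import IntensitySlice
from .psm_axis import DomainGeometry, _sector_of
from .profile_fitting import OnsetLandmarks, SigmoidFit, fit_sigmoid, landmarks

logger = logging.getLogger(__name__)

POLARITY_DOMAINS = ("dorsal", "medial", "ventral", "lateral")
MIN_HALF_PIXELS = 10


@dataclass(frozen=True)
class PolarityRecord:
    """Apical/basal mean intensities for one domain of one slice."""

    embryo_id: str
    marker: str
    domain: str
    axis_position_percent: float
    apical_mean: float
    basal_mean: float
    n_apical_px: int
    n_basal_px: int

    @property
    def delta(self) -> float:
        return self.apical_mean - self.basal_mean


def band_halves(
    mask: np.ndarray, band_depth_px: float
) -> tuple[np.ndarray, np.ndarray]:
    """Split the surface band of a mask into apical and basal halves.

    The band is every mask pixel within ``band_depth_px`` of the outside
    (distance transform); the basal half is the outer half of that depth,
    the apical half the inner half.  Together the halves tile the band
    exactly.
    """
    depth = ndimage.distance_transform_edt(mask)
    band = mask & (depth <= band_depth_px)
    basal = band & (depth <= band_depth_px / 2.0)
    apical = band & ~basal
    return apical, basal


def split_domains_apical_basal(
    slc: IntensitySlice,
    geom: DomainGeometry,
    *,
    stat: str = "mean",
    background_subtract: bool = False,
    swap_apical_basal: bool = False,
) -> list[PolarityRecord]:
    """Per-domain apical/basal intensity summaries for one slice.

    Sectors are assigned by pixel angle about ``apical_reference`` using
    the transverse sector rules of :mod:`psmmet.psm_axis`.  Sectors whose
    apical or basal half has fewer than 10 pixels are dropped with a log
    entry.  ``stat`` selects mean (default, area-independent) or summed
    intensity.  ``swap_apical_basal`` exchanges the two halves (delta is
    negated exactly); it exists for orientation checks.
    """
    slc.validate()
    pixels = slc.pixels.astype(float)
    if background_subtract:
        pixels = pixels - np.median(pixels[~slc.psm_mask]) if (~slc.psm_mask).any() else pixels
    apical, basal = band_halves(slc.psm_mask, geom.surface_band_depth_px)
    if swap_apical_basal:
        apical, basal = basal, apical

    h, w = slc.psm_mask.shape
    yy, xx = np.mgrid[0:h, 0:w]
    ax, ay = slc.apical_reference
    angles = np.degrees(np.arctan2(yy - ay, xx - ax))

    records = []
    for domain in POLARITY_DOMAINS:
        # vectorized sector membership: reuse the corner tie-break rules
        sector = np.frompyfunc(lambda a: _sector_of(a, geom), 1, 1)(angles) == domain
        api = apical & sector
        bas = basal & sector
        if api.sum() < MIN_HALF_PIXELS or bas.sum() < MIN_HALF_PIXELS:
            logger.warning(
                "slice %s @%.1f%%: %s half has < %d px, record dropped",
                slc.embryo_id, slc.axis_position_percent, domain, MIN_HALF_PIXELS,
            )
            continue
        reduce = np.mean if stat == "mean" else np.sum
        records.append(
            PolarityRecord(
                embryo_id=slc.embryo_id,
                marker=slc.marker,
                domain=domain,
                axis_position_percent=slc.axis_position_percent,
                apical_mean=float(reduce(pixels[api])),
                basal_mean=float(reduce(pixels[bas])),
                n_apical_px=int(api.sum()),
                n_basal_px=int(bas.sum()),
            )
        )
    return records


def records_table(records) -> pd.DataFrame:
    """PolarityRecords as a DataFrame with a computed ``delta`` column."""
    df = pd.DataFrame([r.__dict__ for r in records])
    if len(df):
        df["delta"] = df["apical_mean"] - df["basal_mean"]
    return df


def polarity_profile(
    records,
) -> dict[str, tuple[SigmoidFit, OnsetLandmarks | None]]:
    """Per-domain sigmoid fit + landmarks of delta against axis position.

    Needs at least 8 slices per domain (enforced by the fitter).  Domains
    whose fit collapses to flat get ``None`` landmarks.
    """
    df = records_table(records)
    out = {}
    for domain, grp in df.groupby("domain", sort=False):
        fit = fit_sigmoid(
            grp["axis_position_percent"].to_numpy(),
            grp["delta"].to_numpy(),
        )
        lm = None
        if not fit.no_sigmoid and fit.k != 0:
            lm = landmarks(fit)
        out[str(domain)] = (fit, lm)
    return out
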