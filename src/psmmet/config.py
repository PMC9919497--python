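"""Run configuration: the knobs a whole analysis shares, YAML-serializable."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Analysis-wide settings with field defaults matching the defaults
    used throughout the package.

    Attributes
    ----------
    microns_per_pixel
        Physical calibration of outline coordinates; outlines themselves
        are stored in pixels.
    ar_method
        ``"ellipse"`` — aspect ratio from the second-moment (fitted
        ellipse) axes, the standard FIJI shape descriptor; ``"feret"`` —
        max Feret diameter over minimum rotated-rectangle width.  The two
        disagree on concave cells.
    surface_band_depth_px
        Depth of the one-cell surface band used for domain assignment;
        ``None`` means "median cell minor-axis length of the section".
    sector_rotation_deg
        Rotation applied to the four 90-degree sector boundaries of a
        transverse section (anatomy is not always axis-aligned).
    medial_side
        Which image side faces the neural tube in transverse sections.
    dorsal_up
        Whether decreasing image y is the dorsal direction.
    log_response
        Fit sigmoid profiles on log-transformed responses.
    intensity_stat
        ``"mean"`` or ``"sum"`` pixel intensity per apical/basal half.
    background_subtract
        Subtract the per-slice median background before polarity
        quantification.
    timelapse_mode
        ``"fitted"`` — position/time mapping interpolates the segmented
        two-phase fit; ``"raw"`` — interpolate the raw trajectory.
    """

    microns_per_pixel: float = 1.0
    ar_method: str = "ellipse"
    surface_band_depth_px: float | None = None
    sector_rotation_deg: float = 0.0
    medial_side: str = "left"
    dorsal_up: bool = True
    log_response: bool = False
    intensity_stat: str = "mean"
    background_subtract: bool = False
    timelapse_mode: str = "fitted"
    ar_color_breaks: list = field(
        default_factory=lambda: [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
    )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
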