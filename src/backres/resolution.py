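"""Translate a frequency band into sampling intervals and camera pixel counts.

Given a breakpoint band (fc_low, fc_high) from the degradation sweeps and an
oversampling factor k, the minimal sampling interval is d = 1/(2 k fc); the
higher frequency maps to the finer (smaller) interval. The camera pixel count
per axis follows from dividing the region of interest by the fill factor
(the fraction of the image actually covering the subject) and the interval:

    px = round( dimension / (fill_factor * d) )

Default anthropometry covers a 95th-percentile adult male back: interscye
width 454 mm, waist-back height 516 mm; fill factor 0.67. An alternative
preset for a 95th-percentile adult female back (410 mm x 390 mm) is provided.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

__all__ = [
    "ResolutionRequirement",
    "spatial_resolution_band",
    "camera_resolution",
    "requirement_report",
    "MALE_95TH_ROI",
    "FEMALE_95TH_ROI",
]

#: (width, height) of the region of interest in mm.
MALE_95TH_ROI = (454.0, 516.0)
FEMALE_95TH_ROI = (410.0, 390.0)


@dataclass
class ResolutionRequirement:
    """Minimal sampling-interval band and camera pixel counts for a ROI."""

    fc_band: tuple[float, float]
    oversampling: float
    interval_band: tuple[float, float]
    px_x_band: tuple[int, int]
    px_y_band: tuple[int, int]
    W_roi: float
    H_roi: float
    fill_factor: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        return path


def spatial_resolution_band(fc_low: float, fc_high: float,
                            oversampling: float = 5.0) -> tuple[float, float]:
    """Sampling-interval band (d_min, d_max) in mm for a cutoff band.

    d = 1/(2 * oversampling * fc); fc_high gives d_min, fc_low gives d_max.
    """
    if fc_low <= 0 or fc_high <= 0:
        raise ValueError("cutoff frequencies must be positive")
    if fc_low > fc_high:
        raise ValueError("fc_low must not exceed fc_high")
    if oversampling < 1:
        raise ValueError("oversampling must be >= 1")
    factor = 2.0 * oversampling
    return (1.0 / (factor * fc_high), 1.0 / (factor * fc_low))


def camera_resolution(W_roi: float, H_roi: float, fill_factor: float,
                      d: float) -> tuple[int, int]:
    """Minimal camera pixel counts (x, y) for a sampling interval d (mm)."""
    if W_roi <= 0 or H_roi <= 0 or d <= 0:
        raise ValueError("dimensions and sampling interval must be positive")
    if not 0 < fill_factor <= 1:
        raise ValueError("fill_factor must be in (0, 1]")
    px_x = int(round(W_roi / (fill_factor * d)))
    px_y = int(round(H_roi / (fill_factor * d)))
    return px_x, px_y


def requirement_report(fc_band: tuple[float, float], oversampling: float = 5.0,
                       W_roi: float = MALE_95TH_ROI[0],
                       H_roi: float = MALE_95TH_ROI[1],
                       fill_factor: float = 0.67) -> ResolutionRequirement:
    """Compose the full resolution requirement for a breakpoint band.

    Pixel bands pair the coarse interval (d_max) with the lower pixel count
    and the fine interval (d_min) with the higher one.
    """
    fc_low, fc_high = fc_band
    d_min, d_max = spatial_resolution_band(fc_low, fc_high, oversampling)
    px_lo = camera_resolution(W_roi, H_roi, fill_factor, d_max)
    px_hi = camera_resolution(W_roi, H_roi, fill_factor, d_min)
    return ResolutionRequirement(
        fc_band=(float(fc_low), float(fc_high)),
        oversampling=float(oversampling),
        interval_band=(d_min, d_max),
        px_x_band=(px_lo[0], px_hi[0]),
        px_y_band=(px_lo[1], px_hi[1]),
        W_roi=float(W_roi),
        H_roi=float(H_roi),
        fill_factor=float(fill_factor),
    )
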