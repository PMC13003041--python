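"""Region-of-interest densitometry, glial area fractions, and stereology.

Optical density is background-normalised by subtracting the mean intensity
of an anatomical reference region (e.g. corpus callosum, basal cerebral
peduncle) from the mean intensity of the region of interest.  Glial
activation is the area fraction of marker-positive pixels after a fixed
enhancement pipeline.  Cell numbers are estimated with the optical
fractionator, N = sum(Q) / (ssf * asf * hsf), and densities via Cavalieri
volume estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import image_ops as ops
from .image_ops import ImageStack


@dataclass
class ROI:
    """A named anatomical region as a boolean 2-D mask."""

    label: str
    mask: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.label:
            raise ValueError("ROI label must be non-empty")
        if self.mask.ndim != 2 or not self.mask.any():
            raise ValueError(f"ROI {self.label!r} must have a non-empty 2-D mask")


@dataclass
class StereologyParams:
    """Optical-fractionator sampling fractions.

    Defaults follow a common design: every fifth section (ssf = 1/5),
    50 x 50 um counting frames separated by 60 um gaps, and a 95% height
    sampling fraction.  ``separation_is_gap`` controls whether
    ``frame_separation`` is the gap between frames (grid step =
    frame_side + separation, the default) or the full grid step itself.
    """

    ssf: float = 1 / 5
    frame_side: float = 50.0  # um
    frame_separation: float = 60.0  # um
    hsf: float = 0.95
    section_thickness: float = 0.04  # mm, for Cavalieri volume
    separation_is_gap: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.ssf <= 1 and 0 < self.hsf <= 1):
            raise ValueError("ssf and hsf must lie in (0, 1]")
        if self.frame_side <= 0 or self.frame_separation <= 0:
            raise ValueError("frame dimensions must be positive")

    @property
    def asf(self) -> float:
        """Area sampling fraction: frame area over grid-cell area."""
        step = (
            self.frame_side + self.frame_separation
            if self.separation_is_gap
            else self.frame_separation
        )
        return self.frame_side**2 / step**2


@dataclass
class GliaParams:
    """Enhancement settings for glial positive-area quantification."""

    rolling_ball_radius: int = 20
    gaussian_sigma: float = 2.0
    contrast_saturation: float = 0.0035
    threshold_method: str = "moments"

    def __post_init__(self) -> None:
        if self.rolling_ball_radius < 1 or self.gaussian_sigma <= 0:
            raise ValueError("glia parameters must be positive")


def optical_density(
    image: ImageStack, roi: ROI, background_roi: ROI, invert: bool = False
) -> float:
    """Background-normalised optical density of a region.

    OD = mean intensity within ``roi`` minus mean intensity within
    ``background_roi``.  With ``invert=True`` the image is photometrically
    inverted first, so that on brightfield scans of immunostained sections
    more staining yields a larger OD.  Negative values are reported, not
    clamped.  Units are arbitrary scanner units.
    """
    if image.shape[0] != 1:
        raise ValueError("optical_density expects a single-section (depth-1) image")
    img = image.voxels[0].astype(np.float64)
    if invert:
        img = (2**image.bit_depth - 1) - img
    for r in (roi, background_roi):
        if r.mask.shape != img.shape:
            raise ValueError(f"ROI {r.label!r} does not match the image shape")
    return float(img[roi.mask].mean() - img[background_roi.mask].mean())


def animal_region_od(section_ods: list[float], region: str = "") -> dict:
    """Per-animal OD: the mean across that animal's sections."""
    if not section_ods:
        raise ValueError("at least one per-section OD is required")
    return {
        "region": region,
        "n_sections": len(section_ods),
        "od": float(np.mean(section_ods)),
    }


def positive_area_fraction(
    image: ImageStack, params: GliaParams | None = None
) -> dict:
    """Marker-positive area fraction of a calibrated 2-D image.

    Pipeline: rolling-ball background subtraction, Gaussian blur, linear
    auto-contrast, moment-preserving threshold, then the fraction of
    foreground pixels.  Also reports the absolute positive area and the
    total analysed area in mm^2.
    """
    params = params or GliaParams()
    if not image.is_calibrated:
        raise ValueError("positive_area_fraction requires a calibrated image")
    img = ops.to_uint8(image)
    _, img = ops.rolling_ball_background(img, params.rolling_ball_radius)
    img = ops.gaussian_blur(img, params.gaussian_sigma)
    img = ops.enhance_contrast(img, params.contrast_saturation)
    threshold = ops.moments_threshold(ops.stack_histogram(img))
    binary = ops.binarize(img, threshold)
    n_fg = int(binary.voxels.sum())
    n_total = binary.voxels.size
    px_mm = image.pixel_size / 1000.0  # um -> mm
    total_area_mm2 = n_total * px_mm**2
    positive_area_mm2 = n_fg * px_mm**2
    return {
        "fraction": n_fg / n_total,
        "positive_area_mm2": positive_area_mm2,
        "total_area_mm2": total_area_mm2,
        "per_mm2": (n_fg / n_total) / 1.0,  # fraction of each analysed mm^2
        "threshold": threshold,
    }


def optical_fractionator(
    section_counts: list[float], params: StereologyParams
) -> float:
    """Estimated total cell number from systematically sampled counts.

    N = sum(Q) * (1/ssf) * (1/asf) * (1/hsf), with the area sampling
    fraction derived from the counting-frame geometry.
    """
    counts = np.asarray(section_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("section counts must be non-negative")
    total_q = counts.sum()
    return float(total_q / (params.ssf * params.asf * params.hsf))


def cavalieri_density(
    section_areas_mm2: list[float], params: StereologyParams, n_estimate: float
) -> tuple[float, float]:
    """Cavalieri volume and resulting cell density.

    V = sum(section areas) * section thickness * (1/ssf) in mm^3;
    density = N / V in cells per mm^3.
    """
    areas = np.asarray(section_areas_mm2, dtype=float)
    if (areas < 0).any():
        raise ValueError("section areas must be non-negative")
    volume = float(areas.sum() * params.section_thickness / params.ssf)
    if volume == 0:
        if n_estimate > 0:
            raise ValueError("zero estimated volume with a positive cell count")
        return 0.0, 0.0
    return volume, n_estimate / volume
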