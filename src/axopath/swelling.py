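"""End-to-end axonal-swelling quantification from z-stacks.

The batch macro replicated here converts each stack to 8-bit, inverts the
background contrast, applies rolling-ball background subtraction, constant
pixel subtraction, median smoothing and linear contrast enhancement, then
thresholds and labels connected components.  A component counts as an
axonal swelling only if its largest single-slice cross-section exceeds
``min_area`` (default 0.53 um^2) and it contains at least ``min_voxels``
voxels (default 5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import image_ops as ops
from .image_ops import ImageStack, ParticleSet


@dataclass
class SwellingParams:
    """Configuration of the swelling-quantification macro.

    ``min_area`` is compared strictly ("larger than"); ``min_voxels`` is an
    inclusive minimum.  ``projection_2d`` switches to analysing the
    maximum-intensity projection, where "voxels" degenerate to pixels.
    """

    min_area: float = 0.53  # um^2, strict
    min_voxels: int = 5  # inclusive
    rolling_ball_radius: int = 15
    subtract_value: float = 70.0
    median_radius: int = 1
    contrast_saturation: float = 0.0035
    threshold_method: str = "moments"
    invert: bool = True
    projection_2d: bool = False

    def __post_init__(self) -> None:
        if self.min_area <= 0:
            raise ValueError("min_area must be positive")
        if self.min_voxels < 1:
            raise ValueError("min_voxels must be >= 1")
        if self.threshold_method != "moments":
            raise ValueError(f"unsupported threshold method {self.threshold_method!r}")


@dataclass
class SwellingResult:
    """Per-stack quantification output.

    ``median_volume_um3`` is NaN (undefined) when no swelling survives the
    filters.
    """

    n_swellings: int
    median_volume_um3: float
    particles: ParticleSet
    params: SwellingParams
    stack_id: str = ""
    threshold: int = 0

    @property
    def median_volume_defined(self) -> bool:
        return not math.isnan(self.median_volume_um3)


@dataclass
class AnimalSwellingSummary:
    """Per-animal totals pooled over its image stacks."""

    animal_id: str
    n_stacks: int
    total_swellings: int
    median_volume_um3: float
    volumes_um3: list[float] = field(default_factory=list, repr=False)


def quantify_stack(
    stack: ImageStack, params: SwellingParams | None = None, stack_id: str = ""
) -> SwellingResult:
    """Run the full macro on one calibrated stack.

    Processing order: 8-bit conversion, contrast inversion, rolling-ball
    background subtraction, pixel subtraction, median smoothing, contrast
    enhancement, automatic (moment-preserving) thresholding, connected
    components, then the two physical particle filters.  Deterministic.
    """
    params = params or SwellingParams()
    if not stack.is_calibrated:
        raise ValueError(
            "stack must carry pixel_size and z_step: the particle area filter "
            "is defined in physical units"
        )
    img = ops.to_uint8(stack)
    if params.invert:
        img = ops.invert(img)
    if params.projection_2d:
        # maximum-intensity projection of the signal-bright image
        img = img.with_voxels(img.voxels.max(axis=0)[np.newaxis])
    _, img = ops.rolling_ball_background(img, params.rolling_ball_radius)
    img = ops.subtract_constant(img, params.subtract_value)
    img = ops.median_filter(img, params.median_radius)
    img = ops.enhance_contrast(img, params.contrast_saturation)
    threshold = ops.moments_threshold(ops.stack_histogram(img))
    binary = ops.binarize(img, threshold)
    particles = ops.connected_components(binary, connectivity="3d")

    kept = [
        p
        for p in particles
        if p.max_slice_area_um2 > params.min_area and p.n_voxels >= params.min_voxels
    ]
    kept_set = ParticleSet(particles=kept, labels=particles.labels)
    volumes = [p.volume_um3 for p in kept]
    median_volume = float(np.median(volumes)) if volumes else float("nan")
    return SwellingResult(
        n_swellings=len(kept),
        median_volume_um3=median_volume,
        particles=kept_set,
        params=params,
        stack_id=stack_id,
        threshold=threshold,
    )


def summarize_animal(
    results: list[SwellingResult], animal_id: str
) -> AnimalSwellingSummary:
    """Pool per-stack results into per-animal totals.

    The total is the sum of per-stack counts; the median volume is taken
    over the pooled particle volumes of all stacks (NaN if none).
    """
    if not results:
        raise ValueError("summarize_animal requires at least one SwellingResult")
    volumes: list[float] = []
    for r in results:
        volumes.extend(p.volume_um3 for p in r.particles)
    total = sum(r.n_swellings for r in results)
    median = float(np.median(volumes)) if volumes else float("nan")
    return AnimalSwellingSummary(
        animal_id=animal_id,
        n_stacks=len(results),
        total_swellings=total,
        median_volume_um3=median,
        volumes_um3=volumes,
    )


def match_detections(
    result: SwellingResult,
    centres_um: list[tuple[float, float, float]],
    pixel_size: float,
    z_step: float,
    tolerance_um: float = 1.5,
) -> tuple[int, int, int]:
    """Greedy matching of detected particles against reference centres.

    Returns ``(true_positives, false_positives, false_negatives)``; each
    reference centre can absorb at most one detection within the matching
    tolerance (Euclidean distance in physical units).
    """
    det = [
        (p.centroid[2] * pixel_size, p.centroid[1] * pixel_size, p.centroid[0] * z_step)
        for p in result.particles
    ]  # (x, y, z) um
    unmatched = list(range(len(centres_um)))
    tp = 0
    for dx, dy, dz in det:
        best, best_d = None, tolerance_um
        for j in unmatched:
            cx, cy, cz = centres_um[j]
            d = math.dist((dx, dy, dz), (cx, cy, cz))
            if d <= best_d:
                best, best_d = j, d
        if best is not None:
            unmatched.remove(best)
            tp += 1
    fp = len(det) - tp
    fn = len(unmatched)
    return tp, fp, fn
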