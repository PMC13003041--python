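"""Reusable image operators for batch neuropathology quantification.

Every operator mirrors one step of the ImageJ-style batch workflows used for
axonal-swelling and glial quantification: 8-bit conversion, contrast
inversion, rolling-ball background subtraction, constant pixel subtraction,
median smoothing, linear contrast enhancement, Gaussian blur,
moment-preserving (Tsai) automatic thresholding, and connected-component
particle analysis with physical calibration.

All 2-D operators act slice-wise on z-stacks; radii and sigmas are in
pixels, while particle volumes and cross-sectional areas are reported in
physical units derived from the stack calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal
import warnings

import numpy as np
from scipy import ndimage


# ---------------------------------------------------------------------------
# containers


@dataclass
class ImageStack:
    """A calibrated 3-D intensity stack (z, y, x).

    A 2-D image is represented as a depth-1 stack.  ``pixel_size`` is the
    in-plane sampling in micrometres per pixel and ``z_step`` the inter-slice
    spacing in micrometres.
    """

    voxels: np.ndarray
    bit_depth: int = 8
    pixel_size: float | None = 0.1
    z_step: float | None = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim == 2:
            arr = arr[np.newaxis, ...]
        if arr.ndim != 3:
            raise ValueError(f"expected a 2-D or 3-D array, got ndim={arr.ndim}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.z_step is not None and self.z_step <= 0:
            raise ValueError("z_step must be positive")
        self.voxels = arr

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def is_calibrated(self) -> bool:
        return self.pixel_size is not None and self.z_step is not None

    def with_voxels(self, voxels: np.ndarray, bit_depth: int | None = None) -> "ImageStack":
        return replace(self, voxels=voxels, bit_depth=bit_depth or self.bit_depth)


@dataclass
class BinaryStack:
    """Boolean foreground mask with the calibration of its source stack."""

    voxels: np.ndarray
    pixel_size: float | None = 0.1
    z_step: float | None = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim == 2:
            arr = arr[np.newaxis, ...]
        self.voxels = arr.astype(bool)


@dataclass
class Particle:
    """One connected component with voxel count and physical measurements."""

    label: int
    n_voxels: int
    volume_um3: float
    max_slice_area_um2: float
    centroid: tuple[float, float, float]  # (z, y, x) in voxel coordinates


@dataclass
class ParticleSet:
    """Connected components of a binary stack plus the label image."""

    particles: list[Particle]
    labels: np.ndarray = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.particles)

    def __iter__(self):
        return iter(self.particles)

    @property
    def total_voxels(self) -> int:
        return sum(p.n_voxels for p in self.particles)


# ---------------------------------------------------------------------------
# intensity operators


def to_uint8(stack: ImageStack) -> ImageStack:
    """Linearly rescale a stack to 8 bits.

    The intensity range [min, max] maps to [0, 255] with rounding half away
    from zero; a constant stack maps to all zeros.
    """
    arr = stack.voxels.astype(np.float64)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        out = np.zeros(arr.shape, dtype=np.uint8)
    else:
        scaled = 255.0 * (arr - lo) / (hi - lo)
        # np.round is banker's rounding; the ImageJ convention rounds .5 up
        out = np.floor(scaled + 0.5).astype(np.uint8)
    return replace(stack, voxels=out, bit_depth=8)


def invert(stack: ImageStack) -> ImageStack:
    """Invert an 8-bit stack (v -> 255 - v); involutive."""
    if stack.bit_depth != 8:
        raise ValueError("invert requires an 8-bit stack; call to_uint8 first")
    out = (255 - stack.voxels.astype(np.int16)).astype(np.uint8)
    return replace(stack, voxels=out)


def _ball_structure(radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Footprint and height profile of a ball structuring element.

    The element is the upper hemisphere of a sphere of the given radius:
    height(dx, dy) = sqrt(r^2 - dx^2 - dy^2) over the disc dx^2 + dy^2 <= r^2.
    """
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = xx**2 + yy**2
    footprint = d2 <= r**2
    heights = np.zeros_like(d2, dtype=np.float64)
    heights[footprint] = np.sqrt(r**2 - d2[footprint])
    return footprint, heights


def rolling_ball_background(
    stack: ImageStack, radius: int
) -> tuple[ImageStack, ImageStack]:
    """Rolling-ball background estimation and subtraction, per z-slice.

    The background of each slice is the grayscale morphological opening with
    a ball-height structuring element of the given radius (the ball "rolled"
    under the intensity surface).  The corrected image is the original minus
    the background, clamped at zero.  Returns ``(background, corrected)``.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    nz, ny, nx = stack.shape
    if 2 * radius + 1 > ny or 2 * radius + 1 > nx:
        raise ValueError(
            f"ball diameter {2 * radius + 1} exceeds slice extent ({ny}, {nx})"
        )
    footprint, heights = _ball_structure(radius)
    # non-flat grey opening: erosion then dilation by the ball-height element
    arr = stack.voxels.astype(np.float64)
    bg = np.empty_like(arr)
    for z in range(nz):
        eroded = ndimage.grey_erosion(
            arr[z], footprint=footprint, structure=heights, mode="reflect"
        )
        bg[z] = ndimage.grey_dilation(
            eroded, footprint=footprint, structure=heights, mode="reflect"
        )
    corrected = np.clip(arr - bg, 0, None)
    if stack.bit_depth == 8:
        bg_out = np.clip(np.floor(bg + 0.5), 0, 255).astype(np.uint8)
        corr_out = np.clip(np.floor(corrected + 0.5), 0, 255).astype(np.uint8)
    else:
        bg_out = bg
        corr_out = corrected
    return stack.with_voxels(bg_out), stack.with_voxels(corr_out)


def subtract_constant(stack: ImageStack, value: float) -> ImageStack:
    """Subtract a constant from every voxel, clamping at zero."""
    if not 0 <= value <= 255:
        raise ValueError("subtraction constant must lie in [0, 255]")
    out = np.clip(stack.voxels.astype(np.float64) - value, 0, None)
    if stack.bit_depth == 8:
        out = out.astype(np.uint8)
    return stack.with_voxels(out)


def _disc_footprint(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return xx**2 + yy**2 <= r**2


def median_filter(stack: ImageStack, radius: int = 1) -> ImageStack:
    """Per-slice median smoothing over a disc neighbourhood.

    Edges are handled by reflective padding.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    footprint = _disc_footprint(radius)
    out = np.empty_like(stack.voxels)
    for z in range(stack.shape[0]):
        out[z] = ndimage.median_filter(
            stack.voxels[z], footprint=footprint, mode="reflect"
        )
    return stack.with_voxels(out)


def enhance_contrast(stack: ImageStack, saturated_fraction: float = 0.0035) -> ImageStack:
    """Linear contrast stretch with a saturated pixel fraction.

    The ``saturated_fraction`` and ``1 - saturated_fraction`` intensity
    quantiles map to 0 and 255; values outside are clamped.  A degenerate
    quantile range leaves the stack unchanged with a warning.
    """
    if not 0 <= saturated_fraction < 0.5:
        raise ValueError("saturated_fraction must lie in [0, 0.5)")
    arr = stack.voxels.astype(np.float64)
    lo = np.quantile(arr, saturated_fraction)
    hi = np.quantile(arr, 1 - saturated_fraction)
    if hi <= lo:
        warnings.warn("degenerate intensity range; contrast enhancement is a no-op")
        return stack.with_voxels(stack.voxels.copy())
    stretched = np.clip(255.0 * (arr - lo) / (hi - lo), 0, 255)
    out = np.floor(stretched + 0.5).astype(np.uint8) if stack.bit_depth == 8 else stretched
    return stack.with_voxels(out)


def gaussian_blur(stack: ImageStack, sigma: float) -> ImageStack:
    """Per-slice 2-D Gaussian smoothing with reflective padding."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    arr = stack.voxels.astype(np.float64)
    out = np.empty_like(arr)
    for z in range(stack.shape[0]):
        out[z] = ndimage.gaussian_filter(arr[z], sigma=sigma, mode="reflect")
    if stack.bit_depth == 8:
        out = np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)
    return stack.with_voxels(out)


# ---------------------------------------------------------------------------
# thresholding


def moments_threshold(histogram: np.ndarray) -> int:
    """Tsai's moment-preserving automatic threshold on a gray-level histogram.

    The gray-level image is replaced by the two-level image that preserves
    its first three moments; the threshold is placed at the p-tile of the
    resulting background fraction (smallest bin whose cumulative fraction
    reaches it).  Invariant under uniform scaling of the counts.
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.ndim != 1 or hist.size == 0:
        raise ValueError("histogram must be a non-empty 1-D array")
    total = hist.sum()
    if total <= 0:
        raise ValueError("histogram has no counts")
    populated = np.nonzero(hist)[0]
    if populated.size == 1:
        return int(populated[0])

    levels = np.arange(hist.size, dtype=np.float64)
    p = hist / total
    m1 = np.sum(p * levels)
    m2 = np.sum(p * levels**2)
    m3 = np.sum(p * levels**3)

    # Solve for the two preserved levels z0 < z1 and the background fraction
    # p0 such that p0 + p1 = 1, p0 z0 + p1 z1 = m1, etc.
    cd = m2 - m1 * m1
    if cd <= 0:
        return int(populated[0])
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (-m3 + m2 * m1) / cd
    disc = c1 * c1 - 4.0 * c0
    disc = max(disc, 0.0)
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    if z1 == z0:
        return int(populated[0])
    p0 = (z1 - m1) / (z1 - z0)

    cumulative = np.cumsum(p)
    idx = np.searchsorted(cumulative, p0, side="left")
    return int(min(idx, hist.size - 1))


def stack_histogram(stack: ImageStack, bins: int = 256) -> np.ndarray:
    """256-bin intensity histogram over all voxels of an 8-bit stack."""
    return np.bincount(stack.voxels.ravel().astype(np.int64), minlength=bins)[:bins]


def binarize(stack: ImageStack, threshold: int) -> BinaryStack:
    """Foreground mask of voxels strictly above the threshold."""
    return BinaryStack(
        stack.voxels > threshold, pixel_size=stack.pixel_size, z_step=stack.z_step
    )


# ---------------------------------------------------------------------------
# particle analysis


def connected_components(
    binary: BinaryStack, connectivity: Literal["2d", "3d"] = "3d"
) -> ParticleSet:
    """Label connected foreground components and measure each particle.

    In 3-D mode voxels are 26-connected; in 2-D mode each slice is labelled
    independently with 8-connectivity.  Per particle: voxel count, volume
    (voxels x pixel_size^2 x z_step) and the maximum single-slice
    cross-sectional area (pixels in the largest slice x pixel_size^2).
    """
    mask = binary.voxels
    if connectivity == "3d":
        structure = np.ones((3, 3, 3), dtype=bool)
        labels, n = ndimage.label(mask, structure=structure)
    elif connectivity == "2d":
        structure2d = np.ones((3, 3), dtype=bool)
        labels = np.zeros(mask.shape, dtype=np.int64)
        n = 0
        for z in range(mask.shape[0]):
            lab, k = ndimage.label(mask[z], structure=structure2d)
            lab = lab.astype(np.int64)
            lab[lab > 0] += n
            labels[z] = lab
            n += k
    else:
        raise ValueError(f"unknown connectivity mode {connectivity!r}")

    px = binary.pixel_size
    dz = binary.z_step
    particles: list[Particle] = []
    if n > 0:
        idx = np.arange(1, n + 1)
        counts = ndimage.sum_labels(np.ones_like(labels), labels, idx)
        centroids = ndimage.center_of_mass(mask, labels, idx)
        # per-slice pixel counts for each label -> max cross-section
        max_slice = np.zeros(n, dtype=np.int64)
        for z in range(mask.shape[0]):
            sl = labels[z]
            if sl.any():
                c = np.bincount(sl.ravel(), minlength=n + 1)[1:]
                max_slice = np.maximum(max_slice, c)
        for i in idx:
            nv = int(counts[i - 1])
            vol = nv * px * px * dz if (px and dz) else float("nan")
            area = int(max_slice[i - 1]) * px * px if px else float("nan")
            particles.append(
                Particle(
                    label=int(i),
                    n_voxels=nv,
                    volume_um3=vol,
                    max_slice_area_um2=area,
                    centroid=tuple(float(v) for v in centroids[i - 1]),
                )
            )
    return ParticleSet(particles=particles, labels=labels)
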