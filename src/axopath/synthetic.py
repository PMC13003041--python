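"""Synthetic data with known ground truth for the neuropathology pipeline.

Two generators and one reconstruction utility:

* :func:`generate_image_stack` renders fluorescence-like z-stacks containing
  curvilinear fibres and ellipsoidal axonal swellings at recorded positions,
  so the swelling-detection pipeline can be scored against ground truth.
* :func:`generate_cohort` simulates per-animal cohort tables in which
  dopaminergic fibre optical density declines over time and swelling counts
  follow an inverted-U trajectory, with a faster male time course —
  the statistical structure the degeneration-staging analysis assumes.
* :func:`reconstruct_stage_scores` enumerates the per-animal stage-score
  vectors admissible under printed group summaries (mean, SD, n), which is
  how small published cohorts can be recovered exactly from a results table.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .image_ops import ImageStack

# ---------------------------------------------------------------------------
# image simulation


@dataclass
class ImageSimConfig:
    """Parameters of the fibre-plus-swelling stack simulation.

    Default calibration is 0.1 um/pixel in-plane with a 1 um z-step, under
    which the 0.53 um^2 particle-area filter corresponds to 53 pixels.
    ``swelling_radius_range`` sets the in-plane half-max radius (um) of
    swellings built to pass both particle filters; ``small_radius_range``
    the radius of sub-filter distractor swellings.
    """

    width: int = 144
    height: int = 144
    depth: int = 10
    pixel_size: float = 0.1  # um / pixel
    z_step: float = 1.0  # um
    n_fibres: int = 8
    fibre_intensity: float = 60.0  # 8-bit units
    n_swellings_large: int = 12
    n_swellings_small: int = 5
    swelling_radius_range: tuple[float, float] = (0.5, 0.8)  # um, half-max
    small_radius_range: tuple[float, float] = (0.15, 0.25)  # um, half-max
    swelling_intensity: float = 180.0
    background_gradient_amplitude: float = 10.0
    noise_sd: float = 3.0
    seed: int = 0
    render: str = "fluorescence"  # or "brightfield"
    on_boundary: str = "reposition"  # or "error"

    def __post_init__(self) -> None:
        if min(self.width, self.height, self.depth) <= 0:
            raise ValueError("stack dimensions must be positive")
        if self.pixel_size <= 0 or self.z_step <= 0:
            raise ValueError("calibration must be positive")
        for rng in (self.swelling_radius_range, self.small_radius_range):
            if not (0 < rng[0] <= rng[1]):
                raise ValueError("radius ranges must be positive and ordered")
        if min(self.n_fibres, self.n_swellings_large, self.n_swellings_small) < 0:
            raise ValueError("object counts must be non-negative")
        if self.render not in ("fluorescence", "brightfield"):
            raise ValueError("render must be 'fluorescence' or 'brightfield'")
        if self.on_boundary not in ("reposition", "error"):
            raise ValueError("on_boundary must be 'reposition' or 'error'")


@dataclass
class GroundTruth:
    """Recorded geometry of every simulated swelling plus fibre paths.

    ``swelling_centres`` are (x, y, z) positions in micrometres;
    ``passes_filter`` flags objects that satisfy the particle filters
    (max single-slice area > ``min_area`` and voxel count >= ``min_voxels``)
    evaluated on the half-maximum support at the configured calibration.
    """

    swelling_centres: list[tuple[float, float, float]] = field(default_factory=list)
    swelling_radii_um: list[tuple[float, float]] = field(default_factory=list)  # (r_xy, r_z)
    swelling_volumes: list[float] = field(default_factory=list)  # um^3, half-max support
    passes_filter: list[bool] = field(default_factory=list)
    fibre_paths: list[np.ndarray] = field(default_factory=list)

    @property
    def n_objects(self) -> int:
        return len(self.swelling_centres)

    @property
    def n_passing(self) -> int:
        return int(np.sum(self.passes_filter))


def _halfmax_support_metrics(
    r_xy_um: float, r_z_um: float, pixel_size: float, z_step: float
) -> tuple[int, float, float]:
    """Voxel count, max slice area (um^2) and volume (um^3) of the
    half-maximum ellipsoid of a swelling centred on a voxel centre."""
    rx = r_xy_um / pixel_size  # pixels
    rz = r_z_um / z_step  # slices
    nx = int(np.ceil(rx)) + 1
    nz = int(np.ceil(rz)) + 1
    zz, yy, xx = np.mgrid[-nz : nz + 1, -nx : nx + 1, -nx : nx + 1]
    inside = (xx / rx) ** 2 + (yy / rx) ** 2 + (zz / max(rz, 1e-9)) ** 2 <= 1.0
    n_vox = int(inside.sum())
    max_slice = int(inside.sum(axis=(1, 2)).max())
    area = max_slice * pixel_size**2
    volume = n_vox * pixel_size**2 * z_step
    return n_vox, area, volume


def swelling_passes_filter(
    r_xy_um: float,
    r_z_um: float,
    pixel_size: float,
    z_step: float,
    min_area: float = 0.53,
    min_voxels: int = 5,
) -> bool:
    """Whether a swelling of the given half-max radii satisfies the particle
    filters (area strictly greater, voxel count at least)."""
    n_vox, area, _ = _halfmax_support_metrics(r_xy_um, r_z_um, pixel_size, z_step)
    return area > min_area and n_vox >= min_voxels


def _stamp_gaussian_blob(
    canvas: np.ndarray,
    centre: tuple[float, float, float],  # (z, y, x) voxel coords
    sigma_xy: float,
    sigma_z: float,
    amplitude: float,
) -> None:
    """Add an anisotropic Gaussian truncated at 2 sigma onto the canvas."""
    cz, cy, cx = centre
    ez = max(int(np.ceil(2 * sigma_z)), 0)
    exy = int(np.ceil(2 * sigma_xy))
    z0, z1 = max(int(cz) - ez, 0), min(int(cz) + ez + 1, canvas.shape[0])
    y0, y1 = max(int(cy) - exy, 0), min(int(cy) + exy + 1, canvas.shape[1])
    x0, x1 = max(int(cx) - exy, 0), min(int(cx) + exy + 1, canvas.shape[2])
    zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1]
    d2 = ((xx - cx) / sigma_xy) ** 2 + ((yy - cy) / sigma_xy) ** 2 + (
        (zz - cz) / max(sigma_z, 1e-9)
    ) ** 2
    blob = amplitude * np.exp(-0.5 * d2)
    blob[d2 > 4.0] = 0.0  # truncation at 2 sigma
    region = canvas[z0:z1, y0:y1, x0:x1]
    np.maximum(region, blob, out=region)


def _render_fibres(config: ImageSimConfig, rng: np.random.Generator) -> tuple[np.ndarray, list[np.ndarray]]:
    """Curvilinear tubes of sub-filter calibre, as a max-combined canvas."""
    canvas = np.zeros((config.depth, config.height, config.width))
    sigma = max(0.08 / config.pixel_size, 0.6)  # ~0.16 um calibre
    paths = []
    for _ in range(config.n_fibres):
        x = rng.uniform(0, config.width)
        y = rng.uniform(0, config.height)
        z = rng.uniform(0, config.depth)
        angle = rng.uniform(0, 2 * np.pi)
        pts = []
        n_steps = int(1.5 * max(config.width, config.height))
        for _ in range(n_steps):
            pts.append((x, y, z))
            angle += rng.normal(0, 0.15)
            x += np.cos(angle)
            y += np.sin(angle)
            z += rng.normal(0, 0.05)
            if not (0 <= x < config.width and 0 <= y < config.height):
                break
            z = float(np.clip(z, 0, config.depth - 1))
        path = np.array(pts)
        paths.append(path)
        for px, py, pz in pts:
            zi = int(round(pz))
            if not 0 <= zi < config.depth:
                continue
            # peak on the pixel grid so the tube's maximum equals the
            # configured fibre intensity exactly
            px, py = round(px), round(py)
            e = int(np.ceil(2 * sigma))
            y0, y1 = max(int(py) - e, 0), min(int(py) + e + 1, config.height)
            x0, x1 = max(int(px) - e, 0), min(int(px) + e + 1, config.width)
            if y0 >= y1 or x0 >= x1:
                continue
            yy, xx = np.mgrid[y0:y1, x0:x1]
            prof = config.fibre_intensity * np.exp(
                -0.5 * (((xx - px) / sigma) ** 2 + ((yy - py) / sigma) ** 2)
            )
            np.maximum(canvas[zi, y0:y1, x0:x1], prof, out=canvas[zi, y0:y1, x0:x1])
    return canvas, paths


def generate_image_stack(config: ImageSimConfig) -> tuple[ImageStack, GroundTruth]:
    """Render a calibrated stack and its swelling ground truth.

    Deterministic for a fixed seed.  Fibres are thin bright tubes; swellings
    are anisotropic Gaussian blobs truncated at 2 sigma, either large enough
    to satisfy both particle filters or small enough to fail at least one.
    A smooth background gradient and i.i.d. Gaussian pixel noise are added.
    ``render='brightfield'`` photometrically inverts the result, emulating
    transmitted-light immunostain acquisition (dark signal, bright field).
    """
    rng = np.random.default_rng(config.seed)
    signal = np.zeros((config.depth, config.height, config.width))

    fibre_canvas, fibre_paths = _render_fibres(config, rng)
    np.maximum(signal, fibre_canvas, out=signal)

    gt = GroundTruth(fibre_paths=fibre_paths)
    placed: list[tuple[float, float, float]] = []  # (y, x, margin) pixel coords

    def place(radius_range: tuple[float, float], want_pass: bool) -> None:
        for attempt in range(10000):
            r_xy = rng.uniform(*radius_range)
            r_z = min(r_xy, 0.6 * config.z_step) if want_pass else 0.4 * config.z_step
            # half-max radius r relates to sigma by r = sigma * sqrt(2 ln 2)
            sigma_xy = (r_xy / config.pixel_size) / np.sqrt(2 * np.log(2))
            sigma_z = (r_z / config.z_step) / np.sqrt(2 * np.log(2))
            margin_xy = 2 * sigma_xy + 2
            margin_z = max(2 * sigma_z, 0.5)
            if config.on_boundary == "error":
                cx = rng.uniform(0, config.width)
                cy = rng.uniform(0, config.height)
                cz = rng.uniform(0, config.depth - 1)
                if not (
                    margin_xy <= cx <= config.width - margin_xy
                    and margin_xy <= cy <= config.height - margin_xy
                    and margin_z <= cz <= config.depth - 1 - margin_z
                ):
                    raise ValueError("object would overlap the stack boundary")
            else:
                cx = rng.uniform(margin_xy, config.width - margin_xy)
                cy = rng.uniform(margin_xy, config.height - margin_xy)
                cz = rng.uniform(margin_z, config.depth - 1 - margin_z)
            if any(
                np.hypot(cy - py, cx - px) < margin_xy + pm + 3
                for py, px, pm in placed
            ):
                continue
            ok = swelling_passes_filter(r_xy, r_z, config.pixel_size, config.z_step)
            if ok != want_pass:
                continue
            placed.append((cy, cx, margin_xy))
            _stamp_gaussian_blob(
                signal, (cz, cy, cx), sigma_xy, sigma_z, config.swelling_intensity
            )
            n_vox, _, vol = _halfmax_support_metrics(
                r_xy, r_z, config.pixel_size, config.z_step
            )
            gt.swelling_centres.append(
                (cx * config.pixel_size, cy * config.pixel_size, cz * config.z_step)
            )
            gt.swelling_radii_um.append((r_xy, r_z))
            gt.swelling_volumes.append(vol)
            gt.passes_filter.append(want_pass)
            return
        raise RuntimeError("could not place swelling without boundary overlap")

    for _ in range(config.n_swellings_large):
        place(config.swelling_radius_range, want_pass=True)
    for _ in range(config.n_swellings_small):
        place(config.small_radius_range, want_pass=False)

    # smooth background: tilted plane scaled to the gradient amplitude
    yy, xx = np.mgrid[0 : config.height, 0 : config.width]
    gx, gy = rng.uniform(-1, 1, size=2)
    plane = gx * xx / config.width + gy * yy / config.height
    if np.ptp(plane) > 0:
        plane = (plane - plane.min()) / np.ptp(plane)
    background = config.background_gradient_amplitude * plane

    img = signal + background[np.newaxis, :, :]
    if config.noise_sd > 0:
        img = img + rng.normal(0, config.noise_sd, size=img.shape)
    img = np.clip(img, 0, 255)
    if config.render == "brightfield":
        img = 255.0 - img
    voxels = np.floor(img + 0.5).astype(np.uint8)
    stack = ImageStack(
        voxels=voxels, bit_depth=8, pixel_size=config.pixel_size, z_step=config.z_step
    )
    return stack, gt


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class CohortSimConfig:
    """Animal-level cohort simulation parameters.

    Defaults emulate a two-time-point (60/120 days) viral-overexpression
    design with 5 animals per sex x group x time point, a progressive loss
    of fibre optical density that starts earlier in males, and swelling
    counts following a sex-specific inverted-U time profile (peaking at the
    early time point in males and the late one in females).  Empty-vector
    controls keep baseline optical density and present no swellings.
    """

    n_per_cell: int = 5
    timepoints: tuple[int, ...] = (60, 120)
    th_baseline: float = 100.0  # arbitrary OD units
    th_decline_male: tuple[float, ...] = (35.0, 45.0)  # per time point
    th_decline_female: tuple[float, ...] = (12.0, 40.0)
    swelling_peak_time_male: float = 60.0  # days
    swelling_peak_time_female: float = 120.0
    swelling_peak_mean: float = 250.0  # counts per animal at the peak
    swelling_width_days: float = 45.0
    dispersion: float = 8.0  # negative-binomial size parameter
    od_noise_sd: float = 7.0
    weight_params: dict = field(
        default_factory=lambda: {"male": (23.0, 1.5), "female": (19.0, 1.5)}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_cell < 2:
            raise ValueError("n_per_cell must be >= 2")
        if self.swelling_peak_mean < 0:
            raise ValueError("swelling means must be non-negative")
        if len(self.th_decline_male) != len(self.timepoints) or len(
            self.th_decline_female
        ) != len(self.timepoints):
            raise ValueError("one TH decline value per time point is required")
        if self.swelling_peak_time_male > self.swelling_peak_time_female:
            raise ValueError(
                "male swelling peak must not come after the female peak "
                "(male-earlier progression)"
            )
        if self.dispersion <= 0 or self.od_noise_sd < 0:
            raise ValueError("dispersion must be positive, od_noise_sd non-negative")


COHORT_COLUMNS = [
    "animal_id",
    "sex",
    "group",
    "timepoint_days",
    "th_od",
    "swelling_count",
    "swelling_median_volume_um3",
    "weight_g",
]


def _nbinom_draw(rng: np.random.Generator, mean: float, size_param: float) -> int:
    """Negative binomial with the (mean, dispersion) parameterisation:
    var = mean + mean^2 / dispersion."""
    if mean <= 0:
        return 0
    p = size_param / (size_param + mean)
    return int(rng.negative_binomial(size_param, p))


def generate_cohort(config: CohortSimConfig) -> pd.DataFrame:
    """Simulate a per-animal cohort table.

    One row per animal across sex x group (a53t / empty) x time point.
    TH optical density is normal around a sex- and time-dependent mean;
    swelling counts are negative-binomial around a sex-specific inverted-U
    time profile.  Controls carry zero swellings and baseline TH means.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    counter = 0
    declines = {"male": config.th_decline_male, "female": config.th_decline_female}
    peaks = {
        "male": config.swelling_peak_time_male,
        "female": config.swelling_peak_time_female,
    }
    for t_idx, t in enumerate(config.timepoints):
        for sex in ("male", "female"):
            for group in ("a53t", "empty"):
                for _ in range(config.n_per_cell):
                    counter += 1
                    w_mean, w_sd = config.weight_params[sex]
                    weight = rng.normal(w_mean, w_sd)
                    if group == "a53t":
                        th_mean = config.th_baseline - declines[sex][t_idx]
                        sw_mean = config.swelling_peak_mean * np.exp(
                            -(((t - peaks[sex]) / config.swelling_width_days) ** 2)
                        )
                        count = _nbinom_draw(rng, sw_mean, config.dispersion)
                        med_vol = max(rng.normal(2.0, 0.5), 0.2) if count else np.nan
                    else:
                        th_mean = config.th_baseline
                        count = 0
                        med_vol = np.nan
                    th = rng.normal(th_mean, config.od_noise_sd)
                    rows.append(
                        {
                            "animal_id": f"A{counter:03d}",
                            "sex": sex,
                            "group": group,
                            "timepoint_days": t,
                            "th_od": th,
                            "swelling_count": count,
                            "swelling_median_volume_um3": med_vol,
                            "weight_g": weight,
                        }
                    )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


# ---------------------------------------------------------------------------
# reconstruction of stage scores from printed group summaries


@dataclass
class ScoreReconstruction:
    """All stage-score multisets consistent with a printed mean, ranked by
    closeness of their sample SD to the printed SD."""

    candidates: list[tuple[tuple[int, ...], float]]  # (scores, sample SD)
    printed_mean: float
    printed_sd: float
    n: int

    @property
    def best(self) -> tuple[int, ...] | None:
        return self.candidates[0][0] if self.candidates else None

    @property
    def tied(self) -> bool:
        if len(self.candidates) < 2:
            return False
        d0 = abs(self.candidates[0][1] - self.printed_sd)
        d1 = abs(self.candidates[1][1] - self.printed_sd)
        return np.isclose(d0, d1)

    @property
    def unique(self) -> bool:
        return len(self.candidates) == 1


def reconstruct_stage_scores(
    mean: float, sd: float, n: int, decimals: int = 1
) -> ScoreReconstruction:
    """Enumerate stage-score vectors in {1,2,3}^n matching a printed summary.

    All multisets whose mean rounds to the printed mean (at the printed
    precision) are returned, ordered by |sample SD - printed SD|; exact
    SD ties are preserved in order of enumeration, not broken.  An empty
    candidate list means no admissible vector exists.
    """
    if n > 15:
        raise ValueError("n must be <= 15 for exhaustive enumeration")
    if n < 1:
        raise ValueError("n must be >= 1")
    candidates = []
    for combo in itertools.combinations_with_replacement((1, 2, 3), n):
        v = np.asarray(combo, dtype=float)
        if round(float(v.mean()), decimals) == round(mean, decimals):
            s = float(v.std(ddof=1)) if n > 1 else 0.0
            candidates.append((combo, s))
    candidates.sort(key=lambda c: abs(c[1] - sd))
    return ScoreReconstruction(
        candidates=candidates, printed_mean=mean, printed_sd=sd, n=n
    )


# ---------------------------------------------------------------------------
# on-disk fixtures


def write_stack(stack: ImageStack, gt: GroundTruth, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF with a JSON calibration/ground-truth
    sidecar (same stem, ``.json`` suffix)."""
    path = Path(path)
    tifffile.imwrite(path, stack.voxels, photometric="minisblack")
    sidecar = {
        "pixel_size_um": stack.pixel_size,
        "z_step_um": stack.z_step,
        "bit_depth": stack.bit_depth,
        "swelling_centres_um": [list(c) for c in gt.swelling_centres],
        "swelling_radii_um": [list(r) for r in gt.swelling_radii_um],
        "swelling_volumes_um3": gt.swelling_volumes,
        "passes_filter": gt.passes_filter,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_stack(path: str | Path) -> tuple[ImageStack, dict]:
    """Read a TIFF stack; calibration comes from the JSON sidecar when
    present, otherwise defaults apply."""
    path = Path(path)
    voxels = tifffile.imread(path)
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    stack = ImageStack(
        voxels=voxels,
        bit_depth=meta.get("bit_depth", 8),
        pixel_size=meta.get("pixel_size_um", 0.1),
        z_step=meta.get("z_step_um", 1.0),
    )
    return stack, meta


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cohort.to_csv(path, index=False)
    return path
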