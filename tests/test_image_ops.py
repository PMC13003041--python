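"""Unit and property tests of the slice-wise image operators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from axopath.image_ops import (
    BinaryStack,
    ImageStack,
    _ball_structure,
    binarize,
    connected_components,
    enhance_contrast,
    gaussian_blur,
    invert,
    median_filter,
    moments_threshold,
    rolling_ball_background,
    stack_histogram,
    subtract_constant,
    to_uint8,
)


def stack8(arr, **kw):
    return ImageStack(np.asarray(arr, dtype=np.uint8), bit_depth=8, **kw)


# ---------------------------------------------------------------------------
# intensity rescaling and inversion


class TestToUint8:
    def test_full_range_endpoints(self):
        s = ImageStack(np.array([[[0, 65535]]], dtype=np.uint16), bit_depth=16)
        assert to_uint8(s).voxels.tolist() == [[[0, 255]]]

    def test_constant_maps_to_zero(self):
        s = ImageStack(np.full((1, 4, 4), 7000, dtype=np.uint16), bit_depth=16)
        assert (to_uint8(s).voxels == 0).all()

    def test_rounding_half_away_from_zero(self):
        # round(255 * 100 / 200) = round(127.5) -> 128
        s = ImageStack(np.array([[[0, 100, 200]]], dtype=np.uint16), bit_depth=16)
        assert to_uint8(s).voxels.tolist() == [[[0, 128, 255]]]


class TestInvert:
    def test_zero_goes_to_255(self):
        assert (invert(stack8(np.zeros((1, 3, 3)))).voxels == 255).all()

    def test_pair_values(self):
        out = invert(stack8([[[10, 245]]]))
        assert out.voxels.tolist() == [[[245, 10]]]

    def test_rejects_16bit(self):
        s = ImageStack(np.zeros((1, 2, 2), dtype=np.uint16), bit_depth=16)
        with pytest.raises(ValueError):
            invert(s)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_involution(self, seed):
        arr = np.random.default_rng(seed).integers(0, 256, (2, 8, 8), dtype=np.uint8)
        s = stack8(arr)
        assert (invert(invert(s)).voxels == arr).all()


# ---------------------------------------------------------------------------
# rolling ball


def brute_force_ball_opening(img, radius):
    """Reference grayscale opening: explicit erode-then-dilate loops over the
    ball-height structuring element with symmetric (reflective) padding."""
    fp, h = _ball_structure(radius)
    r = radius
    offs = [
        (dy - r, dx - r, h[dy, dx])
        for dy in range(2 * r + 1)
        for dx in range(2 * r + 1)
        if fp[dy, dx]
    ]
    pad = np.pad(img.astype(float), r, mode="symmetric")
    ny, nx = img.shape
    eroded = np.empty((ny, nx))
    for y in range(ny):
        for x in range(nx):
            eroded[y, x] = min(pad[y + r + dy, x + r + dx] - hh for dy, dx, hh in offs)
    pad_e = np.pad(eroded, r, mode="symmetric")
    opened = np.empty((ny, nx))
    for y in range(ny):
        for x in range(nx):
            opened[y, x] = max(pad_e[y + r + dy, x + r + dx] + hh for dy, dx, hh in offs)
    return opened


class TestRollingBall:
    def test_flat_slice_background_equals_value(self):
        s = stack8(np.full((1, 16, 16), 37))
        bg, corr = rolling_ball_background(s, 3)
        assert (bg.voxels == 37).all()
        assert (corr.voxels == 0).all()

    def test_single_pixel_spike_preserved(self):
        img = np.zeros((1, 24, 24))
        img[0, 12, 12] = 200
        bg, corr = rolling_ball_background(stack8(img), 5)
        assert corr.voxels[0, 12, 12] >= 190
        assert bg.voxels[0, 12, 12] <= 10

    def test_matches_brute_force_opening(self, rng):
        img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        s = ImageStack(img[np.newaxis], bit_depth=8)
        bg, _ = rolling_ball_background(s, 3)
        expected = brute_force_ball_opening(img, 3)
        assert np.abs(bg.voxels[0].astype(float) - expected).max() <= 0.5

    def test_background_below_original_and_residual_identity(self, small_stack):
        bg, corr = rolling_ball_background(small_stack, 4)
        orig = small_stack.voxels.astype(int)
        assert (bg.voxels.astype(int) <= orig + 1).all()
        assert (corr.voxels >= 0).all()
        # corrected + background reproduces the original up to rounding
        assert np.abs(corr.voxels.astype(int) + bg.voxels.astype(int) - orig).max() <= 1

    def test_opening_is_idempotent(self, small_stack):
        bg, _ = rolling_ball_background(small_stack, 4)
        bg2, _ = rolling_ball_background(bg, 4)
        assert np.abs(bg2.voxels.astype(int) - bg.voxels.astype(int)).max() <= 1

    def test_radius_exceeding_slice_rejected(self):
        with pytest.raises(ValueError):
            rolling_ball_background(stack8(np.zeros((1, 8, 8))), 10)


# ---------------------------------------------------------------------------
# pointwise operators


class TestSubtractConstant:
    @pytest.mark.parametrize(
        "values, const, expected",
        [([5, 200], 50, [0, 150]), ([10, 10], 10, [0, 0]), ([3, 9], 0, [3, 9])],
    )
    def test_examples(self, values, const, expected):
        out = subtract_constant(stack8([[values]]), const)
        assert out.voxels.tolist() == [[expected]]

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            subtract_constant(stack8(np.zeros((1, 2, 2))), 300)


class TestMedianFilter:
    def test_constant_unchanged(self):
        s = stack8(np.full((2, 8, 8), 99))
        assert (median_filter(s, 1).voxels == 99).all()

    def test_impulse_removed(self):
        img = np.zeros((1, 9, 9))
        img[0, 4, 4] = 255
        assert median_filter(stack8(img), 1).voxels[0, 4, 4] == 0

    def test_matches_per_pixel_sort_oracle(self, rng):
        img = rng.integers(0, 256, (5, 5)).astype(np.uint8)
        out = median_filter(stack8(img[np.newaxis]), 1).voxels[0]
        pad = np.pad(img.astype(float), 1, mode="symmetric")
        offs = [(-1, 0), (1, 0), (0, -1), (0, 1), (0, 0)]  # disc radius 1
        for y in range(5):
            for x in range(5):
                vals = sorted(pad[y + 1 + dy, x + 1 + dx] for dy, dx in offs)
                assert out[y, x] == vals[len(vals) // 2]


class TestEnhanceContrast:
    def test_full_range_zero_saturation_is_identity(self):
        img = np.zeros((1, 16, 16))
        img[0, 0, 0] = 255
        out = enhance_contrast(stack8(img), 0.0)
        assert (out.voxels == img).all()

    def test_two_value_stretch(self):
        out = enhance_contrast(stack8([[[50, 100]]]), 0.0)
        assert out.voxels.tolist() == [[[0, 255]]]

    def test_ramp_matches_closed_form(self):
        ramp = np.tile(np.arange(256, dtype=np.uint8), (4, 1))
        out = enhance_contrast(stack8(ramp[np.newaxis]), 0.1).voxels[0]
        lo = np.quantile(ramp, 0.1)
        hi = np.quantile(ramp, 0.9)
        expected = np.clip(255.0 * (ramp - lo) / (hi - lo), 0, 255)
        expected = np.floor(expected + 0.5).astype(np.uint8)
        assert (out == expected).all()

    def test_degenerate_range_warns_and_is_identity(self):
        s = stack8(np.full((1, 4, 4), 12))
        with pytest.warns(UserWarning):
            out = enhance_contrast(s, 0.0)
        assert (out.voxels == 12).all()


class TestGaussianBlur:
    def test_constant_unchanged(self):
        s = stack8(np.full((1, 16, 16), 80))
        assert (gaussian_blur(s, 2.0).voxels == 80).all()

    def test_impulse_yields_discrete_kernel(self):
        img = np.zeros((1, 33, 33))
        img[0, 16, 16] = 10000.0
        s = ImageStack(img, bit_depth=16)
        out = gaussian_blur(s, 2.0).voxels[0]
        centre = out[16, 16]
        # ratio of neighbour to centre follows exp(-d^2 / (2 sigma^2))
        assert out[16, 17] / centre == pytest.approx(np.exp(-1 / 8), rel=1e-3)
        assert out[17, 17] / centre == pytest.approx(np.exp(-2 / 8), rel=1e-3)
        assert out.sum() == pytest.approx(10000.0, rel=1e-6)

    def test_large_sigma_approaches_mean(self, rng):
        img = rng.integers(0, 256, (24, 24)).astype(float)
        s = ImageStack(img[np.newaxis], bit_depth=16)
        out = gaussian_blur(s, 50.0).voxels[0]
        assert np.abs(out - img.mean()).max() < 30


# ---------------------------------------------------------------------------
# moment-preserving threshold


def symbolic_moments_threshold(hist):
    """Independent re-derivation: solve the moment-preservation system with
    sympy and place the threshold at the background-fraction p-tile."""
    import sympy as sp

    hist = np.asarray(hist, dtype=float)
    p = hist / hist.sum()
    lv = np.arange(hist.size)
    m1, m2, m3 = (float(np.sum(p * lv**k)) for k in (1, 2, 3))
    z0, z1, p0 = sp.symbols("z0 z1 p0", real=True)
    sols = sp.solve(
        [
            p0 * z0 + (1 - p0) * z1 - m1,
            p0 * z0**2 + (1 - p0) * z1**2 - m2,
            p0 * z0**3 + (1 - p0) * z1**3 - m3,
        ],
        [z0, z1, p0],
        dict=True,
    )
    sols = [s for s in sols if s[z0] < s[z1]]
    assert sols, "no real moment-preserving solution"
    frac = float(sols[0][p0])
    cum = np.cumsum(p)
    return int(np.searchsorted(cum, frac, side="left"))


class TestMomentsThreshold:
    def test_two_spike_histogram_separates(self):
        hist = np.zeros(256)
        hist[50] = 100
        hist[200] = 100
        t = moments_threshold(hist)
        assert 50 <= t < 200

    def test_single_bin_returns_it(self):
        hist = np.zeros(256)
        hist[7] = 42
        assert moments_threshold(hist) == 7

    def test_matches_symbolic_rederivation(self, rng):
        for _ in range(5):
            hist = rng.integers(0, 50, size=20).astype(float)
            hist[hist.sum() == 0] = 1
            if np.count_nonzero(hist) < 2:
                continue
            assert moments_threshold(hist) == symbolic_moments_threshold(hist)

    @given(st.integers(1, 1000))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_invariant_under_count_scaling(self, scale):
        hist = np.zeros(64)
        hist[[3, 17, 40, 60]] = [5, 9, 2, 7]
        assert moments_threshold(hist) == moments_threshold(hist * scale)


# ---------------------------------------------------------------------------
# connected components


def flood_fill_count(mask):
    """Independent 26-connected component count by explicit BFS."""
    mask = mask.astype(bool)
    seen = np.zeros_like(mask)
    count = 0
    dims = mask.shape
    neigh = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        count += 1
        queue = [start]
        seen[start] = True
        while queue:
            z, y, x = queue.pop()
            for dz, dy, dx in neigh:
                nz, ny, nx = z + dz, y + dy, x + dx
                if (
                    0 <= nz < dims[0]
                    and 0 <= ny < dims[1]
                    and 0 <= nx < dims[2]
                    and mask[nz, ny, nx]
                    and not seen[nz, ny, nx]
                ):
                    seen[nz, ny, nx] = True
                    queue.append((nz, ny, nx))
    return count


class TestConnectedComponents:
    def test_empty_stack(self):
        ps = connected_components(BinaryStack(np.zeros((3, 4, 4), bool)))
        assert len(ps) == 0

    def test_diagonal_voxels_across_slices_are_one_particle(self):
        mask = np.zeros((2, 3, 3), bool)
        mask[0, 1, 1] = True
        mask[1, 2, 2] = True  # 26-connected diagonal touch
        ps = connected_components(BinaryStack(mask))
        assert len(ps) == 1
        assert ps.particles[0].n_voxels == 2

    def test_label_count_matches_flood_fill_oracle(self, rng):
        mask = rng.random((16, 16, 16)) < 0.2
        ps = connected_components(BinaryStack(mask))
        assert len(ps) == flood_fill_count(mask)

    def test_voxel_counts_sum_to_foreground(self, rng):
        mask = rng.random((8, 20, 20)) < 0.3
        ps = connected_components(BinaryStack(mask))
        assert ps.total_voxels == int(mask.sum())

    def test_physical_measurements(self):
        mask = np.zeros((2, 4, 4), bool)
        mask[0, :2, :2] = True  # 4 px slice
        mask[1, 0, 0] = True
        ps = connected_components(BinaryStack(mask, pixel_size=0.1, z_step=1.0))
        p = ps.particles[0]
        assert p.n_voxels == 5
        assert p.volume_um3 == pytest.approx(5 * 0.01 * 1.0)
        assert p.max_slice_area_um2 == pytest.approx(4 * 0.01)

    def test_2d_mode_separates_slices(self):
        mask = np.zeros((2, 3, 3), bool)
        mask[:, 1, 1] = True
        assert len(connected_components(BinaryStack(mask), connectivity="2d")) == 2

    def test_threshold_monotonicity_end_to_end(self, small_stack):
        counts = []
        for t in (40, 120, 200):
            fg = int(binarize(small_stack, t).voxels.sum())
            counts.append(fg)
        assert counts == sorted(counts, reverse=True)


def test_histogram_covers_all_voxels(small_stack):
    hist = stack_histogram(small_stack)
    assert hist.sum() == small_stack.voxels.size
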