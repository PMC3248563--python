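"""Unit and property tests for the image-stack operators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormtriage.errors import (
    DegenerateFrameError,
    DimensionError,
    InsufficientFramesError,
    NoContrastError,
)
from wormtriage.imaging import (
    Blob,
    FrameStack,
    blob_geometry,
    deflicker,
    estimate_background,
    label_components,
    max_feret_px,
    otsu_threshold,
    skeleton_longest_path_px,
    subtract_background,
)


def make_stack(frames, interval=0.2, px=10.0):
    return FrameStack(np.asarray(frames, dtype=float), interval, px)


class TestFrameStack:
    def test_rejects_negative_and_nonfinite_intensities(self):
        with pytest.raises(ValueError):
            make_stack(-np.ones((2, 4, 4)))
        with pytest.raises(ValueError):
            make_stack(np.full((2, 4, 4), np.nan))

    def test_rejects_bad_calibration(self):
        with pytest.raises(ValueError):
            FrameStack(np.ones((2, 4, 4)), 0.0, 1.0)
        with pytest.raises(ValueError):
            FrameStack(np.ones((2, 4, 4)), 0.2, -1.0)

    def test_rejects_non_3d(self):
        with pytest.raises(DimensionError):
            make_stack(np.ones((4, 4)))


class TestDeflicker:
    def test_known_frame_means_rescale_to_global_mean(self):
        stack = make_stack(
            [np.full((6, 6), 100.0), np.full((6, 6), 50.0), np.full((6, 6), 200.0)]
        )
        out = deflicker(stack)
        means = out.frames.mean(axis=(1, 2))
        assert np.allclose(means, 350.0 / 3.0)
        # scale factors 7/6, 7/3, 7/12
        assert np.allclose(out.frames[1] / stack.frames[1], 7.0 / 3.0)

    def test_uniform_stack_is_identity(self):
        stack = make_stack(np.full((4, 5, 5), 80.0))
        out = deflicker(stack)
        assert np.allclose(out.frames, stack.frames)

    def test_preserves_total_mean_and_is_idempotent(self):
        rng = np.random.default_rng(0)
        stack = make_stack(rng.uniform(10, 200, size=(6, 8, 8)))
        once = deflicker(stack)
        twice = deflicker(once)
        assert np.isclose(once.frames.mean(), stack.frames.mean())
        assert np.allclose(twice.frames, once.frames, rtol=1e-12)

    def test_zero_mean_frame_names_index(self):
        frames = np.ones((3, 4, 4))
        frames[1] = 0.0
        with pytest.raises(DegenerateFrameError) as err:
            deflicker(make_stack(frames))
        assert err.value.frame_index == 1


class TestBackground:
    def test_per_pixel_maximum(self):
        frames = np.zeros((3, 2, 2))
        frames[:, 0, 0] = (10, 80, 80)
        frames[:, 1, 1] = (5, 5, 5)
        bg = estimate_background(make_stack(frames))
        assert bg[0, 0] == 80
        assert bg[1, 1] == 5

    def test_constant_stack_background_equals_any_frame(self):
        stack = make_stack(np.full((4, 3, 3), 42.0))
        assert np.array_equal(estimate_background(stack), stack.frames[0])

    def test_single_frame_is_insufficient(self):
        with pytest.raises(InsufficientFramesError):
            estimate_background(make_stack(np.ones((1, 4, 4))))

    def test_subtraction_is_clamped_at_zero(self):
        frames = np.array([[[30.0, 90.0]]])
        bg = np.array([[80.0, 80.0]])
        out = subtract_background(make_stack(frames), bg)
        assert out.frames[0, 0, 0] == 50.0
        assert out.frames[0, 0, 1] == 0.0

    def test_subtraction_shape_mismatch(self):
        with pytest.raises(DimensionError):
            subtract_background(make_stack(np.ones((2, 4, 4))), np.ones((3, 3)))

    def test_output_bounded_by_background(self):
        rng = np.random.default_rng(1)
        stack = make_stack(rng.uniform(0, 100, (5, 6, 6)))
        bg = estimate_background(stack)
        out = subtract_background(stack, bg)
        assert (out.frames >= 0).all()
        assert (out.frames <= bg[None] + 1e-9).all()


def brute_force_otsu(image):
    """Independent oracle: exhaustive intra-class-variance minimization over
    the same 256-bin histogram."""
    values = np.asarray(image, dtype=float).ravel()
    lo, hi = values.min(), values.max()
    hist, edges = np.histogram(values, bins=256, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_k, best_var = None, np.inf
    for k in range(255):
        w0 = hist[: k + 1].sum()
        w1 = hist[k + 1:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[: k + 1] * centers[: k + 1]).sum() / w0
        m1 = (hist[k + 1:] * centers[k + 1:]).sum() / w1
        v0 = (hist[: k + 1] * (centers[: k + 1] - m0) ** 2).sum() / w0
        v1 = (hist[k + 1:] * (centers[k + 1:] - m1) ** 2).sum() / w1
        var = (w0 * v0 + w1 * v1) / (w0 + w1)
        if var < best_var - 1e-12:
            best_var, best_k = var, k
    return edges[best_k + 1]


class TestOtsu:
    def test_two_value_image(self):
        img = np.full(100, 20.0)
        img[:10] = 200.0
        thr = otsu_threshold(img.reshape(10, 10))
        assert 20 < thr < 200
        assert (img > thr).mean() == 0.10

    def test_matches_exhaustive_oracle_on_gaussian_mixture(self):
        rng = np.random.default_rng(7)
        img = np.concatenate(
            [rng.normal(40, 8, 3000), rng.normal(150, 15, 1096)]
        ).reshape(64, 64)
        assert otsu_threshold(img) == pytest.approx(brute_force_otsu(img), abs=1e-12)

    def test_agrees_with_skimage_within_one_bin(self):
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(3)
        img = np.concatenate([rng.normal(30, 5, 2000), rng.normal(120, 9, 2096)])
        bin_width = (img.max() - img.min()) / 256
        assert abs(otsu_threshold(img) - threshold_otsu(img, nbins=256)) <= bin_width

    def test_single_bright_pixel_is_foreground(self):
        img = np.full((8, 8), 10.0)
        img[3, 4] = 200.0
        thr = otsu_threshold(img)
        assert (img > thr).sum() == 1

    def test_constant_image_raises(self):
        with pytest.raises(NoContrastError):
            otsu_threshold(np.full((5, 5), 7.0))


def flood_fill_components(binary, connectivity):
    """Independent oracle: BFS flood fill."""
    binary = np.asarray(binary, dtype=bool)
    if connectivity == 8:
        nbrs = [(a, b) for a in (-1, 0, 1) for b in (-1, 0, 1) if (a, b) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(binary)
    comps = []
    for r in range(binary.shape[0]):
        for c in range(binary.shape[1]):
            if binary[r, c] and not seen[r, c]:
                stack, comp = [(r, c)], set()
                seen[r, c] = True
                while stack:
                    y, x = stack.pop()
                    comp.add((y, x))
                    for dy, dx in nbrs:
                        yy, xx = y + dy, x + dx
                        if (
                            0 <= yy < binary.shape[0]
                            and 0 <= xx < binary.shape[1]
                            and binary[yy, xx]
                            and not seen[yy, xx]
                        ):
                            seen[yy, xx] = True
                            stack.append((yy, xx))
                comps.append(frozenset(comp))
    return set(comps)


class TestLabelComponents:
    def test_two_squares_counted_and_filtered(self):
        frame = np.zeros((20, 20), dtype=bool)
        frame[2:7, 2:7] = True
        frame[10:15, 12:17] = True
        blobs = label_components(frame, 8, 1)
        assert [b.area_px for b in blobs] == [25, 25]
        assert blobs[0].centroid == (4.0, 4.0)
        assert blobs[1].centroid == (12.0, 14.0)
        assert label_components(frame, 8, min_area_px=30) == []

    def test_diagonal_join_depends_on_connectivity(self):
        frame = np.zeros((8, 8), dtype=bool)
        frame[1:3, 1:3] = True
        frame[3:5, 3:5] = True  # touches only diagonally at (2,2)-(3,3)
        assert len(label_components(frame, 8)) == 1
        assert len(label_components(frame, 4)) == 2

    def test_empty_frame_gives_empty_list(self):
        assert label_components(np.zeros((5, 5), dtype=bool)) == []

    @given(st.integers(0, 2**31 - 1), st.sampled_from([4, 8]))
    @settings(max_examples=25, deadline=None)
    def test_partition_matches_flood_fill_oracle(self, seed, connectivity):
        rng = np.random.default_rng(seed)
        frame = rng.random((12, 12)) < 0.4
        blobs = label_components(frame, connectivity, 1)
        got = {frozenset(b.pixels) for b in blobs}
        assert got == flood_fill_components(frame, connectivity)
        # partition property: disjoint union covers the foreground
        union = set().union(*(b.pixels for b in blobs)) if blobs else set()
        assert union == {tuple(p) for p in np.argwhere(frame)}
        assert sum(b.area_px for b in blobs) == int(frame.sum())


def square_blob(side, origin=(0, 0)):
    coords = np.array(
        [(r + origin[0], c + origin[1]) for r in range(side) for c in range(side)]
    )
    return Blob(
        frame_index=0,
        centroid=tuple(coords.mean(axis=0)),
        area_px=side * side,
        perimeter_px=4.0 * (side - 1),
        coords=coords,
        bbox=(origin[0], origin[1], origin[0] + side, origin[1] + side),
    )


class TestBlobGeometry:
    def test_three_by_three_square(self):
        geom = blob_geometry(square_blob(3), 1.0)
        assert geom.area_um2 == 9.0
        assert geom.max_feret_um == pytest.approx(2 * np.sqrt(2))

    def test_line_blob_under_half_micron_pixels(self):
        coords = np.array([(0, c) for c in range(10)])
        blob = Blob(0, (0.0, 4.5), 10, 18.0, coords, (0, 0, 1, 10))
        geom = blob_geometry(blob, 0.5)
        assert geom.area_um2 == pytest.approx(2.5)
        assert geom.max_feret_um == pytest.approx(4.5)
        assert geom.skeleton_length_um == pytest.approx(4.5)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_feret_matches_brute_force_pairs(self, seed):
        rng = np.random.default_rng(seed)
        frame = rng.random((10, 10)) < 0.5
        frame[4, 4] = True
        blobs = label_components(frame, 8, 1)
        blob = max(blobs, key=lambda b: b.area_px)
        brute = max(
            float(np.hypot(r1 - r2, c1 - c2))
            for r1, c1 in blob.pixels
            for r2, c2 in blob.pixels
        )
        assert max_feret_px(blob.coords) == pytest.approx(brute)

    def test_feret_hull_path_matches_brute_force_on_large_blob(self):
        rng = np.random.default_rng(5)
        pts = np.unique(rng.integers(0, 40, size=(900, 2)), axis=0)
        from scipy.spatial.distance import cdist

        assert max_feret_px(pts) == pytest.approx(cdist(pts, pts).max())

    def test_geometry_scales_with_pixel_size(self):
        blob = square_blob(4)
        g1 = blob_geometry(blob, 1.0)
        g3 = blob_geometry(blob, 3.0)
        assert g3.area_um2 == pytest.approx(9 * g1.area_um2)
        assert g3.max_feret_um == pytest.approx(3 * g1.max_feret_um)
        assert g3.skeleton_length_um == pytest.approx(3 * g1.skeleton_length_um)

    def test_skeleton_of_straight_line(self):
        mask = np.zeros((3, 42), dtype=bool)
        mask[1, 1:41] = True
        assert skeleton_longest_path_px(mask) == pytest.approx(39.0)
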