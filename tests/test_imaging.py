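"""Unit and property tests for the deterministic image preprocessing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from dermstack import imaging as im


def brute_force_morphology(img, footprint, op):
    """Windowed max/min with symmetric border padding, by explicit loops."""
    kh, kw = footprint.shape
    ph, pw = kh // 2, kw // 2
    pad = np.pad(img, ((ph, ph), (pw, pw)), mode="symmetric")
    out = np.zeros_like(img)
    fn = np.max if op == "dilate" else np.min
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            window = pad[i : i + kh, j : j + kw]
            out[i, j] = fn(window[footprint])
    return out


def brute_force_black_hat(img, k):
    fp = k.footprint()
    closed = brute_force_morphology(
        brute_force_morphology(img, fp, "dilate"), fp, "erode"
    )
    return closed.astype(int) - img.astype(int)


class TestGrayscale:
    def test_equal_channels_pass_through(self):
        img = np.full((8, 8, 3), 100, dtype=np.uint8)
        assert np.array_equal(im.to_grayscale(img), np.full((8, 8), 100, np.uint8))

    def test_pure_colors_match_per_pixel_dot_product(self, rng):
        # independent oracle: per-pixel dot product with the luma weights
        img = rng.integers(0, 256, size=(5, 7, 3), dtype=np.uint8)
        expected = np.empty((5, 7), dtype=np.uint8)
        for i in range(5):
            for j in range(7):
                v = sum(float(img[i, j, c]) * im.LUMA_WEIGHTS[c] for c in range(3))
                expected[i, j] = int(np.floor(v + 0.5))
        assert np.array_equal(im.to_grayscale(img), expected)
        red = np.zeros((2, 2, 3), dtype=np.uint8)
        red[:, :, 0] = 255
        assert im.to_grayscale(red)[0, 0] == 76  # round(255 * 0.299)

    def test_replicated_gray_is_identity(self, rng):
        gray = rng.integers(0, 256, size=(6, 6), dtype=np.uint8)
        assert np.array_equal(im.to_grayscale(im.replicate_channels(gray)), gray)

    def test_rejects_single_channel(self):
        with pytest.raises(ValueError):
            im.to_grayscale(np.zeros((4, 4), dtype=np.uint8))


class TestMorphology:
    def test_constant_image_unchanged_by_closing(self):
        img = np.full((10, 10), 77, dtype=np.uint8)
        assert np.array_equal(im.morph_close(img), img)

    def test_single_dark_pixel_filled(self):
        img = np.full((9, 9), 255, dtype=np.uint8)
        img[4, 4] = 0
        k = im.StructuringElement("rectangle", (3, 3))
        closed = im.morph_close(img, k)
        oracle = brute_force_morphology(
            brute_force_morphology(img, k.footprint(), "dilate"),
            k.footprint(), "erode",
        )
        assert closed[4, 4] == 255
        assert np.array_equal(closed, oracle)

    def test_closing_is_extensive_and_idempotent(self, rng):
        for _ in range(5):
            img = rng.integers(0, 256, size=(16, 16), dtype=np.uint8)
            k = im.StructuringElement("ellipse", (5, 5))
            closed = im.morph_close(img, k)
            assert np.all(closed >= img)
            assert np.array_equal(im.morph_close(closed, k), closed)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        img=arrays(np.uint8, (12, 12), elements=st.integers(0, 255)),
        bump=arrays(np.uint8, (12, 12), elements=st.integers(0, 40)),
    )
    def test_closing_preserves_image_ordering(self, img, bump):
        brighter = np.minimum(img.astype(int) + bump, 255).astype(np.uint8)
        k = im.StructuringElement("cross", (3, 3))
        assert np.all(im.morph_close(img, k) <= im.morph_close(brighter, k))

    def test_kernel_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            im.morph_close(np.zeros((4, 4), dtype=np.uint8),
                           im.StructuringElement("rectangle", (5, 5)))

    @pytest.mark.parametrize("shape", ["rectangle", "ellipse", "cross"])
    def test_black_hat_matches_brute_force_oracle(self, rng, shape):
        k = im.StructuringElement(shape, (3, 3))
        for _ in range(10):
            img = rng.integers(0, 256, size=(16, 16), dtype=np.uint8)
            assert np.array_equal(
                im.black_hat(img, k).astype(int), brute_force_black_hat(img, k)
            )

    def test_black_hat_of_constant_is_zero(self):
        img = np.full((12, 12), 200, dtype=np.uint8)
        assert not im.black_hat(img).any()

    def test_black_hat_isolates_dark_pixel(self):
        img = np.full((9, 9), 255, dtype=np.uint8)
        img[4, 4] = 0
        bh = im.black_hat(img, im.StructuringElement("rectangle", (3, 3)))
        assert bh[4, 4] == 255
        assert bh.sum() == 255

    def test_black_hat_nonnegative_for_random_inputs(self, rng):
        for _ in range(20):
            img = rng.integers(0, 256, size=(16, 16), dtype=np.uint8)
            k = im.StructuringElement("ellipse", (2 * rng.integers(1, 4) + 1,) * 2)
            assert np.all(im.black_hat(img, k).astype(int) >= 0)


class TestGaussianBlur:
    def test_constant_preserved(self):
        img = np.full((20, 20), 131, dtype=np.uint8)
        assert np.allclose(im.gaussian_blur(img, 2.0), 131.0)

    def test_impulse_response_is_sampled_gaussian(self):
        # direct kernel evaluation oracle at the documented truncation
        sigma = 1.5
        img = np.zeros((41, 41), dtype=np.uint8)
        img[20, 20] = 255
        out = im.gaussian_blur(img, sigma)
        half = int(im.BLUR_TRUNCATE * sigma + 0.5)
        x = np.arange(-half, half + 1, dtype=float)
        g = np.exp(-(x**2) / (2 * sigma**2))
        g /= g.sum()
        expected = 255.0 * np.outer(g, g)
        window = out[20 - half : 20 + half + 1, 20 - half : 20 + half + 1]
        assert np.allclose(window, expected, atol=1e-9)

    def test_total_intensity_conserved(self):
        img = np.zeros((41, 41), dtype=np.uint8)
        img[20, 20] = 255
        out = im.gaussian_blur(img, 2.0)
        assert abs(out.sum() - 255.0) / 255.0 < 1e-3

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            im.gaussian_blur(np.zeros((5, 5), dtype=np.uint8), 0.0)


class TestAdaptiveThreshold:
    def test_constant_image_all_white_for_positive_c(self):
        img = np.full((15, 15), 90, dtype=np.uint8)
        out = im.adaptive_threshold(img, im.ThresholdConfig(window=5, C=3.0))
        assert np.all(out == 255)

    def test_constant_image_all_black_at_c_zero(self):
        # strict inequality: value never exceeds its own mean
        img = np.full((15, 15), 90, dtype=np.uint8)
        out = im.adaptive_threshold(img, im.ThresholdConfig(window=5, C=0.0))
        assert np.all(out == 0)

    def test_matches_per_pixel_oracle_on_dark_square(self, rng):
        cfg = im.ThresholdConfig(window=21, C=5.0)
        img = np.full((32, 32), 180, dtype=np.uint8)
        img[12:20, 12:20] = 60
        img = np.clip(img.astype(int) + rng.integers(-20, 21, img.shape), 0, 255)
        img = img.astype(np.uint8)
        out = im.adaptive_threshold(img, cfg)
        # direct per-pixel evaluation of the local weighted-mean rule
        weights = im.threshold_window_weights(cfg.window)
        half = cfg.window // 2
        pad = np.pad(img.astype(float), half, mode="symmetric")
        for i in range(32):
            for j in range(32):
                t = (pad[i : i + cfg.window, j : j + cfg.window] * weights).sum() - cfg.C
                assert (out[i, j] == 255) == (img[i, j] > t)

    def test_output_is_binary(self, rng):
        for _ in range(5):
            img = rng.integers(0, 256, size=(32, 32), dtype=np.uint8)
            out = im.adaptive_threshold(img, im.ThresholdConfig(window=11, C=4.0))
            assert set(np.unique(out)) <= {0, 255}

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            im.ThresholdConfig(window=10)


class TestResize:
    def test_identity_at_target_size(self, rng):
        img = rng.integers(0, 256, size=(224, 224, 3), dtype=np.uint8)
        out = im.resize(img)
        assert np.array_equal(out, img)
        assert out is not img

    def test_constant_preserved_when_downscaling(self):
        img = np.full((448, 448, 3), 83, dtype=np.uint8)
        assert np.all(im.resize(img) == 83)

    def test_checkerboard_block_mean_under_area_interpolation(self):
        # period-2 checkerboard: every 2x2 block averages to 127.5 -> 128
        img = np.zeros((448, 448, 3), dtype=np.uint8)
        img[::2, 1::2] = 255
        img[1::2, ::2] = 255
        out = im.resize(img)
        assert np.all(out == 128)

    def test_downscale_matches_block_mean_oracle(self, rng):
        img = rng.integers(0, 256, size=(448, 448, 3), dtype=np.uint8)
        out = im.resize(img)
        blocks = img.reshape(224, 2, 224, 2, 3).mean(axis=(1, 3))
        assert np.array_equal(out, np.floor(blocks + 0.5).astype(np.uint8))

    def test_resize_is_idempotent(self, rng):
        img = rng.integers(0, 256, size=(300, 260, 3), dtype=np.uint8)
        once = im.resize(img)
        assert np.array_equal(im.resize(once), once)


class TestClassEncoding:
    @pytest.mark.parametrize(
        "name,code",
        [("ACK", 0), ("BCC", 1), ("MEL", 2), ("NEV", 3), ("SCC", 4), ("SEK", 5)],
    )
    def test_fixed_bijection(self, name, code):
        assert im.encode_class(name) == code
        assert im.decode_class(code) == name

    def test_case_insensitive(self):
        assert im.encode_class("sek") == 5

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            im.encode_class("XYZ")

    def test_roundtrip_identity(self):
        for name in im.CLASS_NAMES:
            assert im.decode_class(im.encode_class(name)) == name


class TestEnhanceTriplet:
    def test_constant_image_edge_cases(self):
        img = np.full((224, 224, 3), 140, dtype=np.uint8)
        triplet = im.enhance_triplet(img)
        assert not triplet.blackhat.any()  # closing is the identity
        assert np.all(triplet.adaptive == 255)  # c > c - C for C > 0

    def test_members_match_component_operations(self, rng):
        img = rng.integers(0, 256, size=(224, 224, 3), dtype=np.uint8)
        k = im.StructuringElement("ellipse", (9, 9))
        cfg = im.ThresholdConfig()
        triplet = im.enhance_triplet(img, k, cfg)
        gray = im.to_grayscale(img)
        assert np.array_equal(triplet.original, img)
        assert np.array_equal(triplet.blackhat[:, :, 0], im.black_hat(gray, k))
        assert np.array_equal(
            triplet.adaptive[:, :, 0],
            im.adaptive_threshold(im.gaussian_blur(gray, cfg.sigma), cfg),
        )
        for member in triplet.members():
            assert member.shape == (224, 224, 3)
        for member in (triplet.blackhat, triplet.adaptive):
            assert np.array_equal(member[:, :, 0], member[:, :, 1])
            assert np.array_equal(member[:, :, 0], member[:, :, 2])

    def test_small_input_is_resized(self, rng):
        img = rng.integers(0, 256, size=(100, 150, 3), dtype=np.uint8)
        triplet = im.enhance_triplet(img)
        assert triplet.original.shape == (224, 224, 3)


def test_structuring_element_validation():
    with pytest.raises(ValueError):
        im.StructuringElement("rectangle", (4, 4))
    with pytest.raises(ValueError):
        im.StructuringElement("hexagon", (3, 3))
    fp = im.StructuringElement("cross", (5, 5)).footprint()
    assert fp.sum() == 9  # a plus shape
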