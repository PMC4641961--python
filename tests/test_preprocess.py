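import numpy as np
import pytest

from dermoborder import preprocess as pp


def _rgb(value, shape=(20, 20)):
    img = np.zeros(shape + (3,), dtype=np.uint8)
    img[:] = value
    return img


class TestColorConversions:
    @pytest.mark.parametrize(
        "pixel, expected",
        [((0, 0, 0), 0.0), ((255, 255, 255), 255.0), ((200, 50, 100), 125.0)],
    )
    def test_hsl_lightness(self, pixel, expected):
        img = _rgb(pixel, (2, 3))
        assert np.allclose(pp.compute_lightness(img), expected)

    @pytest.mark.parametrize(
        "pixel, expected",
        [((255, 255, 255), 255.0), ((255, 0, 0), 76.245), ((0, 0, 0), 0.0)],
    )
    def test_ntsc_luma(self, pixel, expected):
        img = _rgb(pixel, (2, 2))
        assert np.allclose(pp.to_grayscale_ntsc(img), expected, atol=1e-9)

    def test_outputs_stay_in_display_range(self, rng):
        img = rng.integers(0, 256, size=(31, 17, 3)).astype(np.uint8)
        for conv in (pp.compute_lightness, pp.to_grayscale_ntsc):
            out = conv(img)
            assert out.shape == (31, 17)
            assert out.min() >= 0.0 and out.max() <= 255.0


class TestFrameRemoval:
    def test_uniform_image_is_untouched(self):
        img = _rgb((128, 128, 128), (40, 50))
        out, rec = pp.remove_black_frame(img)
        assert out.shape == img.shape
        assert rec == pp.CropRecord()

    def test_black_band_plus_extra_rows(self):
        img = _rgb((180, 170, 160), (100, 80))
        img[:20] = 0
        out, rec = pp.remove_black_frame(img)
        assert rec.top == 30  # 20 qualifying rows + 10 extra
        assert rec.bottom == rec.left == rec.right == 0
        assert out.shape[0] == 70

    def test_interior_dark_band_is_preserved(self):
        img = _rgb((180, 170, 160), (100, 80))
        img[40:60] = 0  # dark stripe away from every edge
        out, rec = pp.remove_black_frame(img)
        assert rec == pp.CropRecord()
        assert out.shape == img.shape

    def test_all_black_image_raises(self):
        with pytest.raises(pp.FrameRemovalError):
            pp.remove_black_frame(_rgb((0, 0, 0), (60, 60)))

    def test_full_frame_all_sides_and_idempotence(self):
        img = _rgb((200, 190, 180), (120, 120))
        f = 15
        img[:f] = img[-f:] = 0
        img[:, :f] = img[:, -f:] = 0
        out, rec = pp.remove_black_frame(img)
        assert (rec.top, rec.bottom, rec.left, rec.right) == (25, 25, 25, 25)
        out2, rec2 = pp.remove_black_frame(out)
        assert rec2 == pp.CropRecord()
        assert np.array_equal(out, out2)


class TestBlackTophat:
    def test_constant_image_gives_zero(self):
        assert np.allclose(pp.black_tophat(np.full((30, 30), 90.0), 5), 0.0)

    def test_thin_dark_line_lights_up(self):
        gray = np.full((41, 41), 200.0)
        gray[:, 20] = 50.0
        th = pp.black_tophat(gray, selem_radius=5)
        assert np.allclose(th[:, 20], 150.0)
        assert np.allclose(th[:, :10], 0.0)

    def test_wide_dark_disc_interior_survives_closing(self):
        n, r = 81, 10  # disc diameter 4 x selem radius
        yy, xx = np.mgrid[0:n, 0:n]
        disc = (yy - 40) ** 2 + (xx - 40) ** 2 <= r**2
        gray = np.where(disc, 40.0, 200.0)
        th = pp.black_tophat(gray, selem_radius=5)
        assert th[40, 40] == 0.0

    def test_response_is_nonnegative(self, rng):
        gray = rng.uniform(0, 255, size=(50, 50))
        assert pp.black_tophat(gray, 3).min() >= 0.0


class TestHairDetection:
    def test_zero_response_gives_empty_mask(self):
        assert not pp.detect_hairs(np.zeros((40, 40))).any()

    def test_long_thin_stroke_is_a_hair(self):
        th = np.zeros((100, 100))
        th[50:52, 10:90] = 120.0  # 80 px long, 2 px wide
        mask = pp.detect_hairs(th)
        assert mask[50, 50]
        assert mask.sum() == 160

    def test_round_globule_is_rejected(self):
        th = np.zeros((60, 60))
        yy, xx = np.mgrid[0:60, 0:60]
        th[(yy - 30) ** 2 + (xx - 30) ** 2 <= 36] = 120.0  # radius-6 blob
        assert not pp.detect_hairs(th).any()


class TestInpainting:
    def test_empty_mask_returns_identical_image(self, rng):
        img = rng.integers(0, 256, (20, 20, 3)).astype(np.uint8)
        out = pp.inpaint_hairs(img, np.zeros((20, 20), bool))
        assert np.array_equal(out, img)

    def test_uniform_image_stays_uniform(self):
        img = _rgb((120, 120, 120), (30, 30))
        mask = np.zeros((30, 30), bool)
        mask[10:20, 10:20] = True
        out = pp.inpaint_hairs(img, mask)
        assert np.array_equal(out, img)

    def test_single_pixel_takes_neighbourhood_mean(self):
        img = np.zeros((9, 9, 3), dtype=np.uint8)
        img[...] = (100, 60, 30)
        img[4, 4] = (255, 255, 255)
        mask = np.zeros((9, 9), bool)
        mask[4, 4] = True
        out = pp.inpaint_hairs(img, mask, neighborhood_radius=1)
        assert tuple(out[4, 4]) == (100, 60, 30)

    def test_pixels_outside_mask_never_change(self, rng):
        img = rng.integers(0, 256, (40, 40, 3)).astype(np.uint8)
        mask = rng.random((40, 40)) < 0.2
        mask[0, 0] = False
        out = pp.inpaint_hairs(img, mask)
        assert np.array_equal(out[~mask], img[~mask])

    def test_full_mask_raises(self):
        with pytest.raises(pp.InpaintError):
            pp.inpaint_hairs(_rgb((10, 10, 10)), np.ones((20, 20), bool))
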