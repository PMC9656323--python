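import numpy as np
import pytest

import oracles
from conftest import random_gray
from veinmap.enhancement import (
    EnhanceParams,
    enhance,
    enhance_stages,
    hist_equalize,
    hist_normalize,
    median_smooth,
    noise_threshold,
    sharpen,
)


class TestNormalize:
    def test_worked_example(self):
        # pixel 100 with Min=50, Max=150 -> 127.5 -> 128
        img = np.array([[50, 100, 150]], dtype=np.uint8)
        out = hist_normalize(img)
        assert out[0, 1] == 128
        assert out[0, 0] == 0 and out[0, 2] == 255

    def test_full_range_identity(self):
        img = np.arange(256, dtype=np.uint8).reshape(16, 16)
        assert np.array_equal(hist_normalize(img), img)

    def test_extrema_forced(self):
        img = random_gray(3)
        out = hist_normalize(img, 10, 240)
        assert out.min() == 10 and out.max() == 240

    def test_constant_maps_to_min_n(self):
        img = np.full((4, 4), 99, np.uint8)
        assert (hist_normalize(img, 5, 200) == 5).all()

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            hist_normalize(random_gray(0), 100, 100)


class TestEqualize:
    def test_worked_2x2_example(self):
        img = np.array([[0, 0], [255, 255]], dtype=np.uint8)
        out = hist_equalize(img)
        assert np.array_equal(out, np.array([[128, 128], [255, 255]]))

    def test_constant_maps_to_255(self):
        assert (hist_equalize(np.full((5, 5), 42, np.uint8)) == 255).all()

    def test_mapping_monotone(self):
        img = random_gray(7, (32, 32))
        out = hist_equalize(img)
        order = np.argsort(img.ravel(), kind="stable")
        mapped = out.ravel()[order]
        assert (np.diff(mapped.astype(int)) >= 0).all()


class TestNoiseThreshold:
    def test_three_level_example(self):
        img = np.array([[40] * 5 + [120] * 5 + [200] * 6], dtype=np.uint8).reshape(4, 4)
        t = oracles.brute_otsu(img)
        out = noise_threshold(img)
        expected = np.where(img > t, 255, img)
        assert np.array_equal(out, expected)

    def test_constant_unchanged(self):
        img = np.full((6, 6), 88, np.uint8)
        assert np.array_equal(noise_threshold(img), img)

    def test_dark_pixels_never_touched(self):
        img = random_gray(11)
        t = oracles.brute_otsu(img)
        out = noise_threshold(img)
        assert np.array_equal(out[img <= t], img[img <= t])
        assert (out[img > t] == 255).all()

    def test_bimodal_phantom_levels(self):
        img = np.where(np.random.default_rng(0).random((40, 40)) < 0.3, 60, 180).astype(np.uint8)
        out = noise_threshold(img)
        assert (out[img == 60] == 60).all()
        assert (out[img == 180] == 255).all()


class TestSharpen:
    def test_amount_zero_noop(self):
        img = random_gray(13)
        assert np.array_equal(sharpen(img, 0.0), img)

    def test_constant_unchanged(self):
        img = np.full((8, 8), 70, np.uint8)
        assert np.array_equal(sharpen(img, 2.5), img)

    def test_step_edge_overshoot(self):
        img = np.full((8, 8), 50, np.uint8)
        img[:, 4:] = 200
        out = sharpen(img, 1.0)
        # undershoot on the dark side, overshoot on the bright side
        assert out[3, 3] < 50
        assert out[3, 4] > 200

    def test_negative_amount_rejected(self):
        with pytest.raises(ValueError):
            sharpen(random_gray(0), -0.5)


class TestMedian:
    def test_impulse_removed(self):
        img = np.full((7, 7), 100, np.uint8)
        img[3, 3] = 255
        assert (median_smooth(img, 3) == 100).all()

    def test_constant_unchanged(self):
        img = np.full((5, 5), 9, np.uint8)
        assert np.array_equal(median_smooth(img, 3), img)

    def test_matches_brute_force(self):
        img = random_gray(17, (12, 13))
        assert np.array_equal(median_smooth(img, 3), oracles.brute_median_filter(img, 3))

    def test_even_size_rejected(self):
        with pytest.raises(ValueError):
            median_smooth(random_gray(0), 4)


class TestPipeline:
    def test_constant_input_constant_output(self):
        img = np.full((64, 64), 140, np.uint8)
        out = enhance(img)
        assert (out == out[0, 0]).all()

    def test_stage_names_in_order(self):
        img = random_gray(19, (48, 48))
        names = [n for n, _ in enhance_stages(img)]
        assert names == [
            "input",
            "light_removal",
            "normalize",
            "equalize",
            "threshold",
            "dilate",
            "sharpen",
            "median",
        ]
        from veinmap.phantom import PhantomSpec, make_phantom

        phantom_img = make_phantom(PhantomSpec(size=(96, 128), hair_count=3, seed=1)).image
        hairy_names = [n for n, _ in enhance_stages(phantom_img, hair_mode=True)]
        assert hairy_names[1] == "hair_removal"

    def test_deterministic(self):
        img = random_gray(23, (64, 64))
        assert np.array_equal(enhance(img), enhance(img))

    def test_param_validation(self):
        with pytest.raises(ValueError):
            EnhanceParams(norm_range=(200, 100))
        with pytest.raises(ValueError):
            EnhanceParams(median_size=4)
        with pytest.raises(ValueError):
            EnhanceParams(dilate_polarity="sideways")

    def test_stage_error_carries_stage_name(self, monkeypatch):
        import veinmap.enhancement as E

        def boom(img, p):
            raise ValueError("boom")

        monkeypatch.setattr(E, "remove_light", boom)
        with pytest.raises(RuntimeError, match="light_removal"):
            enhance(random_gray(1, (48, 48)))
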