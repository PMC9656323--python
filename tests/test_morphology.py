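import numpy as np
import pytest

import oracles
from conftest import random_gray, random_mask
from veinmap.morphology import (
    StructuringElement,
    binary_dilate,
    binary_erode,
    blackhat,
    closing,
    cross3,
    gray_dilate,
    gray_erode,
    opening,
    square3,
)

CROSS = cross3()
ANCHOR = (1, 1)


class TestStructuringElement:
    def test_empty_kernel_rejected(self):
        with pytest.raises(ValueError):
            StructuringElement(np.zeros((3, 3), dtype=bool))

    def test_anchor_outside_rejected(self):
        with pytest.raises(ValueError):
            StructuringElement(np.ones((3, 3), bool), anchor=(3, 0))

    def test_default_anchor_center(self):
        assert cross3().anchor == (1, 1)

    def test_from_config_names(self):
        assert np.array_equal(StructuringElement.from_config("cross3").kernel, CROSS.kernel)
        assert np.array_equal(StructuringElement.from_config("square3").kernel, square3().kernel)
        with pytest.raises(ValueError):
            StructuringElement.from_config("hexagon")

    def test_from_config_matrix(self):
        se = StructuringElement.from_config([[1, 1], [0, 1]])
        assert se.kernel.sum() == 3

    def test_reflection_involution(self):
        se = StructuringElement(np.array([[1, 1, 0], [0, 1, 0], [0, 0, 1]], bool), anchor=(0, 1))
        back = se.reflected().reflected()
        assert np.array_equal(back.kernel, se.kernel) and back.anchor == se.anchor


class TestBinary:
    def test_single_pixel_stamps_plus(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        out = binary_dilate(m, CROSS)
        expected = np.zeros((5, 5), bool)
        for r, c in [(2, 2), (1, 2), (3, 2), (2, 1), (2, 3)]:
            expected[r, c] = True
        assert np.array_equal(out, expected)

    def test_dilate_all_false(self):
        m = np.zeros((6, 7), bool)
        assert not binary_dilate(m, CROSS).any()

    def test_erode_all_true_border_preserved(self):
        m = np.ones((5, 5), bool)
        assert binary_erode(m, CROSS).all()

    def test_erode_kills_isolated_pixel(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        assert not binary_erode(m, CROSS).any()

    @pytest.mark.parametrize("seed", [7, 8, 9])
    def test_matches_brute_force(self, seed):
        m = random_mask(seed)
        assert np.array_equal(binary_dilate(m, CROSS), oracles.brute_binary_dilate(m, CROSS.kernel, ANCHOR))
        assert np.array_equal(binary_erode(m, CROSS), oracles.brute_binary_erode(m, CROSS.kernel, ANCHOR))

    def test_asymmetric_se_matches_brute_force(self):
        se = StructuringElement(np.array([[1, 1, 0], [0, 1, 0], [0, 0, 0]], bool), anchor=(0, 0))
        m = random_mask(11, (12, 13))
        assert np.array_equal(binary_dilate(m, se), oracles.brute_binary_dilate(m, se.kernel, se.anchor))
        assert np.array_equal(binary_erode(m, se), oracles.brute_binary_erode(m, se.kernel, se.anchor))


class TestGrayscale:
    def test_constant_fixed_point(self):
        img = np.full((6, 6), 100, np.uint8)
        assert np.array_equal(gray_dilate(img, CROSS), img)
        assert np.array_equal(gray_erode(img, CROSS), img)

    def test_dark_center_hand_example(self):
        img = np.full((5, 5), 200, np.uint8)
        img[2, 2] = 50
        dil = gray_dilate(img, CROSS)
        assert dil[2, 2] == 200 and (dil == 200).all()
        ero = gray_erode(img, CROSS)
        for r, c in [(1, 2), (3, 2), (2, 1), (2, 3), (2, 2)]:
            assert ero[r, c] == 50
        assert ero[0, 0] == 200

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_matches_brute_force(self, seed):
        img = random_gray(seed)
        assert np.array_equal(gray_dilate(img, CROSS), oracles.brute_gray_dilate(img, CROSS.kernel, ANCHOR))
        assert np.array_equal(gray_erode(img, CROSS), oracles.brute_gray_erode(img, CROSS.kernel, ANCHOR))

    def test_nonflat_se(self):
        se = StructuringElement(np.ones((3, 3), bool), values=np.full((3, 3), 10.0))
        img = np.full((5, 5), 100, np.uint8)
        assert (gray_dilate(img, se) == 110).all()
        assert (gray_erode(img, se) == 90).all()

    def test_duality_flat_se(self):
        img = random_gray(42)
        lhs = gray_erode(img, CROSS)
        rhs = 255 - gray_dilate(255 - img, CROSS.reflected())
        assert np.array_equal(lhs, rhs)


class TestDerivedOperators:
    def test_blackhat_constant_is_zero(self):
        assert not blackhat(np.full((8, 8), 77, np.uint8), CROSS).any()

    def test_blackhat_dark_center(self):
        img = np.full((5, 5), 200, np.uint8)
        img[2, 2] = 50
        bh = blackhat(img, CROSS)
        assert bh[2, 2] == 150
        assert bh.sum() == 150

    @pytest.mark.parametrize("seed", [13, 14])
    def test_idempotence(self, seed):
        img = random_gray(seed, (20, 20))
        c1 = closing(img, CROSS)
        o1 = opening(img, CROSS)
        assert np.array_equal(closing(c1, CROSS), c1)
        assert np.array_equal(opening(o1, CROSS), o1)

    def test_extensivity(self):
        img = random_gray(21)
        assert (closing(img, CROSS) >= img).all()
        assert (opening(img, CROSS) <= img).all()

    def test_blackhat_matches_brute_force(self):
        img = random_gray(6)
        assert np.array_equal(blackhat(img, CROSS), oracles.brute_blackhat(img, CROSS.kernel, ANCHOR))
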