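import numpy as np
import pytest

from weedseg.broadleaf import (
    BroadleafError,
    StructuringElement,
    compose_final,
    dilate,
    extract_broadleaf,
    filter_components,
    remove_predicted,
)
from weedseg.synthetic import (
    BROADLEAF,
    GRASS,
    SOYBEAN,
    SceneSpec,
    generate_scene,
    strip_broadleaf,
)
from .oracles import area_filter_bruteforce


class TestStructuringElement:
    def test_even_or_negative_size_rejected(self):
        with pytest.raises(BroadleafError):
            StructuringElement("square", 4)
        with pytest.raises(BroadleafError):
            StructuringElement("square", -1)
        with pytest.raises(BroadleafError):
            StructuringElement("hexagon", 3)

    def test_disk_is_subset_of_square(self):
        disk = StructuringElement("disk", 5).footprint()
        square = StructuringElement("square", 5).footprint()
        assert disk.shape == square.shape == (5, 5)
        assert disk.sum() < square.sum()
        assert (square | disk == square).all()


class TestDilate:
    def test_single_pixel_becomes_block(self):
        m = np.zeros((7, 7), bool)
        m[3, 3] = True
        out = dilate(m, StructuringElement("square", 3))
        assert out.sum() == 9 and out[2:5, 2:5].all()

    def test_border_clipping(self):
        m = np.zeros((5, 5), bool)
        m[0, 0] = True
        out = dilate(m, StructuringElement("square", 3))
        assert out.sum() == 4

    def test_empty_stays_empty(self):
        assert not dilate(np.zeros((6, 6), bool)).any()

    def test_extensive_and_monotone(self, rng):
        m = rng.random((20, 20)) > 0.8
        se = StructuringElement("square", 3)
        once = dilate(m, se)
        twice = dilate(once, se)
        assert (m <= once).all() and (once <= twice).all()


class TestRemovePredicted:
    def test_empty_green_gives_empty(self):
        z = np.zeros((4, 4), bool)
        assert not remove_predicted(z, z, z).any()

    def test_blob_set_algebra(self):
        """Three disjoint blobs; predictions cover two; the third remains."""
        green = np.zeros((32, 32), bool)
        blob_a = (slice(2, 8), slice(2, 8))
        blob_b = (slice(2, 8), slice(20, 28))
        blob_c = (slice(20, 28), slice(4, 12))
        for b in (blob_a, blob_b, blob_c):
            green[b] = True
        soy = np.zeros_like(green)
        soy[blob_a] = True
        grass = np.zeros_like(green)
        grass[blob_b] = True
        remainder = remove_predicted(green, soy, grass)
        expected = np.zeros_like(green)
        expected[blob_c] = True
        np.testing.assert_array_equal(remainder, expected)

    def test_full_prediction_removes_everything(self, rng):
        green = rng.random((10, 10)) > 0.5
        assert not remove_predicted(green, green, np.zeros_like(green)).any()

    def test_result_disjoint_from_predictions(self, rng):
        green = rng.random((16, 16)) > 0.4
        soy = rng.random((16, 16)) > 0.7
        grass = rng.random((16, 16)) > 0.7
        out = remove_predicted(green, soy, grass)
        assert not (out & (soy | grass)).any()

    def test_size_mismatch_rejected(self):
        with pytest.raises(BroadleafError):
            remove_predicted(np.zeros((4, 4), bool), np.zeros((4, 4), bool),
                             np.zeros((5, 5), bool))


class TestFilterComponents:
    def test_known_areas(self):
        m = np.zeros((16, 16), bool)
        m[1, 1:4] = True                 # area 3
        m[8:12, 8:13] = True             # area 20
        out, comps = filter_components(m, min_area=5)
        assert len(comps) == 1 and comps[0][1] == 20
        assert out.sum() == 20

    def test_min_area_zero_is_identity(self, rng):
        m = rng.random((12, 12)) > 0.6
        out, _ = filter_components(m, 0)
        np.testing.assert_array_equal(out, m)

    def test_oversized_threshold_empties_mask(self, rng):
        m = rng.random((12, 12)) > 0.6
        out, comps = filter_components(m, m.size + 1)
        assert not out.any() and comps == []

    @pytest.mark.parametrize("min_area", [1, 4, 9])
    def test_matches_flood_fill_oracle(self, rng, min_area):
        for _ in range(30):
            m = rng.random((32, 32)) > 0.7
            out, _ = filter_components(m, min_area)
            np.testing.assert_array_equal(out, area_filter_bruteforce(m, min_area))

    def test_survivors_partition_the_output(self, rng):
        m = rng.random((24, 24)) > 0.75
        out, comps = filter_components(m, 3)
        painted = np.zeros_like(m)
        for _, area, (yy, xx) in comps:
            assert len(yy) == area
            assert not painted[yy, xx].any()   # pairwise disjoint
            painted[yy, xx] = True
        np.testing.assert_array_equal(painted, out)


class TestComposeFinal:
    def test_all_empty_is_background(self):
        z = np.zeros((4, 4), bool)
        assert (compose_final(z, z, z) == 0).all()

    def test_disjoint_masks_placed_verbatim(self):
        soy = np.zeros((4, 4), bool)
        grass = np.zeros((4, 4), bool)
        broad = np.zeros((4, 4), bool)
        soy[0, 0] = grass[1, 1] = broad[2, 2] = True
        out = compose_final(soy, grass, broad)
        assert out[0, 0] == SOYBEAN and out[1, 1] == GRASS and out[2, 2] == BROADLEAF
        assert (out != 0).sum() == 3

    def test_priority_grass_over_soybean_over_broadleaf(self):
        ones = np.ones((2, 2), bool)
        zeros = np.zeros((2, 2), bool)
        assert (compose_final(ones, zeros, ones) == SOYBEAN).all()
        assert (compose_final(ones, ones, zeros) == GRASS).all()
        assert (compose_final(zeros, zeros, ones) == BROADLEAF).all()


class TestExtractBroadleaf:
    def test_recovers_broadleaf_with_oracle_predictions(self):
        """Using the generator's own soybean/grass truth as the 'model',
        the morphological pipeline must recover the broadleaf plants."""
        ious = []
        for seed in range(5):
            img, truth = generate_scene(SceneSpec(
                size=256, n_soybean=1, n_grass=1, n_broadleaf=1, seed=40 + seed))
            pred = strip_broadleaf(truth)          # perfect 3-class predictions
            final = extract_broadleaf(img, pred)
            got = final == BROADLEAF
            want = truth == BROADLEAF
            inter = (got & want).sum()
            union = (got | want).sum()
            ious.append(inter / union if union else 1.0)
        assert min(ious) >= 0.9

    def test_scene_without_broadleaf_yields_none(self):
        img, truth = generate_scene(SceneSpec(
            size=256, n_soybean=2, n_grass=2, n_broadleaf=0, seed=3))
        final = extract_broadleaf(img, strip_broadleaf(truth))
        assert not (final == BROADLEAF).any()

    def test_speckle_noise_below_area_threshold_is_removed(self):
        """Isolated green specks smaller than min_area must not survive."""
        rng = np.random.default_rng(0)
        img = np.clip(rng.normal(120, 10, (64, 64, 3)), 0, 255).astype(np.uint8)
        img[..., 1] = np.clip(rng.normal(90, 10, (64, 64)), 0, 255)
        for y, x in [(5, 5), (20, 40), (50, 12)]:  # 2x2 specks, area 4 < 16
            img[y:y + 2, x:x + 2] = (30, 200, 30)
        pred = np.zeros((64, 64), int)             # model predicts nothing
        final = extract_broadleaf(img, pred, min_area=16)
        assert (final == 0).all()

    def test_broadleaf_disjoint_from_predictions(self):
        img, truth = generate_scene(SceneSpec(size=256, seed=9))
        pred = strip_broadleaf(truth)
        final = extract_broadleaf(img, pred)
        broad = final == BROADLEAF
        assert not (broad & (pred > 0)).any()
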