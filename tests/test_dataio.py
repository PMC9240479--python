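import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from weedseg.dataio import (
    DEFAULT_PALETTE,
    DataIOError,
    PaletteSpec,
    decode_mask,
    encode_mask,
    import_polygons,
    read_mask,
    split_dataset,
    write_mask,
)
from .oracles import point_in_polygon_evenodd


class TestPalette:
    def test_default_palette_colors(self):
        assert DEFAULT_PALETTE.colors.tolist() == [
            [0, 0, 0], [0, 128, 0], [128, 0, 0], [128, 128, 0]]
        assert DEFAULT_PALETTE.names == ["background", "soybean", "grass", "broadleaf"]

    def test_invalid_palettes_rejected(self):
        with pytest.raises(DataIOError):
            PaletteSpec(entries=(("a", 0, (0, 0, 0)),))
        with pytest.raises(DataIOError):
            PaletteSpec(entries=(
                ("a", 0, (0, 0, 0)), ("b", 1, (0, 0, 0)),
                ("c", 2, (1, 1, 1)), ("d", 3, (2, 2, 2))))


class TestEncodeDecode:
    @pytest.mark.parametrize("value,color", [
        (0, [0, 0, 0]), (1, [0, 128, 0]), (2, [128, 0, 0]), (3, [128, 128, 0])])
    def test_single_pixel_encoding(self, value, color):
        assert encode_mask(np.array([[value]]))[0, 0].tolist() == color

    def test_background_only_mask(self):
        assert (encode_mask(np.zeros((2, 2), dtype=int)) == 0).all()

    def test_unknown_value_rejected(self):
        with pytest.raises(DataIOError, match="without palette"):
            encode_mask(np.array([[7]]))

    @pytest.mark.parametrize("color,value", [
        ([128, 0, 0], 2), ([128, 128, 0], 3), ([0, 128, 0], 1)])
    def test_single_pixel_decoding(self, color, value):
        img = np.array(color, dtype=np.uint8).reshape(1, 1, 3)
        assert decode_mask(img)[0, 0] == value

    def test_off_palette_pixel_reports_coordinates(self):
        img = np.zeros((3, 3, 3), dtype=np.uint8)
        img[1, 2] = (9, 9, 9)
        with pytest.raises(DataIOError, match=r"row=1, col=2"):
            decode_mask(img)

    @given(hnp.arrays(np.int64, (8, 8), elements=st.integers(0, 3)))
    def test_roundtrip_is_exact_inverse(self, mask):
        assert (decode_mask(encode_mask(mask)) == mask).all()


class TestPolygons:
    def test_empty_annotation_gives_background(self):
        assert (import_polygons({"shapes": []}, 4, 4) == 0).all()

    def test_square_polygon_matches_pointwise_oracle(self):
        poly = [[0, 0], [2, 0], [2, 2], [0, 2]]  # covers cols 0-1, rows 0-1
        ann = {"shapes": [{"label": "soybean", "points": poly}]}
        mask = import_polygons(ann, 4, 4)
        expected = np.zeros((4, 4), dtype=int)
        for r in range(4):
            for c in range(4):
                if point_in_polygon_evenodd(c + 0.5, r + 0.5, poly):
                    expected[r, c] = 1
        assert (mask == expected).all()
        assert mask.sum() == 4  # exactly the 2x2 corner

    def test_later_polygon_overwrites_earlier(self):
        sq = [[0, 0], [3, 0], [3, 3], [0, 3]]
        ann = {"shapes": [
            {"label": "soybean", "points": sq},
            {"label": "grass", "points": sq},
        ]}
        mask = import_polygons(ann, 4, 4)
        assert set(np.unique(mask[:3, :3])) == {2}

    def test_unknown_class_name_rejected(self):
        ann = {"shapes": [{"label": "thistle", "points": [[0, 0], [1, 0], [1, 1]]}]}
        with pytest.raises(DataIOError, match="thistle"):
            import_polygons(ann, 4, 4)

    def test_triangle_matches_oracle(self):
        poly = [[0.0, 0.0], [7.0, 0.5], [3.5, 6.5]]
        ann = {"shapes": [{"label": "grass", "points": poly}]}
        mask = import_polygons(ann, 8, 8)
        for r in range(8):
            for c in range(8):
                want = 2 if point_in_polygon_evenodd(c + 0.5, r + 0.5, poly) else 0
                assert mask[r, c] == want


class TestSplit:
    def test_field_protocol_sizes(self):
        ids = [f"img{i}" for i in range(4200)]
        split = split_dataset(ids, (3600 / 4200, 400 / 4200, 200 / 4200), seed=1)
        assert (len(split.train), len(split.validation), len(split.test)) == (3600, 400, 200)

    def test_floor_allocation_with_remainder_to_train(self):
        split = split_dataset(list(range(10)), (0.8, 0.1, 0.1), seed=0)
        assert (len(split.train), len(split.validation), len(split.test)) == (8, 1, 1)

    def test_same_seed_same_membership(self):
        ids = list(range(100))
        a = split_dataset(ids, (0.7, 0.2, 0.1), seed=9)
        b = split_dataset(ids, (0.7, 0.2, 0.1), seed=9)
        assert a.train == b.train and a.validation == b.validation and a.test == b.test

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_partition_properties(self, seed):
        ids = list(range(57))
        s = split_dataset(ids, (0.6, 0.25, 0.15), seed=seed)
        parts = [set(s.train), set(s.validation), set(s.test)]
        assert sum(len(p) for p in parts) == 57
        assert parts[0] | parts[1] | parts[2] == set(ids)
        assert not (parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2])

    def test_bad_inputs_rejected(self):
        with pytest.raises(DataIOError):
            split_dataset([], (0.8, 0.1, 0.1))
        with pytest.raises(DataIOError):
            split_dataset([1, 2], (0.9, 0.2, 0.1))


class TestMaskFiles:
    def test_palette_png_roundtrip(self, tmp_path):
        mask = np.random.default_rng(0).integers(0, 4, (16, 16))
        path = tmp_path / "m.png"
        write_mask(path, mask)
        assert (read_mask(path) == mask).all()

    def test_jpeg_refused_for_masks(self, tmp_path):
        with pytest.raises(DataIOError, match="JPEG"):
            write_mask(tmp_path / "m.jpg", np.zeros((4, 4), dtype=int))
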