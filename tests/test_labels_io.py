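"""MOTS parsing, grayscale stretch, label dialects, patching, augmentation."""

import numpy as np
import pytest
from shapely.geometry import Polygon, box

from vinescout import make_patch_grid
from vinescout._geometry import mask_iou, rasterize_polygon
from vinescout.labels_io import (
    MotsAnnotation,
    MotsParseError,
    adjust_grayscale,
    augment,
    mask_to_label,
    read_labels,
    read_mots,
    rle_decode,
    rle_encode,
    split_dataset,
    split_labels_to_patches,
    write_labels,
    write_mots,
)


def _naive_rle_decode(rle: str, height: int, width: int) -> np.ndarray:
    """Independent decoder: chars -> 5-bit little-endian groups -> counts
    (delta-coded from the third count) -> column-major run expansion."""
    bits_groups = [ord(ch) - 48 for ch in rle]
    counts, current, shift = [], 0, 0
    for g in bits_groups:
        current |= (g & 0x1F) << shift
        shift += 5
        if not g & 0x20:
            if g & 0x10:  # negative: sign-extend
                current -= 1 << shift
            if len(counts) > 2:
                current += counts[-2]
            counts.append(current)
            current, shift = 0, 0
    flat = []
    val = 0
    for c in counts:
        flat.extend([val] * c)
        val = 1 - val
    return np.array(flat, dtype=bool).reshape((width, height)).T


class TestRle:
    def test_hand_built_four_by_four_mask(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = mask[1, 1] = mask[2, 2] = mask[3, 3] = mask[0, 3] = True
        rle = rle_encode(mask)
        decoded = rle_decode(rle, 4, 4)
        assert int(decoded.sum()) == 5
        assert (decoded == mask).all()

    @pytest.mark.parametrize("seed", range(12))
    def test_encoder_against_independent_decoder(self, seed):
        rng = np.random.default_rng(seed)
        h, w = rng.integers(1, 40, size=2)
        mask = rng.random((h, w)) < rng.uniform(0.05, 0.95)
        rle = rle_encode(mask)
        assert (_naive_rle_decode(rle, h, w) == mask).all()
        assert (rle_decode(rle, h, w) == mask).all()

    def test_truncated_rle_rejected(self):
        mask = np.ones((8, 8), dtype=bool)
        rle = rle_encode(mask)
        with pytest.raises(MotsParseError):
            rle_decode(rle, 16, 16)


class TestMotsIO:
    def test_empty_file_gives_no_annotations(self, tmp_path):
        path = tmp_path / "mots.txt"
        path.write_text("")
        assert read_mots(path) == []

    def test_round_trip_preserves_fields(self, tmp_path, rng):
        annotations = [
            MotsAnnotation.from_mask(rng.random((12, 17)) < 0.4, frame_id=f, object_id=o)
            for f, o in [(0, 1), (0, 2), (3, 1)]
        ]
        path = tmp_path / "mots.txt"
        write_mots(annotations, path)
        back = read_mots(path)
        assert back == annotations

    def test_malformed_line_reports_line_number(self, tmp_path):
        good = MotsAnnotation.from_mask(np.zeros((4, 4), bool), 0, 1)
        path = tmp_path / "mots.txt"
        path.write_text(f"0 1 1 4 4 {good.rle}\nbroken line\n")
        with pytest.raises(MotsParseError, match="line 2"):
            read_mots(path)

    def test_truncated_rle_names_frame(self, tmp_path):
        good = MotsAnnotation.from_mask(np.ones((6, 6), bool), 7, 1)
        path = tmp_path / "mots.txt"
        path.write_text(f"7 1 1 9 9 {good.rle}\n")  # dims lie about length
        with pytest.raises(MotsParseError, match="frame 7"):
            read_mots(path)

    def test_duplicate_object_id_in_frame_rejected(self, tmp_path):
        a = MotsAnnotation.from_mask(np.ones((4, 4), bool), 0, 1)
        path = tmp_path / "mots.txt"
        write_mots([a, a], path)
        with pytest.raises(MotsParseError, match="duplicate"):
            read_mots(path)


class TestAdjustGrayscale:
    def test_full_range_image_unchanged(self):
        img = np.linspace(0, 255, 100, dtype=np.uint8).reshape(10, 10)
        out = adjust_grayscale(img, 0, 100)
        assert (out == img).all()

    def test_constant_image_unchanged(self):
        img = np.full((8, 8, 3), 77, dtype=np.uint8)
        assert (adjust_grayscale(img) == img).all()

    def test_two_value_image_stretches_to_full_range(self):
        img = np.where(np.arange(100).reshape(10, 10) < 50, 50, 100).astype(np.uint8)
        out = adjust_grayscale(img, 0, 100)
        assert set(np.unique(out)) == {0, 255}

    def test_invalid_percentiles_rejected(self):
        with pytest.raises(ValueError):
            adjust_grayscale(np.zeros((4, 4), np.uint8), 80, 20)


class TestMaskToLabel:
    def test_centered_square_bbox(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[25:75, 25:75] = True
        label = mask_to_label(mask, (100, 100))
        assert label.bbox == pytest.approx((0.5, 0.5, 0.5, 0.5), abs=0.02)

    def test_empty_mask_returns_none(self):
        assert mask_to_label(np.zeros((10, 10), bool), (10, 10)) is None

    def test_l_shaped_mask_reconstruction(self):
        mask = np.zeros((80, 80), dtype=bool)
        mask[10:70, 10:30] = True
        mask[50:70, 10:70] = True
        label = mask_to_label(mask, (80, 80), simplify_tol=1.0)
        back = rasterize_polygon(label.to_polygon(80, 80), 80, 80)
        assert mask_iou(mask, back) >= 0.95

    def test_bbox_is_tight_box_of_polygon(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[8:40, 16:56] = True
        label = mask_to_label(mask, (64, 64))
        xs = [p[0] for p in label.polygon]
        ys = [p[1] for p in label.polygon]
        cx, cy, w, h = label.bbox
        assert cx == pytest.approx((min(xs) + max(xs)) / 2, abs=1e-4)
        assert w == pytest.approx(max(xs) - min(xs), abs=1e-4)
        assert cy == pytest.approx((min(ys) + max(ys)) / 2, abs=1e-4)
        assert h == pytest.approx(max(ys) - min(ys), abs=1e-4)


class TestLabelDialects:
    @pytest.mark.parametrize("dialect", ["bbox+polygon", "polygon"])
    def test_write_read_round_trip(self, tmp_path, dialect):
        mask = np.zeros((50, 60), dtype=bool)
        mask[10:30, 20:50] = True
        label = mask_to_label(mask, (50, 60))
        path = tmp_path / "labels.txt"
        write_labels([label, label], path, dialect=dialect)
        back = read_labels(path, dialect=dialect)
        assert len(back) == 2
        for a in back:
            assert a.class_id == label.class_id
            assert np.allclose(a.bbox, label.bbox, atol=1e-4)
            assert np.allclose(a.polygon, label.polygon, atol=1e-4)

    def test_unknown_dialect_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="dialect"):
            write_labels([], tmp_path / "x.txt", dialect="weird")


class TestSplitLabelsToPatches:
    def test_instance_appears_only_in_containing_patches(self):
        grid = make_patch_grid((0, 0, 200, 100), 100, 20)
        per_patch = split_labels_to_patches(
            [(0, box(10, 10, 40, 40))], grid, min_visible_fraction=0.0
        )
        hits = [i for i, labels in per_patch.items() if labels]
        assert hits == [
            i for i in range(len(grid))
            if box(*grid.patch_rect(i)).intersects(box(10, 10, 40, 40))
        ]

    def test_straddling_instance_clips_union_to_original(self):
        grid = make_patch_grid((0, 0, 160, 100), 100, 40)
        poly = box(70, 20, 95, 60)  # straddles the seam region
        per_patch = split_labels_to_patches([(0, poly)], grid, min_visible_fraction=0.0)
        pieces = []
        for idx, labels in per_patch.items():
            x0, y0, _, _ = grid.patch_rect(idx)
            for lab in labels:
                from shapely import affinity

                pieces.append(
                    affinity.translate(lab.to_polygon(100, 100), x0, y0)
                )
        assert len(pieces) == 2
        from shapely.ops import unary_union

        union = unary_union(pieces)
        assert union.symmetric_difference(poly).area < 1e-4 * poly.area

    def test_sliver_below_min_visible_fraction_dropped(self):
        grid = make_patch_grid((0, 0, 160, 100), 100, 40)
        poly = box(95, 20, 130, 60)  # only 5 px wide inside patch 0
        per_patch = split_labels_to_patches([(0, poly)], grid, min_visible_fraction=0.2)
        assert per_patch[0] == []
        assert len(per_patch[1]) == 1


class TestAugment:
    POLY = Polygon([(10, 20), (40, 20), (40, 50), (10, 50)])

    def test_hflip_twice_is_identity_on_labels(self, rng):
        img = rng.integers(0, 255, size=(60, 80, 3), dtype=np.uint8)
        once_img, once_polys, _ = augment(img, [self.POLY], {"hflip": 1.0}, seed=0)
        twice_img, twice_polys, _ = augment(once_img, once_polys, {"hflip": 1.0}, seed=0)
        assert (twice_img == img).all()
        assert twice_polys[0].equals(self.POLY)

    def test_rotate_90_convention(self):
        """One clockwise quarter turn of a WxH image sends integer pixel
        (x, y) to (H-1-y, x); in continuous label coordinates (x, y) ->
        (H - y, x)."""
        h, w = 40, 60
        img = np.zeros((h, w, 3), dtype=np.uint8)
        tri = Polygon([(5, 7), (20, 7), (5, 30)])
        out_img, polys, applied = augment(img, [tri], {"rotate": [90]}, seed=0)
        assert applied == ["rotate90"]
        assert out_img.shape[:2] == (w, h)
        got = list(polys[0].exterior.coords[:-1])
        want = [(h - y, x) for x, y in tri.exterior.coords[:-1]]
        assert np.allclose(got, want)

    def test_rotated_pixels_follow_labels(self, rng):
        img = rng.integers(0, 255, size=(40, 60, 3), dtype=np.uint8)
        out_img, _, _ = augment(img, [], {"rotate": [90]}, seed=0)
        # pixel (x=5, y=7) must land at (x=40-1-7, y=5)
        assert (out_img[5, 40 - 1 - 7] == img[7, 5]).all()

    def test_scale_doubles_area_ratio(self, rng):
        img = rng.integers(0, 255, size=(50, 50, 3), dtype=np.uint8)
        out_img, polys, _ = augment(img, [self.POLY], {"scale": (2.0, 2.0)}, seed=0)
        assert polys[0].area == pytest.approx(4 * self.POLY.area)
        assert out_img.shape[0] == 100

    def test_unsupported_op_rejected(self):
        with pytest.raises(ValueError, match="unsupported"):
            augment(np.zeros((8, 8, 3), np.uint8), [], {"shear": 0.5}, seed=0)

    def test_instance_count_preserved(self, rng):
        img = rng.integers(0, 255, size=(64, 64, 3), dtype=np.uint8)
        polys = [self.POLY, Polygon([(1, 1), (5, 1), (5, 5)])]
        _, out, _ = augment(
            img, polys,
            {"hflip": 0.5, "vflip": 0.5, "rotate": [0, 90, 180, 270], "scale": (0.5, 1.5)},
            seed=4,
        )
        assert len(out) == len(polys)


class TestSplitDataset:
    def test_ten_groups_split_seven_three(self):
        train, val = split_dataset(list(range(10)), 0.7, seed=1)
        assert len(train) == 7 and len(val) == 3

    def test_same_seed_same_split(self):
        items = [f"v{i}" for i in range(12)]
        assert split_dataset(items, 0.7, seed=5) == split_dataset(items, 0.7, seed=5)

    def test_partition_is_disjoint_and_exhaustive(self):
        items = list(range(17))
        train, val = split_dataset(items, 0.6, seed=2)
        assert sorted(train + val) == items
        assert not set(train) & set(val)

    def test_groups_never_span_the_split(self):
        items = [(f"video{i % 4}", i) for i in range(20)]
        train, val = split_dataset(items, 0.5, seed=3, key=lambda it: it[0])
        assert not {g for g, _ in train} & {g for g, _ in val}

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError, match="groups"):
            split_dataset([1], 0.7, seed=0)
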