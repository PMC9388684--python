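import numpy as np
import pytest
from PIL import Image

from endoseg.annotations import (
    Annotation,
    MalformedAnnotationError,
    ThickEdgeError,
    grade_complexity,
    load_annotation,
    make_target,
    save_annotation,
)


def make_annotation(shape=(20, 20), edges=(), discard=()):
    px = np.zeros(shape)
    for r, c in edges:
        px[r, c] = 1.0
    for r, c in discard:
        px[r, c] = 0.5
    return Annotation(px)


class TestLoading:
    def test_roundtrip_alphabet(self, tmp_path):
        ann = make_annotation(edges=[(3, 3), (3, 4)], discard=[(10, 10)])
        path = tmp_path / "a.png"
        save_annotation(ann, path)
        loaded = load_annotation(path)
        assert np.array_equal(loaded.pixels, ann.pixels)

    def test_all_zero_is_single_body(self, tmp_path):
        path = tmp_path / "z.png"
        Image.fromarray(np.zeros((8, 8), np.uint8)).save(path)
        ann = load_annotation(path)
        assert ann.body_mask().all()

    def test_out_of_alphabet_value_rejected(self, tmp_path):
        arr = np.zeros((8, 8), np.uint8)
        arr[2, 2] = 17
        path = tmp_path / "bad.png"
        Image.fromarray(arr).save(path)
        with pytest.raises(MalformedAnnotationError):
            load_annotation(path)

    def test_thick_edge_rejected(self):
        px = np.zeros((8, 8))
        px[2:4, 2:4] = 1.0
        with pytest.raises(ThickEdgeError):
            Annotation(px)

    def test_non_trinary_rejected(self):
        with pytest.raises(MalformedAnnotationError):
            Annotation(np.full((4, 4), 0.3))


class TestEdgeTarget:
    def test_no_edges_gives_zero_target(self):
        t = make_target(make_annotation(), "edge")
        assert (t.pixels == 0).all()

    def test_isolated_pixel_gaussian_profile(self):
        ann = make_annotation(edges=[(10, 10)])
        t = make_target(ann, "edge").pixels
        assert t[10, 10] == pytest.approx(1.0)
        for dr, dc in [(-1, 0), (1, 0), (0, -1), (0, 1)]:
            assert t[10 + dr, 10 + dc] == pytest.approx(np.exp(-0.5))
        for dr, dc in [(-1, -1), (1, 1), (-1, 1), (1, -1)]:
            assert t[10 + dr, 10 + dc] == pytest.approx(np.exp(-1.0))
        assert t[10, 14] == 0.0          # outside the 7x7 window
        assert t[10, 13] == pytest.approx(np.exp(-4.5))

    def test_adjacent_pixels_clip_at_one(self):
        ann = make_annotation(edges=[(10, 10), (10, 11)])
        t = make_target(ann, "edge").pixels
        assert t[10, 10] == 1.0 and t[10, 11] == 1.0
        assert t.max() == 1.0

    def test_translation_equivariance(self):
        base = make_annotation(shape=(30, 30), edges=[(12, 12), (12, 13), (13, 14)])
        shifted = make_annotation(shape=(30, 30), edges=[(15, 16), (15, 17), (16, 18)])
        t0 = make_target(base, "edge").pixels
        t1 = make_target(shifted, "edge").pixels
        assert np.allclose(t0[5:25, 5:25], t1[8:28, 9:29])


class TestBodyBlobRoiTargets:
    @pytest.fixture()
    def two_cell_annotation(self):
        # vertical wall at c=10 splits the image into two cells; the left one
        # touches the border only via the wall's absence... both touch border
        px = np.zeros((21, 21))
        px[:, 10] = 1.0          # wall
        px[0, :] = 1.0           # closing edges so inner region exists
        px[-1, :] = 1.0
        px[:, 0] = 1.0
        px[:, -1] = 1.0
        return Annotation(px)

    def test_border_touching_cell_discarded(self):
        px = np.zeros((21, 21))
        px[5, 2:19] = 1.0
        px[15, 2:19] = 1.0
        px[5:16, 2] = 1.0
        px[5:16, 18] = 1.0
        ann = Annotation(px)
        t = make_target(ann, "body").pixels
        assert t[10, 10] == 1.0          # enclosed cell kept
        assert t[2, 10] == 0.0           # region touching border dropped
        assert t[19, 10] == 0.0

    def test_cell_next_to_discard_dropped(self):
        px = np.zeros((21, 21))
        px[5, 2:19] = 1.0
        px[15, 2:19] = 1.0
        px[5:16, 2] = 1.0
        px[5:16, 18] = 1.0
        px[6:15, 3:18][0, 0] = 0.5       # discard pixel inside the cell area
        ann = Annotation(px)
        assert make_target(ann, "body").pixels[10, 10] == 0.0

    def test_blob_dominates_body(self, two_cell_annotation):
        body = make_target(two_cell_annotation, "body").pixels
        blob = make_target(two_cell_annotation, "blob").pixels
        assert (blob >= body - 1e-12).all()

    def test_blob_includes_shared_wall(self):
        # two single-pixel cells in adjacent 3x3 edge rings sharing column 11
        px = np.zeros((21, 21))
        px[9:12, 9:14] = 1.0
        px[10, 10] = 0.0                 # left cell body
        px[10, 12] = 0.0                 # right cell body
        ann = Annotation(px)
        body = make_target(ann, "body").pixels
        blob = make_target(ann, "blob").pixels
        # corner wall pixel between the two bodies: body sees only Gaussian
        # spill (2 * exp(-1)), blob includes the separating edge at value 1
        assert body[9, 11] == pytest.approx(2 * np.exp(-1.0))
        assert blob[9, 11] == 1.0

    def test_roi_binary_and_zero_on_discard(self):
        px = np.zeros((21, 21))
        px[5, 2:19] = 1.0
        px[15, 2:19] = 1.0
        px[5:16, 2] = 1.0
        px[5:16, 18] = 1.0
        px[0:3, 0:3] = 0.5
        ann = Annotation(px)
        roi = make_target(ann, "roi").pixels
        assert set(np.unique(roi)) <= {0.0, 1.0}
        assert (roi[ann.pixels == 0.5] == 0).all()
        # the partial border cell is excluded from the ROI too
        assert roi[19, 10] == 0.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_target(make_annotation(), "ridge")


class TestComplexityGrade:
    @pytest.mark.parametrize("g, b, grade, bin_", [
        (1, 1, 2, "low"),
        (2, 2, 4, "medium"),
        (2, 1, 3, "medium"),
        (3, 3, 6, "high"),
        (3, 2, 5, "high"),
    ])
    def test_grades_and_bins(self, g, b, grade, bin_):
        c = grade_complexity(g, b)
        assert c.grade == grade and c.bin == bin_

    @pytest.mark.parametrize("g, b", [(0, 1), (4, 1), (1, 0), (2, 5)])
    def test_out_of_range_scores_rejected(self, g, b):
        with pytest.raises(ValueError):
            grade_complexity(g, b)
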