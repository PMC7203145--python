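"""Digital staining matrix: construction paths and the encoding rule."""

import json

import numpy as np
import pytest

from microstain.staining_matrix import (
    AnnotationError,
    EncodingRuleError,
    InvalidStainError,
    RoiSpec,
    StainClass,
    blend_matrix,
    one_hot_matrix,
    read_polygon_annotations,
    roi_matrix,
    validate,
)


class TestOneHot:
    def test_single_stain_planes(self):
        dsm = one_hot_matrix(StainClass(1, "HE"), 2, 2, 3)
        assert np.array_equal(dsm.weights[:, :, 0], np.ones((2, 2)))
        assert np.array_equal(dsm.weights[:, :, 1:], np.zeros((2, 2, 2)))

    def test_pixel_vector(self):
        dsm = one_hot_matrix(3, 1, 1, 3)
        assert dsm.weights[0, 0].tolist() == [0.0, 0.0, 1.0]

    @pytest.mark.parametrize("index", [0, 4, -1])
    def test_out_of_range_index(self, index):
        with pytest.raises(InvalidStainError):
            one_hot_matrix(index, 4, 4, 3)

    def test_equals_basis_blend(self):
        for i in range(1, 4):
            e = np.eye(3)[i - 1]
            assert np.array_equal(
                one_hot_matrix(i, 5, 7, 3).weights, blend_matrix(e, 5, 7).weights
            )


class TestBlend:
    def test_uniform_half_blend(self):
        dsm = blend_matrix((0.5, 0.5, 0.0), 4, 4)
        assert np.allclose(dsm.weights, np.broadcast_to([0.5, 0.5, 0.0], (4, 4, 3)))

    def test_rejects_bad_sum(self):
        with pytest.raises(EncodingRuleError):
            blend_matrix((0.3, 0.3, 0.3), 4, 4)

    def test_rejects_negative(self):
        with pytest.raises(EncodingRuleError):
            blend_matrix((1.5, -0.5, 0.0), 4, 4)


class TestRoi:
    def test_rectangle_inside_outside(self):
        # rectangle covering cols 2..5, rows 1..4 (pixel centers)
        spec = RoiSpec(
            polygons=[(np.array([[1.5, 0.5], [5.5, 0.5], [5.5, 4.5], [1.5, 4.5]]),
                       np.array([0.0, 1.0, 0.0]))],
            default_weights=np.array([1.0, 0.0, 0.0]),
        )
        dsm = roi_matrix(spec, 8, 8)
        inside = dsm.weights[1:5, 2:6]
        assert np.allclose(inside, np.broadcast_to([0, 1, 0], inside.shape))
        assert np.allclose(dsm.weights[0, :], np.broadcast_to([1, 0, 0], (8, 3)))
        assert not validate(dsm)

    def test_empty_spec_gives_uniform_default(self):
        spec = RoiSpec(polygons=[], default_weights=np.array([0.0, 0.0, 1.0]))
        dsm = roi_matrix(spec, 4, 4)
        assert np.allclose(dsm.weights, np.broadcast_to([0, 0, 1], (4, 4, 3)))

    def test_single_pixel_rectangle_brute_force(self):
        """A rectangle enclosing only pixel (1, 1): brute-force center test."""
        verts = np.array([[0.6, 0.6], [1.4, 0.6], [1.4, 1.4], [0.6, 1.4]])
        spec = RoiSpec(
            polygons=[(verts, np.array([0.0, 1.0, 0.0]))],
            default_weights=np.array([1.0, 0.0, 0.0]),
        )
        dsm = roi_matrix(spec, 3, 3)

        def inside_evenodd(x, y):
            # ray casting over polygon edges (independent oracle)
            n = len(verts)
            hit = False
            for i in range(n):
                x1, y1 = verts[i]
                x2, y2 = verts[(i + 1) % n]
                if (y1 > y) != (y2 > y):
                    xi = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
                    if x < xi:
                        hit = not hit
            return hit

        expected = np.array(
            [[inside_evenodd(c, r) for c in range(3)] for r in range(3)]
        )
        got = dsm.weights[..., 1] == 1.0
        assert np.array_equal(got, expected)
        assert expected.sum() == 1 and expected[1, 1]

    def test_last_polygon_wins_on_overlap(self):
        sq = np.array([[0.0, 0.0], [6.0, 0.0], [6.0, 6.0], [0.0, 6.0]])
        spec = RoiSpec(
            polygons=[(sq, np.array([0.0, 1.0, 0.0])), (sq, np.array([0.0, 0.0, 1.0]))],
            default_weights=np.array([1.0, 0.0, 0.0]),
        )
        dsm = roi_matrix(spec, 8, 8)
        assert np.allclose(dsm.weights[2, 2], [0, 0, 1])

    def test_idempotent(self):
        spec = RoiSpec(
            polygons=[(np.array([[1.0, 1.0], [5.0, 1.0], [3.0, 5.0]]),
                       np.array([0.0, 0.5, 0.5]))],
            default_weights=np.array([1.0, 0.0, 0.0]),
        )
        a = roi_matrix(spec, 10, 10).weights
        b = roi_matrix(spec, 10, 10).weights
        assert np.array_equal(a, b)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(AnnotationError):
            RoiSpec(
                polygons=[(np.array([[0.0, 0.0], [1.0, 1.0]]), np.array([1.0, 0.0]))],
                default_weights=np.array([1.0, 0.0]),
            )


class TestValidate:
    def test_reports_sum_violation(self):
        dsm = one_hot_matrix(1, 3, 3, 3)
        dsm.weights[1, 2] = [0.6, 0.6, 0.0]
        violations = validate(dsm)
        assert len(violations) == 1
        assert (violations[0]["row"], violations[0]["col"]) == (1, 2)
        assert violations[0]["sum"] == pytest.approx(1.2)

    def test_reports_range_violation(self):
        dsm = one_hot_matrix(1, 2, 2, 3)
        dsm.weights[0, 0] = [1.5, -0.5, 0.0]
        violations = validate(dsm)
        assert len(violations) == 1
        assert "out_of_range" in violations[0]

    @pytest.mark.parametrize("seed", range(5))
    def test_all_construction_paths_validate(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 5))
        w = rng.dirichlet(np.ones(n))
        assert validate(blend_matrix(w, 6, 6)) == []
        assert validate(one_hot_matrix(int(rng.integers(1, n + 1)), 6, 6, n)) == []
        verts = np.array([[1.0, 1.0], [4.0, 1.5], [3.0, 4.0]])
        spec = RoiSpec(
            polygons=[(verts, rng.dirichlet(np.ones(n)))],
            default_weights=rng.dirichlet(np.ones(n)),
        )
        assert validate(roi_matrix(spec, 6, 6)) == []


class TestAnnotations:
    def _write(self, tmp_path, doc):
        path = tmp_path / "ann.json"
        path.write_text(json.dumps(doc))
        return path

    def test_reads_labelled_shape(self, tmp_path):
        path = self._write(
            tmp_path,
            {"shapes": [{"label": "MT", "shape_type": "polygon",
                         "points": [[1, 1], [5, 1], [3, 4]]}]},
        )
        spec = read_polygon_annotations(
            path, {"MT": (0, 1, 0)}, default_weights=(1, 0, 0)
        )
        assert len(spec.polygons) == 1
        assert spec.polygons[0][1].tolist() == [0, 1, 0]

    def test_empty_shapes(self, tmp_path):
        path = self._write(tmp_path, {"shapes": []})
        spec = read_polygon_annotations(path, {}, default_weights=(1.0,))
        assert spec.polygons == []

    def test_two_vertex_shape_rejected(self, tmp_path):
        path = self._write(
            tmp_path,
            {"shapes": [{"label": "MT", "points": [[0, 0], [1, 1]]}]},
        )
        with pytest.raises(AnnotationError):
            read_polygon_annotations(path, {"MT": (1.0,)}, default_weights=(1.0,))

    def test_unknown_label_rejected(self, tmp_path):
        path = self._write(
            tmp_path,
            {"shapes": [{"label": "XX", "points": [[0, 0], [4, 0], [2, 3]]}]},
        )
        with pytest.raises(InvalidStainError):
            read_polygon_annotations(path, {"MT": (1.0,)}, default_weights=(1.0,))

    def test_malformed_json(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(AnnotationError):
            read_polygon_annotations(path, {}, default_weights=(1.0,))
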