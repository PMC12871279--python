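import json

import numpy as np
import pytest

from spotkit import (
    AnnotationVolume,
    LandmarkSet,
    SectionAnchor,
    annotate_regions,
    generate_alignment_fixture,
    parse_alignment,
    to_ccf,
    warp_points,
)
from spotkit.core import ConsistencyError, FormatError


@pytest.fixture()
def fixture_files(tmp_path):
    anch, lmk, vol, truth = generate_alignment_fixture(
        n_sections=2, n_landmarks=9, warp_amplitude=0.1, seed=3
    )
    ap = tmp_path / "anchoring.json"
    lp = tmp_path / "landmarks.json"
    ap.write_text(json.dumps(anch))
    lp.write_text(json.dumps(lmk))
    return ap, lp, vol, truth


class TestParseAlignment:
    def test_counts(self, fixture_files):
        ap, lp, _, _ = fixture_files
        anchors, landmarks = parse_alignment(ap, lp)
        assert len(anchors) == 2
        assert len(landmarks) == 2

    def test_malformed_json(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text("{not json")
        with pytest.raises(FormatError, match="bad.json"):
            parse_alignment(p)

    def test_unanchored_landmark_section(self, tmp_path, fixture_files):
        ap, lp, _, _ = fixture_files
        data = json.loads(lp.read_text())
        data["slices"][0]["filename"] = "ghost.png"
        lp2 = tmp_path / "l2.json"
        lp2.write_text(json.dumps(data))
        with pytest.raises(ConsistencyError):
            parse_alignment(ap, lp2)

    def test_missing_markers_empty_set(self, tmp_path, fixture_files):
        ap, lp, _, _ = fixture_files
        data = json.loads(lp.read_text())
        del data["slices"][0]["markers"]
        lp2 = tmp_path / "l3.json"
        lp2.write_text(json.dumps(data))
        _, landmarks = parse_alignment(ap, lp2)
        assert len(landmarks[0].source) == 0


class TestWarpPoints:
    def test_identity_markers_identity_warp(self):
        src = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], dtype=float)
        lm = LandmarkSet("s", src, src.copy())
        pts = np.array([[3.0, 4.0], [9.0, 1.0]])
        np.testing.assert_allclose(warp_points(pts, lm), pts, atol=1e-9)

    def test_markers_map_exactly_to_targets(self):
        rng = np.random.default_rng(0)
        src = rng.uniform(0, 100, (12, 2))
        tgt = src + rng.normal(0, 3, (12, 2))
        lm = LandmarkSet("s", src, tgt)
        np.testing.assert_allclose(warp_points(src, lm), tgt, atol=1e-8)

    def test_forced_linear_map(self):
        src = np.array([[0, 0], [1, 0], [0, 1]], dtype=float)
        tgt = np.array([[0, 0], [2, 0], [0, 2]], dtype=float)
        lm = LandmarkSet("s", src, tgt)
        out = warp_points(np.array([[0.25, 0.25]]), lm)
        np.testing.assert_allclose(out, [[0.5, 0.5]], atol=1e-12)

    def test_collinear_markers_identity(self):
        src = np.array([[0, 0], [1, 0], [2, 0]], dtype=float)
        lm = LandmarkSet("s", src, src + 5)
        pts = np.array([[0.5, 0.5]])
        np.testing.assert_allclose(warp_points(pts, lm), pts)

    def test_outside_points_use_nearest_triangle_extension(self):
        # affine planted warp extends exactly beyond the hull
        src = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], dtype=float)
        A = np.array([[1.1, 0.0], [0.0, 0.9]])
        tgt = src @ A.T
        lm = LandmarkSet("s", src, tgt)
        pts = np.array([[15.0, 15.0]])
        np.testing.assert_allclose(warp_points(pts, lm), pts @ A.T, atol=1e-9)


class TestToCcf:
    def test_anchor_midpoint(self):
        a = SectionAnchor("s", 1.0, 1.0, o=np.array([10.0, 5.0, 0.0]),
                          u=np.array([20.0, 0.0, 0.0]), v=np.array([0.0, 0.0, -20.0]))
        out = to_ccf(np.array([[0.5, 0.5]]), a)
        np.testing.assert_allclose(out, [[20.0, 5.0, -10.0]])

    def test_origin_maps_to_o(self):
        a = SectionAnchor("s", 7.0, 9.0, o=np.array([1.0, 2.0, 3.0]),
                          u=np.array([4.0, 0.0, 0.0]), v=np.array([0.0, 4.0, 0.0]))
        np.testing.assert_allclose(to_ccf(np.array([[0.0, 0.0]]), a), [[1.0, 2.0, 3.0]])

    def test_identity_atlas_matrix_noop(self):
        a = SectionAnchor("s", 2.0, 2.0, o=np.zeros(3), u=np.array([2.0, 0, 0]), v=np.array([0, 2.0, 0]))
        pts = np.array([[1.0, 1.0]])
        np.testing.assert_allclose(to_ccf(pts, a, np.eye(4)), to_ccf(pts, a))


class TestAnnotateRegions:
    def test_floor_convention(self):
        lab = np.zeros((4, 4, 4), dtype=int)
        lab[1, 1, 1] = 42
        lab[1, 0, 0] = 9
        vol = AnnotationVolume(lab)
        out = annotate_regions(np.array([[30.0, 30.0, 30.0], [-1.0, 0.0, 0.0], [25.0, 0.0, 0.0]]), vol)
        assert list(out) == [42, 0, 9]

    def test_agrees_with_direct_voxel_lookup(self):
        rng = np.random.default_rng(0)
        lab = rng.integers(0, 10, size=(20, 20, 20))
        vol = AnnotationVolume(lab)
        pts = rng.uniform(0, 20 * 25.0, size=(1000, 3))
        got = annotate_regions(pts, vol)
        idx = np.floor(pts / 25.0).astype(int)
        want = lab[idx[:, 0], idx[:, 1], idx[:, 2]]
        np.testing.assert_array_equal(got, want)


class TestFullStack:
    def test_identity_round_trip(self, tmp_path):
        anch, lmk, vol, truth = generate_alignment_fixture(warp_amplitude=0.0, seed=5)
        ap = tmp_path / "a.json"
        lp = tmp_path / "l.json"
        ap.write_text(json.dumps(anch))
        lp.write_text(json.dumps(lmk))
        anchors, landmarks = parse_alignment(ap, lp)
        sec = truth[truth["section"] == anchors[0].name]
        pts = sec[["x", "y"]].to_numpy()
        warped = warp_points(pts, landmarks[0])
        np.testing.assert_allclose(warped, pts, atol=1e-9)
        ccf = to_ccf(warped, anchors[0])
        np.testing.assert_allclose(ccf, sec[["ccf_x", "ccf_y", "ccf_z"]].to_numpy(), atol=1e-9)

    def test_planted_affine_warp_recovered(self, fixture_files):
        ap, lp, vol, truth = fixture_files
        anchors, landmarks = parse_alignment(ap, lp)
        sec = truth[truth["section"] == anchors[0].name]
        warped = warp_points(sec[["x", "y"]].to_numpy(), landmarks[0])
        np.testing.assert_allclose(warped, sec[["warped_x", "warped_y"]].to_numpy(), atol=1e-9)
        ccf = to_ccf(warped, anchors[0])
        np.testing.assert_allclose(ccf, sec[["ccf_x", "ccf_y", "ccf_z"]].to_numpy(), atol=1e-9)
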