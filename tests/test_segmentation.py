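import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from spotkit import (
    LabelVolume,
    VolumeImage,
    assign_transcripts,
    build_cell_polygons,
    compute_geometry,
    make_tiles,
    segment_tile,
    stitch_and_merge,
)
from spotkit.core import ConfigurationError, make_spot_table
from spotkit.segmentation import CellPolygonStack, PolygonPlane
from shapely.geometry import box


class TestMakeTiles:
    @pytest.mark.parametrize(
        "extent,tile,overlap,expected",
        [
            ((0, 0, 700, 350), 350, 0, 2),
            ((0, 0, 350, 350), 350, 0, 1),
            ((0, 0, 700, 700), 350, 50, 9),  # stride 300: ceil(350/300)+1 = 3 per axis
            ((0, 0, 100, 100), 350, 50, 1),  # smaller than one tile
        ],
    )
    def test_tile_counts(self, extent, tile, overlap, expected):
        assert len(make_tiles(extent, tile, overlap)) == expected

    def test_row_major_order_and_coverage(self):
        tiles = make_tiles((0, 0, 700, 700), 350, 50)
        assert [t.index for t in tiles] == list(range(9))
        assert tiles[0].x0 == 0 and tiles[1].x0 == 300  # row-major from min corner
        xs = np.linspace(0.1, 699.9, 40)
        for x in xs:
            for y in xs[:5]:
                assert any(t.x0 <= x < t.x1 and t.y0 <= y < t.y1 for t in tiles)

    def test_invalid_overlap(self):
        with pytest.raises(ConfigurationError):
            make_tiles((0, 0, 10, 10), 10, 10)


def _blob_image(centers, shape=(3, 40, 40), sigma=3.0):
    img = np.zeros(shape)
    zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    for cy, cx in centers:
        img += 50 * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)))
    return VolumeImage(img)


class TestSegmentTile:
    def test_zero_image_gives_zero_labels(self):
        img = VolumeImage(np.zeros((2, 10, 10)))
        out = segment_tile(img, img)
        assert out.labels.max() == 0

    def test_two_separated_blobs_two_labels(self):
        img = _blob_image([(10, 10), (30, 30)])
        out = segment_tile(img, img)
        # oracle: connected components of the thresholded image
        n_cc = ndimage.label(out.labels > 0)[1]
        assert n_cc == 2
        assert len(np.unique(out.labels)) - 1 == 2

    def test_touching_blobs_split_by_watershed(self):
        img = _blob_image([(20, 13), (20, 27)], sigma=4.0)
        out = segment_tile(img, img)
        assert len(np.unique(out.labels)) - 1 == 2
        # watershed splits what connected components cannot
        assert ndimage.label(out.labels > 0)[1] == 1

    def test_unknown_backend(self):
        img = _blob_image([(10, 10)])
        with pytest.raises(ConfigurationError):
            segment_tile(img, img, backend="nope")


class TestAssignTranscripts:
    def test_assignment_and_conservation(self):
        labels = np.zeros((1, 4, 4), dtype=int)
        labels[0, 2, 2] = 7
        vol = LabelVolume(labels, voxel_size=(10.0, 10.0, 10.0))
        spots = make_spot_table(["A", "B", "C"], [25.0, 5.0, 95.0], [25.0, 5.0, 95.0], [0.0, 0.0, 0.0])
        out = assign_transcripts(spots, vol, tile_index=3)
        assert len(out) == 3
        assert out["cell_id"].iloc[0] == "t3-c7"
        assert out["cell_id"].iloc[1] is None  # background voxel
        assert out["cell_id"].iloc[2] is None  # out of volume


def _table(tid_cells, tile):
    tids, cells = zip(*tid_cells)
    return pd.DataFrame({"transcript_id": list(tids), "cell_id": list(cells), "tile_index": tile})


class TestStitchAndMerge:
    def test_majority_share_merges(self):
        # smaller cell: 10 transcripts, 6 shared with a 15-transcript cell
        t0 = _table([(i, "t0-cA") for i in range(15)], 0)
        t1 = _table([(i, "t1-cB") for i in list(range(9, 15)) + list(range(15, 19))], 1)
        out = stitch_and_merge([t0, t1])
        assert out["cell_id"].nunique() == 1
        assert out["transcript_id"].is_unique

    def test_exactly_half_share_does_not_merge(self):
        # smaller cell: 10 transcripts, exactly 5 shared -> contested go to newer tile
        t0 = _table([(i, "t0-cA") for i in range(15)], 0)
        t1 = _table([(i, "t1-cB") for i in list(range(10, 15)) + list(range(15, 20))], 1)
        out = stitch_and_merge([t0, t1])
        assert out["cell_id"].nunique() == 2
        contested = out[out["transcript_id"].isin(range(10, 15))]["cell_id"].unique()
        assert list(contested) == ["t1-cB"]

    def test_disjoint_tiles_concatenate(self):
        t0 = _table([(0, "t0-cA"), (1, "t0-cA")], 0)
        t1 = _table([(2, "t1-cB"), (3, None)], 1)
        out = stitch_and_merge([t0, t1])
        assert out["cell_id"].nunique(dropna=True) == 2
        assert len(out) == 4

    def test_every_transcript_at_most_one_cell(self, small_section):
        from spotkit import RunConfig, process_section

        cfg, spots, dapi, truth = small_section
        adata = process_section(spots, dapi, RunConfig(seed=0))
        # conservation: segmented + unsegmented = non-blank input
        total = adata.X.sum() + adata.var["total_unsegmented"].sum()
        assert total == (~spots["is_blank"]).sum()


class TestPolygons:
    def test_three_points_give_their_triangle(self):
        spots = pd.DataFrame({"x": [0, 1, 0], "y": [0, 0, 1], "z": 0.0})
        stack = build_cell_polygons(spots)
        assert stack.planes[0].polygon.area == pytest.approx(0.5)

    def test_square_fixture_single_closed_polygon(self, square_spots):
        stack = build_cell_polygons(square_spots)
        poly = stack.planes[0].polygon
        assert poly is not None and poly.is_valid and not poly.is_empty
        assert poly.area <= 1.0 + 1e-9

    def test_collinear_points_null_boundary(self):
        spots = pd.DataFrame({"x": [0, 1, 2], "y": [0, 0, 0], "z": 0.0})
        stack = build_cell_polygons(spots)
        assert not stack.has_boundary
        assert compute_geometry(stack) == (0.0, 0.0, (pytest.approx(np.nan, nan_ok=True),) * 3)

    def test_emitted_polygons_simple(self, small_section):
        cfg, spots, dapi, truth = small_section
        top = spots[spots["true_cell"] == "cell0000"]
        stack = build_cell_polygons(top)
        for plane in stack.planes:
            if plane.polygon is not None:
                assert plane.polygon.is_valid and plane.polygon.is_simple


class TestGeometry:
    def test_single_plane_volume(self):
        stack = CellPolygonStack(planes=[PolygonPlane(0.0, box(0, 0, 1, 1))])
        vol, area, _ = compute_geometry(stack, z_spacing=1.5)
        assert vol == pytest.approx(1.5)
        assert area == pytest.approx(1.0)

    def test_two_identical_planes(self):
        stack = CellPolygonStack(
            planes=[PolygonPlane(0.0, box(0, 0, 1, 1)), PolygonPlane(1.0, box(0, 0, 1, 1))]
        )
        vol, _, _ = compute_geometry(stack, z_spacing=1.0)
        assert vol == pytest.approx(2.0)

    def test_area_is_max_plane_area(self):
        stack = CellPolygonStack(
            planes=[PolygonPlane(0.0, box(0, 0, 1, 1)), PolygonPlane(1.0, box(0, 0, 3, 1))]
        )
        _, area, _ = compute_geometry(stack)
        assert area == pytest.approx(3.0)
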