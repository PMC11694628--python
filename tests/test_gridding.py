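"""Segmentation, grid indexing, rotation, and rasterization."""

import numpy as np
import pandas as pd
import pytest

from tripgrid.gridding import (
    GridIndexSequence,
    GridOverflowError,
    LocalProjection,
    Segment,
    align_to_origin,
    assign_grid_indices,
    augment_segment,
    rasterize_occupancy,
    rotate_indices,
    segment_trajectory,
    shift_to_origin,
)
from conftest import random_walk_segment


def make_trip(n, lat0=26.4, lon0=-80.1):
    return pd.DataFrame(
        {
            "timestamp": np.arange(n),
            "lat": np.full(n, lat0),
            "lon": lon0 + np.arange(n) * 1e-4,
        }
    )


def seq_of(pairs, c=1.0):
    return GridIndexSequence(indices=np.asarray(pairs, dtype=np.int64), cell_size_km=c)


class TestSegmentation:
    @pytest.mark.parametrize("n,w,expected", [(13, 13, 1), (20, 13, 8), (5, 13, 0)])
    def test_segment_counts(self, n, w, expected):
        segs = segment_trajectory(make_trip(n), w)
        assert len(segs) == expected
        for s in segs:
            assert len(s.records) == w

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            segment_trajectory(make_trip(10), 1)

    def test_start_indices_are_offsets(self):
        segs = segment_trajectory(make_trip(20), 13)
        assert [s.start_index for s in segs] == list(range(8))

    def test_segment_length_invariant(self):
        with pytest.raises(ValueError):
            Segment(
                records=make_trip(5), driver_id="d", trip_id="t",
                label=0, start_index=0, window_w=6,
            )


class TestShiftToOrigin:
    def segment_from(self, lat, lon):
        df = pd.DataFrame({"timestamp": np.arange(len(lat)), "lat": lat, "lon": lon})
        return Segment(
            records=df, driver_id="d", trip_id="t", label=0,
            start_index=0, window_w=len(lat),
        )

    def test_first_offset_is_origin(self):
        rng = np.random.default_rng(0)
        lat, lon = random_walk_segment(rng)
        off = shift_to_origin(self.segment_from(lat, lon))
        assert off[0] == pytest.approx((0.0, 0.0))

    def test_eastward_segment_monotone_x_zero_y(self):
        lat = np.full(10, 0.0)
        lon = np.arange(10) * 1e-3
        off = shift_to_origin(self.segment_from(lat, lon))
        assert np.all(np.diff(off[:, 0]) > 0)
        assert np.allclose(off[:, 1], 0.0)

    def test_translation_changes_offsets_negligibly(self):
        rng = np.random.default_rng(1)
        lat, lon = random_walk_segment(rng)
        proj = LocalProjection(reference_lat_deg=26.4)
        off = shift_to_origin(self.segment_from(lat, lon), proj)
        off2 = shift_to_origin(self.segment_from(lat + 0.05, lon - 0.08), proj)
        assert np.allclose(off, off2, atol=1e-6)


class TestGridIndices:
    def test_single_cell_path(self):
        off = np.array([[0.0, 0.0], [0.4, 0.2], [0.9, 0.9]])
        seq = assign_grid_indices(off, c=1.0)
        assert np.array_equal(seq.indices, np.zeros((3, 2), dtype=int))

    def test_eastward_two_and_a_half_cells(self):
        xs = np.linspace(0.0, 2.5, 26)
        off = np.column_stack([xs, np.zeros_like(xs)])
        seq = assign_grid_indices(off, c=1.0)
        assert set(seq.indices[:, 0]) == {0, 1, 2}
        assert set(seq.indices[:, 1]) == {0}

    def test_three_by_three_extent(self):
        # a path visiting indices up to (2, 2) stays within a 3x3 raster
        off = np.array(
            [[0.5, 0.5], [1.5, 0.5], [2.5, 0.5], [2.5, 1.5], [1.5, 1.5],
             [1.5, 2.5], [0.5, 2.5]]
        )
        seq = assign_grid_indices(off, c=1.0)
        assert seq.indices.max() == 2
        rasterize_occupancy(seq, 3)  # fits without overflow

    def test_negative_offsets_allowed(self):
        off = np.array([[0.0, 0.0], [-0.5, -1.2]])
        seq = assign_grid_indices(off, c=1.0)
        assert seq.indices[1].tolist() == [-1, -2]

    def test_invalid_cell_size(self):
        with pytest.raises(ValueError):
            assign_grid_indices(np.zeros((2, 2)), c=0.0)


class TestRotation:
    def test_four_quarter_turns_identity(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            seq = seq_of(rng.integers(-4, 5, size=(10, 2)))
            out = seq
            for _ in range(4):
                out = rotate_indices(out, 90)
            assert np.array_equal(out.indices, align_to_origin(seq).indices)

    def test_half_turn_of_two_cell_path(self):
        seq = seq_of([(0, 0), (1, 0)])
        out = rotate_indices(seq, 180)
        assert out.indices.tolist() == [[1, 0], [0, 0]]

    def test_l_shape_against_cell_set_oracle(self):
        # brute-force oracle: rotate the occupied cell set point by point
        seq = seq_of([(0, 0), (1, 0), (2, 0), (2, 1)])
        out = rotate_indices(seq, 90)
        rotated = {(-y, x) for x, y in seq.indices}
        mnx = min(x for x, _ in rotated)
        mny = min(y for _, y in rotated)
        oracle = {(x - mnx, y - mny) for x, y in rotated}
        assert out.occupied_cells == oracle
        assert len(out.occupied_cells) == len(seq.occupied_cells)

    def test_unsupported_angle(self):
        with pytest.raises(ValueError):
            rotate_indices(seq_of([(0, 0)]), 45)

    @pytest.mark.parametrize("extent", [3, 4, 5])
    @pytest.mark.parametrize("angle", [90, 180, 270])
    def test_rotation_rasterization_commute(self, extent, angle):
        # rotating the index sequence then rasterizing occupies the same cell
        # set as rotating the rasterized cells directly (independent oracle)
        def rot_cell(x, y, angle):
            if angle == 90:
                return (-y, x)
            if angle == 180:
                return (-x, -y)
            return (y, -x)

        rng = np.random.default_rng(extent * 7 + angle)
        checked = 0
        for _ in range(60):
            walk = np.cumsum(rng.integers(-1, 2, size=(8, 2)), axis=0)
            seq = seq_of(walk)
            span = walk.max(axis=0) - walk.min(axis=0) + 1
            if span.max() > extent:
                continue
            checked += 1
            left = rasterize_occupancy(rotate_indices(seq, angle), extent).matrix
            cells = rasterize_occupancy(seq, extent).matrix
            rotated = {
                rot_cell(x, y, angle) for y, x in zip(*np.nonzero(cells))
            }
            mnx = min(x for x, _ in rotated)
            mny = min(y for _, y in rotated)
            oracle = np.zeros_like(cells)
            for x, y in rotated:
                oracle[y - mny, x - mnx] = 1
            assert np.array_equal(left, oracle)
        assert checked > 5


class TestRasterization:
    def test_worked_example_occupancy(self):
        # 13-point tour of a 3x3 grid: x right, y up, row 0 southernmost
        pairs = [(0, 0), (0, 0), (1, 0), (1, 0), (2, 0), (2, 0), (2, 1),
                 (1, 1), (1, 1), (1, 1), (1, 2), (0, 2), (0, 2)]
        grid = rasterize_occupancy(seq_of(pairs), 3)
        expected = np.zeros((3, 3), dtype=np.uint8)
        for x, y in {(0, 0), (1, 0), (2, 0), (2, 1), (1, 1), (1, 2), (0, 2)}:
            expected[y, x] = 1
        assert np.array_equal(grid.matrix, expected)
        assert grid.matrix[1, 0] == 0 and grid.matrix[2, 2] == 0

    def test_single_cell(self):
        grid = rasterize_occupancy(seq_of([(0, 0)] * 5), 3)
        assert grid.matrix.sum() == 1

    def test_sum_equals_distinct_cells(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            walk = np.cumsum(rng.integers(-1, 2, size=(15, 2)), axis=0)
            seq = seq_of(walk)
            span = walk.max(axis=0) - walk.min(axis=0) + 1
            if span.max() > 6:
                continue
            grid = rasterize_occupancy(seq, 6)
            assert grid.matrix.sum() == len(seq.occupied_cells)

    def test_overflow_raises(self):
        seq = seq_of([(0, 0), (5, 0)])
        with pytest.raises(GridOverflowError):
            rasterize_occupancy(seq, 3)

    def test_entries_binary(self):
        grid = rasterize_occupancy(seq_of([(0, 0), (1, 1), (1, 1)]), 3)
        assert set(np.unique(grid.matrix)) <= {0, 1}


class TestAugmentation:
    def test_four_variants(self):
        out = augment_segment(seq_of([(0, 0), (1, 0), (1, 1)]))
        assert len(out) == 4

    def test_single_cell_fixed_point(self):
        out = augment_segment(seq_of([(0, 0)] * 3))
        for variant in out:
            assert np.array_equal(variant.indices, out[0].indices)

    def test_variants_share_cell_count(self):
        seq = seq_of([(0, 0), (1, 0), (2, 0), (2, 1)])
        counts = {len(v.occupied_cells) for v in augment_segment(seq)}
        assert counts == {len(seq.occupied_cells)}
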