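"""Skeleton x distance-map diameters, residence fractions, tracking, speed."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dcmorph import (
    CellTimelapseSpec,
    DiameterError,
    Track,
    cell_time_average,
    frame_diameters,
    make_cell_timelapse,
    combine_label_stacks,
    residence_fractions,
    stack_diameters,
    straight_path,
    track_cells,
    track_speed,
)

from conftest import disk_mask


def capsule_frame(width_um, pixel_size=0.25, length=18.0, shape=(128, 192)):
    spec = CellTimelapseSpec(
        n_frames=1, frame_interval=2.0, width_schedule=[width_um],
        length=length, centroid_path=[(24.0, 16.0)], pixel_size=pixel_size,
        image_shape=shape,
    )
    stack, _ = make_cell_timelapse(spec)
    return stack[0]


class TestFrameDiameters:
    def test_disk_max_diameter(self):
        d = frame_diameters(disk_mask(20, (64, 64)), pixel_size=0.5)
        assert abs(d.max_um - 20.0) <= 2 * 0.5  # within 2 px of 2R

    @pytest.mark.parametrize("width", [2.0, 3.0, 4.0, 6.0, 8.0, 10.0])
    def test_capsule_min_diameter_recovery(self, width):
        d = frame_diameters(capsule_frame(width), pixel_size=0.25)
        assert abs(d.min_um - width) <= 0.5

    def test_min_le_mean_le_max(self):
        d = frame_diameters(capsule_frame(6.0), pixel_size=0.25)
        assert d.min_um <= d.mean_um <= d.max_um

    def test_one_pixel_line_flagged_unresolved(self):
        m = np.zeros((32, 32), np.uint8)
        m[16, 5:28] = 1
        d = frame_diameters(m, pixel_size=0.5)
        assert d.unresolved
        assert d.min_um <= 2 * 2 * 0.5  # 2*EDT of a 1-px line is <= 2 px

    def test_empty_and_multicomponent_masks_error(self):
        with pytest.raises(DiameterError):
            frame_diameters(np.zeros((16, 16), np.uint8), 0.5)
        m = np.zeros((32, 32), np.uint8)
        m[2:8, 2:8] = 1
        m[20:26, 20:26] = 1
        with pytest.raises(DiameterError, match="2"):
            frame_diameters(m, 0.5)

    def test_border_touching_flagged(self):
        m = np.zeros((32, 32), np.uint8)
        m[0:10, 10:20] = 1
        assert frame_diameters(m, 0.5).touches_border

    def test_anisotropic_pixels_rejected(self):
        with pytest.raises(DiameterError, match="anisotropic"):
            frame_diameters(disk_mask(10), (0.5, 0.25))

    def test_rotation_robustness(self):
        """90-degree rotation agrees within the discretization tolerance of
        thinning; 45 degrees within 2 pixels."""
        m = capsule_frame(6.0)
        d0 = frame_diameters(m, 0.25)
        d90 = frame_diameters(np.rot90(m).copy(), 0.25)
        assert abs(d90.min_um - d0.min_um) <= 2 * 0.25
        assert abs(d90.max_um - d0.max_um) <= 2 * 0.25
        # 45-degree capsule via a diagonal path
        spec = CellTimelapseSpec(
            n_frames=2, frame_interval=2.0, width_schedule=[6.0, 6.0],
            length=18.0,
            centroid_path=[(16.0, 16.0), (17.0, 17.0)],
            pixel_size=0.25, image_shape=(160, 160),
        )
        stack, _ = make_cell_timelapse(spec)
        d45 = frame_diameters(stack[1], 0.25)
        assert abs(d45.min_um - d0.min_um) <= 2 * 0.25


class TestTimeAverage:
    def test_mean_of_two_frames(self):
        import pandas as pd

        df = pd.DataFrame(
            dict(cell_id=[1, 1], frame=[0, 1], min_diam_um=[3.0, 5.0],
                 mean_diam_um=[4.0, 6.0], max_diam_um=[5.0, 7.0])
        )
        out = cell_time_average(df)
        assert float(out["avg_min_um"].iloc[0]) == 4.0
        assert float(out["avg_max_um"].iloc[0]) == 6.0

    def test_single_frame_identity(self):
        import pandas as pd

        df = pd.DataFrame(
            dict(cell_id=[1], frame=[0], min_diam_um=[3.0],
                 mean_diam_um=[3.5], max_diam_um=[4.0])
        )
        out = cell_time_average(df)
        assert float(out["avg_min_um"].iloc[0]) == 3.0

    def test_constant_width_capsule_matches_truth(self):
        spec = CellTimelapseSpec(
            n_frames=6, frame_interval=2.0, width_schedule=[4.0] * 6,
            length=18.0, centroid_path=straight_path((15.0, 16.0), 1.0, 6),
            pixel_size=0.25, image_shape=(128, 192),
        )
        stack, truth = make_cell_timelapse(spec)
        per_frame = stack_diameters(stack, 0.25)
        out = cell_time_average(per_frame)
        assert float(out["avg_min_um"].iloc[0]) == pytest.approx(4.0, abs=0.5)


class TestResidenceFractions:
    def test_counting_example(self):
        res = residence_fractions(
            [3, 3, 5, 5, 5, 5, 3, 5, 5, 5], frame_interval=4.0
        )
        assert res.fraction_2to4 == pytest.approx(0.3)
        assert res.fraction_gt4 == pytest.approx(0.7)
        assert res.total_time_min == 40.0

    def test_submicron_diameters_fall_outside_both_bins(self):
        res = residence_fractions([1.0] * 20, 2.0)
        assert res.fraction_2to4 == 0.0
        assert res.fraction_gt4 == 0.0

    def test_short_track_rejected_but_overridable(self):
        with pytest.raises(ValueError, match="40"):
            residence_fractions([3.0, 5.0], 2.0)
        res = residence_fractions([3.0, 5.0], 2.0, enforce_min_duration=False)
        assert res.fraction_2to4 == 0.5

    def test_generator_occupancy_recovered_exactly(self):
        widths = [3.0] * 7 + [5.0] * 14  # 1/3 thin, 2/3 wide
        spec = CellTimelapseSpec(
            n_frames=21, frame_interval=2.0, width_schedule=widths,
            length=18.0, centroid_path=[(20.0, 16.0)] * 21,
            pixel_size=0.25, image_shape=(128, 192),
        )
        stack, _ = make_cell_timelapse(spec)
        per_frame = stack_diameters(stack, 0.25)
        res = residence_fractions(per_frame["min_diam_um"], 2.0)
        assert res.fraction_2to4 == pytest.approx(7 / 21)
        assert res.fraction_gt4 == pytest.approx(14 / 21)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        diams=st.lists(st.floats(0.5, 12.0), min_size=20, max_size=60),
        seed=st.integers(0, 100),
    )
    def test_order_invariance_and_bound(self, diams, seed):
        """Fractions depend only on the multiset of diameters; sum <= 1."""
        rng = np.random.default_rng(seed)
        shuffled = list(rng.permutation(diams))
        a = residence_fractions(diams, 2.0)
        b = residence_fractions(shuffled, 2.0)
        assert a.fraction_2to4 == pytest.approx(b.fraction_2to4)
        assert a.fraction_gt4 == pytest.approx(b.fraction_gt4)
        assert a.fraction_2to4 + a.fraction_gt4 <= 1.0 + 1e-12


def two_cell_stack(step_b=(0.0, 0.0)):
    a = CellTimelapseSpec(
        n_frames=5, frame_interval=2.0, width_schedule=[4.0] * 5,
        length=14.0, centroid_path=straight_path((12.0, 12.0), 1.0, 5),
        pixel_size=0.25, image_shape=(160, 256),
    )
    b = CellTimelapseSpec(
        n_frames=5, frame_interval=2.0, width_schedule=[4.0] * 5,
        length=14.0,
        centroid_path=straight_path((50.0, 30.0), np.hypot(*step_b) or 0.0,
                                    5, direction=step_b if any(step_b) else (1, 0)),
        pixel_size=0.25, image_shape=(160, 256),
    )
    return combine_label_stacks(
        [make_cell_timelapse(a), make_cell_timelapse(b)]
    )


class TestTracking:
    def test_single_stationary_cell(self):
        spec = CellTimelapseSpec(
            n_frames=6, frame_interval=2.0, width_schedule=[4.0] * 6,
            length=14.0, centroid_path=[(20.0, 16.0)] * 6,
            pixel_size=0.25, image_shape=(128, 192),
        )
        stack, _ = make_cell_timelapse(spec)
        tracks = track_cells(stack.astype(np.int32), 0.25, 2.0)
        assert len(tracks) == 1
        assert len(tracks[0].frames) == 6
        assert track_speed(tracks[0]) == pytest.approx(0.0, abs=1e-9)

    def test_two_separated_cells_two_tracks(self):
        labels, truth = two_cell_stack()
        tracks = track_cells(labels, 0.25, 2.0)
        assert len(tracks) == 2
        assert all(len(t.frames) == 5 for t in tracks)

    def test_displacement_gate_terminates_track(self):
        # one cell teleports beyond the 20 µm gate at frame 2
        spec1 = CellTimelapseSpec(
            n_frames=2, frame_interval=2.0, width_schedule=[4.0] * 2,
            length=14.0, centroid_path=[(12.0, 16.0)] * 2,
            pixel_size=0.25, image_shape=(160, 256),
        )
        s1, _ = make_cell_timelapse(spec1)
        spec2 = CellTimelapseSpec(
            n_frames=2, frame_interval=2.0, width_schedule=[4.0] * 2,
            length=14.0, centroid_path=[(52.0, 16.0)] * 2,
            pixel_size=0.25, image_shape=(160, 256),
        )
        s2, _ = make_cell_timelapse(spec2)
        stack = np.concatenate([s1[:1], s2[:1]]).astype(np.int32)
        tracks = track_cells(stack, 0.25, 2.0, max_disp_um=20.0)
        assert len(tracks) == 2  # gate blocked the 40 µm jump
        assert [len(t.frames) for t in tracks] == [1, 1]

    def test_greedy_behavior_documented_on_truth(self):
        labels, truth = two_cell_stack(step_b=(1.0, 0.0))
        tracks = track_cells(labels, 0.25, 2.0)
        # both manifest cells recovered with their full lifetimes
        assert sorted(len(t.frames) for t in tracks) == [5, 5]


class TestTrackSpeed:
    def test_straight_path_unit_speed(self):
        tr = Track(
            cell_id=1,
            frames=np.arange(5),
            centroids_um=np.array(straight_path((0.0, 0.0), 2.0, 5)),
            frame_interval=2.0,
        )
        assert track_speed(tr, "mean") == pytest.approx(1.0)
        assert track_speed(tr, "median") == pytest.approx(1.0)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 30, size=(8, 2))
        tr = Track(1, np.arange(8), pts, 2.0)
        ang = 0.7
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        tr2 = Track(1, np.arange(8), pts @ R.T + np.array([5.0, -3.0]), 2.0)
        assert track_speed(tr2) == pytest.approx(track_speed(tr))
        assert track_speed(tr2, "mean") == pytest.approx(track_speed(tr, "mean"))

    def test_duplicate_frames_rejected(self):
        with pytest.raises(ValueError):
            Track(1, np.array([0, 0, 1]), np.zeros((3, 2)), 2.0)

    def test_single_point_track_has_no_speed(self):
        tr = Track(1, np.array([0]), np.zeros((1, 2)), 2.0)
        with pytest.raises(ValueError):
            track_speed(tr)

    def test_generator_speed_recovered(self):
        spec = CellTimelapseSpec(
            n_frames=6, frame_interval=2.0, width_schedule=[4.0] * 6,
            length=14.0, centroid_path=straight_path((12.0, 16.0), 2.0, 6),
            pixel_size=0.25, image_shape=(160, 256),
        )
        stack, _ = make_cell_timelapse(spec)
        tracks = track_cells(stack.astype(np.int32), 0.25, 2.0)
        assert track_speed(tracks[0], "median") == pytest.approx(1.0, abs=0.05)
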