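"""Geometry, binning, occupancy and epoch-slicing primitives."""

import numpy as np
import pytest
from matplotlib.path import Path as MplPath

from zebrabehave.core import (
    Arena,
    ArenaPartition,
    Epoch,
    LightSchedule,
    OutOfArenaError,
    Trajectory,
    binned_distance,
    equal_area_split,
    juvenile_sectors,
    larval_light_dark_schedule,
    path_length,
    point_in_zone,
    segment_epochs,
    zone_occupancy,
)

from conftest import (
    loop_binned_distance,
    loop_path_length,
    make_random_trajectory,
    oracle_center_membership,
)


class TestTrajectoryInvariants:
    def test_rejects_non_monotone_times(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            Trajectory("f", "WT", [0.0, 0.2, 0.1], [0, 0, 0], [0, 0, 0], fps=10)

    def test_rejects_fps_mismatch(self):
        t = np.arange(100) * 0.1  # 10 Hz data declared as 25 fps
        with pytest.raises(ValueError, match="sampling interval"):
            Trajectory("f", "WT", t, np.zeros(100), np.zeros(100), fps=25)

    def test_rejects_nonfinite_valid_samples(self):
        with pytest.raises(ValueError, match="finite"):
            Trajectory("f", "WT", [0.0, 0.04], [0.0, np.nan], [0.0, 0.0], fps=25)

    def test_rejects_unknown_genotype(self):
        with pytest.raises(ValueError, match="genotype"):
            Trajectory("f", "XX", [0.0], [0.0], [0.0], fps=25)


class TestPointInZone:
    def test_arena_centre_is_central(self, square_arena):
        part = equal_area_split(square_arena)
        assert point_in_zone((150.0, 150.0), part, "center")
        assert not point_in_zone((150.0, 150.0), part, "periphery")

    def test_corner_is_peripheral(self, square_arena):
        part = equal_area_split(square_arena)
        assert point_in_zone((0.0, 0.0), part, "periphery")
        assert not point_in_zone((0.0, 0.0), part, "center")

    def test_unknown_zone_errors(self, square_arena):
        part = equal_area_split(square_arena)
        with pytest.raises(KeyError, match="unknown zone"):
            point_in_zone((1.0, 1.0), part, "nowhere")

    def test_out_of_arena_errors(self, square_arena):
        part = equal_area_split(square_arena)
        with pytest.raises(OutOfArenaError):
            point_in_zone((-5.0, 10.0), part, "center")

    def test_boundary_belongs_to_first_listed_zone(self, square_arena):
        # the shared boundary of the equal-area split: periphery is listed first
        part = equal_area_split(square_arena)
        w, _ = square_arena.dims
        edge_x = (w - w / np.sqrt(2.0)) / 2.0
        assert point_in_zone((edge_x, 150.0), part, "periphery")
        assert not point_in_zone((edge_x, 150.0), part, "center")

    @pytest.mark.parametrize("shape", ["rectangle", "circle"])
    def test_matches_independent_containment_oracle(self, shape):
        arena = (Arena("rectangle", (300.0, 200.0)) if shape == "rectangle"
                 else Arena("circle", (22.1,)))
        part = equal_area_split(arena)
        rng = np.random.default_rng(42)
        xmin, ymin, xmax, ymax = arena.bounds()
        pts = []
        while len(pts) < 1000:
            px = rng.uniform(xmin, xmax)
            py = rng.uniform(ymin, ymax)
            if arena.contains(px, py):
                pts.append((px, py))
        for px, py in pts:
            expected = oracle_center_membership(arena, px, py)
            assert point_in_zone((px, py), part, "center") == expected

    def test_polygon_containment_against_matplotlib(self, square_arena):
        # same geometry, third-party point-in-polygon implementation
        part = equal_area_split(square_arena)
        poly = part.geometry("center")
        mpl = MplPath(np.asarray(poly.exterior.coords))
        rng = np.random.default_rng(7)
        xy = rng.uniform(0.0, 300.0, size=(1000, 2))
        ours = np.array([point_in_zone(tuple(p), part, "center") for p in xy])
        theirs = mpl.contains_points(xy)
        assert np.array_equal(ours, theirs)


class TestPathLength:
    def test_stationary_fish_is_zero(self):
        t = np.arange(10) * 0.04
        tr = Trajectory("f", "WT", t, np.full(10, 5.0), np.full(10, 5.0), fps=25)
        assert path_length(tr) == 0.0

    def test_three_four_five(self):
        tr = Trajectory("f", "WT", [0.0, 0.04], [0.0, 3.0], [0.0, 4.0], fps=25)
        assert path_length(tr) == pytest.approx(5.0, abs=1e-15)

    def test_matches_loop_oracle(self, square_arena):
        tr = make_random_trajectory(square_arena, duration_s=4.0, seed=3)  # 100 steps
        assert path_length(tr) == pytest.approx(loop_path_length(tr), rel=1e-12)

    def test_no_valid_samples_errors(self):
        tr = Trajectory("f", "WT", [0.0, 0.04], [0, 1], [0, 0],
                        valid=[False, False], fps=25)
        with pytest.raises(ValueError, match="no valid samples"):
            path_length(tr)


class TestBinnedDistance:
    def test_constant_speed_bins(self):
        # 1 mm/s along x for 5 min at 25 fps
        fps, dur = 25.0, 300.0
        t = np.arange(int(dur * fps) + 1) / fps
        tr = Trajectory("f", "WT", t, t * 1.0, np.zeros_like(t), fps=fps)
        bins = binned_distance(tr, 30.0)
        assert len(bins) == 10
        assert np.allclose(bins["distance_mm"], 30.0)

    def test_45_min_recording_gives_90_bins(self):
        fps = 25.0
        t = np.arange(int(2700 * fps) + 1) / fps
        tr = Trajectory("f", "WT", t, np.zeros_like(t), np.zeros_like(t), fps=fps)
        assert len(binned_distance(tr, 30.0)) == 90

    def test_matches_frame_loop_oracle(self, square_arena):
        tr = make_random_trajectory(square_arena, duration_s=90.0, seed=11)
        ours = binned_distance(tr, 30.0)["distance_mm"].to_numpy()
        oracle = loop_binned_distance(tr, 30.0)
        assert np.allclose(ours, oracle, rtol=1e-9, atol=1e-12)

    def test_bin_sums_conserve_path_length(self, square_arena):
        tr = make_random_trajectory(square_arena, duration_s=60.0, seed=5)
        bins = binned_distance(tr, 30.0)
        assert bins["distance_mm"].sum() == pytest.approx(path_length(tr), rel=1e-12)

    def test_short_recording_errors(self):
        t = np.arange(10) / 25.0
        tr = Trajectory("f", "WT", t, t, t, fps=25)
        with pytest.raises(ValueError, match="shorter than one bin"):
            binned_distance(tr, 30.0)


class TestGapHandling:
    def _gappy(self, gap_frames: int, fps: float = 25.0):
        n = 200
        t = np.arange(n) / fps
        x = np.linspace(0.0, 10.0, n)
        valid = np.ones(n, dtype=bool)
        valid[50 : 50 + gap_frames] = False
        return Trajectory("f", "WT", t, x, np.zeros(n), valid, fps=fps)

    def test_short_gap_is_bridged(self):
        tr = self._gappy(10)  # 0.4 s gap, linear path: interpolation is exact
        assert path_length(tr) == pytest.approx(10.0, rel=1e-12)

    def test_long_gap_excluded_from_accrual(self):
        tr = self._gappy(50)  # 2 s gap
        _, _, ok = tr.cleaned_xy()
        assert not ok[50:100].any()
        # the distance spanned by the gap is not accrued
        assert path_length(tr) < 10.0 * (1 - 45 / 200)

    def test_heavily_missing_bin_is_flagged(self):
        fps = 25.0
        n = int(60 * fps) + 1
        t = np.arange(n) / fps
        valid = np.ones(n, dtype=bool)
        valid[int(10 * fps) : int(25 * fps)] = False  # 15 s hole in bin 0
        tr = Trajectory("f", "WT", t, np.zeros(n), np.zeros(n), valid, fps=fps)
        bins = binned_distance(tr, 30.0)
        assert bool(bins["flagged"].iloc[0]) and not bool(bins["flagged"].iloc[1])


class TestZoneOccupancy:
    def test_single_zone_gets_full_duration(self, square_arena):
        part = equal_area_split(square_arena)
        n = 250
        t = np.arange(n) / 25.0
        tr = Trajectory("f", "WT", t, np.full(n, 150.0), np.full(n, 150.0), fps=25)
        occ = zone_occupancy(tr, part)
        assert occ["center"][0] == pytest.approx(n / 25.0)
        assert occ["periphery"] == (0.0, 0.0)

    def test_covering_partition_conserves_time(self, square_arena):
        part = equal_area_split(square_arena)
        tr = make_random_trajectory(square_arena, duration_s=30.0, seed=9)
        occ = zone_occupancy(tr, part)
        total = sum(v[0] for v in occ.values())
        assert total == pytest.approx(len(tr) / tr.fps, abs=1.0 / tr.fps)

    def test_matches_per_frame_classification_oracle(self, square_arena):
        part = equal_area_split(square_arena)
        tr = make_random_trajectory(square_arena, duration_s=20.0, seed=13)
        occ = zone_occupancy(tr, part)
        t_center = sum(
            1.0 / tr.fps
            for i in range(len(tr))
            if oracle_center_membership(square_arena, tr.x[i], tr.y[i])
        )
        assert occ["center"][0] == pytest.approx(t_center, rel=1e-12)

    def test_empty_window_errors(self, square_arena):
        part = equal_area_split(square_arena)
        tr = make_random_trajectory(square_arena, duration_s=5.0, seed=1)
        with pytest.raises(ValueError, match="empty window"):
            zone_occupancy(tr, part, window=(3.0, 3.0))


class TestSegmentEpochs:
    def test_default_larval_schedule_structure(self):
        sched = larval_light_dark_schedule()
        assert sched.labels == ["baseline", "L0", "D1", "L1", "D2", "L2", "D3", "L3"]
        for lab in ["D1", "L1", "D2", "L2", "D3", "L3"]:
            e = next(e for e in sched.epochs if e.label == lab)
            assert e.end_s - e.start_s == 300.0
        dirs = [d for _, d in sched.transitions]
        assert dirs == ["light_to_dark", "dark_to_light"] * 3
        light = [e for e in sched.epochs if e.illumination == "light"]
        assert all(e.lux == 100.0 for e in light)

    def test_slices_partition_the_schedule(self, square_arena):
        sched = larval_light_dark_schedule(20.0, 10.0, 10.0, 3)
        tr = make_random_trajectory(square_arena, duration_s=sched.duration, seed=2)
        parts = segment_epochs(tr, sched)
        counts = sum(len(p) for p in parts.values())
        in_schedule = np.sum((tr.t >= sched.start_s) & (tr.t <= sched.end_s))
        assert counts == in_schedule
        # sample-for-sample reconstruction
        recon = np.concatenate([parts[lab].t for lab in sched.labels])
        assert np.array_equal(recon, tr.t[(tr.t >= sched.start_s) & (tr.t <= sched.end_s)])

    def test_empty_schedule_errors(self):
        with pytest.raises(ValueError, match="at least one epoch"):
            LightSchedule([])

    def test_schedule_longer_than_recording_errors(self, square_arena):
        sched = larval_light_dark_schedule()
        tr = make_random_trajectory(square_arena, duration_s=10.0, seed=2)
        with pytest.raises(ValueError, match="longer than recording"):
            segment_epochs(tr, sched)


class TestPartitionValidation:
    def test_overlapping_zones_rejected(self, square_arena):
        from shapely.geometry import box

        with pytest.raises(ValueError, match="overlap"):
            ArenaPartition(square_arena,
                           [("a", box(0, 0, 200, 300)), ("b", box(100, 0, 300, 300))])

    def test_juvenile_sectors_are_quarter_bands(self, circle_arena):
        part = juvenile_sectors(circle_arena)
        (d,) = circle_arena.dims
        r = d / 2.0
        assert point_in_zone((0.0, 0.9 * r), part, "conspecific")
        assert point_in_zone((0.0, -0.9 * r), part, "empty")
        # the middle half of the well belongs to neither sector
        assert not point_in_zone((0.0, 0.0), part, "conspecific")
        assert not point_in_zone((0.0, 0.0), part, "empty")
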