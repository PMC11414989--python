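"""Preprocessing: centering, forward-fill, outlier capping, phase framing."""

import numpy as np
import pandas as pd
import pytest

from lprscreen.preprocess import (
    FeatureScaler,
    WellGeometry,
    apply_scaler,
    cap_outliers,
    center_coordinates,
    compute_angular_velocity,
    compute_outlier_threshold,
    downsample_tensor,
    extract_phase,
    fit_scaler,
    forward_fill,
    invert_scaler,
    preprocess_track,
)
from lprscreen.synthetic_data import BehaviorParams, simulate_larva
from lprscreen.track_data import AssaySchedule, Phase

from conftest import make_track


class TestOutlierThreshold:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((3.9, 2.5, 120, 40), 3.25),  # 5 dpf larva, startle response, 25 fps
            ((1, 1, 40, 40), 1.0),
            ((2, 3, 120, 40), 2.0),
        ],
    )
    def test_values(self, args, expected):
        assert compute_outlier_threshold(*args) == pytest.approx(expected)

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            compute_outlier_threshold(0, 2.5, 120, 40)


class TestCenterCoordinates:
    geometry = WellGeometry(radius=3.25, centers={"A1": (10.0, 20.0)})

    def test_well_center_maps_to_origin(self):
        tr = make_track([0.0], x=[10.0], y=[20.0])
        out = center_coordinates(tr, self.geometry)
        assert out.frames.loc[0, ["x", "y"]].tolist() == [0.0, 0.0]

    def test_boundary_point_stays_on_boundary(self):
        tr = make_track([0.0], x=[10.0 + 3.25], y=[20.0])
        out = center_coordinates(tr, self.geometry)
        assert out.frames.loc[0, "x"] == pytest.approx(3.25)
        assert out.frames.loc[0, "y"] == pytest.approx(0.0)

    def test_outside_point_clipped_along_bearing(self):
        # a point 2r out must land at radius r with the same unit bearing
        dx, dy = 2 * 3.25 * 0.6, 2 * 3.25 * 0.8
        tr = make_track([0.0], x=[10.0 + dx], y=[20.0 + dy])
        out = center_coordinates(tr, self.geometry)
        x, y = out.frames.loc[0, "x"], out.frames.loc[0, "y"]
        assert np.hypot(x, y) == pytest.approx(3.25)
        np.testing.assert_allclose(
            [x, y] / np.hypot(x, y), [dx, dy] / np.hypot(dx, dy)
        )

    def test_unknown_well_raises(self):
        geo = WellGeometry(radius=3.25, centers={}, default_center=None)
        with pytest.raises(KeyError, match="A1"):
            center_coordinates(make_track([0.0]), geo)


class TestForwardFill:
    sched = AssaySchedule(acclimation=0.2, cycle_light=0.2, cycle_dark=0.1, n_cycles=1)

    def test_complete_track_unchanged(self):
        n = int(round(self.sched.total_duration * 10))
        tr = make_track(np.full(n, 0.1))
        out = forward_fill(tr, self.sched, 10.0)
        pd.testing.assert_frame_equal(out.frames, tr.frames)

    def test_missing_interior_frame_filled(self):
        # 5-frame grid at 10 fps; frame index 2 missing
        tr = make_track(
            [0.0, 0.1, 0.1, 0.1],
            t=[0.0, 0.1, 0.3, 0.4],
            x=[0.0, 1.0, 3.0, 4.0],
            y=[0.0, 0.5, 1.5, 2.0],
        )
        out = forward_fill(tr, self.sched, 10.0)
        assert out.n_frames == 5
        filled = out.frames.iloc[2]
        assert filled["x"] == 1.0 and filled["y"] == 0.5
        assert filled["dist"] == 0.0
        assert filled["vel"] == out.frames.iloc[1]["vel"]

    def test_single_frame_becomes_constant_track(self):
        tr = make_track([0.3], t=[0.1], x=[2.0], y=[1.0])
        out = forward_fill(tr, self.sched, 10.0)
        assert out.n_frames == 5
        assert (out.frames["x"] == 2.0).all()
        assert out.frames["dist"].tolist() == [0.0, 0.3, 0.0, 0.0, 0.0]

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            forward_fill(make_track([]), self.sched, 10.0)


class TestCapOutliers:
    def test_below_cap_unchanged(self):
        tr = make_track([0.1, 0.2, 0.3])
        out, n = cap_outliers(tr, cap=3.25)
        assert n == 0
        pd.testing.assert_frame_equal(out.frames, tr.frames)

    def test_single_outlier_capped_with_velocity(self):
        tr = make_track([0.1, 10.0, 0.2], frame_rate=25.0)
        out, n = cap_outliers(tr, cap=3.25)
        assert n == 1
        assert out.frames.loc[1, "dist"] == 3.25
        assert out.frames.loc[1, "vel"] == pytest.approx(3.25 * 25)

    def test_all_frames_capped(self):
        tr = make_track([5.0, 6.0, 7.0])
        out, n = cap_outliers(tr, cap=3.25)
        assert n == 3
        assert (out.frames["dist"] == 3.25).all()


@pytest.fixture(scope="module")
def full_track():
    tr = simulate_larva(
        BehaviorParams(missing_frame_prob=0.01), seed=3, frame_rate=25.0
    )
    return preprocess_track(tr)


class TestExtractPhase:

    def test_cycle2_windows_match_brute_force_scan(self, full_track):
        sched = AssaySchedule()
        t = full_track.frames["t"].to_numpy()
        for phase, (lo, hi) in [
            (Phase.LIGHT, (720.0, 900.0)),
            (Phase.DARK, (900.0, 1080.0)),
        ]:
            tensor = extract_phase(full_track, 2, phase, sched)
            expected = full_track.frames["x"].to_numpy()[(t >= lo) & (t < hi)]
            np.testing.assert_array_equal(tensor.matrix[:, 1], expected)
            # t column is re-zeroed to the window start
            assert tensor.matrix[0, 0] == 0.0
            assert tensor.matrix[-1, 0] == pytest.approx(180.0 - 1 / 25)

    def test_full_scale_tensor_shape(self, full_track):
        tensor = extract_phase(full_track, 2, Phase.LIGHT)
        assert tensor.matrix.shape == (4500, 5)
        assert tensor.flatten().shape == (22500,)

    def test_light_dark_windows_disjoint_and_contiguous(self):
        sched = AssaySchedule()
        for cycle in (1, 2, 3):
            l0, l1 = sched.phase_window(cycle, Phase.LIGHT)
            d0, d1 = sched.phase_window(cycle, Phase.DARK)
            assert l1 == d0 and d1 - l0 == 360.0

    def test_short_track_rejected(self):
        with pytest.raises(ValueError, match="forward_fill"):
            extract_phase(make_track([0.1] * 10), 2, Phase.LIGHT)

    def test_frame_major_flattening(self):
        mat = np.arange(20.0).reshape(4, 5)
        from lprscreen.preprocess import PhaseTensor

        t = PhaseTensor("s", Phase.LIGHT, 2, mat)
        np.testing.assert_array_equal(t.flatten()[:5], mat[0])


class TestDownsample:
    def test_distance_conserved(self):
        tr = preprocess_track(
            simulate_larva(BehaviorParams(missing_frame_prob=0), seed=5)
        )
        tensor = extract_phase(tr, 2, Phase.DARK)
        small = downsample_tensor(tensor, 5)
        assert small.matrix.shape == (900, 5)
        assert small.matrix[:, 3].sum() == pytest.approx(tensor.matrix[:, 3].sum())

    def test_uneven_factor_rejected(self):
        tr = preprocess_track(simulate_larva(BehaviorParams(), seed=5))
        tensor = extract_phase(tr, 2, Phase.DARK)
        with pytest.raises(ValueError):
            downsample_tensor(tensor, 7)


class TestScaler:
    def _tensor(self, mat):
        from lprscreen.preprocess import PhaseTensor

        return PhaseTensor("s", Phase.LIGHT, 2, mat)

    def test_scaled_controls_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        tensors = [self._tensor(rng.normal(3, 2, size=(50, 5))) for _ in range(4)]
        sc = fit_scaler(tensors)
        stacked = np.vstack([apply_scaler(sc, t).matrix for t in tensors])
        np.testing.assert_allclose(stacked.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(stacked.std(axis=0), 1, atol=1e-12)

    def test_apply_invert_identity(self):
        rng = np.random.default_rng(1)
        tensors = [self._tensor(rng.normal(size=(20, 5))) for _ in range(3)]
        sc = fit_scaler(tensors)
        back = invert_scaler(sc, apply_scaler(sc, tensors[0]))
        np.testing.assert_allclose(back.matrix, tensors[0].matrix, atol=1e-9)

    def test_two_tensor_fixture_matches_hand_zscores(self):
        a = self._tensor(np.tile([0.0, 1.0, 2.0, 3.0, 4.0], (2, 1)))
        b = self._tensor(np.tile([2.0, 3.0, 4.0, 5.0, 6.0], (2, 1)))
        sc = fit_scaler([a, b])
        # each feature has values {v, v+2} twice: mean v+1, population sd 1
        np.testing.assert_allclose(sc.mean, [1.0, 2.0, 3.0, 4.0, 5.0])
        np.testing.assert_allclose(sc.scale, np.ones(5))
        np.testing.assert_allclose(apply_scaler(sc, a).matrix[0], -np.ones(5))

    def test_zero_variance_feature_named(self):
        a = self._tensor(np.column_stack([np.arange(4.0)] * 4 + [np.ones(4)]))
        b = self._tensor(np.column_stack([np.arange(4.0) + 1] * 4 + [np.ones(4)]))
        with pytest.raises(ValueError, match="vel"):
            fit_scaler([a, b])

    def test_scaler_requires_positive_scale(self):
        with pytest.raises(ValueError):
            FeatureScaler(mean=np.zeros(5), scale=np.array([1, 1, 0, 1, 1.0]))


class TestTensorArchive:
    def test_roundtrip_with_scaler_and_config(self, tmp_path):
        from lprscreen.preprocess import PhaseTensor, load_tensors, save_tensors

        rng = np.random.default_rng(0)
        tensors = [
            PhaseTensor(f"s{i}", phase, 2, rng.normal(size=(20, 5)))
            for i in range(3)
            for phase in (Phase.LIGHT, Phase.DARK)
        ]
        sc = fit_scaler(tensors)
        path = tmp_path / "tensors.h5"
        save_tensors(tensors, path, scaler=sc, config={"downsample": 5})
        back, sc2, cfg = load_tensors(path)
        assert len(back) == len(tensors)
        orig = {(t.subject_id, t.phase): t.matrix for t in tensors}
        for t in back:
            np.testing.assert_array_equal(t.matrix, orig[(t.subject_id, t.phase)])
        np.testing.assert_allclose(sc2.mean, sc.mean)
        assert cfg == {"downsample": 5}


class TestAngularVelocity:
    def test_straight_line_is_zero(self):
        n = 10
        tr = make_track(np.full(n, 0.1), x=np.arange(n) * 0.1, y=np.zeros(n))
        np.testing.assert_allclose(compute_angular_velocity(tr), 0.0)

    def test_right_angle_turn_magnitude(self):
        tr = make_track(
            [0.0, 1.0, 1.0],
            x=[0.0, 1.0, 1.0],
            y=[0.0, 0.0, 1.0],
            frame_rate=25.0,
        )
        omega = compute_angular_velocity(tr)
        assert abs(omega[0]) == pytest.approx(90.0 / 0.04)

    def test_stationary_larva_is_zero(self):
        tr = make_track(np.zeros(8))
        np.testing.assert_allclose(compute_angular_velocity(tr), 0.0)

    def test_heading_carried_over_pause(self):
        # move east, pause, move east: no turning
        tr = make_track(
            [0.0, 1.0, 0.0, 1.0],
            x=[0.0, 1.0, 1.0, 2.0],
            y=np.zeros(4),
        )
        np.testing.assert_allclose(compute_angular_velocity(tr), 0.0)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            compute_angular_velocity(make_track([0.0, 0.1]))


class TestPipelineProperties:
    def test_preprocessing_is_idempotent(self, mini_schedule):
        tr = simulate_larva(
            BehaviorParams(missing_frame_prob=0.02),
            schedule=mini_schedule,
            frame_rate=10.0,
            seed=11,
        )
        once = preprocess_track(tr, schedule=mini_schedule)
        twice = preprocess_track(once, schedule=mini_schedule)
        pd.testing.assert_frame_equal(once.frames, twice.frames)

    def test_distance_matches_displacement_before_capping(self, mini_schedule):
        tr = simulate_larva(
            BehaviorParams(missing_frame_prob=0),
            schedule=mini_schedule,
            frame_rate=10.0,
            seed=12,
        )
        f = tr.frames
        d = np.hypot(np.diff(f["x"]), np.diff(f["y"]))
        np.testing.assert_allclose(f["dist"].to_numpy()[1:], d, atol=1e-6)
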