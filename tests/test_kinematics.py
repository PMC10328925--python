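"""Displacement, turning angle, axis continuity, uMM/sMM and Δϕ."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from morphomig import (
    TrackConfig,
    compute_track,
    ma_dynamics,
    propagate_axis_directions,
    resample_track,
    signed_angle,
    turning_angle,
    umm_angle,
)
from morphomig.geometry import ShapeState, fit_second_moment_ellipse
from morphomig.kinematics import displacement
from morphomig.synthetic import Scenario, frames_from_arrays, simulate


def _shape(x, y, phi=0.0, eps=0.5, index=1, dt=1.0):
    return ShapeState(
        frame_index=index,
        time_s=(index - 1) * dt,
        centroid_x_um=x,
        centroid_y_um=y,
        minor_axis_a_um=20.0 * (1 - eps),
        major_axis_b_um=20.0,
        orientation_phi_deg=phi,
        elongation_eps=eps,
        area_um2=100.0,
    )


def _track_shapes(points, phis=None, eps=0.5):
    phis = phis if phis is not None else [0.0] * len(points)
    return [
        _shape(x, y, phi, eps, index=i + 1)
        for i, ((x, y), phi) in enumerate(zip(points, phis))
    ]


class TestDisplacement:
    def test_three_four_five(self, unit_config):
        dx, dy, norm, speed, flagged = displacement(
            _shape(0, 0), _shape(3, 4), unit_config
        )
        assert (dx, dy, norm) == (3, 4, 5)
        assert not flagged

    def test_identical_centroids_flagged(self, unit_config):
        *_, norm, _, flagged = displacement(_shape(1, 1), _shape(1, 1), unit_config)
        assert norm == 0 and flagged

    def test_speed_uses_frame_interval(self):
        config = TrackConfig(pixel_size_um=1.0, frame_interval_s=10.0)
        *_, speed, _ = displacement(_shape(0, 0), _shape(3, 4), config)
        assert speed == pytest.approx(0.5)


class TestSignedAngle:
    # screen coordinates (y down): right → down is a clockwise turn, positive
    @pytest.mark.parametrize(
        "p, q, expected",
        [
            ((1, 0), (0, 1), 90.0),
            ((1, 0), (0, -1), -90.0),
            ((1, 0), (1, 1), 45.0),
            ((1, 0), (1, 0), 0.0),
            ((1, 0), (-1, 0), 180.0),
        ],
    )
    def test_forced_conventions(self, p, q, expected):
        assert signed_angle(p, q) == pytest.approx(expected)

    @given(
        st.floats(-1e3, 1e3), st.floats(-1e3, 1e3),
        st.floats(-1e3, 1e3), st.floats(-1e3, 1e3),
    )
    @settings(max_examples=200, derandomize=True)
    def test_range_contract(self, px, py, qx, qy):
        if math.hypot(px, py) < 1e-6 or math.hypot(qx, qy) < 1e-6:
            return
        ang = signed_angle((px, py), (qx, qy))
        assert -180.0 < ang <= 180.0


class TestTurningAngle:
    def test_straight_motion_is_zero(self):
        assert turning_angle((2, 1), (2, 1)) == pytest.approx(0.0)

    def test_exact_reversal_is_180(self):
        assert abs(turning_angle((1, 0.5), (-1, -0.5))) == pytest.approx(180.0)

    def test_missing_displacement_gives_nan_not_exception(self):
        assert math.isnan(turning_angle(None, (1, 0)))
        assert math.isnan(turning_angle((1, 0), None))


class TestAxisContinuity:
    def test_constant_orientation_constant_direction(self):
        dirs = propagate_axis_directions([30.0] * 5)
        assert all(d == dirs[0] for d in dirs)

    def test_near_180_wrap_is_flipped(self):
        # 10° → 170° must read as a −20° swing, not +160°
        u1, u2 = propagate_axis_directions([10.0, 170.0])
        assert u1[0] * u2[0] + u1[1] * u2[1] >= 0
        assert ma_dynamics(u1, u2) == pytest.approx(-20.0, abs=1e-9)

    def test_perpendicular_tie_resolves_to_plus_90(self):
        u1, u2 = propagate_axis_directions([0.0, 90.0])
        assert ma_dynamics(u1, u2) == pytest.approx(90.0)

    @given(st.lists(st.floats(0.0, 179.99), min_size=2, max_size=30))
    @settings(max_examples=100, derandomize=True)
    def test_directions_are_unit_and_continuous(self, phis):
        dirs = propagate_axis_directions(phis)
        for u in dirs:
            assert math.hypot(*u) == pytest.approx(1.0)
        for a, b in zip(dirs, dirs[1:]):
            assert a[0] * b[0] + a[1] * b[1] >= 0
            assert abs(ma_dynamics(a, b)) <= 90.0 + 1e-9


class TestUmmAngle:
    @pytest.mark.parametrize(
        "u, d, expected",
        [((1, 0), (2, 0), 0.0), ((1, 0), (0, 3), 90.0), ((1, 0), (1, 1), 45.0)],
    )
    def test_analytic_cases(self, u, d, expected):
        assert umm_angle(u, d) == pytest.approx(expected)

    def test_invariant_to_axis_flip(self):
        assert umm_angle((1, 0), (1, 2)) == pytest.approx(umm_angle((-1, 0), (1, 2)))


class TestComputeTrack:
    def test_descriptor_counts_for_91_frames(self, unit_config):
        pts = [(10 + 2 * i, 20 + 0.5 * i) for i in range(91)]
        steps = compute_track(_track_shapes(pts), unit_config)
        assert len(steps) == 90
        assert sum(1 for s in steps if not math.isnan(s.sMM_deg)) == 90
        assert sum(1 for s in steps if not math.isnan(s.turning_alpha_deg)) == 89
        assert sum(1 for s in steps if not math.isnan(s.ma_dynamics_dphi_deg)) == 90

    def test_stationary_track_is_all_flagged(self, unit_config):
        steps = compute_track(_track_shapes([(5, 5)] * 6), unit_config)
        assert all(s.zero_displacement for s in steps)
        assert all(math.isnan(s.sMM_deg) for s in steps)
        assert all(math.isnan(s.turning_alpha_deg) for s in steps)
        assert all(s.ma_dynamics_dphi_deg == 0 for s in steps)

    def test_fewer_than_two_frames_rejected(self, unit_config):
        with pytest.raises(ValueError, match=">= 2"):
            compute_track(_track_shapes([(0, 0)]), unit_config)

    def test_side_flip_changes_smm_sign(self, unit_config):
        # axis along x; displacement first below the axis on screen (+y),
        # then crossing to the other side
        pts = [(0, 0), (3, 1), (6, 2), (9, 1), (12, 0)]
        steps = compute_track(_track_shapes(pts), unit_config)
        signs = [math.copysign(1, s.sMM_deg) for s in steps]
        assert signs == [1, 1, -1, -1]
        for s in steps:
            assert abs(s.sMM_deg) == pytest.approx(s.uMM_deg)

    def test_reference_side_is_fixed_at_first_sided_step(self, unit_config):
        # first step exactly along the axis (side 0, flagged no-reference),
        # second step establishes the reference
        pts = [(0, 0), (3, 0), (6, 1), (9, 2)]
        steps = compute_track(_track_shapes(pts), unit_config)
        assert steps[0].no_reference_side
        assert steps[0].sMM_deg == pytest.approx(0.0)
        assert steps[1].sMM_deg > 0

    def test_motion_along_axis_is_plus_zero(self, unit_config):
        pts = [(0, 0), (4, 0), (8, 0)]
        steps = compute_track(_track_shapes(pts), unit_config)
        for s in steps:
            assert s.sMM_deg == 0.0 and math.copysign(1, s.sMM_deg) == 1

    def test_low_elongation_flag_follows_cutoff(self, unit_config):
        pts = [(0, 0), (4, 0), (8, 0)]
        steps = compute_track(_track_shapes(pts, eps=0.05), unit_config)
        assert all(s.low_elongation for s in steps)
        steps = compute_track(_track_shapes(pts, eps=0.5), unit_config)
        assert not any(s.low_elongation for s in steps)

    def test_dphi_handedness_is_configurable(self):
        cfg = TrackConfig(1.0, 1.0, dphi_clockwise_positive=False)
        pts = [(0, 0), (4, 0), (8, 0)]
        steps = compute_track(_track_shapes(pts, phis=[0, 5, 10]), cfg)
        assert steps[0].ma_dynamics_dphi_deg == pytest.approx(-5.0)


class TestResample:
    def test_identity_at_k_1(self, unit_config):
        shapes = _track_shapes([(i, 0) for i in range(10)])
        kept, cfg = resample_track(shapes, unit_config, 1)
        assert len(kept) == 10 and cfg.frame_interval_s == 1.0

    def test_91_frames_k3_keeps_31(self, unit_config):
        shapes = _track_shapes([(i, 0) for i in range(91)])
        kept, cfg = resample_track(shapes, unit_config, 3)
        assert len(kept) == 31
        assert cfg.frame_interval_s == 3.0
        assert [s.frame_index for s in kept[:3]] == [1, 2, 3]
        assert kept[1].time_s == 3.0  # absolute times preserved

    def test_constant_velocity_glider_smm_unchanged(self, unit_config):
        masks, _ = simulate(Scenario.preset("lateral_mover", seed=0, n_frames=20))
        frames = frames_from_arrays(masks, unit_config)
        shapes = [fit_second_moment_ellipse(f, unit_config) for f in frames]
        smm_full = [s.sMM_deg for s in compute_track(shapes, unit_config)]
        kept, cfg = resample_track(shapes, unit_config, 4)
        smm_k = [s.sMM_deg for s in compute_track(kept, cfg)]
        assert np.nanmean(np.abs(smm_k)) == pytest.approx(
            np.nanmean(np.abs(smm_full)), abs=0.5
        )

    def test_k_too_large_rejected(self, unit_config):
        shapes = _track_shapes([(i, 0) for i in range(5)])
        with pytest.raises(ValueError):
            resample_track(shapes, unit_config, 5)
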