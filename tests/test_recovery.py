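"""Edge recovery: triple solver, least squares, gating, bar estimation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import sbfsim as sbf
from sbfsim.recovery import Percept, Status

from conftest import angle_diff_mod180, brute_force_edge, random_edge_triple


def _ev(x, y, t, kind="offset", eid=0):
    return sbf.TransformationEvent(eid, x, y, t, kind)


class TestTripleSolver:
    def test_vertical_bar_triple_across_the_fold(self):
        # sawtooth points crossed by a vertical edge at 10 deg/s
        e0 = _ev(0.4, 0.4, 40.0, eid=1)
        e1 = _ev(0.8, 0.8, 80.0, eid=2)
        e2 = _ev(1.2, 0.4, 120.0, eid=3)
        est = sbf.recover_edge_from_triple(e0, e1, e2)
        assert est.status is Status.UNIQUE
        assert angle_diff_mod180(est.orientation_deg, 90.0) < 1e-9
        assert est.normal_speed_deg_s == pytest.approx(10.0, rel=1e-12)
        assert est.normal_direction == pytest.approx((1.0, 0.0))

    def test_collinear_triple_is_ambiguous(self):
        est = sbf.recover_edge_from_triple(
            _ev(0.0, 0.0, 0.0), _ev(0.4, 0.4, 17.0, eid=1), _ev(0.8, 0.8, 60.0, eid=2)
        )
        assert est.status is Status.AMBIGUOUS_COLLINEAR
        assert est.orientation_deg is None

    def test_simultaneous_noncollinear_events_are_inconsistent(self):
        est = sbf.recover_edge_from_triple(
            _ev(0.0, 0.0, 10.0), _ev(0.4, 0.4, 10.0, eid=1), _ev(0.8, 0.0, 10.0, eid=2)
        )
        assert est.status is Status.INCONSISTENT

    def test_duplicate_positions_are_insufficient(self):
        est = sbf.recover_edge_from_triple(
            _ev(0.0, 0.0, 0.0), _ev(0.0, 0.0, 10.0, eid=1), _ev(0.8, 0.4, 20.0, eid=2)
        )
        assert est.status is Status.INSUFFICIENT

    def test_nonfinite_input_raises(self):
        with pytest.raises(sbf.ParameterError):
            sbf.recover_edge_from_triple(
                _ev(0.0, 0.0, 0.0), _ev(0.4, math.nan, 10.0, eid=1), _ev(0.8, 0.0, 20.0, eid=2)
            )

    def test_matches_brute_force_oracle_on_random_triples(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            events, theta, speed = random_edge_triple(rng)
            est = sbf.recover_edge_from_triple(*events)
            assert est.status is Status.UNIQUE
            P = np.array([[e.x_deg, e.y_deg] for e in events])
            t = np.array([e.time_ms for e in events])
            theta_bf, speed_bf = brute_force_edge(P, t)
            assert angle_diff_mod180(est.orientation_deg, theta_bf) <= 0.5
            assert abs(est.normal_speed_deg_s - speed_bf) / speed_bf <= 0.01
            # and both agree with the generating edge
            assert angle_diff_mod180(est.orientation_deg, theta) < 1e-6
            assert est.normal_speed_deg_s == pytest.approx(speed, rel=1e-9)

    @given(
        phi=st.floats(0.0, 360.0),
        seed=st.integers(0, 10_000),
    )
    def test_rotation_equivariance(self, phi, seed):
        rng = np.random.default_rng(seed)
        events, theta, speed = random_edge_triple(rng)
        c, s = math.cos(math.radians(phi)), math.sin(math.radians(phi))
        R = np.array([[c, -s], [s, c]])
        rotated = [
            sbf.TransformationEvent(e.element_id, *(R @ e.position), e.time_ms, e.kind)
            for e in events
        ]
        est = sbf.recover_edge_from_triple(*rotated)
        assert est.status is Status.UNIQUE
        assert angle_diff_mod180(est.orientation_deg, (theta + phi) % 180.0) < 1e-6
        assert est.normal_speed_deg_s == pytest.approx(speed, rel=1e-9)

    @given(
        dt=st.floats(0.0, 500.0),
        seed=st.integers(0, 10_000),
    )
    def test_time_shift_invariance(self, dt, seed):
        rng = np.random.default_rng(seed)
        events, theta, speed = random_edge_triple(rng)
        shifted = [
            sbf.TransformationEvent(e.element_id, e.x_deg, e.y_deg, e.time_ms + dt, e.kind)
            for e in events
        ]
        a = sbf.recover_edge_from_triple(*events)
        b = sbf.recover_edge_from_triple(*shifted)
        assert angle_diff_mod180(a.orientation_deg, b.orientation_deg) < 1e-9
        assert a.normal_speed_deg_s == pytest.approx(b.normal_speed_deg_s, rel=1e-9)

    @given(seed=st.integers(0, 10_000))
    def test_collinear_inputs_never_yield_an_orientation(self, seed):
        rng = np.random.default_rng(seed)
        p0 = rng.uniform(0, 2, 2)
        d = rng.uniform(-1, 1, 2)
        while np.linalg.norm(d) < 1e-3:
            d = rng.uniform(-1, 1, 2)
        events = [
            _ev(*(p0 + k * d), float(rng.uniform(0, 100)), eid=k) for k in range(3)
        ]
        est = sbf.recover_edge_from_triple(*events)
        assert est.status in (Status.AMBIGUOUS_COLLINEAR, Status.INSUFFICIENT)
        assert est.orientation_deg is None


class TestLeastSquares:
    def test_three_events_match_the_closed_form(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            events, _, _ = random_edge_triple(rng)
            tri = sbf.recover_edge_from_triple(*events)
            lsq = sbf.recover_edge_lsq(events)
            assert lsq.status is Status.UNIQUE
            assert angle_diff_mod180(lsq.orientation_deg, tri.orientation_deg) < 1e-8
            assert lsq.normal_speed_deg_s == pytest.approx(tri.normal_speed_deg_s, rel=1e-8)

    def test_noiseless_schedule_recovers_generator_exactly(self, fast_schedule):
        offs = fast_schedule.by_kind("offset")[:10]
        est = sbf.recover_edge_lsq(offs)
        assert est.status is Status.UNIQUE
        assert angle_diff_mod180(est.orientation_deg, 90.0) < 1e-9
        assert est.normal_speed_deg_s == pytest.approx(13.2, rel=1e-9)
        assert est.residual_rms_ms == pytest.approx(0.0, abs=1e-9)

    def test_time_noise_appears_in_the_residual(self):
        rng = np.random.default_rng(11)
        geom = sbf.build_sawtooth(0.4, n_dots=21)
        bar = sbf.VirtualBar(width_deg=0.3, speed_deg_s=10.0, start_x_deg=-0.3)
        resids = []
        for _ in range(30):
            sched = sbf.schedule_bar_events(geom, bar)
            offs = [
                sbf.TransformationEvent(
                    e.element_id, e.x_deg, e.y_deg, e.time_ms + rng.normal(0, 2.0), e.kind
                )
                for e in sched.by_kind("offset")
            ]
            est = sbf.recover_edge_lsq(offs)
            resids.append(est.residual_rms_ms)
        assert 1.0 < float(np.mean(resids)) < 3.0

    def test_collinear_point_set_is_rank_deficient(self):
        events = [_ev(0.1 * k, 0.2 * k, 5.0 * k, eid=k) for k in range(6)]
        assert sbf.recover_edge_lsq(events).status is Status.AMBIGUOUS_COLLINEAR

    def test_fewer_than_three_events_insufficient(self):
        events = [_ev(0.0, 0.0, 0.0), _ev(0.4, 0.4, 10.0, eid=1)]
        assert sbf.recover_edge_lsq(events).status is Status.INSUFFICIENT

    def test_mixed_kinds_rejected(self):
        events = [
            _ev(0.0, 0.0, 0.0),
            _ev(0.4, 0.4, 10.0, kind="onset", eid=1),
            _ev(0.8, 0.0, 20.0, eid=2),
        ]
        with pytest.raises(sbf.ParameterError):
            sbf.recover_edge_lsq(events)


class TestGating:
    def test_short_soa_chain_forms_one_group_with_all_offsets(self, exp1_geometry):
        bar = sbf.VirtualBar(width_deg=0.2, speed_deg_s=13.2, start_x_deg=-0.2)  # SOA ~30 ms
        sched = sbf.schedule_bar_events(exp1_geometry, bar)
        groups = sbf.gate_events(sched, kinds=("offset",))
        assert len(groups) == 1
        assert len(groups[0]) == len(sched.by_kind("offset"))

    def test_soa_150ms_schedule_is_gated_out(self, exp1_geometry):
        bar = sbf.VirtualBar(width_deg=0.2, speed_deg_s=2.6, start_x_deg=-0.2)  # SOA ~154 ms
        sched = sbf.schedule_bar_events(exp1_geometry, bar)
        assert sbf.gate_events(sched, kinds=("offset",)) == []

    def test_three_events_at_the_gate_span_160ms(self):
        events = [_ev(0.0, 0.0, 0.0), _ev(0.4, 0.4, 80.0, eid=1), _ev(0.8, 0.0, 160.0, eid=2)]
        sched = sbf.EventSchedule.from_events(events)
        groups = sbf.gate_events(sched, kinds=("offset",))
        assert len(groups) == 1
        assert len(groups[0]) == 3
        assert groups[0][-1].time_ms - groups[0][0].time_ms == pytest.approx(160.0)


class TestBarEstimate:
    @pytest.mark.parametrize("width,speed,spacing", [
        (0.13, 13.2, 0.4),
        (0.53, 13.2, 0.4),   # EOD > SOA, overlapping occlusions
        (0.39, 7.9, 0.2),
        (0.26, 10.5, 0.6),
    ])
    def test_round_trip_recovery_of_bar_parameters(self, width, speed, spacing):
        geom = sbf.build_sawtooth(spacing, n_dots=15)
        bar = sbf.VirtualBar(width_deg=width, speed_deg_s=speed, start_x_deg=-width)
        sched = sbf.schedule_bar_events(geom, bar)
        est = sbf.estimate_bar(sched)
        assert est.percept is Percept.SBF
        assert angle_diff_mod180(est.orientation_deg, 90.0) < 1e-6
        assert est.speed_deg_s == pytest.approx(speed, rel=1e-9)
        assert est.width_deg == pytest.approx(width, rel=1e-9)
        assert est.width_consistent

    def test_gated_out_schedule_predicts_apparent_motion(self, exp1_geometry):
        bar = sbf.VirtualBar(width_deg=0.39, speed_deg_s=2.6, start_x_deg=-0.39)
        sched = sbf.schedule_bar_events(exp1_geometry, bar)
        est = sbf.estimate_bar(sched)
        assert est.percept is Percept.APPARENT_MOTION
        assert est.width_deg is None

    def test_oblique_bar_recovers_normal_speed_and_perpendicular_width(self):
        geom = sbf.build_sawtooth(0.4, n_dots=15)
        bar = sbf.VirtualBar(
            width_deg=0.3, speed_deg_s=13.2, orientation_deg=60.0, start_x_deg=-2.0
        )
        sched = sbf.schedule_bar_events(geom, bar)
        cfg = sbf.RecoveryConfig(soa_gate_ms=120.0, window_ms=300.0)
        est = sbf.estimate_bar(sched, cfg)
        assert est.percept is Percept.SBF
        assert angle_diff_mod180(est.orientation_deg, 60.0) < 1e-6
        assert est.speed_deg_s == pytest.approx(bar.normal_speed_deg_s, rel=1e-9)
        assert est.width_deg == pytest.approx(0.3, rel=1e-9)


class TestPerceptPrediction:
    @pytest.mark.parametrize("spacing,speed,expected", [
        (0.4, 13.2, Percept.SBF),             # fast reference condition
        (0.4, 2.6, Percept.APPARENT_MOTION),  # slow reference condition
        (0.2, 2.6, Percept.SBF),              # closest spacing rescues slow bars
        (1.2, 13.2, Percept.APPARENT_MOTION),
        (2.0, 13.2, Percept.APPARENT_MOTION),
    ])
    def test_reference_pattern(self, spacing, speed, expected):
        bar = sbf.VirtualBar(width_deg=0.26, speed_deg_s=speed)
        assert sbf.predict_percept(spacing, bar) is expected
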