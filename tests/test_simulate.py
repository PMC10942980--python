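import numpy as np
import pytest

from overstride.gait import detect_foot_contacts, peak_braking_force
from overstride.imu import (sagittal_angle_per_frame_method,
                            static_pose_calibrate)
from overstride.kinematics import marker_xyz, overstriding_from_markers
from overstride.signal import filter_table
from overstride.simulate import (SimConfig, simulate_participant,
                                 simulate_stride_table)


class TestDeterminism:
    def test_same_seed_identical_output(self):
        cfg = SimConfig(n_participants=1, tm_duration=4, og_duration=4,
                        seed=5)
        a1, t1 = simulate_participant(cfg, 0)
        a2, t2 = simulate_participant(cfg, 0)
        assert a1 == a2
        for cond in t1:
            np.testing.assert_array_equal(
                t1[cond]["markers"].data.to_numpy(),
                t2[cond]["markers"].data.to_numpy())
        np.testing.assert_array_equal(t1["OG"]["imu"]["foot"].quat,
                                      t2["OG"]["imu"]["foot"].quat)

    def test_different_seed_differs(self):
        cfg = SimConfig(n_participants=1, tm_duration=4, og_duration=4)
        a1, _ = simulate_participant(cfg.__class__(**{
            **cfg.__dict__, "seed": 1}), 0)
        a2, _ = simulate_participant(cfg.__class__(**{
            **cfg.__dict__, "seed": 2}), 0)
        assert a1.leg_length != a2.leg_length


class TestGeometricConsistency:
    def test_noiseless_overstriding_identity(self, noiseless_participant):
        cfg, (anthro, trials) = noiseless_participant
        for cond, tr in trials.items():
            if cond == "static":
                continue
            st = tr["truth"].strides
            m = tr["markers"]
            troch = marker_xyz(m, "trochanter")
            mall = marker_xyz(m, "lat_malleolus")
            for k in range(len(st)):
                v = overstriding_from_markers(troch, mall, m.time,
                                              tr["truth"].fc_times[k],
                                              anthro.leg_length)
                expect = (anthro.thigh_length
                          * np.sin(np.radians(st.theta_thigh_fc[k]))
                          + anthro.shank_length
                          * np.sin(np.radians(st.theta_shank_fc[k])))
                assert v.raw == pytest.approx(expect, abs=1e-9)

    def test_marker_and_imu_truth_consistent(self, noiseless_participant):
        # angles computed from markers equal the angles encoded in the
        # IMU stream before corruption
        from overstride.pipeline import _mocap_angles
        cfg, (anthro, trials) = noiseless_participant
        tr = trials["TM_SF85"]
        theta_m = _mocap_angles(tr["markers"])
        for seg in ("thigh", "shank", "foot"):
            np.testing.assert_allclose(theta_m[seg],
                                       tr["truth"].theta_true[seg],
                                       atol=1e-9)

    def test_noiseless_imu_recovers_truth(self, noiseless_participant):
        cfg, (anthro, trials) = noiseless_participant
        tr = trials["TM_SF80"]
        truth = tr["truth"]
        s = tr["imu"]["thigh"]
        mounting = static_pose_calibrate(s, (0.2, 1.4))
        ang = sagittal_angle_per_frame_method(s, mounting)
        true_at = np.interp(truth.lag + s.time, truth.time,
                            truth.theta_true["thigh"])
        np.testing.assert_allclose(ang.theta, true_at, atol=1e-6)


class TestEventTruth:
    def test_detected_events_match_truth(self, small_participant):
        anthro, trials = small_participant
        tr = trials["TM_SF90"]
        truth = tr["truth"]
        forces = filter_table(tr["forces"], 50.0)
        ev = detect_foot_contacts(forces.channel("f_z"), forces.sample_rate)
        n = len(truth.strides)
        np.testing.assert_allclose(ev.fc_times[:n + 1], truth.fc_times,
                                   atol=5e-4)
        to_det = np.array([b[1] for b in ev.stride_bounds()])
        np.testing.assert_allclose(to_det, truth.to_times, atol=5e-4)

    def test_pbf_recovered_within_one_percent(self, small_participant):
        anthro, trials = small_participant
        tr = trials["TM_SF75"]
        truth = tr["truth"]
        forces = filter_table(tr["forces"], 50.0)
        ev = detect_foot_contacts(forces.channel("f_z"), forces.sample_rate)
        for k, (fc0, to, _) in enumerate(ev.stride_bounds()):
            p = peak_braking_force(forces.channel("f_x"), forces.time,
                                   (fc0, to), anthro.body_weight)
            assert p == pytest.approx(truth.strides.pbf_bw[k], rel=0.01)

    def test_commanded_stride_frequency_reproduced(self, small_participant):
        anthro, trials = small_participant
        st = trials["TM_SF90"]["truth"].strides
        assert st["stride_frequency"].mean() == pytest.approx(90.0, abs=0.5)


@pytest.fixture(scope="module")
def table():
    return simulate_stride_table(SimConfig(seed=3))


class TestStudyStructure:
    def test_overstriding_and_pbf_decrease_with_sf(self, table):
        tm = table[table.condition.str.startswith("TM")]
        m = tm.groupby("condition")[["overstriding_m", "pbf_bw"]].mean()
        m = m.sort_index()  # TM_SF75 ... TM_SF95
        assert m["overstriding_m"].is_monotonic_decreasing
        assert m["pbf_bw"].is_monotonic_decreasing

    def test_per_participant_os_range_near_six_cm(self, table):
        tm = table[table.condition.str.startswith("TM")]
        g = tm.groupby(["participant_id", "condition"])[
            "overstriding_m"].mean().reset_index()
        rng_ = g.groupby("participant_id")["overstriding_m"].agg(
            lambda x: x.max() - x.min())
        assert rng_.mean() == pytest.approx(0.059, abs=0.02)

    def test_pbf_range_near_paper_value(self, table):
        tm = table[table.condition.str.startswith("TM")]
        g = tm.groupby(["participant_id", "condition"])[
            "pbf_bw"].mean().reset_index()
        rng_ = g.groupby("participant_id")["pbf_bw"].agg(
            lambda x: x.max() - x.min())
        assert rng_.mean() == pytest.approx(0.18, abs=0.08)

    def test_tm_trials_have_enough_strides(self, table):
        counts = table[table.condition.str.startswith("TM")].groupby(
            ["participant_id", "condition"]).size()
        assert (counts >= 22).all()

    def test_duty_cycle_and_pbf_in_valid_ranges(self, table):
        assert table["duty_cycle"].between(0, 1, inclusive="neither").all()
        assert (table["pbf_bw"] >= 0).all()
        assert table["stride_frequency"].between(40, 140).all()
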