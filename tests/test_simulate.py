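"""Ground-truth generator and renderer contracts."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import duogait as dg
from duogait.insole import ForceThresholds, detect_gait_events, heel_toe_forces
from duogait.simulate import ImpairmentEffect, assign_ratings

from conftest import noise_free_spec


class TestTimelineSampling:
    def test_degenerate_spec_places_events_at_phase_fractions(self):
        spec = noise_free_spec(n_cycles=5)
        spec.lead_in_s = 0.0
        spec.mean_cycle_duration_s = {"slow": 1.0, "normal": 1.0, "fast": 1.0}
        tl = dg.sample_gait_timeline(spec, speed_class="normal")
        for k, c in enumerate(tl.cycles):
            assert c.t01 == pytest.approx(k, abs=1e-9)
            assert c.t02 == pytest.approx(k + 0.12, abs=1e-9)
            assert c.t04 == pytest.approx(k + 0.40, abs=1e-9)
            assert c.t05 == pytest.approx(k + 0.50, abs=1e-9)
            assert c.t06 == pytest.approx(k + 0.62, abs=1e-9)
            assert c.t07 == pytest.approx(k + 0.65, abs=1e-9)
            assert c.t08 == pytest.approx(k + 0.90, abs=1e-9)
            assert c.t01_next == pytest.approx(k + 1.0, abs=1e-9)

    def test_same_spec_and_seed_give_identical_timelines(self):
        spec = dg.SimulationSpec(cycles_per_session=8, seed=5)
        a = dg.sample_gait_timeline(spec, impairment_rating=2)
        b = dg.sample_gait_timeline(spec, impairment_rating=2)
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())

    def test_rating_inflates_loading_response_variability(self):
        # same seed stream, 200 cycles each: rating 4 must spread t02-t01 more
        spec = dg.SimulationSpec(cycles_per_session=200, seed=9)
        stds = {}
        for rating in (0, 4):
            tl = dg.sample_gait_timeline(spec, impairment_rating=rating)
            lr = np.array([c.t02 - c.t01 for c in tl.cycles])
            stds[rating] = lr.std(ddof=1)
        assert stds[4] > stds[0]

    @given(seed=st.integers(0, 10_000), rating=st.integers(0, 4))
    def test_sampled_timelines_satisfy_ordering_invariants(self, seed, rating):
        spec = dg.SimulationSpec(cycles_per_session=6, seed=seed)
        tl = dg.sample_gait_timeline(spec, impairment_rating=rating,
                                     state="OFF")
        tl.validate()  # strict event order, contiguity, finite times
        for a, b in zip(tl.cycles, tl.cycles[1:]):
            assert a.t01_next == b.t01

    def test_unorderable_jitter_raises_diagnostic(self):
        spec = dg.SimulationSpec(cycles_per_session=4, seed=0,
                                 base_event_jitter_s=0.5,
                                 max_cycle_retries=3)
        with pytest.raises(RuntimeError, match="retries"):
            dg.sample_gait_timeline(spec)

    def test_invalid_phase_fractions_rejected(self):
        spec = dg.SimulationSpec()
        spec.phase_fractions = dict(spec.phase_fractions, t04=0.05)
        with pytest.raises(ValueError, match="increase"):
            spec.validate()


class TestInsoleRenderer:
    def test_noise_free_crossings_match_truth_within_one_sample(self, clean_session):
        spec, tl, insole, _, _ = clean_session
        forces = heel_toe_forces(insole)
        seq = detect_gait_events(insole.time_s, forces, ForceThresholds())
        truth = tl.to_frame()
        got = pd.DataFrame([c.as_tuple() for c in seq.cycles],
                           columns=truth.columns)
        assert len(got) == len(truth)
        assert (got - truth).abs().max().max() < 0.010

    def test_empty_timeline_renders_baseline_below_thresholds(self):
        spec = dg.SimulationSpec(seed=2)
        tl = dg.GaitTimeline(cycles=())
        rec = dg.render_insole(tl, spec)
        # no regional force approaches a plausible contact level
        for foot in (rec.left, rec.right):
            assert foot.total_force.max() < 10.0  # N; stance peaks are >200 N
        seq = detect_gait_events(rec.time_s, heel_toe_forces(rec),
                                 ForceThresholds(heel_newton=10.0,
                                                 toe_newton=10.0))
        assert seq.events == []

    def test_amplitude_doubling_scales_force_but_not_event_times(self):
        spec = noise_free_spec(n_cycles=4)
        tl = dg.sample_gait_timeline(spec)
        rec1 = dg.render_insole(tl, spec)
        spec2 = dataclasses.replace(
            spec, insole=dataclasses.replace(spec.insole, amplitude_scale=2.0))
        rec2 = dg.render_insole(tl, spec2)
        assert rec2.right.total_force.max() == pytest.approx(
            2 * rec1.right.total_force.max(), rel=1e-9)
        s1 = detect_gait_events(rec1.time_s, heel_toe_forces(rec1))
        s2 = detect_gait_events(rec2.time_s, heel_toe_forces(rec2))
        t1 = [e.time_s for e in s1.events]
        t2 = [e.time_s for e in s2.events]
        assert t1 == pytest.approx(t2, abs=1e-6)

    def test_cop_advances_heel_to_toe_during_stance(self, clean_session):
        _, tl, insole, _, _ = clean_session
        c = tl.cycles[2]
        t = insole.time_s
        early = (t > c.t01 + 0.05) & (t < c.t03 - 0.05)   # heel-only
        late = (t > c.t04 + 0.05) & (t < c.t06 - 0.05)    # toe-only
        assert insole.right.cop[early, 1].mean() < -0.2
        assert insole.right.cop[late, 1].mean() > 0.2


class TestImuRenderer:
    def test_swing_argmax_lies_at_window_midpoint(self, clean_session):
        spec, tl, _, left, right = clean_session
        for rec, side in ((left, "left"), (right, "right")):
            t = rec.time_s
            gz = rec.gyro[:, 2]
            for c in tl.cycles:
                to, ic = ((c.t06, c.t01_next) if side == "right"
                          else (c.t02, c.t05))
                m = (t >= to) & (t <= ic)
                t_peak = t[m][np.argmax(gz[m])]
                assert abs(t_peak - 0.5 * (to + ic)) <= 1.0 / 59.5

    def test_zero_cycle_timeline_stays_below_detection_floor(self):
        spec = dg.SimulationSpec(seed=4)
        tl = dg.GaitTimeline(cycles=())
        left, right = dg.render_imu(tl, spec)
        assert np.abs(left.gyro).max() < 50
        assert np.abs(right.gyro).max() < 50

    def test_left_right_stride_durations_symmetric_without_asymmetry(self, clean_session):
        spec, tl, _, left, right = clean_session
        from duogait.imu import detect_imu_gait_events
        durs = {}
        for side, rec in (("left", left), ("right", right)):
            ev = detect_imu_gait_events(rec.gyro[:, 2], rec.time_s)
            ic = ev.times("ic")
            durs[side] = np.diff(ic).mean()
        assert abs(durs["left"] - durs["right"]) <= 1.0 / 59.5


class TestCohort:
    def test_manifest_has_one_row_per_condition(self, default_cohort):
        cohort, _, _ = default_cohort
        # 19 subjects x 2 states x 3 speeds x 2 repetitions
        assert len(cohort.manifest) == 228
        assert cohort.manifest["session_id"].is_unique

    def test_impairment_label_follows_rating(self, default_cohort):
        cohort, _, _ = default_cohort
        man = cohort.manifest
        assert (man.loc[man["rating"] == 0, "impaired"] == False).all()  # noqa: E712
        assert (man.loc[man["rating"] >= 1, "impaired"] == True).all()  # noqa: E712

    def test_cohort_reproducible_from_seed(self):
        spec = dg.SimulationSpec(n_subjects=2, cycles_per_session=5,
                                 speeds=("normal",), seed=13)
        a = dg.generate_cohort(spec)
        b = dg.generate_cohort(spec)
        pd.testing.assert_frame_equal(a.manifest, b.manifest)
        np.testing.assert_array_equal(
            a.sessions[0].insole.left.pressure,
            b.sessions[0].insole.left.pressure)
        np.testing.assert_array_equal(a.sessions[1].imu_left.gyro,
                                      b.sessions[1].imu_left.gyro)

    def test_rating_assignment_matches_count_table(self):
        rng = np.random.default_rng(0)
        ratings = assign_ratings(19, (4, 11, 2, 2, 0), rng)
        assert sorted(ratings) == [0] * 4 + [1] * 11 + [2] * 2 + [3] * 2

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="n_subjects"):
            dg.generate_cohort(dg.SimulationSpec(n_subjects=0))

    def test_off_state_amplifies_variability_for_rated_subjects(self):
        spec = dg.SimulationSpec(cycles_per_session=300, seed=21)
        on = dg.sample_gait_timeline(spec, impairment_rating=3, state="ON")
        off = dg.sample_gait_timeline(spec, impairment_rating=3, state="OFF")
        lr_on = np.std([c.t02 - c.t01 for c in on.cycles], ddof=1)
        lr_off = np.std([c.t02 - c.t01 for c in off.cycles], ddof=1)
        assert lr_off > lr_on
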