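"""Force-threshold and kinematic gait event detection."""

import numpy as np
import pytest

from gaitval import events as ev
from gaitval import kinematics as kin
from gaitval.errors import DataError, EventDetectionError
from gaitval.pipelines import EVENT_FILTER, orthographic_sagittal
from gaitval.synthetic import (NoiseModel, RaterModel, forward_kinematics,
                               generate_subject, synthesize_grf)


class TestForceEvents:
    def test_zero_noise_grf_recovers_truth_within_2ms(self, clean_trial):
        gt = clean_trial.ground_truth["events"]["right"]
        out = ev.detect_events_force(clean_trial.grf_vertical["Fz2"],
                                     clean_trial.fs_grf, side="right")
        for hs in out.heel_strikes:
            assert min(abs(hs - gt["heel_strikes"])) <= 0.002
        for to in out.toe_offs:
            assert min(abs(to - gt["toe_offs"])) <= 0.002

    def test_all_zero_signal_raises(self):
        with pytest.raises(EventDetectionError):
            ev.detect_events_force(np.zeros(5000), 1000.0)

    def test_zero_threshold_finds_contact_onset(self, subject):
        fs = 1000.0
        grf = synthesize_grf(subject, [0.5], [1.1], fs, 2.0)
        out = ev.detect_events_force(grf, fs, threshold=0.0)
        first_nonzero = np.flatnonzero(grf > 0)[0] / fs
        assert out.heel_strikes[0] == pytest.approx(first_nonzero, abs=1.5e-3)

    def test_short_spikes_are_discarded(self, subject):
        fs = 1000.0
        grf = synthesize_grf(subject, [0.5], [1.1], fs, 2.0)
        grf[50:60] = 400.0          # 10 ms artifact
        out = ev.detect_events_force(grf, fs)
        assert out.heel_strikes[0] == pytest.approx(0.5, abs=0.003)

    def test_events_interleave(self, clean_trial):
        out = ev.detect_events_force(clean_trial.grf_vertical["Fz1"],
                                     clean_trial.fs_grf, side="left")
        cycles = out.cycles()
        assert cycles
        for h0, to, h1 in cycles:
            assert h0 < to < h1


def _filtered_foot(trial, side="right"):
    m2, fs = orthographic_sagittal(trial, side)
    prefix = side[0].upper()
    heel = kin.butterworth_lowpass(m2[prefix + "HEEL"], fs, EVENT_FILTER)
    toe = kin.butterworth_lowpass(m2[prefix + "TOE2"], fs, EVENT_FILTER)
    return heel, toe, fs


class TestKinematicEvents:
    def test_zero_noise_heel_strikes_within_one_frame(self, clean_trial):
        heel, _, fs = _filtered_foot(clean_trial)
        gt = clean_trial.ground_truth["events"]["right"]["heel_strikes"]
        hs = ev.detect_heel_strike_kinematic(heel, fs)
        assert len(hs) >= 2
        for h in hs:
            assert min(abs(h - gt)) <= 1.0 / fs + 1e-9

    def test_zero_noise_toe_offs_within_one_frame(self, clean_trial):
        _, toe, fs = _filtered_foot(clean_trial)
        gt = clean_trial.ground_truth["events"]["right"]["toe_offs"]
        to = ev.detect_toe_off_kinematic(toe, fs)
        assert len(to) >= 2
        for t in to:
            assert min(abs(t - gt)) <= 1.0 / fs + 1e-9

    def test_stationary_marker_raises(self):
        flat = np.tile([0.3, 0.05], (400, 1))
        with pytest.raises(EventDetectionError):
            ev.detect_heel_strike_kinematic(flat, 100.0)

    def test_flat_toe_trajectory_raises(self):
        x = np.linspace(0, 4, 400)
        flat = np.column_stack([x, np.full(400, 0.02)])
        with pytest.raises(EventDetectionError):
            ev.detect_toe_off_kinematic(flat, 100.0)

    def test_shift_equivariance(self, clean_trial):
        """A time-shifted copy of the trajectory shifts every event by
        exactly the shift."""
        heel, _, fs = _filtered_foot(clean_trial)
        base = ev.detect_heel_strike_kinematic(heel, fs)
        shift = 30
        shifted = np.vstack([np.tile(heel[0], (shift, 1)), heel[:-shift]])
        moved = ev.detect_heel_strike_kinematic(shifted, fs)
        expected = base + shift / fs
        expected = expected[expected < (heel.shape[0] - 1) / fs]
        matched = [m for m in moved if min(abs(m - expected)) < 1e-9]
        assert len(matched) >= len(expected) - 1

    def test_frame_rate_consistency_200_vs_100(self, clean_trial):
        """Detection at 200 Hz and on the 100 Hz downsample agree within one
        frame of the coarser rate."""
        m2_hi, fs_hi = orthographic_sagittal(clean_trial, "right", fs_out=200.0)
        heel_hi = kin.butterworth_lowpass(m2_hi["RHEEL"], fs_hi, EVENT_FILTER)
        hs_hi = ev.detect_heel_strike_kinematic(heel_hi, fs_hi)
        heel_lo, _, fs_lo = _filtered_foot(clean_trial)
        hs_lo = ev.detect_heel_strike_kinematic(heel_lo, fs_lo)
        for h in hs_lo:
            assert min(abs(h - hs_hi)) <= 1.0 / fs_lo + 1e-9

    def test_interleaving_of_combined_detection(self, clean_trial):
        heel, toe, fs = _filtered_foot(clean_trial)
        out = ev.detect_events_kinematic(heel, toe, fs, side="right")
        assert out.cycles()


class TestToeOffBiasDirection:
    def test_kinematic_toe_off_not_earlier_than_force_on_average(self):
        """Across many noisy trials, the marker-based toe-off falls at or
        after the force-plate toe-off (the known 2D-late bias direction)."""
        diffs = []
        for seed in range(25):
            subject = generate_subject(rng_seed=seed)
            trial = forward_kinematics(subject, 3, RaterModel(rater_id=1),
                                       NoiseModel(), rng_seed=seed + 3000)
            heel, toe, fs = _filtered_foot(trial)
            try:
                to_kin = ev.detect_toe_off_kinematic(toe, fs)
            except EventDetectionError:
                continue
            to_force = ev.detect_events_force(trial.grf_vertical["Fz2"],
                                              trial.fs_grf,
                                              side="right").toe_offs
            for t in to_kin:
                i = np.argmin(abs(to_force - t))
                if abs(to_force[i] - t) < 0.1:
                    diffs.append(t - to_force[i])
        assert len(diffs) >= 50
        assert np.mean(diffs) > 0.0


class TestGaitEventsContainer:
    def test_non_interleaved_events_rejected(self):
        with pytest.raises(DataError):
            ev.GaitEvents(side="right", heel_strikes=[0.0, 1.0],
                          toe_offs=[0.4, 0.6], method="kinematic")

    def test_descending_times_rejected(self):
        with pytest.raises(DataError):
            ev.GaitEvents(side="left", heel_strikes=[1.0, 0.5],
                          toe_offs=[], method="force_threshold")
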