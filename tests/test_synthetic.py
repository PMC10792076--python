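"""The synthetic gait simulator: determinism, physics, calibration."""

import numpy as np
import pytest

from gaitval import agreement as ag
from gaitval import synthetic as syn
from gaitval.errors import ConfigurationError, DataError


class TestGenerateSubject:
    def test_deterministic_per_seed(self):
        a = syn.generate_subject(rng_seed=7)
        b = syn.generate_subject(rng_seed=7)
        assert a.height == b.height
        assert a.stride_length == b.stride_length
        for j in a.angle_waveforms:
            assert np.array_equal(a.angle_waveforms[j], b.angle_waveforms[j])

    def test_velocity_identity_is_exact(self):
        s = syn.generate_subject(rng_seed=1)
        assert s.velocity == pytest.approx(s.stride_length * s.cadence / 120.0,
                                           rel=1e-12)
        assert 1.1 <= s.velocity <= 1.7

    def test_degenerate_cohort_yields_identical_subjects(self):
        cfg = syn.CohortConfig(height_sd=0, velocity_sd=0, stride_time_sd=0,
                               stance_fraction_sd=0, pelvis_rom_sd=0, bmi_sd=0)
        subjects = [syn.generate_subject(cfg, rng_seed=s) for s in (1, 2, 3)]
        assert len({round(s.stride_length, 12) for s in subjects}) == 1
        assert len({round(s.height, 12) for s in subjects}) == 1

    def test_infeasible_stance_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            syn.CohortConfig(stance_fraction_mean=1.0)
        with pytest.raises(ConfigurationError):
            syn.CohortConfig(stance_fraction_mean=0.95)

    def test_marginal_calibration_of_the_cohort(self):
        """Over 500 subjects, mean walking velocity and stride time match the
        configured population marginals."""
        vels, times = [], []
        for seed in range(500):
            s = syn.generate_subject(rng_seed=seed)
            vels.append(s.velocity)
            times.append(s.stride_time)
        assert np.mean(vels) == pytest.approx(1.42, abs=0.03)
        assert np.mean(times) == pytest.approx(1.02, abs=0.02)

    def test_waveform_roms_positive(self, subject):
        from gaitval.synthetic import fourier_eval
        phase = np.linspace(0, 1, 200, endpoint=False)
        for joint, coef in subject.angle_waveforms.items():
            curve = fourier_eval(coef, phase)
            assert curve.max() - curve.min() > 0


class TestForwardKinematics:
    def test_bit_identical_for_same_seed(self, subject):
        kw = dict(rater=syn.RaterModel(rater_id=2), noise=syn.NoiseModel(),
                  rng_seed=99)
        a = syn.forward_kinematics(subject, 3, **kw)
        b = syn.forward_kinematics(subject, 3, **kw)
        for name in a.markers_3d:
            assert np.array_equal(a.markers_3d[name], b.markers_3d[name])
        assert np.array_equal(a.grf_vertical["Fz1"], b.grf_vertical["Fz1"])
        for side in a.pixels_2d:
            for name in a.pixels_2d[side]:
                assert np.array_equal(a.pixels_2d[side][name],
                                      b.pixels_2d[side][name])

    def test_single_stride_rejected(self, subject):
        with pytest.raises(DataError):
            syn.forward_kinematics(subject, 1, rng_seed=0)

    def test_rigid_chain_at_zero_noise(self, clean_trial):
        """Thigh, shank and foot marker separations stay constant to 1e-9 m
        (the heel-pad transient is confined to the final pre-contact window,
        where the heel marker may deviate from the rigid foot)."""
        m = clean_trial.markers_3d
        for a, b in (("RTROCH", "RKNE"), ("RKNE", "RANK"), ("LTROCH", "LKNE"),
                     ("RASI", "RPSI"), ("RTOE", "RTOE2")):
            d = np.linalg.norm(m[a] - m[b], axis=1)
            assert d.max() - d.min() < 1e-9

    def test_heel_pad_transient_is_bounded(self, clean_trial):
        m = clean_trial.markers_3d
        d = np.linalg.norm(m["RHEEL"] - m["RTOE2"], axis=1)
        assert d.max() - d.min() < 0.013      # pad compliance, not free noise

    def test_thigh_marker_distance_under_noise(self, subject):
        noise = syn.NoiseModel()
        trial = syn.forward_kinematics(subject, 3, syn.RaterModel.identity(),
                                       noise, rng_seed=5)
        m = trial.markers_3d
        d = np.linalg.norm(m["RTROCH"] - m["RKNE"], axis=1)
        clean = syn.forward_kinematics(subject, 3, syn.RaterModel.identity(),
                                       syn.NoiseModel.zero(), rng_seed=5)
        d0 = np.linalg.norm(clean.markers_3d["RTROCH"]
                            - clean.markers_3d["RKNE"], axis=1).mean()
        bound = (3 * noise.soft_tissue_amplitude + 3 * noise.tracking_jitter_sd
                 + 0.03)
        assert np.max(np.abs(d - d0)) <= bound

    def test_ground_truth_toe_off_is_the_stance_fraction(self, subject):
        trial = syn.forward_kinematics(subject, 3, rng_seed=1)
        for side in ("left", "right"):
            assert trial.ground_truth["parameters"][side]["toe_off_pct"] == \
                pytest.approx(100 * subject.stance_fraction, abs=1e-12)

    def test_ground_truth_events_interleave(self, clean_trial):
        for side in ("left", "right"):
            ev = clean_trial.ground_truth["events"][side]
            hs, to = ev["heel_strikes"], ev["toe_offs"]
            for i in range(len(hs) - 1):
                inside = to[(to > hs[i]) & (to < hs[i + 1])]
                assert inside.size == 1

    def test_marker_set_is_complete(self, clean_trial):
        names = set(clean_trial.markers_3d)
        for base in ("TROCH", "HEEL", "TOE2", "ASI", "PSI", "KNE", "ANK"):
            assert "R" + base in names and "L" + base in names

    def test_streams_are_consistent_in_duration(self, clean_trial):
        t = clean_trial
        n3 = next(iter(t.markers_3d.values())).shape[0]
        ng = t.grf_vertical["Fz1"].shape[0]
        n2 = next(iter(t.pixels_2d["right"].values())).shape[0]
        assert (n3 - 1) / t.fs_3d == pytest.approx(t.duration, abs=0.01)
        assert (ng - 1) / t.fs_grf == pytest.approx(t.duration, abs=0.01)
        assert (n2 - 1) / t.fs_2d == pytest.approx(t.duration, abs=0.02)
        for pos in t.markers_3d.values():
            assert np.all(np.isfinite(pos))


class TestSynthesizeGrf:
    def test_threshold_crossings_match_truth_within_2ms(self, subject):
        fs = 1000.0
        hs, to = [1.0, 2.05], [1.62, 2.67]
        grf = syn.synthesize_grf(subject, hs, to, fs, 3.5)
        above = grf > 20.0
        onsets = np.flatnonzero(np.diff(above.astype(int)) == 1) + 1
        offsets = np.flatnonzero(np.diff(above.astype(int)) == -1) + 1
        for h, i in zip(hs, onsets):
            assert abs(i / fs - h) <= 0.002
        for t, i in zip(to, offsets):
            assert abs(i / fs - t) <= 0.002

    def test_peak_force_scales_with_body_weight(self):
        s = syn.generate_subject(rng_seed=0)
        s.weight = 64.3
        grf = syn.synthesize_grf(s, [0.5], [1.12], 1000.0, 2.0)
        bw = 64.3 * 9.80665     # ~630.8 N
        assert 1.0 * bw <= grf.max() <= 1.3 * bw

    def test_zero_outside_stance_before_noise(self, subject):
        fs = 1000.0
        grf = syn.synthesize_grf(subject, [1.0], [1.6], fs, 3.0)
        t = np.arange(grf.size) / fs
        assert np.all(grf[(t < 1.0) | (t > 1.6)] == 0.0)

    def test_underresolved_rate_rejected(self, subject):
        with pytest.raises(ConfigurationError):
            syn.synthesize_grf(subject, [0.5], [1.1], 100.0, 2.0)


class TestVarianceDecomposition:
    def test_day_effects_reduce_between_day_agreement(self):
        """Adding day-to-day gait variability can only lower the between-day
        ICC of ground-truth stride time (Monte-Carlo over one cohort)."""
        rng = np.random.default_rng(77)

        def day_matrix(day_sd):
            rows = []
            for i in range(40):
                s = syn.generate_subject(rng_seed=1000 + i)
                vals = []
                for day in (1, 2):
                    f = np.exp(rng.normal(0, day_sd)) if day == 2 else 1.0
                    noise = syn.NoiseModel(trial_gait_sd=0.015,
                                           day_effect_sd=day_sd)
                    tr = syn.forward_kinematics(
                        s, 2, syn.RaterModel.identity(), noise,
                        rng_seed=int(rng.integers(2 ** 31)),
                        cadence_factor=f)
                    vals.append(tr.ground_truth["stride_time"])
                rows.append(vals)
            return np.asarray(rows)

        icc_quiet = ag.icc_two_way(day_matrix(0.0), model="ICC3k").icc
        icc_day = ag.icc_two_way(day_matrix(0.03), model="ICC3k").icc
        assert icc_quiet >= icc_day
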