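"""Filtering, segment angles, cycle normalization, range of motion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitval import kinematics as kin
from gaitval.errors import ConfigurationError, DataError, MissingMarkerError


class TestButterworth:
    def test_dc_gain_is_one(self):
        x = np.full(500, 3.7)
        y = kin.butterworth_lowpass(x, 100.0)
        assert np.allclose(y, x, atol=1e-9)

    @pytest.mark.parametrize("freq,min_gain,max_gain", [
        (1.0, 0.99, 1.001),      # passband: amplitude preserved within 1%
        (40.0, 0.0, 0.01),       # far stopband: below 1% of input
    ])
    def test_analytic_magnitude_response(self, freq, min_gain, max_gain):
        fs = 100.0
        t = np.arange(0, 30, 1 / fs)
        x = np.sin(2 * np.pi * freq * t)
        y = kin.butterworth_lowpass(x, fs)
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        gain = np.max(np.abs(y[mid]))
        assert min_gain <= gain <= max_gain
        # zero-lag design: |H|^2 of the 2nd-order prototype
        expected = 1.0 / (1.0 + (freq / 6.0) ** 4)
        assert gain == pytest.approx(expected, abs=0.01)

    def test_cutoff_at_or_above_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            kin.butterworth_lowpass(np.zeros(100), 10.0,
                                    kin.FilterSpec(cutoff=6.0))

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_linearity_superposition(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=300)
        b = rng.normal(size=300)
        fs = 100.0
        left = kin.butterworth_lowpass(a + 2.0 * b, fs)
        right = kin.butterworth_lowpass(a, fs) + 2.0 * kin.butterworth_lowpass(b, fs)
        assert np.allclose(left, right, atol=1e-9)

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        x = kin.butterworth_lowpass(rng.normal(size=600), 100.0,
                                    kin.FilterSpec(cutoff=10))
        shift = 50
        y_shifted = kin.butterworth_lowpass(np.roll(x, shift), 100.0)
        y = kin.butterworth_lowpass(x, 100.0)
        interior = slice(100, 500)
        assert np.allclose(np.roll(y, shift)[interior], y_shifted[interior],
                           atol=1e-6)


class TestSegmentAngle:
    def test_axis_anchors(self):
        assert kin.segment_angle([[0, 0]], [[1, 0]])[0] == pytest.approx(0.0)
        assert kin.segment_angle([[0, 0]], [[0, 1]])[0] == pytest.approx(90.0)

    def test_coincident_markers_flagged_per_frame(self):
        prox = np.array([[0.0, 0.0], [0.0, 0.0], [0.0, 0.0]])
        dist = np.array([[1.0, 0.0], [0.0, 0.0], [1.0, 0.1]])
        ang = kin.segment_angle(prox, dist)
        assert np.isnan(ang[1])
        assert np.isfinite(ang[0]) and np.isfinite(ang[2])

    def test_constant_rotation_rate_recovered(self):
        fs, omega = 200.0, 2.0    # rad/s
        t = np.arange(0, 3, 1 / fs)
        prox = np.zeros((t.size, 2))
        dist = np.column_stack([np.cos(omega * t), np.sin(omega * t)])
        ang = np.radians(kin.segment_angle(prox, dist))
        rate = np.gradient(ang, 1 / fs)
        assert np.allclose(rate[5:-5], omega, atol=1e-6)

    def test_unwrapped_across_the_branch_cut(self):
        fs = 100.0
        t = np.arange(0, 2, 1 / fs)
        dist = np.column_stack([np.cos(4 * t), np.sin(4 * t)])
        ang = kin.segment_angle(np.zeros_like(dist), dist)
        assert np.all(np.abs(np.diff(ang)) < 10)   # no 360-degree jumps


def _standing_markers(n=10, pelvis_tilt_deg=0.0):
    """A straight-leg standing pose, foot flat, in metric sagittal coords."""
    tilt = np.radians(pelvis_tilt_deg)
    markers = {
        "TROCH": [0.0, 0.90],
        "KNE": [0.0, 0.47],
        "ANK": [0.0, 0.07],
        "HEEL": [-0.06, 0.02],
        "TOE2": [0.18, 0.02],
        "PSI": [-0.15, 1.00],
        "ASI": [-0.15 + 0.2 * np.cos(tilt), 1.00 - 0.2 * np.sin(tilt)],
    }
    return {k: np.tile(np.asarray(v, dtype=float), (n, 1))
            for k, v in markers.items()}


class TestRelativeAngles:
    def test_neutral_standing_reads_zero(self):
        curves = kin.relative_angles(_standing_markers(), "right",
                                     hip_reference="vertical")
        assert curves["knee"].values[0] == pytest.approx(0.0, abs=1e-9)
        assert curves["ankle"].values[0] == pytest.approx(0.0, abs=1e-9)
        assert curves["hip"].values[0] == pytest.approx(0.0, abs=1e-9)

    def test_pelvis_tilt_reported_directly(self):
        curves = kin.relative_angles(_standing_markers(pelvis_tilt_deg=5.0),
                                     "right")
        assert np.allclose(curves["pelvis"].values, 5.0, atol=1e-9)

    def test_missing_marker_is_named(self):
        markers = _standing_markers()
        del markers["TOE2"]
        with pytest.raises(MissingMarkerError, match="TOE2"):
            kin.relative_angles(markers, "right")

    def test_hip_reference_option_changes_only_hip(self):
        m = _standing_markers(pelvis_tilt_deg=8.0)
        pelvis_ref = kin.relative_angles(m, "right", hip_reference="pelvis")
        vert_ref = kin.relative_angles(m, "right", hip_reference="vertical")
        assert np.allclose(pelvis_ref["knee"].values, vert_ref["knee"].values)
        assert not np.allclose(pelvis_ref["hip"].values, vert_ref["hip"].values)


class TestTimeNormalize:
    def test_linear_ramp_stays_linear(self):
        fs = 100.0
        v = np.arange(0, 200) / fs        # ramp with slope 1 per second
        out = kin.time_normalize(v, fs, (0.5, 1.5))
        assert out.shape == (101,)
        assert np.allclose(out, np.linspace(0.5, 1.5, 101), atol=1e-12)

    def test_between_frame_boundaries_interpolate(self):
        # three frames at 1 Hz holding 0, 10, 20: a cycle from t=0.5 to 1.5
        out = kin.time_normalize([0.0, 10.0, 20.0], 1.0, (0.5, 1.5),
                                 n_points=3)
        assert out == pytest.approx([5.0, 10.0, 15.0])

    def test_reversed_heel_strikes_rejected(self):
        with pytest.raises(DataError):
            kin.time_normalize(np.zeros(100), 100.0, (0.8, 0.2))

    def test_cycle_beyond_recording_rejected(self):
        with pytest.raises(DataError):
            kin.time_normalize(np.zeros(100), 100.0, (0.5, 2.0))


class TestRangeOfMotion:
    def test_sinusoid_amplitude(self):
        t = np.linspace(0, 1, 101)
        assert kin.range_of_motion(3.0 * np.sin(2 * np.pi * t)) == \
            pytest.approx(6.0, abs=1e-6)

    def test_constant_curve_is_zero(self):
        assert kin.range_of_motion(np.full(101, 4.2)) == 0.0

    @settings(max_examples=25, deadline=None)
    @given(st.floats(-50, 50))
    def test_invariant_to_additive_offset(self, offset):
        rng = np.random.default_rng(7)
        curve = rng.normal(size=101)
        assert kin.range_of_motion(curve + offset) == \
            pytest.approx(kin.range_of_motion(curve), abs=1e-9)


class TestProductionFilterAttenuation:
    def test_six_hz_filter_rom_attenuation_is_bounded(self, clean_trial):
        """The production 6 Hz zero-lag filter shaves some range of motion
        off gait curves (it does so on any physiological waveform); the
        attenuation stays within a small, characterised bound."""
        from gaitval.pipelines import orthographic_sagittal
        m2, fs = orthographic_sagittal(clean_trial, "right")
        req = {b: m2["R" + b] for b in kin.REQUIRED_MARKERS}
        raw = kin.relative_angles(req, "right")
        filt_markers = {b: kin.butterworth_lowpass(v, fs, kin.FilterSpec())
                        for b, v in req.items()}
        filt = kin.relative_angles(filt_markers, "right")
        interior = slice(int(0.5 * fs), -int(0.5 * fs))
        for joint in ("hip", "knee", "ankle", "pelvis"):
            loss = (kin.range_of_motion(raw[joint].values[interior])
                    - kin.range_of_motion(filt[joint].values[interior]))
            assert -0.2 <= loss <= 2.0


class TestScaleFreedom:
    def test_angles_unchanged_by_metric_rescaling(self, clean_trial):
        """Uniform scaling of the sagittal coordinates (a calibration-scale
        change) leaves the angle curves untouched: angles are scale-free."""
        from gaitval.pipelines import orthographic_sagittal
        m2, fs = orthographic_sagittal(clean_trial, "right")
        req = {b: m2["R" + b] for b in kin.REQUIRED_MARKERS}
        a = kin.relative_angles(req, "right")
        scaled = {k: 1.37 * v for k, v in req.items()}
        b = kin.relative_angles(scaled, "right")
        for joint in a:
            assert np.allclose(a[joint].values, b[joint].values, atol=1e-9)
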