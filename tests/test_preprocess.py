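"""Filtering, resampling and gait-event detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bouncework import errors
from bouncework.preprocess import (
    assign_feet_and_strides,
    detect_contacts,
    filter_forces,
    lowpass_zero_phase,
    resample_spline,
)
from bouncework.trial_io import ForceSeries, MarkerTrajectories

FS = 1000.0


class TestLowpass:
    def test_dc_gain_exactly_one(self):
        x = np.full(4000, 3.7)
        y = lowpass_zero_phase(x, 30.0, FS)
        assert np.max(np.abs(y - 3.7)) < 1e-9

    def test_passband_sine_amplitude_and_phase(self):
        t = np.arange(0, 8.0, 1 / FS)
        x = np.sin(2 * np.pi * 1.0 * t)
        y = lowpass_zero_phase(x, 30.0, FS)
        core = slice(2000, 6000)
        amp = np.max(np.abs(y[core]))
        assert abs(amp - 1.0) < 0.01
        # zero phase: peak position preserved within one sample
        xp = 2000 + np.argmax(x[core])
        yp = 2000 + np.argmax(y[core])
        assert abs(xp - yp) <= 1

    def test_stopband_attenuation(self):
        t = np.arange(0, 4.0, 1 / FS)
        x = np.sin(2 * np.pi * 200.0 * t)
        y = lowpass_zero_phase(x, 30.0, FS)
        atten_db = 20 * np.log10(np.max(np.abs(y[1000:3000])))
        assert atten_db < -40.0

    def test_two_pass_half_power_at_cutoff(self):
        """The pre-warped design puts the −3 dB point of the *two-pass*
        response at the configured cutoff."""
        t = np.arange(0, 8.0, 1 / FS)
        x = np.sin(2 * np.pi * 30.0 * t)
        y = lowpass_zero_phase(x, 30.0, FS)
        amp = np.max(np.abs(y[2000:6000]))
        assert abs(amp - 2 ** -0.5) < 0.02

    def test_symmetric_pulse_peak_unmoved(self):
        t = np.arange(4000)
        x = np.exp(-0.5 * ((t - 2000) / 30.0) ** 2)
        y = lowpass_zero_phase(x, 20.0, FS)
        assert abs(int(np.argmax(y)) - 2000) <= 1

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(errors.ParameterError):
            lowpass_zero_phase(np.zeros(1000), 500.0, FS)


class TestResample:
    @staticmethod
    def markers_from(t, y, z, name="GT_R"):
        return MarkerTrajectories(t, {name: np.column_stack([y, z])})

    def test_same_rate_is_identity(self):
        t = np.arange(0, 1.0, 1 / 200)
        mk = self.markers_from(t, np.sin(t), np.cos(t))
        out = resample_spline(mk, 200.0)
        assert out is mk

    def test_cubic_polynomial_exact_on_interior(self):
        t = np.arange(0, 2.0, 1 / 200)
        poly = lambda x: 0.3 * x**3 - 0.5 * x**2 + 0.1 * x + 2.0
        mk = self.markers_from(t, poly(t), poly(t) / 2)
        out = resample_spline(mk, 1000.0)
        n = out.time.size
        core = slice(n // 20, -n // 20)
        np.testing.assert_allclose(out["GT_R"][core, 0],
                                   poly(out.time[core]), atol=1e-9)

    def test_sine_interpolation_error_small(self):
        t = np.arange(0, 2.0, 1 / 200)
        mk = self.markers_from(t, np.sin(2 * np.pi * 5 * t), np.zeros(t.size))
        out = resample_spline(mk, 1000.0)
        n = out.time.size
        core = slice(n // 20, -n // 20)
        err = np.max(np.abs(out["GT_R"][core, 0]
                            - np.sin(2 * np.pi * 5 * out.time[core])))
        assert err < 1e-4

    def test_downsampling_rejected(self):
        t = np.arange(0, 1.0, 1 / 200)
        mk = self.markers_from(t, t, t)
        with pytest.raises(errors.ParameterError):
            resample_spline(mk, 100.0)

    def test_gap_rejected(self):
        t = np.arange(0, 1.0, 1 / 200)
        y = t.copy()
        y[10] = np.nan
        mk = self.markers_from(t, y, t)
        with pytest.raises(errors.GeometryError):
            resample_spline(mk, 1000.0)


class TestDetectContacts:
    BW = 70.0 * 9.81

    def test_zero_force_no_contacts(self):
        with pytest.warns(UserWarning, match="no foot contact"):
            c = detect_contacts(np.zeros(5000), self.BW, FS)
        assert len(c) == 0

    def test_constant_body_weight_single_contact(self):
        c = detect_contacts(np.full(5000, self.BW), self.BW, FS)
        assert c.intervals == [(0, 5000)]

    def test_half_sine_crossings_match_closed_form(self):
        """Onset/offset within one sample of the analytic threshold
        crossing t* = (0.3/π)·asin(0.1·m·g/1600) of each burst."""
        t = np.arange(0, 3.0, 1 / FS)
        fz = np.zeros_like(t)
        for k in range(4):
            m = (t >= 0.7 * k) & (t < 0.7 * k + 0.3)
            fz[m] = 1600.0 * np.sin(np.pi * (t[m] - 0.7 * k) / 0.3)
        c = detect_contacts(fz, self.BW, FS)
        t_star = (0.3 / np.pi) * np.arcsin(0.1 * self.BW / 1600.0)
        assert len(c) == 4
        for k, (a, b) in enumerate(c.intervals):
            assert abs(a / FS - (0.7 * k + t_star)) <= 1.5 / FS
            assert abs(b / FS - (0.7 * k + 0.3 - t_star)) <= 1.5 / FS

    def test_debounce_drops_chatter(self):
        fz = np.zeros(1000)
        fz[100:110] = self.BW  # 10 ms blip
        fz[300:600] = self.BW
        c = detect_contacts(fz, self.BW, FS)
        assert c.intervals == [(300, 600)]

    @given(st.floats(0.05, 0.4), st.floats(0.05, 0.4))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_threshold(self, f1, f2):
        """Raising the threshold never lengthens any contact interval."""
        rng = np.random.default_rng(11)
        t = np.arange(0, 2.0, 1 / FS)
        fz = np.clip(900 * np.sin(2 * np.pi * 2.8 * t), 0, None) \
            + 20 * rng.standard_normal(t.size)
        lo, hi = sorted((f1, f2))
        c_lo = detect_contacts(np.clip(fz, 0, None), self.BW, FS, lo)
        c_hi = detect_contacts(np.clip(fz, 0, None), self.BW, FS, hi)
        mask_lo = np.zeros(t.size, bool)
        for a, b in c_lo.intervals:
            mask_lo[a:b] = True
        for a, b in c_hi.intervals:
            # every high-threshold contact is inside a low-threshold one
            assert mask_lo[a:b].all()


class TestStrides:
    def test_generator_contacts_all_labelled_correctly(self, rigid_sim,
                                                       rigid_results):
        _, trial, truth = rigid_sim
        seg = rigid_results.segmentation
        truth_by_onset = {}
        for a, b, foot in truth.contacts:
            truth_by_onset[a] = foot
        onsets = sorted(truth_by_onset)
        for foot in ("R", "L"):
            for a, b in seg.contacts[foot]:
                nearest = min(onsets, key=lambda o: abs(o - a))
                assert truth_by_onset[nearest] == foot
                assert abs(nearest - a) < 30  # threshold-crossing offset

    def test_stride_count_matches_generator(self, rigid_sim, rigid_results):
        params, _, truth = rigid_sim
        n = rigid_results.segmentation.n_strides
        assert abs(n - params.n_strides) <= 1

    def test_strides_partition_the_analysed_span(self, rigid_results):
        seg = rigid_results.segmentation
        for (a0, b0), (a1, b1) in zip(seg.strides, seg.strides[1:]):
            assert b0 == a1
        for s0, s1 in seg.strides:
            assert s1 > s0

    def test_single_contact_yields_no_stride(self):
        t = np.arange(0, 1.0, 1 / FS)
        fz = np.zeros_like(t)
        fz[400:700] = 1500.0
        forces = ForceSeries(t, np.zeros_like(t), fz, np.zeros_like(t))
        mt = np.arange(0, 1.0, 1 / 200)
        mk = MarkerTrajectories(mt, {
            "ankle_R": np.tile([0.0, 0.1], (mt.size, 1)),
            "ankle_L": np.tile([0.5, 0.1], (mt.size, 1))})
        contacts = detect_contacts(fz, 70 * 9.81, FS)
        with pytest.warns(UserWarning, match="zero complete strides"):
            seg = assign_feet_and_strides(contacts, forces, mk)
        assert seg.n_strides == 0


def test_filtered_force_stays_nonnegative(rigid_sim):
    _, trial, _ = rigid_sim
    out = filter_forces(trial.forces, 30.0)
    assert np.all(out.F_z >= 0.0)
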