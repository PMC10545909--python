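"""Y, NPQ, ΦPSII and the six-variable kinetic features."""

import math

import numpy as np
import pytest

import pulsescope as ps
from pulsescope.photoparams import NPQResult


def trace(values, timestamps=None, corrected=True):
    values = np.asarray(values, dtype=float)
    if timestamps is None:
        timestamps = np.arange(len(values), dtype=float) * 60.0
    return ps.FluorescenceTrace("t", values, timestamps, background_corrected=corrected)


class TestComputeY:
    def test_hand_arithmetic(self):
        res = ps.compute_Y(trace([100, 100, 100, 100, 400]), pulse_frames=[4])
        assert res.F_prime == pytest.approx(100.0)
        assert res.Fm == pytest.approx(400.0)
        assert res.Y == pytest.approx(0.75)

    def test_saturated_measuring_light_gives_zero(self):
        # F' reaching Fm is the saturated-laser regime: Y = 0
        res = ps.compute_Y(trace([400, 400, 400, 400, 400]), pulse_frames=[4])
        assert res.Y == pytest.approx(0.0)

    def test_all_zero_trace_rejected(self):
        with pytest.raises(ValueError, match="Fm"):
            ps.compute_Y(trace([0, 0, 0, 0, 0]), pulse_frames=[4])

    def test_fm_below_f_prime_warns_and_returns_negative(self, caplog):
        with caplog.at_level("WARNING"):
            res = ps.compute_Y(trace([500, 500, 400]), pulse_frames=[2])
        assert res.Y < 0
        assert any("saturating" in r.message for r in caplog.records)

    def test_requires_pre_pulse_frame(self):
        with pytest.raises(ValueError, match="pre-pulse"):
            ps.compute_Y(trace([400, 100]), pulse_frames=[0])


class TestNPQSeries:
    def test_hand_arithmetic(self, standard_timeline):
        values = [400.0] * 3 + [200.0] * 12
        res = ps.compute_npq_series(trace(values), standard_timeline)
        assert res.Fm_dark == pytest.approx(400.0)
        assert np.all(np.isnan(res.npq[:3]))  # dark frames carry no NPQ
        np.testing.assert_allclose(res.npq[3:], 1.0)

    def test_no_quenching_gives_zero(self, standard_timeline):
        res = ps.compute_npq_series(trace([400.0] * 15), standard_timeline)
        np.testing.assert_allclose(res.npq[3:], 0.0)

    def test_nonpositive_frames_marked_nan_not_dropped(self, standard_timeline):
        values = [400.0] * 3 + [200.0] * 11 + [0.0]
        res = ps.compute_npq_series(trace(values), standard_timeline)
        assert math.isnan(res.npq[-1])
        assert len(res.npq) == 15

    def test_nonpositive_dark_reference_rejected(self, standard_timeline):
        with pytest.raises(ValueError, match="dark"):
            ps.compute_npq_series(trace([0.0] * 15), standard_timeline)

    def test_scale_invariance(self, standard_timeline):
        values = np.array([400.0] * 3 + list(np.linspace(350, 150, 12)))
        a = ps.compute_npq_series(trace(values), standard_timeline)
        b = ps.compute_npq_series(trace(values * 7.5), standard_timeline)
        np.testing.assert_allclose(b.npq[3:], a.npq[3:], rtol=1e-12)
        assert b.Fm_dark == pytest.approx(7.5 * a.Fm_dark)

    def test_recovers_simulated_plateau(self, standard_timeline):
        """Fm′ = Fm/(1+NPQ) inverts exactly: a plateau of 2.0 is recovered."""
        fm = 400.0
        values = [fm] * 3 + [fm / (1 + 2.0)] * 12
        res = ps.compute_npq_series(trace(values), standard_timeline)
        np.testing.assert_allclose(res.npq[3:], 2.0, rtol=1e-12)


class TestPhiPSII:
    @pytest.mark.parametrize(
        "fs,fm,expected",
        [(400.0, 400.0, 0.0), (100.0, 400.0, 0.75), (0.0, 400.0, 1.0)],
    )
    def test_quotient(self, fs, fm, expected):
        assert ps.compute_phi_psii(fs, fm) == pytest.approx(expected)

    def test_fs_above_fm_warns(self, caplog):
        with caplog.at_level("WARNING"):
            assert ps.compute_phi_psii(500.0, 400.0) < 0
        assert any("negative" in r.message for r in caplog.records)

    def test_nonpositive_fm_rejected(self):
        with pytest.raises(ValueError):
            ps.compute_phi_psii(10.0, 0.0)


class TestExtractFeatures:
    def npq_result(self, timeline, npq):
        return NPQResult(Fm_dark=400.0, npq=np.asarray(npq, float),
                         timestamps=timeline.timestamps)

    def test_constant_light_npq(self, standard_timeline):
        npq = [np.nan] * 3 + [0.8] * 6 + [0.1] * 6
        feats = ps.extract_features(self.npq_result(standard_timeline, npq),
                                    standard_timeline, area_frac=25.0)
        assert feats.npq_av == pytest.approx(0.8)
        assert feats.npq_max == pytest.approx(0.8)
        assert feats.induction == pytest.approx(0.0)
        assert feats.fmax == pytest.approx(400.0)
        assert feats.area_frac == pytest.approx(25.0)

    def test_induction_slope_closed_form(self, standard_timeline):
        # NPQ = 0, 0.5, 1.0 at 0/60/120 s after light-on -> 0.5 min⁻¹
        npq = [np.nan] * 3 + [0.0, 0.5, 1.0] + [1.0] * 3 + [0.0] * 6
        feats = ps.extract_features(self.npq_result(standard_timeline, npq),
                                    standard_timeline)
        assert feats.induction == pytest.approx(0.5)

    def test_decay_slope_closed_form(self, standard_timeline):
        # NPQ = 1.0, 0.6, 0.2 at 0/60/120 s after light-off -> −0.4 min⁻¹
        npq = [np.nan] * 3 + [1.0] * 6 + [1.0, 0.6, 0.2] + [0.2] * 3
        feats = ps.extract_features(self.npq_result(standard_timeline, npq),
                                    standard_timeline)
        assert feats.decay == pytest.approx(-0.4)

    def test_window_boundary_inclusive_at_120s(self, standard_timeline):
        """Only the three frames with t − t_on ≤ 120 s enter the slope."""
        npq = [np.nan] * 3 + [0.0, 0.5, 1.0, 99.0, 99.0, 99.0] + [0.0] * 6
        feats = ps.extract_features(self.npq_result(standard_timeline, npq),
                                    standard_timeline)
        assert feats.induction == pytest.approx(0.5)

    def test_npqmax_at_least_npqav(self, standard_timeline):
        npq = [np.nan] * 3 + [0.2, 1.5, 0.9, 0.8, 0.7, 0.6] + [0.3] * 6
        feats = ps.extract_features(self.npq_result(standard_timeline, npq),
                                    standard_timeline)
        assert feats.npq_max >= feats.npq_av
        assert feats.npq_max == pytest.approx(1.5)

    def test_no_actinic_frames_leaves_light_features_undefined(self):
        tl = ps.build_timeline(3, 0, 0, 60.0)
        npq = [np.nan] * 3
        feats = ps.extract_features(self.npq_result(tl, npq), tl)
        assert math.isnan(feats.npq_av)
        assert math.isnan(feats.npq_max)
        assert math.isnan(feats.induction)
        assert math.isnan(feats.decay)

    def test_single_window_point_leaves_slope_undefined(self):
        tl = ps.build_timeline(1, 1, 0, 180.0)
        npq = [np.nan, 0.7]
        feats = ps.extract_features(self.npq_result(tl, npq), tl)
        assert math.isnan(feats.induction)

    def test_transient_scene_peaks_before_last_light_frame(self, standard_timeline):
        """Low-light transient overshoot: NPQmax before the end of the light
        phase, and NPQmax > NPQav."""
        kin = ps.Kinetics(npq_max=0.3, tau_ind=60.0, tau_rel=120.0,
                          transient_amp=1.5, transient_tau=80.0)
        curve = ps.npq_curve(standard_timeline, kin)
        res = NPQResult(Fm_dark=400.0, npq=np.where(np.arange(15) < 3, np.nan, curve),
                        timestamps=standard_timeline.timestamps)
        feats = ps.extract_features(res, standard_timeline)
        light = standard_timeline.indices(ps.Phase.ACTINIC)
        assert curve[light].argmax() < len(light) - 1
        assert curve[light][-1] < 0.5 * feats.npq_max
        assert feats.npq_max > feats.npq_av
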