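"""Ground-truth kinetics, event bookkeeping, forward render and calibration
scenes of the synthetic generator."""

import numpy as np
import pytest

import endokin as ek
from endokin.synthetic import RAB7_TAU_DEFAULT


class TestSimulateTruth:
    def test_coupling_anchor_exact(self, default_truth):
        """Rab7 is at exactly half its plateau when Rab5 starts declining."""
        truth = default_truth
        t_dec = truth.events["rab5_decline_start"]
        rab7 = truth.amplitude_funcs["rab7"]
        assert rab7(np.array([t_dec]))[0] / truth.kin.rab7_plateau_amp \
            == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("coupling", [0.3, 0.5, 0.7])
    def test_coupling_generalizes(self, coupling):
        kin = ek.MarkerKineticsParams(conversion_coupling=coupling)
        truth = ek.simulate_truth(kin)
        t_dec = truth.events["rab5_decline_start"]
        frac = truth.amplitude_funcs["rab7"](np.array([t_dec]))[0] \
            / kin.rab7_plateau_amp
        assert frac == pytest.approx(coupling, abs=1e-12)

    def test_amplitude_invariance_of_events(self, default_truth):
        """Doubling the Rab7 plateau leaves every normalized event relation
        unchanged."""
        doubled = ek.simulate_truth(
            ek.MarkerKineticsParams(rab7_plateau_amp=300.0))
        for k, v in default_truth.events.items():
            assert doubled.events[k] == pytest.approx(v)
        t = default_truth.times_min
        a = default_truth.amplitudes("rab7")
        b = doubled.amplitudes("rab7")
        np.testing.assert_allclose(a / a.max(), b / b.max(), atol=1e-12)

    def test_rab5_boundary_values(self, default_truth):
        """Rab5 pulse evaluates to 0, peak_amp, 0 at onset, peak and
        conversion end."""
        kin = default_truth.kin
        f = default_truth.amplitude_funcs["rab5"]
        ev = default_truth.events
        pts = f(np.array([ev["rab5_onset"], ev["rab5_peak"],
                          ev["conversion_end"]]))
        np.testing.assert_allclose(
            pts, [0.0, kin.rab5_peak_amp, 0.0], atol=1e-9)

    def test_conversion_end_from_duration(self, default_truth):
        ev = default_truth.events
        assert ev["conversion_end"] - ev["conversion_start"] == \
            pytest.approx(default_truth.kin.conversion_duration_min)

    def test_halfmax_event_is_logistic_midpoint(self, default_truth):
        """Recorded half-max crossing equals the analytic midpoint of the
        Rab7 logistic within one time step (here: exactly, detected from
        the noiseless sampled trace)."""
        truth = default_truth
        tr = ek.normalize_trace(ek.KineticTrace(
            "x", "rab7", truth.times_min, truth.amplitudes("rab7")))
        ev = ek.detect_rab7_halfmax(tr)
        assert abs(ev.t_ref_min - truth.events["rab7_halfmax"]) \
            <= truth.frame_interval_min

    def test_ph_sigmoid_shape(self, default_truth):
        truth = default_truth
        php = truth.ph_params
        center = truth.events["rab7_halfmax"]
        assert truth.ph_func(np.array([center]))[0] == pytest.approx(
            (php.ph_pre_rab5 + php.ph_post_conversion) / 2)
        assert truth.ph_func(np.array([0.0]))[0] == pytest.approx(
            php.ph_pre_rab5, abs=0.01)
        assert truth.ph_func(np.array([1000.0]))[0] == pytest.approx(
            php.ph_post_conversion, abs=1e-6)

    def test_multi_peak_keeps_main_peak_tallest(self):
        truth = ek.simulate_truth(ek.MarkerKineticsParams(
            rab5_onset_min=14.0, multi_peak_count=2), n_frames=45)
        a = truth.amplitudes("rab5")
        t = truth.times_min
        assert t[np.argmax(a)] == truth.events["rab5_peak"]
        # the precursor peak exists and is smaller
        pre = a[t < truth.kin.rab5_onset_min]
        assert 0 < pre.max() < truth.kin.rab5_peak_amp

    def test_conversion_window_exceeding_span_rejected(self):
        with pytest.raises(ValueError, match="span"):
            ek.simulate_truth(ek.MarkerKineticsParams(rab5_onset_min=30.0),
                              n_frames=30)

    def test_too_short_conversion_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            ek.simulate_truth(ek.MarkerKineticsParams(
                conversion_duration_min=0.5))

    def test_param_validation(self):
        with pytest.raises(ValueError, match="coupling"):
            ek.MarkerKineticsParams(conversion_coupling=1.0)
        with pytest.raises(ValueError, match="amplitudes"):
            ek.MarkerKineticsParams(rab5_peak_amp=-1.0)
        with pytest.raises(ValueError, match="accessory_pattern"):
            ek.MarkerKineticsParams(accessory_pattern="wiggle")
        with pytest.raises(ValueError, match="range"):
            ek.PhTrajectoryParams(ph_pre_rab5=9.0)
        with pytest.raises(ValueError, match="ph_pre"):
            ek.PhTrajectoryParams(ph_pre_rab5=5.0, ph_post_conversion=6.0)

    def test_ko_truth_has_no_conversion(self):
        truth = ek.simulate_truth(ek.MarkerKineticsParams(
            rab7_plateau_amp=0.0), n_frames=30)
        assert truth.events["rab7_halfmax"] is None
        assert (truth.amplitudes("rab7") == 0).all()
        # Rab5 persists at peak amplitude to the end of the recording
        assert truth.amplitudes("rab5")[-1] == truth.kin.rab5_peak_amp


class TestRender:
    def test_zero_noise_equals_expectation(self, default_truth,
                                           noiseless_rp):
        stack, roi = ek.render_timelapse(default_truth, None, noiseless_rp)
        geom = roi.geometries[0]
        h, w = noiseless_rp.image_size
        yy, xx = np.mgrid[0:h, 0:w]
        ring = np.exp(-0.5 * ((np.hypot(yy - geom.cy, xx - geom.cx)
                               - geom.radius_px)
                              / noiseless_rp.rim_sigma_px) ** 2)
        for ci, ch in enumerate(("rab5", "rab7")):
            amps = default_truth.amplitudes(ch)
            want = noiseless_rp.background_level + amps[:, None, None] * ring
            np.testing.assert_allclose(stack.pixels[:, ci], want, atol=1e-12)

    def test_seed_contract(self, default_truth):
        rp1 = ek.RenderParams(seed=42)
        s1, _ = ek.render_timelapse(default_truth, None, rp1)
        s2, _ = ek.render_timelapse(default_truth, None, rp1)
        np.testing.assert_array_equal(s1.pixels, s2.pixels)
        s3, _ = ek.render_timelapse(default_truth, None,
                                    ek.RenderParams(seed=43))
        assert not np.array_equal(s1.pixels, s3.pixels)

    def test_lumen_ratio_closed_form(self, noiseless_rp):
        """Noiseless luminal YFP/CFP at clamped pH equals the sensor
        forward model evaluated independently."""
        sensor = ek.SensorModel()
        scenes = ek.generate_calibration_set([6.0, 5.0, 4.0, 7.0, 6.5],
                                             sensor, noiseless_rp)
        scene = scenes[0]
        shape = scene.stack.pixels.shape[2:]
        lum = ek.lumen_pixels(scene.roi, shape)
        y = lum.values(scene.stack.pixels[0, 0]).mean() \
            - noiseless_rp.background_level
        c = lum.values(scene.stack.pixels[0, 1]).mean() \
            - noiseless_rp.background_level
        want = (sensor.brightness_yfp * sensor.f_yfp(6.0)
                / (sensor.brightness_cfp * sensor.f_cfp(6.0)))
        assert y / c == pytest.approx(float(want), rel=1e-12)

    def test_geometry_must_fit(self):
        with pytest.raises(ValueError, match="margin"):
            ek.RenderParams(image_size=(32, 32), endosome_radius_px=12.0)

    def test_sensor_channel_is_filled_disk(self, default_truth,
                                           noiseless_rp):
        stack, roi = ek.render_timelapse(default_truth, ek.SensorModel(),
                                         noiseless_rp)
        geom = roi.geometries[0]
        yfp = stack.channel("yfp")[0]
        inside = yfp[int(geom.cy), int(geom.cx)]
        outside = yfp[2, 2]
        assert inside > outside == noiseless_rp.background_level


class TestCalibrationSet:
    def test_scene_count_and_span(self):
        phs = [4.0, 4.5, 5.0, 5.5, 6.0, 6.5, 7.0, 7.5]
        scenes = ek.generate_calibration_set(phs)
        assert len(scenes) == 8
        assert [s.ph_truth for s in scenes] == phs

    def test_noiseless_ratios_strictly_increase_with_ph(self, noiseless_rp):
        phs = [4.0, 4.5, 5.0, 5.5, 6.0, 6.5, 7.0, 7.5]
        scenes = ek.generate_calibration_set(phs, ek.SensorModel(),
                                             noiseless_rp)
        ratios = []
        for s in scenes:
            lum = ek.lumen_pixels(s.roi, s.stack.pixels.shape[2:])
            y = lum.values(s.stack.pixels[0, 0]).mean() \
                - noiseless_rp.background_level
            c = lum.values(s.stack.pixels[0, 1]).mean() \
                - noiseless_rp.background_level
            ratios.append(y / c)
        assert all(a < b for a, b in zip(ratios, ratios[1:]))

    def test_repeated_ph_identical_expectations(self, noiseless_rp):
        scenes = ek.generate_calibration_set([6.0] * 5, ek.SensorModel(),
                                             noiseless_rp)
        for s in scenes[1:]:
            np.testing.assert_array_equal(s.stack.pixels,
                                          scenes[0].stack.pixels)

    def test_too_few_levels_warns(self):
        with pytest.warns(UserWarning, match="fewer than 5"):
            ek.generate_calibration_set([5.0, 6.0])

    def test_out_of_range_ph_rejected(self):
        with pytest.raises(ValueError, match="range"):
            ek.generate_calibration_set([3.0, 5.0, 6.0, 6.5, 7.0])


def test_sensor_monotonicity():
    s = ek.SensorModel()
    ph = np.linspace(3.5, 8.0, 50)
    assert (np.diff(s.f_yfp(ph)) > 0).all()
    assert (np.diff(s.f_cfp(ph)) <= 0).all()
    assert (np.diff(s.ratio(ph)) > 0).all()


def test_default_tau_puts_conversion_start_on_grid(default_truth):
    ev = default_truth.events
    assert RAB7_TAU_DEFAULT * np.log(9.0) == pytest.approx(1.0)
    assert ev["conversion_start"] == pytest.approx(
        ev["rab7_halfmax"] - 1.0)
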