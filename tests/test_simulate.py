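"""Simulator ground truth: beat clock, Ca²⁺ kernel, pool depletion, rendering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiolum import (DrugEvent, beat_kernel, simulate_ca_trace,
                       simulate_luminescence, render_image_stack,
                       simulate_geometry, simulate_gcamp, extract_trace,
                       ellipsoid_volume, detect_beats)

from conftest import make_config, simulate_recording


class TestBeatClock:
    def test_every_beat_conduction_gives_atrial_rate(self):
        gt = simulate_ca_trace(make_config(duration=60.0, atrial_rate=180.0))
        assert gt.beat_times_ventricle.size == 180
        assert np.allclose(np.diff(gt.beat_times_ventricle), 1.0 / 3.0)

    def test_two_to_one_block_halves_ventricular_rate(self):
        gt = simulate_ca_trace(make_config(duration=60.0, atrial_rate=180.0,
                                           conduction_ratio=2))
        assert gt.beat_times_atrium.size == 180
        assert gt.beat_times_ventricle.size == 90
        # ventricular rate 90 bpm -> AV ratio 0.5 by construction
        assert gt.beat_times_ventricle.size / gt.beat_times_atrium.size == 0.5

    @given(n=st.integers(1, 7), rate=st.floats(60, 300), duration=st.floats(5, 40))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_thinning_count_invariant(self, n, rate, duration):
        gt = simulate_ca_trace(make_config(duration=duration, atrial_rate=rate,
                                           conduction_ratio=n, acq_freq=2.0))
        n_atr = gt.beat_times_atrium.size
        n_ven = gt.beat_times_ventricle.size
        assert abs(n_ven - n_atr // n) <= 1

    def test_conduction_zero_rejected(self):
        with pytest.raises(ValueError):
            make_config(conduction_ratio=0)

    def test_nonpositive_time_constants_rejected(self):
        with pytest.raises(ValueError):
            make_config(tau_rise=0.0)
        with pytest.raises(ValueError):
            make_config(tau_decay=-0.1)


class TestKernel:
    def test_unit_peak(self):
        u = np.linspace(0, 2, 200001)
        g = beat_kernel(u, 0.02, 0.2)
        assert g.max() == pytest.approx(1.0, abs=1e-9)
        assert np.all(g >= 0)
        assert beat_kernel(np.array([-0.01]), 0.02, 0.2)[0] == 0.0

    def test_rise_time_matches_dense_grid_oracle(self):
        """10-90% rise of a single transient vs brute-force 10 µs evaluation."""
        tau_r, tau_d = 0.02, 0.2
        # oracle: dense evaluation of the kernel itself
        u = np.arange(0, 1.5, 1e-5)
        g = beat_kernel(u, tau_r, tau_d)
        t10 = u[np.argmax(g >= 0.1)]
        t90 = u[np.argmax(g >= 0.9)]
        oracle_rise = t90 - t10

        cfg = make_config(duration=4.0, atrial_rate=30.0, tau_rise=tau_r,
                          tau_decay=tau_d, acq_freq=100.0)
        gt = simulate_ca_trace(cfg)
        beats = detect_beats(gt.ca_trace)
        rises = np.array([f.rise_10_90 for f in beats.features])
        rises = rises[~np.isnan(rises)]
        assert np.median(rises) == pytest.approx(oracle_rise, rel=0.05)


class TestGroundTruthInvariants:
    def test_pool_non_increasing_and_lambda_is_hill(self, config):
        gt = simulate_ca_trace(config)
        assert np.all(np.diff(gt.pool_trace.values) <= 0)
        ca = gt.ca_trace.values
        expected = config.lambda_max * ca ** 3 / (config.kd ** 3 + ca ** 3)
        np.testing.assert_allclose(gt.lambda_trace.values, expected, rtol=1e-12)
        assert np.all(gt.lambda_trace.values >= 0)

    def test_drug_event_scales_amplitude_with_ramp(self):
        # slow rate so transients are isolated and extrema are clean
        ev = DrugEvent(time=10.0, ca_scale=2.0, ramp_tau=2.0)
        cfg = make_config(duration=40.0, atrial_rate=60.0, drug_event=ev, acq_freq=9.0)
        gt = simulate_ca_trace(cfg)
        t = gt.ca_trace.times
        ca = gt.ca_trace.values
        early_peak = ca[t < 9.5].max() - cfg.ca_diastolic
        late_peak = ca[t > 35].max() - cfg.ca_diastolic
        assert late_peak / early_peak == pytest.approx(2.0, rel=0.02)
        # diastolic level untouched unless requested (small residual from the
        # previous transient's tail at 60 bpm: g(1 s) ~ 1e-3 of peak)
        assert ca[t > 35].min() == pytest.approx(cfg.ca_diastolic, abs=0.02)


class TestLuminescence:
    def test_constant_lambda_closed_form(self):
        """With near-constant Ca²⁺, frame counts follow A0·(e^{-λt1} − e^{-λt2})."""
        cfg = make_config(ca_diastolic=2.0, ca_amplitude=1e-9, duration=10.0,
                          acq_freq=5.0, bg_rate=0.0)
        lam = cfg.lambda_max * cfg.ca_diastolic ** 3 / (cfg.kd ** 3 + cfg.ca_diastolic ** 3)
        gt = simulate_ca_trace(cfg)
        lum = simulate_luminescence(gt, cfg, noise=False)
        k = np.arange(cfg.n_frames)
        expected = cfg.pool0 * (np.exp(-lam * k / cfg.acq_freq)
                                - np.exp(-lam * (k + 1) / cfg.acq_freq))
        np.testing.assert_allclose(lum.expected, expected, rtol=1e-6)

    def test_photon_conservation_with_triton(self):
        """Noise off, detection 1, bg 0, full release: frame means sum to pool0."""
        cfg = make_config(duration=20.0, triton_time=8.0, bg_rate=0.0, acq_freq=9.0)
        gt = simulate_ca_trace(cfg)
        lum = simulate_luminescence(gt, cfg, noise=False)
        # 12 s of release at 2 /s leaves an e^-24 residual
        assert lum.expected.sum() == pytest.approx(cfg.pool0, rel=1e-8)

    def test_poisson_totals_match_analytic_mean(self):
        """Monte-Carlo: total counts over repeats within 3 SE of expectation."""
        cfg = make_config(duration=5.0, pool0=2.0e4, bg_rate=10.0, acq_freq=9.0)
        gt = simulate_ca_trace(cfg)
        rng = np.random.default_rng(1234)
        totals = np.array([
            simulate_luminescence(gt, cfg, rng=rng).trace.values.sum()
            for _ in range(100)
        ])
        analytic = simulate_luminescence(gt, cfg, noise=False).expected.sum()
        se = totals.std(ddof=1) / 10.0
        assert abs(totals.mean() - analytic) < 3 * se

    def test_seed_determinism(self, config):
        gt = simulate_ca_trace(config)
        a = simulate_luminescence(gt, config).trace.values
        b = simulate_luminescence(gt, config).trace.values
        np.testing.assert_array_equal(a, b)

    def test_empty_recording_rejected(self):
        cfg = make_config(pool0=500.0, detect_eff=0.1)
        gt = simulate_ca_trace(cfg)
        with pytest.raises(ValueError, match="empty"):
            simulate_luminescence(gt, cfg)


class TestRenderStack:
    def test_zero_signal_background_level(self):
        cfg = make_config(duration=2.0, acq_freq=9.0, bg_rate=90.0, seed=5)
        counts = np.zeros(18)
        stack, rois = render_image_stack({"ventricle": counts}, cfg)
        vent_mask = rois[0].mask(stack.shape[1:])
        per_roi = stack[:, vent_mask].sum(axis=1).mean()
        assert per_roi == pytest.approx(cfg.bg_rate / cfg.acq_freq, rel=0.15)

    def test_round_trip_recovers_chamber_totals(self):
        cfg, gt, lum = simulate_recording(duration=4.0, acq_freq=9.0, bg_rate=20.0)
        stack, rois = render_image_stack(
            {"ventricle": lum.trace.values}, cfg,
            beat_times=gt.beat_times_ventricle,
        )
        vent = next(r for r in rois if r.label == "ventricle")
        rec = extract_trace(stack, vent, sampling_rate=cfg.acq_freq)
        npix = int(vent.mask(stack.shape[1:]).sum())
        expected = lum.trace.values + cfg.bg_rate / cfg.acq_freq
        resid = rec.values - expected
        # per-frame Poisson error ~ sqrt(mean); allow 5 sigma on each frame
        sigma = np.sqrt(np.maximum(expected, 1.0))
        assert np.all(np.abs(resid) < 5 * sigma + 5)

    def test_pixel_counts_are_poisson(self):
        """Uniform spread over the mask: per-pixel mean and variance agree."""
        cfg = make_config(duration=40.0, acq_freq=1.0, bg_rate=0.0, seed=3)
        counts = np.full(40, 5000.0)
        stack, rois = render_image_stack({"ventricle": counts}, cfg)
        mask = rois[0].mask(stack.shape[1:])
        pix = stack[:, mask].astype(float)
        mean = pix.mean()
        var = pix.var(ddof=1)
        assert var == pytest.approx(mean, rel=0.1)  # Poisson: var = mean

    def test_saturation_clamped_with_warning(self):
        cfg = make_config(duration=2.0, acq_freq=1.0, bg_rate=0.0)
        huge = np.full(2, 1.0e9)
        with pytest.warns(UserWarning, match="saturated"):
            stack, _ = render_image_stack({"ventricle": huge}, cfg)
        assert stack.max() == 65535

    def test_negative_counts_rejected(self, config):
        with pytest.raises(ValueError):
            render_image_stack({"ventricle": np.array([-1.0, 2.0])}, config)


class TestGeometry:
    def test_fractional_shortening_definition(self):
        cfg = make_config(duration=5.0, acq_freq=50.0)
        geom = simulate_geometry(cfg, fs_major=0.28, fs_minor=0.3,
                                 dd_major=100.0, dd_minor=80.0)
        es = geom.phase == "ES"
        assert geom.major_um[es].min() == pytest.approx(72.0)

    def test_fs_recovered_to_machine_precision(self):
        cfg = make_config(duration=5.0, acq_freq=50.0)
        fs_maj, fs_min = 0.28, 0.33
        geom = simulate_geometry(cfg, fs_maj, fs_min, 100.0, 80.0)
        ed, es = geom.phase == "ED", geom.phase == "ES"
        rec_maj = (geom.major_um[ed].mean() - geom.major_um[es].mean()) / geom.major_um[ed].mean()
        rec_min = (geom.minor_um[ed].mean() - geom.minor_um[es].mean()) / geom.minor_um[ed].mean()
        assert rec_maj == pytest.approx(fs_maj, abs=1e-12)
        assert rec_min == pytest.approx(fs_min, abs=1e-12)

    def test_edv_from_diastolic_pair(self):
        # (pi/6) * 100 * 80^2 in um^3
        assert ellipsoid_volume(100.0, 80.0) * 1e6 == pytest.approx(335103.2, rel=1e-4)

    def test_area_is_ellipse_area(self):
        cfg = make_config(duration=2.0, acq_freq=10.0)
        geom = simulate_geometry(cfg, 0.2, 0.2, 100.0, 80.0)
        np.testing.assert_allclose(
            geom.area_um2, (np.pi / 4) * geom.major_um * geom.minor_um, rtol=1e-12)

    def test_invalid_fs_rejected(self, config):
        with pytest.raises(ValueError):
            simulate_geometry(config, 1.2, 0.3, 100.0, 80.0)


class TestGcamp:
    def test_dff_peak_without_bleach(self):
        cfg = make_config(duration=10.0, atrial_rate=60.0)
        f0, amp = 200.0, 80.0
        trace = simulate_gcamp(cfg, f0=f0, amp=amp)
        assert trace.sampling_rate == 200.0
        dff_peak = (trace.values.max() - trace.values.min()) / trace.values.min()
        assert dff_peak == pytest.approx(amp / f0, rel=0.01)

    def test_decay_tau_recovered_from_transients(self):
        """Simulate-and-refit: fitted decay constant within 10% at high SNR."""
        from cardiolum import delta_f_over_f0

        tau_d = 0.15
        cfg = make_config(duration=20.0, atrial_rate=60.0, tau_rise=0.02,
                          tau_decay=tau_d, seed=7)
        f0, amp = 1000.0, 500.0
        trace = simulate_gcamp(cfg, f0=f0, amp=amp, noise_sd=amp / 25.0)
        norm = delta_f_over_f0(trace, smoothing=True)
        beats = detect_beats(norm.dff)
        decays = np.array([f.decay_90_10 for f in beats.features])
        decays = decays[~np.isnan(decays)]
        # 90->10 decay of the kernel, dense-grid oracle
        u = np.arange(0, 2.0, 1e-5)
        g = beat_kernel(u, cfg.tau_rise, cfg.tau_decay)
        pk = np.argmax(g)
        after = g[pk:]
        t90 = u[pk + np.argmax(after <= 0.9)]
        t10 = u[pk + np.argmax(after <= 0.1)]
        assert np.median(decays) == pytest.approx(t10 - t90, rel=0.10)
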