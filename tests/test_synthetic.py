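"""Synthetic generators: breathing waveform, profile stream, camera, phantom."""

import numpy as np
import pytest
from scipy import signal as sps

from respgate.camera import align_signals
from respgate.containers import RespiratorySignal
from respgate.synthetic import (
    BreathingParams,
    CoilModel,
    PhantomGeometry,
    VelocityPhantomParams,
    generate_breathing_waveform,
    generate_camera_signal,
    generate_chest_video,
    generate_profile_stream,
    generate_velocity_phantom,
)


class TestBreathingWaveform:
    def test_zero_amplitude_gives_baseline_plus_drift(self):
        p = BreathingParams(amplitude=0.0, amplitude_jitter_sd=0.0, duration=40.0)
        sig, _ = generate_breathing_waveform(p, seed=0)
        expected = p.z0 + p.drift_rate / 60.0 * sig.t
        assert np.allclose(sig.amplitude, expected)

    def test_jitter_free_waveform_is_exactly_periodic(self):
        # rate chosen so one period is an integer number of samples
        p = BreathingParams(
            period=4.0, period_jitter_sd=0.0, amplitude_jitter_sd=0.0,
            drift_rate=0.0, duration=40.0, rate=20.0,
        )
        sig, _ = generate_breathing_waveform(p, seed=0)
        n_cycle = int(p.period * p.rate)
        assert np.allclose(sig.amplitude[:-n_cycle], sig.amplitude[n_cycle:])
        assert sig.amplitude.max() - sig.amplitude.min() == pytest.approx(p.amplitude)
        assert sig.amplitude.max() == pytest.approx(p.z0)

    def test_periodogram_peak_at_breathing_frequency(self):
        p = BreathingParams(period=4.0, duration=300.0, drift_rate=0.0)
        sig, _ = generate_breathing_waveform(p, seed=1)
        f, pxx = sps.periodogram(sig.amplitude - sig.amplitude.mean(), fs=sig.rate)
        peak = f[int(np.argmax(pxx))]
        assert abs(peak - 0.25) <= f[1] - f[0]

    def test_rejects_frequency_outside_nyquist(self):
        with pytest.raises(ValueError):
            BreathingParams(period=0.05, rate=22.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_plateau_occupies_more_than_half_the_range(self, seed):
        # end-expiratory plateau dominance for shape_exponent >= 2
        p = BreathingParams(duration=120.0)
        sig, _ = generate_breathing_waveform(p, seed=seed)
        a = sig.amplitude
        mid = 0.5 * (a.max() + a.min())
        assert np.sum(a > mid) > a.size / 2

    def test_reproducible(self):
        p = BreathingParams(duration=30.0)
        s1, _ = generate_breathing_waveform(p, seed=42)
        s2, _ = generate_breathing_waveform(p, seed=42)
        assert np.array_equal(s1.amplitude, s2.amplitude)


class TestProfileStream:
    def test_static_waveform_gives_identical_time_columns(self, short_breathing):
        _, sig, _ = short_breathing
        static = sig.copy(amplitude=np.full(sig.n, 180.0), t=sig.t[:])
        stream = generate_profile_stream(static, snr=np.inf)
        ref = stream.profiles[:, :, 0]
        assert np.allclose(stream.profiles, ref[:, :, None])

    def test_uniform_phantom_concentrates_energy_at_k0(self):
        g = PhantomGeometry(
            fov=360.0, n_x=64,
            blocks=(("liver", 0.0, 150.0), ("liver", 150.0, 360.0)),
            moving_interface=1, heart_coupling=0.0,
        )
        t = np.arange(64) * 0.045
        sig_static = RespiratorySignal(t=t, amplitude=np.full(64, 150.0), rate=1 / 0.045)
        coils = CoilModel(centers_mm=(180.0,), widths_mm=(1e6,), gains=(1.0,))
        stream = generate_profile_stream(sig_static, g=g, coils=coils, snr=np.inf)
        mag = np.abs(stream.profiles[0, :, 0])
        k0 = g.n_x // 2
        assert mag[k0] > 100 * np.max(np.delete(mag, k0))

    def test_interface_position_tracks_waveform(self):
        # edge-detection oracle on the noiseless projection
        from respgate.self_gating import profiles_to_projection

        rate = 1 / 0.045
        t = np.arange(int(60 * rate)) / rate
        w = RespiratorySignal(
            t=t, amplitude=180.0 - 8.0 * (1 + np.sin(2 * np.pi * 0.3 * t)) / 2, rate=rate
        )
        g = PhantomGeometry(heart_coupling=0.0)
        stream = generate_profile_stream(w, g=g, snr=np.inf)
        proj = profiles_to_projection(stream)
        dx = g.fov / g.n_x
        lo, hi = int(150 / dx), int(210 / dx)  # search window around the interface
        grad = np.abs(np.diff(proj.xsos[lo:hi, :], axis=0))
        edge_mm = (lo + np.argmax(grad, axis=0) + 1.0) * dx
        assert np.max(np.abs(edge_mm - w.amplitude)) <= dx

    def test_parseval_energy_conservation(self, noiseless_stream):
        s = noiseless_stream
        x = np.fft.fftshift(
            np.fft.ifft(np.fft.ifftshift(s.profiles, axes=1), axis=1, norm="ortho"),
            axes=1,
        )
        for c in range(s.n_coils):
            ek = float(np.sum(np.abs(s.profiles[c]) ** 2))
            ex = float(np.sum(np.abs(x[c]) ** 2))
            assert abs(ek - ex) <= 1e-9 * ek

    def test_rejects_nonpositive_snr(self, short_breathing):
        _, sig, _ = short_breathing
        with pytest.raises(ValueError):
            generate_profile_stream(sig, snr=0.0)

    def test_rejects_excursion_outside_blocks(self, short_breathing):
        _, sig, _ = short_breathing
        runaway = sig.copy(amplitude=sig.amplitude + 90.0)
        with pytest.raises(ValueError, match="excursion"):
            generate_profile_stream(runaway, snr=np.inf)

    def test_reproducible(self, short_breathing):
        _, sig, _ = short_breathing
        s1 = generate_profile_stream(sig, snr=15.0, seed=3)
        s2 = generate_profile_stream(sig, snr=15.0, seed=3)
        assert np.array_equal(s1.profiles, s2.profiles)


class TestCameraSignal:
    def test_identity_settings_reproduce_waveform(self, short_breathing):
        _, sig, _ = short_breathing
        y = generate_camera_signal(
            sig, delay_ms=0.0, gain=1.0, offset=0.0, noise_sd=0.0,
            camera_rate=sig.rate,
        )
        assert np.allclose(y.amplitude, sig.amplitude)

    def test_negative_gain_anticorrelates(self, short_breathing):
        _, sig, _ = short_breathing
        y = generate_camera_signal(
            sig, delay_ms=0.0, gain=-1.0, offset=5.0, noise_sd=0.0,
            camera_rate=sig.rate,
        )
        r = np.corrcoef(y.amplitude, sig.amplitude)[0, 1]
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_injected_delay_recovered_by_alignment(self, short_breathing):
        _, sig, _ = short_breathing
        y = generate_camera_signal(sig, delay_ms=500.0, noise_sd=0.0, camera_rate=22.0)
        res = align_signals(sig, y)
        assert abs(res.delay_ms - 500.0) <= 0.5 * res.grid_dt_s * 1000.0


class TestChestVideo:
    def test_zero_modulation_gives_static_frames(self, short_breathing):
        _, sig, _ = short_breathing
        v = generate_chest_video(sig, modulation=0.0, noise_sd=0.0, seed=0)
        assert np.allclose(v.frames, v.frames[:, :, :1])

    def test_noiseless_patch_mean_is_affine_in_waveform(self, short_breathing):
        _, sig, _ = short_breathing
        v = generate_chest_video(sig, noise_sd=0.0, seed=0)
        patch_mean = v.frames[8:16, 16:24, :].mean(axis=(0, 1))
        w = np.interp(np.arange(v.n_t) / v.frame_rate + sig.t[0], sig.t, sig.amplitude)
        r = np.corrcoef(patch_mean, w)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_rejects_patch_outside_frame(self, short_breathing):
        _, sig, _ = short_breathing
        with pytest.raises(ValueError):
            generate_chest_video(sig, frame_shape=(32, 32), patch=(0, 40, 0, 8))


class TestVelocityPhantom:
    def test_zero_perturbation_gives_identical_fields(self):
        p = VelocityPhantomParams(perturbation_sd=0.0, noise_sd=0.0)
        a, b, _, _ = generate_velocity_phantom(p, seed=0)
        assert np.array_equal(a.components, b.components)

    def test_discrete_flow_matches_analytic_disc_integral(self, phantom_pair):
        p, field_a, _, mask, truth = phantom_pair
        # analytic peak flow: pi R^2 v_peak max(h) / 2 = 157.08 mL/s per cm^2 of R=10mm;
        # here R=15mm so scale accordingly
        k = p.grid_shape[p.axis] // 2
        plane = np.take(field_a.components[p.axis], k, axis=p.axis)
        plane_mask = np.take(mask.mask, k, axis=p.axis)
        area = (p.voxel_mm / 10.0) ** 2
        q = plane[plane_mask].sum(axis=0) * area
        peak = np.argmax(truth["h"])
        analytic = np.pi * (p.radius_mm / 10.0) ** 2 * p.v_peak * truth["h"][peak] / 2.0
        assert q[peak] == pytest.approx(analytic, rel=0.03)

    def test_mask_matches_exhaustive_center_scan(self, phantom_pair):
        p, _, _, mask, _ = phantom_pair
        nx, ny, nz = p.grid_shape
        cx, cy = (nx - 1) / 2.0 * p.voxel_mm, (ny - 1) / 2.0 * p.voxel_mm
        count = 0
        for i in range(nx):
            for j in range(ny):
                r2 = (i * p.voxel_mm - cx) ** 2 + (j * p.voxel_mm - cy) ** 2
                if r2 <= p.radius_mm**2:
                    count += nz
        assert mask.n_voxels == count

    def test_vessel_must_fit_in_grid(self):
        with pytest.raises(ValueError):
            VelocityPhantomParams(grid_shape=(8, 8, 8), radius_mm=15.0)

    def test_reproducible(self):
        p = VelocityPhantomParams()
        a1, b1, _, _ = generate_velocity_phantom(p, seed=9)
        a2, b2, _, _ = generate_velocity_phantom(p, seed=9)
        assert np.array_equal(a1.components, a2.components)
        assert np.array_equal(b1.components, b2.components)
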