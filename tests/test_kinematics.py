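import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import FS, fit_circle_radius
from helpers import zupt_bruteforce

from wristkin import (
    FusionConfig,
    ImuCapture,
    NoiseModel,
    PipelineConfig,
    circle_preset,
    integrate_rectangles,
    out_and_back_preset,
    process_capture,
    read_capture_csv,
    read_track_csv,
    remove_dc,
    remove_gravity,
    simulate_truth,
    smooth_acceleration,
    speed_magnitude,
    truth_to_imu,
    write_capture_csv,
    write_track_csv,
    zero_velocity_update,
)

DT = 1.0 / FS
G = 9.80665


class TestRemoveGravity:
    def test_stationary_reading_becomes_zero(self):
        a = np.tile([0.0, 0.0, -G], (100, 1))
        np.testing.assert_allclose(remove_gravity(a, G), 0.0, atol=1e-12)

    def test_free_fall_reads_g_downward(self):
        """Zero specific force means the device accelerates at g Down."""
        dyn = remove_gravity(np.zeros((10, 3)), G)
        np.testing.assert_allclose(np.linalg.norm(dyn, axis=1), G)
        assert np.all(dyn[:, 2] > 0)  # NED Down is positive z

    def test_add_then_remove_is_identity(self, rng):
        a = rng.normal(size=(50, 3))
        added = a.copy()
        added[:, 2] -= G
        np.testing.assert_allclose(remove_gravity(added, G), a, atol=1e-12)


class TestSmoothing:
    def test_constant_signal_unchanged(self):
        np.testing.assert_allclose(
            smooth_acceleration(np.full(200, 3.5), 50), 3.5)

    def test_impulse_spreads_over_window(self):
        x = np.zeros(300)
        x[100] = 1.0
        y = smooth_acceleration(x, 50)
        np.testing.assert_allclose(y[100:150], 1.0 / 50, atol=1e-12)
        np.testing.assert_allclose(y[:100], 0.0)
        np.testing.assert_allclose(y[150:], 0.0)

    def test_matches_bruteforce_windowed_mean(self, rng):
        x = rng.normal(size=500)
        y = smooth_acceleration(x, 50)
        for i in range(0, 500, 37):
            lo = max(0, i - 49)
            assert abs(y[i] - x[lo:i + 1].mean()) < 1e-12

    def test_white_noise_variance_reduced_by_N(self, rng):
        x = rng.normal(size=100_000)
        y = smooth_acceleration(x, 50)[49:]  # skip the startup ramp
        ratio = y.var() / x.var()
        assert abs(ratio - 1.0 / 50) < 0.2 / 50

    def test_rejects_window_longer_than_signal(self):
        with pytest.raises(ValueError):
            smooth_acceleration(np.zeros(10), 50)

    def test_exponential_mode_smooths_too(self, rng):
        x = rng.normal(size=2000)
        y = smooth_acceleration(x, 50, mode="exponential")
        assert y.var() < 0.1 * x.var()


class TestIntegration:
    def test_constant_acceleration(self):
        a = np.full(500, 2.0)  # 2 m/s² over 1 s at 500 Hz
        v = integrate_rectangles(a, DT)
        assert abs(v[-1] - 2.0) < 1e-12

    def test_zero_signal_holds_initial(self):
        v = integrate_rectangles(np.zeros(100), DT, initial=1.5)
        np.testing.assert_allclose(v, 1.5)

    def test_ramp_error_within_one_rectangle_bound(self):
        t = np.arange(1000) * DT
        slope = 3.0
        v = integrate_rectangles(slope * t, DT)
        exact = 0.5 * slope * (t + DT) ** 2  # integral up to each step's end
        # left-rectangle rule: |error| <= max|signal| * dt per unit time
        bound = slope * t[-1] * DT
        assert np.abs(v - exact).max() <= bound + 1e-12


class TestRemoveDc:
    def test_constant_input_decays(self):
        x = np.full(5000, 2.0)
        y = remove_dc(x, cutoff=1.0, fs=FS)
        assert np.abs(y[2500:]).max() < 0.01 * 2.0

    def test_zero_input_zero_output(self):
        np.testing.assert_allclose(remove_dc(np.zeros(100), 50.0, FS), 0.0)

    def test_passband_sinusoid_preserved(self):
        """A tone well above the cutoff passes within 5% of unit gain."""
        t = np.arange(5000) * DT
        x = np.sin(2 * np.pi * 50.0 * t)  # 50 Hz tone, 1 Hz cutoff
        y = remove_dc(x, cutoff=1.0, fs=FS)
        amp = (y[2000:].max() - y[2000:].min()) / 2
        assert abs(amp - 1.0) < 0.05

    def test_rejects_cutoff_at_or_above_nyquist(self):
        with pytest.raises(ValueError):
            remove_dc(np.zeros(10), cutoff=250.0, fs=FS)


class TestZupt:
    def test_long_quiet_window_is_fully_zeroed(self):
        a = np.full((100, 3), 0.1)
        v = np.full((100, 3), 1.7)
        out, mask = zero_velocity_update(a, v, limit=0.3, count=60)
        assert np.all(out == 0.0)
        assert mask.all()

    def test_run_shorter_than_count_is_untouched(self):
        a = np.full((61, 3), 5.0)
        a[1:60] = 0.0  # 59 quiet samples bracketed by large accelerations
        v = np.ones((61, 3))
        out, mask = zero_velocity_update(a, v, limit=0.3, count=60)
        np.testing.assert_array_equal(out, v)
        assert not mask.any()

    def test_matches_bruteforce_scan_on_random_inputs(self, rng):
        for _ in range(300):
            n = int(rng.integers(5, 150))
            count = int(rng.integers(1, 12))
            a = rng.normal(scale=0.4, size=(n, 3))
            v = rng.normal(size=(n, 3))
            mine, mask = zero_velocity_update(a, v, limit=0.3, count=count)
            ref, ref_mask = zupt_bruteforce(a, v, limit=0.3, count=count)
            np.testing.assert_array_equal(mine, ref)
            np.testing.assert_array_equal(mask, ref_mask)


class TestSpeed:
    def test_pythagorean_triple(self):
        assert speed_magnitude([3.0], [4.0], [0.0])[0] == 5.0

    def test_zero(self):
        assert speed_magnitude([0.0], [0.0], [0.0])[0] == 0.0

    def test_symmetry_under_permutation_and_sign(self, rng):
        v = rng.normal(size=(50, 3))
        s = speed_magnitude(v[:, 0], v[:, 1], v[:, 2])
        np.testing.assert_allclose(
            s, speed_magnitude(-v[:, 2], v[:, 0], -v[:, 1]))


class TestProcessCapture:
    def test_stationary_capture_is_null_case(self, stationary_capture,
                                             recon_cfg):
        track = process_capture(stationary_capture, cfg=recon_cfg)
        assert np.linalg.norm(track.position[-1]) < 0.05
        assert np.all(track.speed == 0.0)

    def test_out_and_back_returns_near_origin(self, recon_cfg):
        spec = out_and_back_preset(distance=1.0, duration=6.0)
        truth = simulate_truth(spec, FS)
        cap = truth_to_imu(truth, NoiseModel.zero())
        track = process_capture(cap, cfg=recon_cfg)
        assert np.linalg.norm(track.position[-1]) < 0.15
        assert np.all(track.velocity[-1] == 0.0)  # ZUPT ends the motion

    def test_circle_radius_recovered(self, recon_cfg):
        spec = circle_preset(radius=1.0)
        truth = simulate_truth(spec, FS)
        cap = truth_to_imu(truth, NoiseModel.zero())
        track = process_capture(cap, cfg=recon_cfg)
        r = fit_circle_radius(track.position[500:, :2])
        assert abs(r - 1.0) < 0.2

    def test_track_invariants(self, discus_capture, recon_cfg):
        track = process_capture(discus_capture, cfg=recon_cfg)
        n = discus_capture.n_samples
        for arr in (track.accel_earth, track.velocity, track.position):
            assert len(arr) == n
        np.testing.assert_array_equal(track.position[0], 0.0)
        assert np.all(track.speed >= 0.0)
        assert np.all(track.speed[track.zupt_mask] == 0.0)

    def test_deterministic(self, stationary_capture, recon_cfg):
        a = process_capture(stationary_capture, cfg=recon_cfg)
        b = process_capture(stationary_capture, cfg=recon_cfg)
        np.testing.assert_array_equal(a.position, b.position)
        np.testing.assert_array_equal(a.speed, b.speed)

    def test_stage_failure_names_the_stage(self):
        tiny = ImuCapture(DT, np.zeros((10, 3)), np.zeros((10, 3)),
                          np.tile([0.2, 0.0, 0.4], (10, 1)))
        with pytest.raises(RuntimeError, match="acceleration smoothing"):
            process_capture(tiny, cfg=PipelineConfig(smoothing_window=50))

    def test_doubling_noise_does_not_improve_position(self):
        """Median final-position error is monotone in accelerometer noise."""
        spec = out_and_back_preset(distance=0.5, duration=3.0, hold=0.5)
        truth = simulate_truth(spec, FS)
        cfg = PipelineConfig.reconstruction()
        fcfg = FusionConfig(sample_period=DT)

        def median_err(sigma):
            errs = []
            for seed in range(20):
                cap = truth_to_imu(truth, NoiseModel(
                    accel_sigma=sigma, gyro_sigma=0.0, mag_sigma=0.0,
                    gyro_bias=np.zeros(3), gyro_drift_rate=0.0, seed=seed))
                tr = process_capture(cap, fcfg, cfg)
                errs.append(np.linalg.norm(tr.position[-1]))
            return np.median(errs)

        assert median_err(0.10) >= median_err(0.05)


class TestCsvRoundTrip:
    def test_capture_round_trip(self, tmp_path, stationary_capture):
        p = tmp_path / "cap.csv"
        write_capture_csv(stationary_capture, p)
        back = read_capture_csv(p)
        assert back.n_samples == stationary_capture.n_samples
        assert abs(back.sample_period - DT) < 1e-12
        np.testing.assert_allclose(back.accel_xyz,
                                   stationary_capture.accel_xyz, atol=1e-9)

    def test_track_round_trip(self, tmp_path, stationary_capture, recon_cfg):
        track = process_capture(stationary_capture, cfg=recon_cfg)
        p = tmp_path / "track.csv"
        write_track_csv(track, p)
        back = read_track_csv(p)
        np.testing.assert_allclose(back.position, track.position, atol=1e-9)
        np.testing.assert_allclose(back.speed, track.speed, atol=1e-9)

    def test_malformed_capture_names_missing_columns(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("t,ax,ay\n0,1,2\n0.002,1,2\n")
        with pytest.raises(ValueError, match="az"):
            read_capture_csv(p)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.integers(1, 8), st.integers(20, 80), st.integers(0, 2 ** 31 - 1))
def test_zupt_property_matches_oracle(count, n, seed):
    """Randomized ZUPT inputs agree with the naive window-sweep oracle."""
    r = np.random.default_rng(seed)
    a = r.normal(scale=0.35, size=(n, 3))
    v = r.normal(size=(n, 3))
    mine, _ = zero_velocity_update(a, v, limit=0.3, count=count)
    ref, _ = zupt_bruteforce(a, v, limit=0.3, count=count)
    np.testing.assert_array_equal(mine, ref)
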