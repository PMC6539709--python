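"""Signal chain: baseline removal, windows, low-pass, deconvolution, limits."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

import oadepth as oa
from oadepth.sigproc import (
    ButterworthSpec,
    NoPulseError,
    SignalMask,
    TimeSeries,
    butterworth_gain,
)


def make_trace(samples, dt=4e-9, t0=0.0):
    return TimeSeries(samples=np.asarray(samples, float), dt=dt, t0=t0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


class TestBaselineRemoval:
    @pytest.mark.parametrize("order", [3, 10])
    def test_annihilates_polynomials(self, order, rng):
        t = np.linspace(0, 4e-6, 1000)
        coeffs = rng.normal(size=order + 1)
        samples = np.polynomial.polynomial.polyval((t - 2e-6) / 2e-6, coeffs)
        trace = make_trace(samples, dt=t[1] - t[0])
        out = oa.remove_pyroelectric_baseline(trace, order=10)
        assert np.max(np.abs(out.samples)) < 1e-8 * max(np.max(np.abs(samples)), 1.0)

    def test_masked_pulse_survives(self):
        t = np.linspace(0, 4e-6, 2000)
        dt = t[1] - t[0]
        baseline = 3.0 - 2.0 * (t / 4e-6) ** 2 + 0.5 * (t / 4e-6) ** 5
        pulse = np.exp(-0.5 * ((t - 2e-6) / 30e-9) ** 2)
        trace = make_trace(baseline + pulse, dt=dt)
        mask = SignalMask(((1.8e-6, 2.2e-6),))
        out = oa.remove_pyroelectric_baseline(trace, mask)
        recovered = out.samples[(t >= 1.8e-6) & (t < 2.2e-6)]
        injected = pulse[(t >= 1.8e-6) & (t < 2.2e-6)]
        assert np.max(np.abs(recovered - injected)) < 0.01 * injected.max()

    def test_idempotent_projection(self, rng):
        trace = make_trace(rng.normal(size=1500))
        mask = SignalMask(((1e-6, 2e-6),))
        once = oa.remove_pyroelectric_baseline(trace, mask)
        twice = oa.remove_pyroelectric_baseline(once, mask)
        assert np.allclose(once.samples, twice.samples, atol=1e-9 * np.abs(once.samples).max())

    def test_insufficient_samples_rejected(self):
        trace = make_trace(np.arange(12.0))
        mask = SignalMask(((0.0, 4e-9 * 8),))
        with pytest.raises(ValueError):
            oa.remove_pyroelectric_baseline(trace, mask, order=10)

    def test_synthetic_trace_correlates_with_truth(self, matched_synth):
        spec, trace, truth = matched_synth
        mask = oa.propose_signal_mask(
            spec.stack, spec.stack.n_layers - 1, trigger_delay=spec.trigger_delay,
            max_reflections=2, amplitude_floor=1e-3,
        )
        out = oa.remove_pyroelectric_baseline(trace, mask)
        corr = np.corrcoef(out.samples, truth.oa.samples)[0, 1]
        assert corr > 0.99


class TestTimeWindow:
    def test_gain_at_center_and_edges(self):
        n = 1001
        trace = make_trace(np.ones(n), dt=1e-9)
        center, hw = 500e-9, 100e-9
        out = oa.butterworth_time_window(trace, center, hw, order=4)
        assert out.samples[trace.index_at(center)] == pytest.approx(1.0, rel=1e-9)
        assert out.samples[trace.index_at(center - hw)] == pytest.approx(2 ** -0.5, rel=1e-9)
        assert out.samples[trace.index_at(center + hw)] == pytest.approx(2 ** -0.5, rel=1e-9)

    def test_integral_matches_quadrature(self):
        dt = 1e-9
        n = 100001
        trace = make_trace(np.ones(n), dt=dt)
        center, hw, order = 50e-6, 1e-6, 4
        out = oa.butterworth_time_window(trace, center, hw, order)
        discrete = np.sum(out.samples) * dt
        analytic, _ = quad(
            lambda t: 1.0 / np.sqrt(1.0 + ((t - center) / hw) ** (2 * order)),
            0.0, (n - 1) * dt, limit=400,
        )
        assert discrete == pytest.approx(analytic, rel=1e-6)

    def test_bad_half_width(self):
        trace = make_trace(np.ones(100))
        with pytest.raises(ValueError):
            oa.butterworth_time_window(trace, 0.0, -1e-9)

    def test_disjoint_window_rejected(self):
        trace = make_trace(np.ones(100), dt=1e-9)
        with pytest.raises(ValueError):
            oa.butterworth_time_window(trace, 1.0, 1e-9)


class TestLowpass:
    def test_dc_unchanged(self):
        trace = make_trace(np.full(4096, 3.7))
        out = oa.butterworth_lowpass(trace, cutoff=20e6, order=4)
        assert np.allclose(out.samples, 3.7, atol=1e-12)

    def test_sinusoid_at_cutoff(self):
        dt = 4e-9
        n = 5000
        f = 20e6
        t = dt * np.arange(n)
        trace = make_trace(np.sin(2 * np.pi * f * t), dt=dt)
        out = oa.butterworth_lowpass(trace, cutoff=f, order=4)
        core = slice(n // 4, 3 * n // 4)  # avoid edge effects
        ratio = np.abs(out.samples[core]).max() / np.abs(trace.samples[core]).max()
        assert ratio == pytest.approx(2 ** -0.5, rel=0.01)

    def test_stopband_power(self, rng):
        dt = 4e-9
        trace = make_trace(rng.normal(size=8192), dt=dt)
        cutoff = 15e6
        out = oa.butterworth_lowpass(trace, cutoff=cutoff, order=4)
        spec = np.abs(np.fft.rfft(out.samples)) ** 2
        freqs = np.fft.rfftfreq(trace.n, dt)
        assert spec[freqs > 2 * cutoff].sum() / spec.sum() < 0.01

    @given(
        order=st.integers(min_value=1, max_value=8),
        cutoff_frac=st.floats(min_value=0.05, max_value=0.45),
    )
    def test_gain_monotone_nonincreasing(self, order, cutoff_frac):
        freqs = np.linspace(0.0, 0.5, 201)
        gain = butterworth_gain(freqs, cutoff_frac, order)
        assert gain[0] == 1.0
        assert np.all(np.diff(gain) <= 1e-15)

    def test_cutoff_above_nyquist_rejected(self):
        trace = make_trace(np.ones(100), dt=4e-9)
        with pytest.raises(ValueError):
            oa.butterworth_lowpass(trace, cutoff=200e6)


class TestExtractIrf:
    def test_recovers_known_kernel(self, matched_synth):
        """On an echo-free probe the extracted IRF matches the true kernel."""
        spec, trace, truth = matched_synth
        mask = oa.propose_signal_mask(
            spec.stack, spec.stack.n_layers - 1, trigger_delay=spec.trigger_delay,
            max_reflections=2, amplitude_floor=1e-3,
        )
        arrival = truth.pressure.times[int(np.argmax(np.abs(truth.pressure.samples)))]
        window = ButterworthSpec("time_window", (arrival - 0.15e-6, arrival + 0.15e-6), 4)
        irf = oa.extract_irf(trace, window, mask=mask)
        k = irf.kernel.samples
        peak_idx = int(np.argmax(np.abs(k)))
        half = truth.kernel.n // 2
        segment = k[peak_idx - half: peak_idx + half + 1]
        segment = segment / np.max(np.abs(segment))
        nrmse = np.sqrt(np.mean((segment - truth.kernel.samples) ** 2))
        assert nrmse < 0.05
        assert irf.reference_arrival == pytest.approx(arrival, abs=2 * trace.dt)

    def test_endpoints_below_one_percent(self, matched_synth):
        spec, trace, truth = matched_synth
        arrival = truth.pressure.times[int(np.argmax(np.abs(truth.pressure.samples)))]
        window = ButterworthSpec("time_window", (arrival - 0.15e-6, arrival + 0.15e-6), 4)
        irf = oa.extract_irf(trace, window)
        peak = np.max(np.abs(irf.kernel.samples))
        assert abs(irf.kernel.samples[0]) < 0.01 * peak
        assert abs(irf.kernel.samples[-1]) < 0.01 * peak

    def test_no_pulse_raises(self, rng):
        trace = make_trace(rng.normal(0.0, 1e-3, 2000))
        window = ButterworthSpec("time_window", (3e-6, 4e-6), 4)
        with pytest.raises(NoPulseError):
            oa.extract_irf(trace, window)


def centered_kernel(n, dt, cutoff=20e6, order=4):
    """Zero-phase Butterworth kernel stored with its peak at index 0."""
    impulse = np.zeros(n)
    impulse[0] = 1.0
    freqs = np.fft.rfftfreq(n, dt)
    return np.fft.irfft(np.fft.rfft(impulse) * butterworth_gain(freqs, cutoff, order), n)


class TestDeconvolve:
    def test_self_deconvolution_is_impulse(self, matched_synth):
        spec, trace, truth = matched_synth
        arrival = truth.pressure.times[int(np.argmax(np.abs(truth.pressure.samples)))]
        window = ButterworthSpec("time_window", (arrival - 0.15e-6, arrival + 0.15e-6), 4)
        irf = oa.extract_irf(trace, window)
        out = oa.deconvolve(irf.kernel, irf)
        mag = np.abs(out.samples)
        peak_idx = int(np.argmax(mag))
        assert peak_idx in (0, out.n - 1)  # zero lag (circularly)
        # main lobe of the 20 MHz low-passed impulse spans ~1/cutoff
        lobe = int(round(1.0 / (20e6 * out.dt)))
        lags = (np.arange(out.n) + out.n // 2) % out.n - out.n // 2
        away = mag[np.abs(lags) > lobe]
        assert away.max() < 0.05 * mag.max()

    def test_round_trip_reproduces_lowpassed_input(self, rng):
        dt = 4e-9
        n = 2048
        t = dt * np.arange(n)
        pressure = np.zeros(n)
        for t0, amp, w in [(2e-6, 1.0, 20e-9), (3e-6, -0.5, 30e-9), (4.5e-6, 0.3, 15e-9)]:
            pressure += amp * np.exp(-0.5 * ((t - t0) / w) ** 2)
        kernel = centered_kernel(n, dt)
        signal = make_trace(np.fft.irfft(np.fft.rfft(pressure) * np.fft.rfft(kernel), n), dt=dt)
        out = oa.deconvolve(signal, make_trace(kernel, dt=dt))
        expected = oa.butterworth_lowpass(make_trace(pressure, dt=dt)).samples
        nrmse = np.sqrt(np.mean((out.samples - expected) ** 2)) / np.max(np.abs(expected))
        assert nrmse < 0.02

    def test_dt_mismatch_rejected(self):
        a = make_trace(np.ones(64), dt=4e-9)
        b = make_trace(np.ones(64), dt=5e-9)
        with pytest.raises(ValueError):
            oa.deconvolve(a, b)

    def test_zero_irf_rejected(self):
        a = make_trace(np.ones(64))
        b = make_trace(np.zeros(64))
        with pytest.raises(ValueError):
            oa.deconvolve(a, b)


class TestLinearity:
    """Every chain stage commutes with scalar multiplication of the input."""

    @pytest.mark.parametrize("scale", [3.0, -0.5])
    def test_stages_are_linear(self, scale, rng):
        dt = 4e-9
        samples = rng.normal(size=1024)
        trace = make_trace(samples, dt=dt)
        scaled = make_trace(scale * samples, dt=dt)
        mask = SignalMask(((1e-6, 1.5e-6),))
        kernel = make_trace(centered_kernel(1024, dt), dt=dt)

        for op in (
            lambda x: oa.remove_pyroelectric_baseline(x, mask),
            lambda x: oa.butterworth_time_window(x, 2e-6, 0.5e-6),
            lambda x: oa.butterworth_lowpass(x),
            lambda x: oa.deconvolve(x, kernel),
        ):
            direct = op(scaled).samples
            commuted = scale * op(trace).samples
            assert np.allclose(direct, commuted, atol=1e-9 * np.abs(direct).max())


class TestResolutionLimits:
    def test_reference_numbers(self):
        limits = oa.resolution_limits(20e6, 2150.0, 10e-6)
        assert limits["min_duration"] == pytest.approx(50e-9)
        assert limits["min_depth"] == pytest.approx(0.1075e-3)
        assert round(limits["min_depth"] * 1e3, 2) == 0.11
        assert limits["min_mu_a_cutoff"] == pytest.approx(1 / 0.1075e-3)
        assert limits["min_mu_a_detector"] == pytest.approx(100e3)

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            oa.resolution_limits(0.0, 2150.0, 10e-6)
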