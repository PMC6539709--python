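"""Synthetic raw-trace generator with ground truth.

Emulates what the acquisition system records for a given layer stack so
every pipeline stage can be tested against a known answer:

    raw(t) = [ pressure(t - trigger_delay) * kernel ](t)   (OA component,
              normalized to unit peak)
           + pyroelectric drift (smooth valley starting at the laser shot)
           + white Gaussian noise

The detector kernel stands in for the measured delta-response: either an
impulse shaped by the zero-phase Butterworth magnitude (flat to the -3 dB
bandwidth) or a derivative-of-Gaussian.  The pyroelectric valley is a
gamma-like bump ``(u / tau)**3 * exp(-u / tau)`` starting at the laser
shot — deliberately *not* a physical pyroelectric model, just a smooth
low-order shape that a 10th-order polynomial baseline fit can absorb,
which is all the processing chain assumes about it.  (Its first two
derivatives vanish at the onset; shapes with an onset kink, such as a
difference of exponentials, leave percent-level polynomial interpolation
residuals inside the masked signal regions and would contaminate the
extracted response.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.signal import fftconvolve

from .acoustics import LayerStack
from .forward_sim import SimulationGrid, initial_pressure_profile, simulate
from .sigproc import TimeSeries, butterworth_gain

__all__ = ["SynthSpec", "GroundTruth", "make_synthetic_irf", "synth_raw_trace"]

KERNEL_SHAPES = ("lowpassed-delta", "gaussian-derivative")


@dataclass(frozen=True)
class SynthSpec:
    """Conditions of a synthetic acquisition.

    Defaults reproduce the reference measurement conditions: 1.12 us
    laser-to-trigger delay, 50 J/m^2 surface fluence, a detector bandwidth
    at the 20 MHz processing cutoff, a pyroelectric valley that dominates
    the unit-peak acoustic component (depth 2.0), and 250 MS/s sampling —
    far above twice the 20 MHz band while keeping records short.
    """

    stack: LayerStack | None
    seed: int = 0
    sample_rate: float = 250e6
    duration: float = 4.5e-6
    trigger_delay: float = 1.12e-6
    fluence: float = 50.0
    kernel_bandwidth: float = 20e6
    kernel_shape: str = "lowpassed-delta"
    kernel_order: int = 4
    pyro_depth: float = 2.0
    pyro_onset: float | None = None  # defaults to trigger_delay
    pyro_timescale: float = 1.0e-6  # gamma-shape timescale; valley bottom at 3 tau
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.kernel_shape not in KERNEL_SHAPES:
            raise ValueError(f"kernel_shape must be one of {KERNEL_SHAPES}")
        for name in ("sample_rate", "duration", "kernel_bandwidth", "pyro_timescale"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")
        for name in ("trigger_delay", "fluence", "pyro_depth", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.kernel_order < 1:
            raise ValueError("kernel_order must be >= 1")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def n_samples(self) -> int:
        return max(2, int(round(self.duration * self.sample_rate)))

    @property
    def onset(self) -> float:
        return self.trigger_delay if self.pyro_onset is None else self.pyro_onset


@dataclass(frozen=True)
class GroundTruth:
    """Noise-free constituents of a synthetic trace.

    In the noiseless case ``oa + drift`` equals the returned trace exactly,
    and ``oa`` equals the discrete convolution of ``pressure`` with
    ``kernel`` (mode "same", kernel peak at its centre sample).
    """

    pressure: TimeSeries  # delayed, scaled pressure on the trace grid
    kernel: TimeSeries
    oa: TimeSeries
    drift: np.ndarray
    noise: np.ndarray

    @property
    def clean(self) -> np.ndarray:
        return self.oa.samples + self.drift


def _gaussian_derivative_sigma(bandwidth: float) -> float:
    """Sigma of g'(t) whose upper -3 dB point sits at ``bandwidth``.

    |H(f)| ~ f exp(-2 pi^2 sigma^2 f^2) peaks at f* = 1/(2 pi sigma); in
    x = f/f* the relative magnitude is x exp((1 - x^2)/2), so the -3 dB
    crossing x3 solves x exp((1 - x^2)/2) = 1/sqrt(2) for x > 1.
    """
    x3 = brentq(lambda x: x * np.exp((1 - x * x) / 2) - 1 / np.sqrt(2), 1.0, 5.0)
    f_star = bandwidth / x3
    return 1.0 / (2 * np.pi * f_star)


def make_synthetic_irf(spec: SynthSpec) -> TimeSeries:
    """Generate a unit-peak detector kernel of the requested bandwidth.

    The kernel's spectrum magnitude falls to 1/sqrt(2) at
    ``spec.kernel_bandwidth``; its support is finite and centred so that
    convolving with mode "same" introduces no time shift.
    """
    dt = spec.dt
    nyquist = 0.5 / dt
    if spec.kernel_bandwidth >= nyquist:
        raise ValueError(
            f"kernel bandwidth {spec.kernel_bandwidth:.4g} Hz must be below "
            f"Nyquist {nyquist:.4g} Hz"
        )
    half = max(4, int(round(8.0 / (spec.kernel_bandwidth * dt))))
    n = 2 * half + 1
    t = (np.arange(n) - half) * dt
    if spec.kernel_shape == "lowpassed-delta":
        impulse = np.zeros(n)
        impulse[half] = 1.0
        freqs = np.fft.rfftfreq(n, dt)
        gain = butterworth_gain(freqs, spec.kernel_bandwidth, spec.kernel_order)
        kernel = np.fft.irfft(np.fft.rfft(impulse) * gain, n)
    else:  # gaussian-derivative
        sigma = _gaussian_derivative_sigma(spec.kernel_bandwidth)
        kernel = -t / sigma * np.exp(-0.5 * (t / sigma) ** 2)
    peak = float(np.max(np.abs(kernel)))
    kernel = kernel / peak
    return TimeSeries(samples=kernel, dt=dt, t0=-half * dt)


def _pyro_drift(times: np.ndarray, spec: SynthSpec) -> np.ndarray:
    """Smooth valley of depth ``pyro_depth`` starting at the onset.

    Gamma-like shape ``(u / tau)**3 exp(-u / tau)`` with its bottom (unit
    magnitude before scaling) at ``u = 3 tau``; identically zero before the
    onset and twice continuously differentiable across it.
    """
    if spec.pyro_depth == 0.0:
        return np.zeros_like(times)
    tau = spec.pyro_timescale
    u = np.maximum(times - spec.onset, 0.0) / tau
    shape = u**3 * np.exp(-u)
    peak = 27.0 * np.exp(-3.0)  # value at u = 3
    return -spec.pyro_depth * shape / peak


def synth_raw_trace(spec: SynthSpec) -> tuple[TimeSeries, GroundTruth]:
    """Generate a raw acquisition trace and its noise-free ground truth.

    The stack's pressure transient is simulated at the detector plane,
    delayed by the trigger delay onto the acquisition axis, convolved with
    the detector kernel and normalized to unit peak; the pyroelectric
    valley and seeded Gaussian noise are added on top.  With
    ``stack=None`` (or a stack without absorbers) the acoustic component is
    zero — a drift-only trace.  The same seed reproduces the trace
    byte-for-byte; different seeds change only the noise.
    """
    dt = spec.dt
    n = spec.n_samples
    times = dt * np.arange(n)

    pressure = np.zeros(n)
    if spec.stack is not None and any(l.mu_a > 0 for l in spec.stack.layers):
        grid = SimulationGrid.from_stack(spec.stack)
        p0 = initial_pressure_profile(spec.stack, grid, fluence=spec.fluence)
        window = max(dt, spec.duration - spec.trigger_delay)
        sim = simulate(spec.stack, p0, grid, duration=window)
        pressure = np.interp(
            times - spec.trigger_delay, sim.times, sim.samples, left=0.0, right=0.0
        )

    kernel = make_synthetic_irf(spec)
    oa = fftconvolve(pressure, kernel.samples, mode="same")
    peak = float(np.max(np.abs(oa)))
    if peak > 0:
        scale = 1.0 / peak
        oa *= scale
        pressure = pressure * scale

    drift = _pyro_drift(times, spec)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd > 0 else np.zeros(n)

    trace = TimeSeries(
        samples=oa + drift + noise,
        dt=dt,
        t0=0.0,
        trigger_delay=spec.trigger_delay,
    )
    truth = GroundTruth(
        pressure=TimeSeries(pressure, dt=dt, t0=0.0, trigger_delay=spec.trigger_delay),
        kernel=kernel,
        oa=TimeSeries(oa, dt=dt, t0=0.0, trigger_delay=spec.trigger_delay),
        drift=drift,
        noise=noise,
    )
    return trace, truth
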