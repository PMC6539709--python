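"""Signal chain for optoacoustic depth profiles.

The processing pipeline mirrors how a raw piezoelectric A-scan becomes a
pressure depth profile:

1. :func:`remove_pyroelectric_baseline` — subtract the slow pyroelectric
   valley (direct light absorption heating the sensor film) by fitting a
   10th-order polynomial to the trace with the acoustic arrivals masked out.
2. :func:`butterworth_time_window` / :func:`extract_irf` — isolate the
   system's response to a quasi-delta pressure input (a very strongly
   absorbing thick sample) with a smooth Butterworth window and zero-pad it
   back to the record length.
3. :func:`deconvolve` — divide the signal spectrum by the IRF spectrum,
   stabilised by a spectral floor and a zero-phase frequency-domain
   Butterworth low-pass (20 MHz by default).
4. :func:`resolution_limits` — the closed-form depth/absorption resolution
   bounds implied by the low-pass cutoff and the sensor film thickness.

All filters use the Butterworth magnitude ``1 / sqrt(1 + x**(2 n))`` so the
gain is exactly 1 at the centre/DC and ``1/sqrt(2)`` at the edge/cutoff.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from .acoustics import LayerStack, enumerate_echoes

__all__ = [
    "TimeSeries",
    "SignalMask",
    "ButterworthSpec",
    "IRF",
    "NoPulseError",
    "remove_pyroelectric_baseline",
    "butterworth_gain",
    "butterworth_time_window",
    "butterworth_lowpass",
    "extract_irf",
    "deconvolve",
    "align_first_peak",
    "resolution_limits",
    "propose_signal_mask",
]


class NoPulseError(ValueError):
    """Raised when no optoacoustic pulse is detectable where one is required."""


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled trace.

    ``t0`` is the time of the first sample on the acquisition axis (t = 0 at
    the DAQ trigger; the laser fires at ``trigger_delay`` on that axis, so
    acoustic arrivals appear at ``trigger_delay`` + time of flight).
    Amplitudes are volts for raw traces and arbitrary pressure units after
    deconvolution.
    """

    samples: np.ndarray
    dt: float
    t0: float = 0.0
    trigger_delay: float | None = None
    pulse_energy: float | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("samples must be a 1D array with at least 2 points")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if not (math.isfinite(self.dt) and self.dt > 0):
            raise ValueError(f"dt must be finite and > 0, got {self.dt!r}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    @property
    def duration(self) -> float:
        return self.dt * (self.n - 1)

    def with_samples(self, samples: np.ndarray) -> "TimeSeries":
        return dataclasses.replace(self, samples=np.asarray(samples, dtype=float))

    def index_at(self, t: float) -> int:
        """Index of the sample nearest to time ``t`` (clipped to the trace)."""
        return int(np.clip(round((t - self.t0) / self.dt), 0, self.n - 1))


@dataclass(frozen=True)
class SignalMask:
    """Time intervals ``[start, end)`` flagged as containing acoustic signal.

    Masked intervals are excluded from baseline fitting.  Intervals are
    normalized on construction: sorted and overlapping/touching ones merged.
    """

    intervals: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        cleaned: list[tuple[float, float]] = []
        for start, end in self.intervals:
            if not (math.isfinite(start) and math.isfinite(end)):
                raise ValueError("mask interval bounds must be finite")
            if end <= start:
                raise ValueError(f"empty mask interval [{start}, {end})")
            cleaned.append((float(start), float(end)))
        cleaned.sort()
        merged: list[tuple[float, float]] = []
        for start, end in cleaned:
            if merged and start <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], end))
            else:
                merged.append((start, end))
        object.__setattr__(self, "intervals", tuple(merged))

    @property
    def empty(self) -> bool:
        return not self.intervals

    def contains(self, times: np.ndarray) -> np.ndarray:
        """Boolean array: True where a time falls inside a masked interval."""
        times = np.asarray(times, dtype=float)
        out = np.zeros(times.shape, dtype=bool)
        for start, end in self.intervals:
            out |= (times >= start) & (times < end)
        return out


@dataclass(frozen=True)
class ButterworthSpec:
    """Settings of a Butterworth magnitude filter.

    ``domain = "time_window"``: ``cutoff`` is the ``(start, end)`` pair of
    window edge times in seconds (gain 1/sqrt(2) at each edge).
    ``domain = "frequency_lowpass"``: ``cutoff`` is the -3 dB frequency in Hz.
    """

    domain: str
    cutoff: float | tuple[float, float]
    order: int = 4

    def __post_init__(self) -> None:
        if self.domain not in ("time_window", "frequency_lowpass"):
            raise ValueError(f"unknown filter domain {self.domain!r}")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.domain == "time_window":
            try:
                lo, hi = self.cutoff  # type: ignore[misc]
            except TypeError:
                raise ValueError("time_window cutoff must be a (start, end) pair")
            if not (hi > lo):
                raise ValueError("window edges must be ordered")
            object.__setattr__(self, "cutoff", (float(lo), float(hi)))
        else:
            cutoff = float(self.cutoff)  # type: ignore[arg-type]
            if not (cutoff > 0):
                raise ValueError("low-pass cutoff must be positive")
            object.__setattr__(self, "cutoff", cutoff)

    @property
    def window_center(self) -> float:
        lo, hi = self.cutoff  # type: ignore[misc]
        return 0.5 * (lo + hi)

    @property
    def window_half_width(self) -> float:
        lo, hi = self.cutoff  # type: ignore[misc]
        return 0.5 * (hi - lo)


@dataclass(frozen=True)
class IRF:
    """Instrument response function: the processed delta-response trace.

    ``kernel`` keeps the full record length (zero-padded outside the
    Butterworth window) so its FFT shares the frequency grid of any signal
    of the same length.  ``reference_arrival`` is the kernel peak time on
    the acquisition axis.
    """

    kernel: TimeSeries
    window: ButterworthSpec
    mask: SignalMask | None
    baseline_order: int
    reference_arrival: float


DEFAULT_LOWPASS = ButterworthSpec("frequency_lowpass", 20e6, 4)


# ---------------------------------------------------------------------------
# Baseline removal
# ---------------------------------------------------------------------------

def remove_pyroelectric_baseline(
    trace: TimeSeries,
    mask: SignalMask | None = None,
    order: int = 10,
) -> TimeSeries:
    """Subtract a least-squares polynomial baseline fitted off-signal.

    A polynomial of the given order (default 10) is fitted, in time, to the
    samples outside the masked intervals and subtracted from the whole
    trace.  The fit uses a domain rescaled to [-1, 1], which is the same
    projection but numerically well conditioned at order 10.
    """
    if order < 0:
        raise ValueError("polynomial order must be >= 0")
    times = trace.times
    keep = np.ones(trace.n, dtype=bool)
    if mask is not None and not mask.empty:
        keep = ~mask.contains(times)
    n_keep = int(keep.sum())
    if n_keep < order + 1:
        raise ValueError(
            f"baseline fit needs at least {order + 1} unmasked samples, "
            f"have {n_keep}"
        )
    poly = np.polynomial.Polynomial.fit(times[keep], trace.samples[keep], deg=order)
    return trace.with_samples(trace.samples - poly(times))


# ---------------------------------------------------------------------------
# Butterworth filters
# ---------------------------------------------------------------------------

def butterworth_gain(x: np.ndarray, cutoff: float, order: int) -> np.ndarray:
    """Butterworth magnitude ``1 / sqrt(1 + (x / cutoff)**(2 order))``."""
    ratio = np.abs(np.asarray(x, dtype=float)) / cutoff
    return 1.0 / np.sqrt(1.0 + ratio ** (2 * order))


def butterworth_time_window(
    trace: TimeSeries,
    center: float,
    half_width: float,
    order: int = 4,
) -> TimeSeries:
    """Multiply a trace by a Butterworth window centred at ``center``.

    The gain is exactly 1 at the centre and 1/sqrt(2) at
    ``center +- half_width``, decaying monotonically beyond; unlike a boxcar
    this creates no sharp cut-offs that would ring after an FFT.
    """
    if not (half_width > 0):
        raise ValueError("half_width must be positive")
    window = butterworth_gain(trace.times - center, half_width, order)
    lo, hi = trace.times[0], trace.times[-1]
    if center + half_width <= lo or center - half_width >= hi:
        raise ValueError("window does not overlap the trace")
    return trace.with_samples(trace.samples * window)


def butterworth_lowpass(
    trace: TimeSeries,
    cutoff: float = 20e6,
    order: int = 4,
) -> TimeSeries:
    """Zero-phase frequency-domain Butterworth low-pass.

    The two-sided spectrum is multiplied by the real, symmetric magnitude
    ``|H(f)| = 1 / sqrt(1 + (f / cutoff)**(2 order))``: DC gain is exactly 1,
    gain at the cutoff 1/sqrt(2), and peak timing is preserved (no phase).
    """
    nyquist = 0.5 / trace.dt
    if not (0 < cutoff < nyquist):
        raise ValueError(
            f"cutoff must lie in (0, Nyquist = {nyquist:.6g} Hz), got {cutoff!r}"
        )
    spectrum = np.fft.rfft(trace.samples)
    freqs = np.fft.rfftfreq(trace.n, trace.dt)
    filtered = np.fft.irfft(spectrum * butterworth_gain(freqs, cutoff, order), trace.n)
    return trace.with_samples(filtered)


# ---------------------------------------------------------------------------
# IRF extraction
# ---------------------------------------------------------------------------

def extract_irf(
    trace: TimeSeries,
    window: ButterworthSpec,
    mask: SignalMask | None = None,
    baseline_order: int = 10,
    support_gain: float = 1e-4,
) -> IRF:
    """Isolate the instrument response from a quasi-delta measurement.

    Pipeline: pyroelectric baseline removal -> Butterworth time window
    around the primary pulse -> hard zero where the window gain has decayed
    below ``support_gain`` (zero-padding back to the original record
    length).  Raises :class:`NoPulseError` if the in-window peak does not
    exceed 5x the robust noise level estimated outside the window.
    """
    if window.domain != "time_window":
        raise ValueError("extract_irf needs a time_window ButterworthSpec")
    base = remove_pyroelectric_baseline(trace, mask, baseline_order)
    times = base.times
    center = window.window_center
    half_width = window.window_half_width
    in_window = np.abs(times - center) <= half_width
    if not np.any(in_window):
        raise ValueError("window does not overlap the trace")

    peak = float(np.max(np.abs(base.samples[in_window])))
    outside = np.abs(times - center) > 3 * half_width
    if np.any(outside):
        noise = 1.4826 * float(np.median(np.abs(base.samples[outside])))
    else:
        noise = 0.0
    if peak == 0.0 or (noise > 0 and peak < 5 * noise):
        raise NoPulseError(
            f"no detectable pulse in window: peak {peak:.3g} vs noise floor {noise:.3g}"
        )

    gain = butterworth_gain(times - center, half_width, window.order)
    kernel = base.samples * gain
    kernel[gain < support_gain] = 0.0
    out = base.with_samples(kernel)
    peak_idx = int(np.argmax(np.abs(kernel)))
    return IRF(
        kernel=out,
        window=window,
        mask=mask,
        baseline_order=baseline_order,
        reference_arrival=float(times[peak_idx]),
    )


# ---------------------------------------------------------------------------
# Deconvolution
# ---------------------------------------------------------------------------

def deconvolve(
    signal: TimeSeries,
    irf: "IRF | TimeSeries",
    lowpass: ButterworthSpec = DEFAULT_LOWPASS,
    epsilon: float = 1e-3,
) -> TimeSeries:
    """Recover the pressure profile by filtered spectral division.

    ``out = IFFT( |H_lowpass(f)| * FFT(signal) / FFT(irf) )`` with
    denominator magnitudes clamped to ``epsilon * max|FFT(irf)|`` so that
    spectral nulls of the IRF cannot blow up the quotient.  Both traces must
    share the sampling interval and should be baseline-removed.  Because the
    IRF kernel carries its own arrival delay, the quotient is automatically
    re-referenced: the primary pulse of the output lands near t - t0 = 0
    (wrapping circularly), so the first peak can be placed at time zero with
    :func:`align_first_peak`.
    """
    kernel_trace = irf.kernel if isinstance(irf, IRF) else irf
    if lowpass.domain != "frequency_lowpass":
        raise ValueError("deconvolve needs a frequency_lowpass ButterworthSpec")
    if not (epsilon > 0):
        raise ValueError("epsilon must be positive")
    if abs(kernel_trace.dt - signal.dt) > 1e-9 * signal.dt:
        raise ValueError(
            f"sampling mismatch: signal dt {signal.dt!r} vs IRF dt {kernel_trace.dt!r}"
        )
    n = signal.n
    kernel = kernel_trace.samples
    if kernel.size < n:
        kernel = np.concatenate([kernel, np.zeros(n - kernel.size)])
    elif kernel.size > n:
        kernel = kernel[:n]
    if not np.any(kernel):
        raise ValueError("IRF kernel is identically zero")

    num = np.fft.rfft(signal.samples)
    den = np.fft.rfft(kernel)
    freqs = np.fft.rfftfreq(n, signal.dt)
    nyquist = 0.5 / signal.dt
    if not (lowpass.cutoff < nyquist):
        raise ValueError("low-pass cutoff must be below Nyquist")

    mag = np.abs(den)
    floor = epsilon * float(mag.max())
    safe = np.where(
        mag >= floor,
        den,
        np.where(mag > 0, den * (floor / np.maximum(mag, 1e-300)), floor),
    )
    gain = butterworth_gain(freqs, float(lowpass.cutoff), lowpass.order)
    out = np.fft.irfft(gain * num / safe, n)
    return signal.with_samples(out)


def align_first_peak(trace: TimeSeries, threshold: float = 0.5) -> TimeSeries:
    """Shift the time axis so the first major peak sits at t = 0.

    The first local maximum of ``|x|`` exceeding ``threshold`` times the
    global maximum is taken as the primary pulse; samples are rolled so it
    lands at index 0 (the deconvolution quotient is circular, so rolling is
    lossless) and ``t0`` is reset to zero.
    """
    mag = np.abs(trace.samples)
    peak = float(mag.max())
    if peak == 0.0:
        raise ValueError("cannot align an all-zero trace")
    candidates = np.flatnonzero(
        (mag >= threshold * peak)
        & (mag >= np.roll(mag, 1))
        & (mag >= np.roll(mag, -1))
    )
    first = int(candidates[0])
    rolled = np.roll(trace.samples, -first)
    return dataclasses.replace(trace, samples=rolled, t0=0.0)


# ---------------------------------------------------------------------------
# Resolution limits
# ---------------------------------------------------------------------------

def resolution_limits(
    cutoff: float,
    sound_velocity: float,
    detector_thickness: float,
) -> dict[str, float]:
    """Closed-form axial resolution bounds of the processing chain.

    * ``min_duration`` = 1 / cutoff: the shortest signal the low-pass keeps.
    * ``min_depth`` = min_duration x sound velocity: the shallowest source
      depth that can still be resolved.
    * ``min_mu_a_cutoff`` = 1 / min_depth: the smallest absorption
      coefficient that still confines the source within one resolvable depth
      (the requirement for treating a thick absorber as a delta source).
    * ``min_mu_a_detector`` = 1 / detector thickness: the same bound set by
      the sensor film itself (features thinner than the film are unresolvable).
    """
    if not (cutoff > 0 and sound_velocity > 0 and detector_thickness > 0):
        raise ValueError("all resolution inputs must be positive")
    min_duration = 1.0 / cutoff
    min_depth = min_duration * sound_velocity
    return {
        "min_duration": min_duration,
        "min_depth": min_depth,
        "min_mu_a_cutoff": 1.0 / min_depth,
        "min_mu_a_detector": 1.0 / detector_thickness,
    }


# ---------------------------------------------------------------------------
# Mask proposal from predicted arrivals
# ---------------------------------------------------------------------------

def propose_signal_mask(
    stack: LayerStack,
    source_boundary: int,
    trigger_delay: float = 0.0,
    half_width: float = 150e-9,
    max_reflections: int = 2,
    amplitude_floor: float = 1e-2,
    detection_boundary: int | None = None,
) -> SignalMask:
    """Propose baseline-fit exclusion intervals from predicted echo arrivals.

    Enumerates the echo train of the stack and flags ``+- half_width``
    around every predicted arrival (shifted by the trigger delay onto the
    acquisition axis).  The user remains free to edit or replace the mask.
    """
    echoes = enumerate_echoes(
        stack,
        source_boundary,
        max_reflections=max_reflections,
        amplitude_floor=amplitude_floor,
        detection_boundary=detection_boundary,
    )
    intervals = [
        (trigger_delay + p.arrival_time - half_width,
         trigger_delay + p.arrival_time + half_width)
        for p in echoes
    ]
    return SignalMask(tuple(intervals))
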