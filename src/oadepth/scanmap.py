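"""Pyroelectric active-area mapping and pulse-energy calibration.

The piezoelectric film also responds pyroelectrically to direct light
absorption, but only where its two electrodes overlap — so laterally
scanning a small illumination spot over the film and recording the
pyroelectric transient amplitude at each position maps the detector's
active area.  Each pixel averages several repeated shots, is normalized by
the per-shot pulse energy, and the finished map is scaled to its maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .sigproc import TimeSeries

__all__ = [
    "ScanMap",
    "EnergyCalibration",
    "pyro_amplitude",
    "assemble_scan_map",
    "calibrate_energy",
]


@dataclass(frozen=True)
class ScanMap:
    """2D grid of energy-normalized pyroelectric amplitudes in [0, 1]."""

    x1_positions: np.ndarray
    x2_positions: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        x1 = np.asarray(self.x1_positions, dtype=float)
        x2 = np.asarray(self.x2_positions, dtype=float)
        amp = np.asarray(self.amplitude, dtype=float)
        object.__setattr__(self, "x1_positions", x1)
        object.__setattr__(self, "x2_positions", x2)
        object.__setattr__(self, "amplitude", amp)
        if amp.shape != (x1.size, x2.size):
            raise ValueError(
                f"amplitude shape {amp.shape} inconsistent with position grids "
                f"({x1.size}, {x2.size})"
            )
        if np.any(amp < 0) or np.any(amp > 1 + 1e-12):
            raise ValueError("map amplitudes must lie in [0, 1]")


def pyro_amplitude(trace: TimeSeries) -> float:
    """Peak absolute amplitude of a (DC-corrected) pyroelectric transient.

    The transient's "amplitude" is taken as ``max |x(t)|`` — the simplest
    consistent metric for a unipolar valley; peak-to-peak would differ only
    by a map-wide factor and cancel in the normalization.
    """
    return float(np.max(np.abs(trace.samples)))


def assemble_scan_map(
    traces: Sequence[Sequence[Sequence[TimeSeries]]],
    pulse_energies: "float | Sequence[Sequence[Sequence[float]]]",
    x1_positions: Sequence[float],
    x2_positions: Sequence[float],
) -> ScanMap:
    """Build the active-area map from per-position repeated transients.

    ``traces[i][j]`` is the list of repeated shots at position
    ``(x1_positions[i], x2_positions[j])``.  Each pixel is the mean over
    repeats of ``pyro_amplitude / pulse_energy``; the finished map is
    divided by its maximum (so the color scale of a plot runs to 1).
    ``pulse_energies`` is either a single energy for every shot or a nested
    structure matching ``traces``.
    """
    x1 = np.asarray(x1_positions, dtype=float)
    x2 = np.asarray(x2_positions, dtype=float)
    if len(traces) != x1.size:
        raise ValueError("traces grid and x1_positions disagree")
    scalar_energy = np.isscalar(pulse_energies)
    if scalar_energy and float(pulse_energies) <= 0:  # type: ignore[arg-type]
        raise ValueError("pulse energy must be positive")
    amp = np.zeros((x1.size, x2.size))
    for i, row in enumerate(traces):
        if len(row) != x2.size:
            raise ValueError(f"row {i} of traces grid and x2_positions disagree")
        for j, repeats in enumerate(row):
            if len(repeats) == 0:
                raise ValueError(f"pixel ({i}, {j}) has no repeats")
            values = []
            for k, trace in enumerate(repeats):
                if scalar_energy:
                    energy = float(pulse_energies)  # type: ignore[arg-type]
                else:
                    energy = float(pulse_energies[i][j][k])
                if energy <= 0:
                    raise ValueError(f"pixel ({i}, {j}) shot {k}: energy must be > 0")
                values.append(pyro_amplitude(trace) / energy)
            amp[i, j] = float(np.mean(values))
    peak = amp.max()
    if peak > 0:
        amp /= peak
    return ScanMap(x1_positions=x1, x2_positions=x2, amplitude=amp)


@dataclass(frozen=True)
class EnergyCalibration:
    """Through-origin linear map from photodiode volts to pulse energy."""

    gain: float  # J per V
    residual_rms: float  # J
    n: int

    def __call__(self, diode_reading: "float | np.ndarray") -> "float | np.ndarray":
        return self.gain * np.asarray(diode_reading, dtype=float)


def calibrate_energy(
    diode_readings: Sequence[float],
    reference_energies: Sequence[float],
) -> EnergyCalibration:
    """Least-squares proportionality between diode readings and energies.

    Fits ``E = g * V`` through the origin (zero light gives zero diode
    signal) and reports the gain plus the RMS residual.  Needs at least two
    pairs and non-degenerate readings.
    """
    v = np.asarray(diode_readings, dtype=float)
    e = np.asarray(reference_energies, dtype=float)
    if v.shape != e.shape or v.ndim != 1:
        raise ValueError("diode readings and energies must be 1D and paired")
    if v.size < 2:
        raise ValueError("energy calibration needs at least 2 paired readings")
    denom = float(np.dot(v, v))
    if denom == 0.0:
        raise ValueError("degenerate calibration: all diode readings are zero")
    gain = float(np.dot(v, e)) / denom
    residual = e - gain * v
    return EnergyCalibration(
        gain=gain,
        residual_rms=float(np.sqrt(np.mean(residual**2))),
        n=v.size,
    )
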