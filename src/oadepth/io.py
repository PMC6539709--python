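"""Readers and writers for trace and layer-stack files.

Traces are two-column delimited text (time, amplitude) with ``#``-prefixed
header lines carrying the sampling metadata; stacks are small YAML files
listing the layers from the detector-side outermost (backing) toward the
sample.  A packaged fixture (``table1.cfg``) describes the reference probe
glued between two PMMA sheets together with the ink-on-glass test sample.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .acoustics import Layer, LayerStack
from .sigproc import SignalMask, TimeSeries

__all__ = [
    "read_trace",
    "write_trace",
    "read_stack",
    "read_mask",
    "table1_stack",
    "black_plastic_stack",
]

_HEADER_FLOATS = ("dt", "t0", "trigger_delay", "pulse_energy")


def write_trace(trace: TimeSeries, path: "str | Path") -> None:
    """Write a trace as two-column text with a ``#`` metadata header.

    Values are written with shortest-round-trip precision, so
    ``read_trace(write_trace(x))`` reproduces the samples exactly.
    """
    path = Path(path)
    lines = ["# oadepth trace", f"# dt = {float(trace.dt)!r}", f"# t0 = {float(trace.t0)!r}"]
    if trace.trigger_delay is not None:
        lines.append(f"# trigger_delay = {float(trace.trigger_delay)!r}")
    if trace.pulse_energy is not None:
        lines.append(f"# pulse_energy = {float(trace.pulse_energy)!r}")
    lines.append("# columns = time_s amplitude")
    times = trace.times
    for t, a in zip(times, trace.samples):
        lines.append(f"{float(t)!r}\t{float(a)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_trace(path: "str | Path") -> TimeSeries:
    """Read a two-column trace file written by :func:`write_trace`.

    Requires a ``dt`` header; rejects traces whose time column is not
    uniform to 1e-6 relative; malformed numeric rows are reported with
    their line number.
    """
    path = Path(path)
    header: dict[str, float] = {}
    times: list[float] = []
    amplitudes: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    key = key.strip()
                    if key in _HEADER_FLOATS:
                        try:
                            header[key] = float(value.strip())
                        except ValueError as exc:
                            raise ValueError(
                                f"{path}:{lineno}: bad header value for {key!r}"
                            ) from exc
                continue
            fields = line.replace(",", " ").split()
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two columns, got {len(fields)}"
                )
            try:
                times.append(float(fields[0]))
                amplitudes.append(float(fields[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric row") from exc
    if not times:
        raise ValueError(f"{path}: no data rows")
    if "dt" not in header:
        raise ValueError(f"{path}: missing required 'dt' header")
    dt = header["dt"]
    t = np.asarray(times)
    steps = np.diff(t)
    if steps.size and np.max(np.abs(steps - dt)) > 1e-6 * abs(dt):
        raise ValueError(f"{path}: non-uniform time column (declared dt = {dt!r})")
    return TimeSeries(
        samples=np.asarray(amplitudes),
        dt=dt,
        t0=header.get("t0", float(t[0])),
        trigger_delay=header.get("trigger_delay"),
        pulse_energy=header.get("pulse_energy"),
    )


def _stack_from_config(config: Any, source: str) -> LayerStack:
    if not isinstance(config, dict) or "layers" not in config:
        raise ValueError(f"{source}: stack config must be a mapping with a 'layers' list")
    entries = config["layers"]
    if not isinstance(entries, list) or not entries:
        raise ValueError(f"{source}: 'layers' must be a non-empty list")
    layers = []
    for i, entry in enumerate(entries):
        if not isinstance(entry, dict):
            raise ValueError(f"{source}: layer {i} must be a mapping")
        missing = {"material", "sound_velocity_m_s", "thickness_mm"} - entry.keys()
        if missing:
            raise ValueError(f"{source}: layer {i} missing keys {sorted(missing)}")
        layers.append(
            Layer(
                name=str(entry["material"]),
                sound_velocity=float(entry["sound_velocity_m_s"]),
                thickness=float(entry["thickness_mm"]) * 1e-3,
                density=float(entry.get("density_kg_m3", 1000.0)),
                mu_a=float(entry.get("mu_a_per_mm", 0.0)) * 1e3,
            )
        )
    detector_index = config.get("detector_index")
    if detector_index is None:
        label = str(config.get("detector", "PVDF")).lower()
        matches = [i for i, l in enumerate(layers) if l.name.lower() == label]
        if len(matches) != 1:
            raise ValueError(
                f"{source}: cannot identify the detector layer {label!r} "
                f"(found {len(matches)} matches); set detector_index"
            )
        detector_index = matches[0]
    boundaries = config.get("boundaries", ["air", "air"])
    return LayerStack(
        layers=tuple(layers),
        detector_index=int(detector_index),
        outer_boundaries=tuple(boundaries),
    )


def read_stack(path: "str | Path") -> LayerStack:
    """Read a layer stack from a YAML config file.

    Layer keys: ``material``, ``sound_velocity_m_s``, ``thickness_mm`` and
    optionally ``density_kg_m3`` (default 1000) and ``mu_a_per_mm``
    (default 0).  The detector layer is named via ``detector`` (material
    label, default ``PVDF``) or pinned with ``detector_index``.
    """
    path = Path(path)
    config = yaml.safe_load(path.read_text())
    if config is None:
        raise ValueError(f"{path}: empty stack config")
    return _stack_from_config(config, str(path))


def read_mask(path: "str | Path") -> SignalMask:
    """Read a signal mask: a YAML list of ``[start_us, end_us]`` pairs."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, list):
        raise ValueError(f"{path}: mask file must be a list of [start_us, end_us]")
    return SignalMask(tuple((float(lo) * 1e-6, float(hi) * 1e-6) for lo, hi in data))


def table1_stack() -> LayerStack:
    """The packaged reference stack: probe layers plus ink-on-glass sample."""
    text = resources.files("oadepth").joinpath("data/table1.cfg").read_text()
    return _stack_from_config(yaml.safe_load(text), "table1.cfg")


def black_plastic_stack(
    mu_a_per_mm: float = 100.0,
    sound_velocity: float = 2150.0,
    thickness: float = 1.65e-3,
) -> LayerStack:
    """The probe's fronting/backing layers with a thick black-plastic sample.

    This is the delta-source configuration used to measure the instrument
    response: an absorber so strong (~100 mm^-1) that the photoacoustic
    source layer is thinner than both the sensor film and the resolvable
    depth, and thick enough (1.65 mm) that its internal reflections fall
    outside the processing window.
    """
    probe = table1_stack().layers[:5]
    sample = Layer(
        name="Black plastic",
        sound_velocity=sound_velocity,
        thickness=thickness,
        density=1000.0,
        mu_a=mu_a_per_mm * 1e3,
    )
    return LayerStack(layers=probe + (sample,), detector_index=2)
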