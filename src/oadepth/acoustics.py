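"""Layer-stack acoustics for 1D depth profiling.

Data model for stacks of material slabs plus the elementary arithmetic the
rest of the package builds on: acoustic impedances, pressure reflection and
transmission coefficients, times of flight, and enumeration of the echo
train that a pulse launched at one boundary produces at the detector plane.

Conventions
-----------
* Layers are ordered from the detector side outward: index 0 is the
  outermost backing layer, indices increase toward the sample.
* Boundary ``i`` separates layer ``i - 1`` from layer ``i``; boundary 0 and
  boundary ``n_layers`` are the two outer faces of the stack.
* All quantities are SI: metres, seconds, kg/m^3, 1/m.
* Reflection and transmission are in the *pressure* convention,
  ``R = (Z2 - Z1) / (Z2 + Z1)`` and ``T = 1 + R = 2 Z2 / (Z1 + Z2)``,
  because a piezoelectric film responds to pressure, not intensity.
* The two outer faces carry a boundary condition rather than a material:
  ``"air"`` is the pressure-release limit (Z -> 0, R = -1), ``"rigid"`` the
  hard limit (Z -> inf, R = +1), and ``"absorbing"`` terminates rays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
__all__ = [
    "Layer",
    "LayerStack",
    "EchoPath",
    "BOUNDARY_CONDITIONS",
    "acoustic_impedance",
    "reflection_coefficient",
    "transmission_coefficient",
    "time_of_flight",
    "enumerate_echoes",
]

BOUNDARY_CONDITIONS = ("air", "rigid", "absorbing")


@dataclass(frozen=True)
class Layer:
    """A homogeneous material slab.

    Parameters
    ----------
    name : str
        Material label (e.g. ``"PMMA"``).
    sound_velocity : float
        Longitudinal sound velocity in m/s, strictly positive.
    thickness : float
        Slab thickness in m, non-negative (zero-thickness layers are legal
        and contribute no time of flight).
    density : float
        Mass density in kg/m^3, strictly positive.  Defaults to 1000 (all
        layers of the reference probe are modelled at the density of water).
    mu_a : float
        Optical absorption coefficient in 1/m, non-negative.
    """

    name: str
    sound_velocity: float
    thickness: float
    density: float = 1000.0
    mu_a: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.sound_velocity) and self.sound_velocity > 0):
            raise ValueError(
                f"layer {self.name!r}: sound_velocity must be finite and > 0, "
                f"got {self.sound_velocity!r}"
            )
        if not (math.isfinite(self.density) and self.density > 0):
            raise ValueError(
                f"layer {self.name!r}: density must be finite and > 0, "
                f"got {self.density!r}"
            )
        if not (math.isfinite(self.thickness) and self.thickness >= 0):
            raise ValueError(
                f"layer {self.name!r}: thickness must be finite and >= 0, "
                f"got {self.thickness!r}"
            )
        if not (math.isfinite(self.mu_a) and self.mu_a >= 0):
            raise ValueError(
                f"layer {self.name!r}: mu_a must be finite and >= 0, "
                f"got {self.mu_a!r}"
            )

    @property
    def impedance(self) -> float:
        """Acoustic impedance Z = rho * c in kg m^-2 s^-1."""
        return self.density * self.sound_velocity

    @property
    def transit_time(self) -> float:
        """One-way acoustic transit time d / c in seconds."""
        return self.thickness / self.sound_velocity


def acoustic_impedance(layer: Layer) -> float:
    """Acoustic impedance Z = rho * c of a layer, in kg m^-2 s^-1."""
    return layer.impedance


@dataclass(frozen=True)
class LayerStack:
    """Ordered stack of layers with outer boundary conditions.

    ``layers[0]`` is the detector-side outermost layer (the backing);
    indices increase toward the sample.  ``detector_index`` points at the
    piezoelectric sensing layer.  ``outer_boundaries`` gives the condition
    at the backing-side and sample-side outer faces, each one of
    ``"air"``, ``"rigid"`` or ``"absorbing"``.
    """

    layers: tuple[Layer, ...]
    detector_index: int
    outer_boundaries: tuple[str, str] = ("air", "air")

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        object.__setattr__(self, "outer_boundaries", tuple(self.outer_boundaries))
        if len(self.layers) < 1:
            raise ValueError("a LayerStack needs at least one layer")
        if not (0 <= self.detector_index < len(self.layers)):
            raise ValueError(
                f"detector_index {self.detector_index} out of range for "
                f"{len(self.layers)} layers"
            )
        if len(self.outer_boundaries) != 2 or any(
            bc not in BOUNDARY_CONDITIONS for bc in self.outer_boundaries
        ):
            raise ValueError(
                f"outer_boundaries must be a pair drawn from {BOUNDARY_CONDITIONS}, "
                f"got {self.outer_boundaries!r}"
            )

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def n_boundaries(self) -> int:
        return len(self.layers) + 1

    @property
    def total_thickness(self) -> float:
        return sum(layer.thickness for layer in self.layers)

    @property
    def detector_layer(self) -> Layer:
        return self.layers[self.detector_index]

    @property
    def detection_boundary(self) -> int:
        """Sample-side face of the detector layer — where arrivals are timed."""
        return self.detector_index + 1

    def boundary_positions(self) -> list[float]:
        """Depth of each boundary from the backing-side outer face, in m."""
        positions = [0.0]
        for layer in self.layers:
            positions.append(positions[-1] + layer.thickness)
        return positions

    def _check_boundary(self, index: int, what: str = "boundary") -> None:
        if not (0 <= index <= self.n_layers):
            raise IndexError(
                f"{what} index {index} out of range 0..{self.n_layers}"
            )


def reflection_coefficient(z1: float, z2: float) -> float:
    """Pressure reflection coefficient for incidence from medium 1 onto 2.

    ``R = (Z2 - Z1) / (Z2 + Z1)``.  ``z2 = 0`` is the pressure-release (air)
    sentinel giving R = -1; ``z2 = inf`` the rigid sentinel giving R = +1.
    """
    if z1 < 0 or z2 < 0:
        raise ValueError("impedances must be non-negative")
    if z1 == 0 and z2 == 0:
        raise ValueError("reflection coefficient undefined for two zero impedances")
    if math.isinf(z1) and math.isinf(z2):
        raise ValueError("reflection coefficient undefined for two rigid media")
    if math.isinf(z2):
        return 1.0
    if math.isinf(z1):
        return -1.0
    return (z2 - z1) / (z2 + z1)


def transmission_coefficient(z1: float, z2: float) -> float:
    """Pressure transmission coefficient T = 1 + R = 2 Z2 / (Z1 + Z2)."""
    return 1.0 + reflection_coefficient(z1, z2)


def time_of_flight(stack: LayerStack, from_boundary: int, to_boundary: int) -> float:
    """One-way acoustic time of flight between two boundaries, in seconds.

    Sum of thickness / sound_velocity over the traversed layers; symmetric
    in its arguments and zero when they coincide.
    """
    stack._check_boundary(from_boundary, "from_boundary")
    stack._check_boundary(to_boundary, "to_boundary")
    lo, hi = sorted((from_boundary, to_boundary))
    return sum(layer.transit_time for layer in stack.layers[lo:hi])


@dataclass(frozen=True)
class EchoPath:
    """One reflection itinerary from the source to the detection plane.

    ``itinerary`` lists the boundary indices visited in order, starting at
    the source boundary and ending at the detection boundary.
    ``amplitude_factor`` is the product of the pressure reflection and
    transmission coefficients picked up along the way; ``n_reflections``
    counts direction reversals (outer-face bounces included).
    """

    itinerary: tuple[int, ...]
    arrival_time: float
    amplitude_factor: float
    n_reflections: int

    @property
    def reflection_boundaries(self) -> tuple[int, ...]:
        """Boundaries at which the path reversed direction."""
        it = self.itinerary
        out = []
        for k in range(1, len(it) - 1):
            if (it[k] - it[k - 1]) * (it[k + 1] - it[k]) < 0:
                out.append(it[k])
        return tuple(out)


def enumerate_echoes(
    stack: LayerStack,
    source_boundary: int,
    max_reflections: int = 3,
    amplitude_floor: float = 1e-3,
    detection_boundary: int | None = None,
) -> list[EchoPath]:
    """Enumerate every echo path from a boundary source to the detector.

    A unit-amplitude impulse is launched from ``source_boundary`` in both
    directions and traced through the stack: at every interior boundary the
    ray branches into a transmitted and a reflected ray (pressure
    convention), at the outer faces it reflects with R = -1 (air), R = +1
    (rigid) or terminates (absorbing).  Each time a ray crosses the
    detection plane an :class:`EchoPath` is recorded.  Rays are pruned once
    they exceed ``max_reflections`` direction changes or their cumulative
    ``|amplitude_factor|`` drops below ``amplitude_floor``.

    The returned list is sorted by arrival time and is complete for the
    given bounds; the direct (zero-reflection) path is always present when
    it satisfies the bounds.
    """
    if max_reflections < 0:
        raise ValueError("max_reflections must be >= 0")
    if amplitude_floor < 0:
        raise ValueError("amplitude_floor must be >= 0")
    stack._check_boundary(source_boundary, "source_boundary")
    if detection_boundary is None:
        detection_boundary = stack.detection_boundary
    stack._check_boundary(detection_boundary, "detection_boundary")

    n = stack.n_layers
    paths: list[EchoPath] = []

    if source_boundary == detection_boundary:
        paths.append(EchoPath((source_boundary,), 0.0, 1.0, 0))

    # Work stack of rays: (boundary, direction, time, amplitude, n_refl, itinerary)
    rays: list[tuple[int, int, float, float, int, tuple[int, ...]]] = []
    for direction in (+1, -1):
        layer_idx = source_boundary if direction > 0 else source_boundary - 1
        if 0 <= layer_idx < n:
            rays.append(
                (source_boundary, direction, 0.0, 1.0, 0, (source_boundary,))
            )

    while rays:
        b, d, t, amp, refl, itin = rays.pop()
        layer = stack.layers[b if d > 0 else b - 1]
        arrive = b + d
        t2 = t + layer.transit_time
        itin2 = itin + (arrive,)
        if arrive == detection_boundary:
            paths.append(EchoPath(itin2, t2, amp, refl))
        z1 = layer.impedance
        if arrive == 0 or arrive == n:
            bc = stack.outer_boundaries[0 if arrive == 0 else 1]
            if bc == "absorbing":
                continue
            r = -1.0 if bc == "air" else 1.0
            if refl + 1 <= max_reflections and abs(amp * r) >= amplitude_floor:
                rays.append((arrive, -d, t2, amp * r, refl + 1, itin2))
            continue
        z2 = stack.layers[arrive if d > 0 else arrive - 1].impedance
        r = reflection_coefficient(z1, z2)
        tr = 1.0 + r
        if abs(amp * tr) >= amplitude_floor and tr != 0.0:
            rays.append((arrive, d, t2, amp * tr, refl, itin2))
        if r != 0.0 and refl + 1 <= max_reflections and abs(amp * r) >= amplitude_floor:
            rays.append((arrive, -d, t2, amp * r, refl + 1, itin2))

    paths.sort(key=lambda p: (p.arrival_time, p.n_reflections, -abs(p.amplitude_factor)))
    return paths
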