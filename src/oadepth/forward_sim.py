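"""1D finite-difference acoustic forward model for layered media.

Simulates the optoacoustic pressure transient recorded at the detector
plane: a Beer-Lambert initial pressure distribution is deposited in the
absorbing layers and propagated through the piecewise-constant impedance
profile with a first-order staggered-grid pressure/velocity leapfrog
scheme.  The scheme is the standard one for 1D acoustics — pressure at cell
centres, particle velocity at cell edges — which handles impedance jumps
without any interface fitting and conserves the discrete acoustic energy
with reflective outer boundaries.

The model is strictly one-dimensional (a near-field assumption): no
diffraction, no shear, no frequency-dependent attenuation.  The finite
laser pulse duration is not convolved in either — it is orders of magnitude
shorter than every processing time scale and is subsumed by the measured
instrument response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .acoustics import LayerStack
from .sigproc import TimeSeries

__all__ = [
    "SimulationGrid",
    "InitialPressure",
    "initial_pressure_profile",
    "simulate",
]


@dataclass(frozen=True)
class SimulationGrid:
    """Uniform spatial grid with per-cell material maps sampled from a stack.

    Cell ``i`` is centred at ``(i + 1/2) * dx`` measured from the
    backing-side outer face; material properties are looked up at the cell
    centre, so every layer boundary lands within half a cell of its exact
    position.  ``dt`` respects the CFL bound ``dt <= dx / max(c)``.
    """

    dx: float
    dt: float
    n_cells: int
    sound_velocity: np.ndarray
    density: np.ndarray
    mu_a: np.ndarray
    layer_index: np.ndarray
    detector_cell: int
    detector_cells: tuple[int, int]  # half-open cell range of the detector layer

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("grid needs at least 2 cells")
        if not (self.dx > 0 and self.dt > 0):
            raise ValueError("dx and dt must be positive")
        cmax = float(np.max(self.sound_velocity))
        if self.dt > self.dx / cmax * (1 + 1e-12):
            raise ValueError(
                f"CFL violation: dt = {self.dt:.4g} exceeds dx/max(c) = "
                f"{self.dx / cmax:.4g}"
            )

    @property
    def cell_transit_time(self) -> float:
        """Transit time of the fastest wave across one cell."""
        return self.dx / float(np.max(self.sound_velocity))

    @property
    def cell_centers(self) -> np.ndarray:
        return (np.arange(self.n_cells) + 0.5) * self.dx

    @classmethod
    def from_stack(
        cls,
        stack: LayerStack,
        cells_per_thinnest: int = 4,
        cfl: float = 0.9,
        dx: float | None = None,
    ) -> "SimulationGrid":
        """Build a grid resolving the thinnest nonzero layer with >= 4 cells."""
        thicknesses = [layer.thickness for layer in stack.layers if layer.thickness > 0]
        if not thicknesses:
            raise ValueError("stack has no layer of nonzero thickness")
        if dx is None:
            dx = min(thicknesses) / cells_per_thinnest
        if not (0 < cfl <= 1):
            raise ValueError("cfl must be in (0, 1]")
        total = stack.total_thickness
        n_cells = max(2, int(math.ceil(total / dx)))
        centers = (np.arange(n_cells) + 0.5) * dx
        upper = np.cumsum([layer.thickness for layer in stack.layers])
        layer_index = np.minimum(
            np.searchsorted(upper, centers, side="left"), stack.n_layers - 1
        )
        velocity = np.array([stack.layers[i].sound_velocity for i in layer_index])
        density = np.array([stack.layers[i].density for i in layer_index])
        mu_a = np.array([stack.layers[i].mu_a for i in layer_index])
        dt = cfl * dx / float(velocity.max())
        det = np.flatnonzero(layer_index == stack.detector_index)
        if det.size == 0:
            # zero-thickness detector layer: fall back to the nearest cell
            pos = stack.boundary_positions()[stack.detector_index]
            cell = int(np.clip(round(pos / dx - 0.5), 0, n_cells - 1))
            det_range = (cell, cell + 1)
            det_cell = cell
        else:
            det_range = (int(det[0]), int(det[-1]) + 1)
            det_cell = int(det[(det.size - 1) // 2])
        return cls(
            dx=dx,
            dt=dt,
            n_cells=n_cells,
            sound_velocity=velocity,
            density=density,
            mu_a=mu_a,
            layer_index=layer_index,
            detector_cell=det_cell,
            detector_cells=det_range,
        )


@dataclass(frozen=True)
class InitialPressure:
    """Per-cell initial pressure p0 (Pa) with its provenance."""

    p0: np.ndarray
    fluence: float
    grueneisen: np.ndarray

    def __post_init__(self) -> None:
        p0 = np.asarray(self.p0, dtype=float)
        object.__setattr__(self, "p0", p0)
        object.__setattr__(self, "grueneisen", np.asarray(self.grueneisen, dtype=float))
        if not np.all(np.isfinite(p0)):
            raise ValueError("p0 must be finite")
        if np.any(p0 < 0):
            raise ValueError("p0 must be non-negative")


def initial_pressure_profile(
    stack: LayerStack,
    grid: SimulationGrid,
    fluence: float = 50.0,
    grueneisen: float | np.ndarray = 1.0,
) -> InitialPressure:
    """Beer-Lambert optoacoustic source term.

    Illumination enters from the detector side (cell 0) and attenuates
    cumulatively along depth:

        p0(z) = Gamma(z) * mu_a(z) * F * exp(-integral_0^z mu_a dz')

    ``grueneisen`` may be a scalar or one value per layer; it defaults to 1
    everywhere because only relative amplitudes and timings matter in this
    package — the absolute pressure scale is arbitrary.
    """
    if fluence < 0:
        raise ValueError("fluence must be non-negative")
    gamma = np.asarray(grueneisen, dtype=float)
    if gamma.ndim == 0:
        gamma_cells = np.full(grid.n_cells, float(gamma))
    elif gamma.size == stack.n_layers:
        gamma_cells = gamma[grid.layer_index]
    else:
        raise ValueError(
            f"grueneisen must be a scalar or one value per layer "
            f"({stack.n_layers}), got {gamma.size}"
        )
    mu = grid.mu_a
    # optical depth from the illuminated face to each cell centre
    tau = np.cumsum(mu) * grid.dx - 0.5 * mu * grid.dx
    p0 = gamma_cells * mu * fluence * np.exp(-tau)
    return InitialPressure(p0=p0, fluence=fluence, grueneisen=gamma_cells)


def simulate(
    stack: LayerStack,
    p0: InitialPressure,
    grid: SimulationGrid,
    duration: float,
    record: str = "center",
    record_cell: int | None = None,
    track_energy: bool = False,
) -> "TimeSeries | tuple[TimeSeries, np.ndarray]":
    """Propagate an initial pressure field and record it at the detector.

    Staggered leapfrog update (p at cell centres, v at cell edges)::

        v_{i+1/2} <- v_{i+1/2} - dt / (rho_{i+1/2} dx) * (p_{i+1} - p_i)
        p_i       <- p_i - dt * rho_i c_i^2 / dx * (v_{i+1/2} - v_{i-1/2})

    with initial conditions p = p0, v = 0 (the source splits into two
    counter-propagating halves by itself).  Outer faces follow the stack's
    boundary conditions: ``air`` (pressure-release ghost), ``rigid``
    (v = 0) or ``absorbing`` (first-order characteristic).

    ``record`` selects the detector sample: ``"center"`` takes the pressure
    at the centre cell of the detector layer, ``"average"`` the mean over
    its thickness.  ``record_cell`` overrides both.  With
    ``track_energy=True`` a ``(trace, energy)`` pair is returned where
    ``energy[k]`` is the discrete acoustic energy at step k.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if record not in ("center", "average"):
        raise ValueError("record must be 'center' or 'average'")
    p = np.array(p0.p0, dtype=float)
    if p.size != grid.n_cells:
        raise ValueError("initial pressure size does not match the grid")
    if not np.any(p):
        raise ValueError("initial pressure is identically zero (empty source)")

    c = grid.sound_velocity
    rho = grid.density
    bulk = rho * c * c
    rho_edge = np.concatenate([rho[:1], 0.5 * (rho[:-1] + rho[1:]), rho[-1:]])
    coef_v = grid.dt / (rho_edge * grid.dx)
    coef_p = grid.dt * bulk / grid.dx
    left_bc, right_bc = stack.outer_boundaries

    steps = max(1, int(round(duration / grid.dt)))
    v = np.zeros(grid.n_cells + 1)
    lo, hi = grid.detector_cells
    if record_cell is not None:
        sample = lambda field: field[record_cell]  # noqa: E731
    elif record == "average":
        sample = lambda field: float(np.mean(field[lo:hi]))  # noqa: E731
    else:
        sample = lambda field: field[grid.detector_cell]  # noqa: E731

    samples = np.empty(steps + 1)
    samples[0] = sample(p)
    energy = np.empty(steps) if track_energy else None
    # edge velocities sit on the outer faces and are shared with the mirror
    # image implied by the reflective boundary conditions: half weight
    edge_weight = np.ones(grid.n_cells + 1)
    edge_weight[0] = edge_weight[-1] = 0.5
    half_dx = grid.dx

    for k in range(steps):
        v_prev = v.copy() if track_energy else None
        v[1:-1] -= coef_v[1:-1] * (p[1:] - p[:-1])
        if left_bc == "air":
            v[0] -= coef_v[0] * 2.0 * p[0]
        elif left_bc == "rigid":
            v[0] = 0.0
        else:  # absorbing: outgoing left-travelling characteristic p = -rho c v
            v[0] = -p[0] / (rho[0] * c[0])
        if right_bc == "air":
            v[-1] += coef_v[-1] * 2.0 * p[-1]
        elif right_bc == "rigid":
            v[-1] = 0.0
        else:
            v[-1] = p[-1] / (rho[-1] * c[-1])
        if track_energy:
            # conserved discrete energy of the leapfrog: compressional part at
            # integer steps, kinetic part as the staggered product v_- * v_+
            compress = 0.5 * np.sum(p * p / bulk) * half_dx
            kinetic = 0.5 * np.sum(edge_weight * rho_edge * v_prev * v) * half_dx
            energy[k] = compress + kinetic
        p -= coef_p * (v[1:] - v[:-1])
        samples[k + 1] = sample(p)

    trace = TimeSeries(samples=samples, dt=grid.dt, t0=0.0)
    if track_energy:
        return trace, energy
    return trace
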