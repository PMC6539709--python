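# Methods

This note documents the models behind `oadepth`, the choices made where the
design was genuinely open, and what the synthetic tests do and do not show
about real measurements.

## Physical model and conventions

The medium is a 1D stack of homogeneous slabs, ordered from the
detector-side outermost layer (the backing) toward the sample; boundary *i*
separates layer *i−1* from layer *i*. All internal quantities are SI. The
two outer faces carry a boundary condition instead of a material: `air`
(pressure release, R = −1), `rigid` (R = +1) or `absorbing`.

Reflection and transmission use the **pressure** convention,
R = (Z₂−Z₁)/(Z₂+Z₁) and T = 1 + R, because the piezoelectric film responds
to pressure. A consequence worth stating: the product of T-coefficients
along a one-way path up an impedance ladder can exceed 1 (pressure
amplitude gain is not energy gain); only round-trip products are bounded by
1. `EchoPath.amplitude_factor` is therefore not clamped.

Arrivals are timed at the sample-side face of the PVDF layer (the first
surface the wave reaches); the finite-difference detector sample defaults to
the centre cell of the PVDF layer, which adds half a film transit
(~2 ns) — far below the 50 ns resolution limit of the processing chain.

## Echo enumeration

`enumerate_echoes` launches a unit ray from the source boundary in both
directions and branches at every boundary into a transmitted and a
reflected ray, recording an `EchoPath` each time a ray crosses the
detection plane. Rays are pruned at `max_reflections` direction changes
(default 3) and below an `amplitude_floor` (default 10⁻³, keeping the echo
list finite; both configurable). The enumeration is verified in the tests
against an independently written exhaustive recursion on ≤3-layer stacks
and against peak positions of the finite-difference output.

## Finite-difference forward model

First-order staggered-grid leapfrog: pressure at cell centres, particle
velocity at cell edges,

    v_{i+1/2} ← v_{i+1/2} − Δt/(ρ_{i+1/2} Δx) (p_{i+1} − p_i)
    p_i       ← p_i − Δt ρ_i c_i² / Δx (v_{i+1/2} − v_{i−1/2})

with edge densities arithmetic-averaged across interfaces. This is the
standard scheme for piecewise-constant impedance profiles: no interface
fitting, stable under the CFL bound, and it conserves the discrete energy

    E = Σ p² Δx / (2ρc²) + Σ w ρ v⁻v⁺ Δx / 2

exactly (v⁻v⁺ is the product of the velocities straddling the pressure
update; the outer-edge weights w = ½ account for the mirror image implied
by a reflective face). The energy-conservation test bounds drift at 0.1%;
in practice it is at round-off.

Grid defaults: Δx resolves the thinnest nonzero layer with ≥4 cells
(2.5 µm for the 10 µm film), Δt = 0.9 Δx/max(c). Layer boundaries land
within half a cell of their exact positions. Pressure-release outer faces
are imposed through an antisymmetric ghost cell; `absorbing` faces use the
first-order outgoing characteristic v = ±p/(ρc), which is reflective at the
~1% level for oblique spectral content — adequate here because absorbing
faces are only used in tests to discard uninteresting wave halves.

Known numerical limitation: an interface with matched impedance but
different sound velocities transmits perfectly in the continuum limit but
scatters ~0.7% numerically at the default resolution. The matched-media
test therefore uses two layers of one material, where the scheme is exact.

The initial pressure is Beer–Lambert, p₀(z) = Γ(z) µa(z) F exp(−∫µa dz′),
illuminated from the detector side (the probe is transparent). The
Grüneisen parameter Γ defaults to 1 in every layer: all comparisons in this
package are shape- and timing-based, so the absolute pressure scale is
arbitrary. The nanosecond laser pulse duration is not modelled — it is two
orders of magnitude below the resolution limit and is subsumed by the
measured IRF.

Not modelled at all, by design: acoustic attenuation and dispersion, shear
waves, oblique incidence, and diffraction (a multi-dimensional effect; the
probe operates in the near field where the 1D approximation holds — for
late arrivals in real data this is the first assumption to break).

## Signal chain

* **Pyroelectric baseline**: least-squares polynomial of order 10 fitted to
  the trace with the signal regions masked, then subtracted everywhere.
  The fit uses a domain rescaled to [−1, 1] — the identical projection,
  conditioned at order 10. Masks are user-supplied interval lists; a helper
  proposes them from the enumerated echo arrivals (default ±150 ns, the
  support of a 20 MHz kernel).
* **Time window**: multiplication by the Butterworth magnitude
  W(t) = 1/√(1+((t−t₀)/τ)²ⁿ) — a *window*, not a causal filter: the shape
  is a symmetric envelope and multiplication cannot ring. Gain is exactly 1
  at the centre and 1/√2 at the edges.
* **IRF extraction**: baseline removal → window around the primary pulse →
  hard zero where the window gain has fallen below 10⁻⁴ (zero-padding back
  to the record length, so signal and IRF spectra share one frequency
  grid). A pulse is required to exceed 5× the robust (MAD-based) noise
  level estimated outside the window.
* **Low-pass**: the two-sided spectrum is multiplied by the real, symmetric
  Butterworth magnitude — zero phase, so peak timing is preserved; DC gain
  is exactly 1, cutoff gain 1/√2, default cutoff 20 MHz.
* **Deconvolution**: filtered spectral division. Denominator magnitudes
  below ε·max|FFT(IRF)| are clamped to that floor (ε = 10⁻³ default),
  preventing blow-up at spectral nulls; with the low-pass in place the
  result is insensitive to ε over several decades. Because the IRF kernel
  carries its own arrival delay, the quotient is self-referencing: the
  primary pulse lands at (circular) lag zero and `align_first_peak` places
  the first major peak at t = 0.
* **Butterworth order** is nowhere pinned by the underlying measurement
  procedure; both window and low-pass default to order 4 — steep enough to
  suppress out-of-band noise, gentle enough not to ring — and are
  configurable.

The closed-form resolution limits follow from the cutoff: a 20 MHz band
supports nothing shorter than 50 ns; at c = 2150 m/s that is 0.1075 mm of
travel, so sources shallower than ~0.1 mm (equivalently, absorbers weaker
than ~9.3 mm⁻¹) cannot be resolved, and the 10 µm film itself sets a
~100 mm⁻¹ bound for the delta-source approximation.

## Scan maps and energy calibration

A pixel's amplitude is the peak |V| of its pyroelectric transient — the
simplest metric consistent with a unipolar valley (peak-to-peak would
differ by a map-wide factor and cancel in the normalization). Pixels
average repeated shots, each divided by its pulse energy, and the map is
normalized to its maximum. Pulse-energy calibration is a through-origin
least-squares proportionality (zero light ⇒ zero diode signal), reported
with its RMS residual.

## Synthetic data generator

`synth_raw_trace` emulates a raw acquisition:

    raw(t) = OA(t) + drift(t) + noise(t)

* **OA component**: the finite-difference pressure at the detector, delayed
  by the 1.12 µs laser-to-trigger delay onto the acquisition axis, convolved
  with a synthetic detector kernel, and normalized to unit peak.
* **Kernel**: default a unit impulse shaped by the zero-phase Butterworth
  magnitude (flat to the −3 dB bandwidth, default 20 MHz, compact support —
  <0.2% of peak beyond ±100 ns); a derivative-of-Gaussian alternative (with
  the σ solved so its upper −3 dB point matches the requested bandwidth) is
  available for band-pass-like detectors.
* **Drift**: a gamma-like valley −d·(u/τ)³e^(−u/τ) starting at the laser
  shot, depth d = 2 (twice the OA peak — the valley dominates the raw
  trace), τ = 1 µs (bottom ~3 µs after onset). The shape is deliberately
  not a physical pyroelectric model: the processing chain treats the drift
  as unknown and only assumes a 10th-order polynomial can absorb it, so the
  generator must honour exactly that. Shapes with an onset kink (e.g. a
  difference of exponentials) fail the requirement — the polynomial leaves
  10–30% interpolation residuals inside the masked gaps — which is why the
  first two derivatives of the valley vanish at the onset.
* **Noise**: seeded white Gaussian, σ = 0.01 of the OA peak. The same seed
  reproduces the trace bit-for-bit; different seeds change only the noise.

Defaults are the reference measurement conditions: 1.12 µs trigger delay,
50 J/m² fluence, and a 4.5 µs record at 250 MS/s — far above twice the
20 MHz band while keeping records short. (The record length is chosen so
the echo train's masked intervals stay clear of the trace ends; a masked
interval touching an end leaves the baseline polynomial unconstrained
there and it extrapolates.)

What the generator does **not** emulate: electromagnetic pickup and
grounding artifacts, the sample-capacitance dependence of the pyroelectric
shape, acoustic attenuation, jitter, and quantization. Passing tests
demonstrate the correctness of the processing chain's algebra and its
noise robustness at these conditions — not that the chain is robust to
every artifact a physical acquisition can produce.

## Test-fixture choices

Ground-truth comparisons of the *extracted* IRF against the *generating*
kernel use an impedance-matched variant of the probe (same velocities,
densities set so ρc is uniform): with the real layer impedances the probe's
internal reverberation — a few-percent echo within ~30 ns of the primary —
is genuinely part of the instrument response, so the extracted IRF differs
from the bare kernel by physics, not by error. End-to-end checks (arrival
recovery within one sample, echo ordering of the ink-on-glass stack) run on
the full-impedance stacks.

Two reference figures anchor the timing tests: the primary pulse of the
delta-sample measurement at trigger delay + fronting transit
(1.12 + 0.19 ≈ 1.31 µs on the acquisition axis; the corresponding measured
transit in the hardware is slightly longer, ~0.21 µs, plausibly adhesive
layers thicker than their nominal estimates), and the backing–air round
trip ~3.6 µs after the primary. The packaged layer table models all
densities at 1 kg/dm³, so impedance contrasts stem from velocity contrasts
alone.
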