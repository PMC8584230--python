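# Methods

## Models

### Clamp-current model

The modulator-activated difference current is decomposed into two
voltage-gated inward currents:

* a fast **persistent** current, `I_MI = ḡ_MI · m · (V − 35 mV)` with
  `m∞ = S((V+19)/18)` and τ_m = 2 ms (`S(x) = 1/(1+e^{−x})`);
* a **transient** current, `I_MI-T = ḡ_MI-T · m³h · (V − 24 mV)` with
  `m∞ = S((V+11.8)/12)`, `τ_m = 2 + 150·sech((V+20)/4)` ms,
  `h∞ = S(−(V+40)/7)` and
  `τ_h = 100 + 600·sech(0.1(V+30)) + 200·S(0.2(V+30))` ms.

The τ_m shape is the load-bearing kinetic feature: activation is slow
(≈150 ms) only inside the slow-wave voltage window around −20 mV and fast
everywhere else. This single property produces the frequency *reversal*: a
small-amplitude periodic waveform (−60…−20 mV) elicits less current at high
cycle frequency (m cannot build up inside the window), while the same
waveform rescaled to −80…+20 mV elicits more current at high frequency (the
kinetics are fast there and the slope-dependence of inactivation wins).

With ḡ entered in the published units, the model currents come out on the
measured difference-current scale and the package labels them nA; the
logistic-I-V fit's `g` is in the same ḡ units (nA/mV).

In the `ghk_ca` variant the transient current is instead a calcium current
in the Goldman–Hodgkin–Katz constant-field form

    i = P_Ca · pref · ζ · ([Ca]in − [Ca]out e^{−ζ}) / (1 − e^{−ζ}),
    ζ = zFV/RT,

gated by the same m³h, multiplied by an instantaneous calcium-dependent
inactivation `h∞([Ca]) = 1/(1+([Ca]/0.015)^4)` (no relaxation time of its
own is given; the slow dynamics come from the pool itself), and coupled to
a microdomain calcium pool

    d[Ca]/dt = ([Ca]∞ − [Ca])/τ_Ca − φ · (P₁/(zF·vol·P)) · i,

with [Ca]∞ = 0.02 mM, τ_Ca = 12 s, vol = 6.49 µm³. Calcium accumulated over
repeated depolarizations reduces both the driving force and h∞([Ca]),
producing the slow multi-second rundown of the total current that the ohmic
variant cannot show, and its absence when the calcium component is blocked.

### Units of the calcium machinery

The published flux expression is dimensionally coherent only if `i` is a
current *density*: with concentrations in mol/m³ (numerically mM),
permeabilities in m/s and F in C/mol, `P₁/(zF·vol·P)` has units mol/(C·m)
and the product with A/m² is exactly mM/s. The package adopts this reading.
Two calibration constants remain genuinely free:

* **φ (`flux_scale`)** — a dimensionless scaling of the pool coefficient.
  At φ = 1 the printed constants make the pool equilibrate within a single
  stimulus cycle, which leaves no slow rundown at all; the rundown requires
  accumulation slow compared with one cycle so that it rides on the pool's
  12 s clearance. The clamp config ships φ = 0.1 (decay time constants of a
  few seconds, steady/initial amplitude ratio ≈ 0.78 at 400 mV/s); the
  neuron config ships φ = 0.045, which places burst-driven calcium
  excursions onto the sensitive range of the calcium-dependent gates
  (half-saturations 0.015–0.03 mM) and yields the reference burst (below).
* **`area_um2`** — the effective cluster membrane area converting the GHK
  density into a total clamp current (562 µm², set once so the GHK
  variant's initial-sweep peak matches the ohmic variant under the
  400 mV/s ramp-and-hold). The pool never sees this constant: it consumes
  the density, so the rundown dynamics are amplitude-independent.

The printed prefactor of the flux (`F·ζ`) and the conventional one
(`z·F·ζ`) are both available per config; the clamp model ships the printed
form, the neuron model the conventional one (with the printed form the
neuron's calcium current is half as large and the model falls one to two
spikes short of its published burst).

### Two-compartment LP neuron

Soma/neurite and axon are 200 µm × 200 µm cylinders (lateral area only,
π·d·L = 0.1257 mm²; no end caps), capacitance 3.183 / 0.795 µF/cm², coupled
by 0.15 µS. Soma carries leak, I_A, I_h, I_Ca (GHK), I_K(Ca), I_MI and
I_MI-T; the axon carries leak, I_Na and I_K. Per-area conductances (µS/mm²)
multiply the compartment area. Synaptic inhibition is a symmetric
triangular conductance (peak 1 µS/mm², reversal −80 mV, duty 0.5) whose
active window opens at the start of each cycle; burst phases are measured
from the conductance peak. Runs last 20 cycles from rest (−55 mV, gates at
steady state, [Ca] at rest) and the last four cycles are analysed.

The modulator-current gating in the neuron uses a space-clamp-shifted
parameterization (the receptors sit electrotonically distal to the soma):
every I_MI-T gating scale is exactly 2.5× narrower than its clamp-model
counterpart (12→4.8, 4→1.6, 7→2.8 mV; τ_h scales 10→4 and 5→2 mV), with
shifted half-voltages. This 2.5× pattern is also the internal consistency
check that fixes how the typeset gating expressions are parsed: published
conductance-model tables print expressions like `S(v+52.54.8)` whose
fraction grouping must be reconstructed, and only the readings in the
shipped configs make all five scale ratios equal. All such readings are
config entries, not code, so any alternative parse is a one-line edit.

Two readings could not be fixed by typography alone and were chosen on
mechanistic grounds (both are noted in the config comments):

* the I_K(Ca) calcium gate is implemented as `1/(1+(0.03/[Ca])^1.25)`,
  *rising* with calcium — the literal falling reading would make calcium
  entry reduce I_K(Ca), inverting the burst-termination mechanism this
  current exists to provide;
* the I_Ca calcium-dependent inactivation is `S(−([Ca]−12.5)/7)`,
  effectively constant (≈0.86) over the model's working calcium range.

### Modulator configurations

Four variants are shipped: the reference model (ḡ_MI = 0.227,
ḡ_MI-T = 2.27 µS/mm², calcium-permeable I_MI-T), the same pair without
calcium permeability, an I_MI-only model (ḡ_MI = 0.995) and an
I_MI-T-only model (ḡ_MI-T = 3.63). In the calcium-permeable variants the
I_MI-T membrane current stays ohmic (E = −16 mV) while its current feeds
the calcium pool; a config flag can make it fully GHK instead. At 1 Hz
drive the reference model fires 7 spikes per burst in every analysed cycle;
the I_MI-T-only variant also fires 7, the I_MI-only variant 8 (the
published conductances were tuned to a slightly different kinetic
reconstruction, and no remaining free parameter equalizes the last variant
without breaking the reference count).

## Analysis pipeline

Difference current = modulator − control on identical grids (mismatched
grids are an error, never silently resampled). Savitzky–Golay smoothing
(order 5, frames 51/101 for V/I; order 3, frame 901 for waveform currents)
via `scipy.signal.savgol_filter`. Ramp protocols average the last 3 of 5
sweeps; ramp-and-hold and waveform protocols the last 5 cycles ("initial
state" = sweep 1, "steady state" = mean of the last five).

The logistic I-V fit `I = g(V−E_rev)/(1+exp(−(V−V½)/k))` is nonlinear least
squares (lmfit/Levenberg–Marquardt), initialized from the data (E_rev from
the zero crossing of the depolarized end, g from the slope of the last 20%
of points, V½ at half-maximal |I|, k = 5 mV) and bounded
(g ∈ [0, 10³], k ∈ [0.5, 50] mV, E_rev ∈ [−20, 80] mV); it is deterministic
and reports a convergence flag and parameter standard errors. I_max/V_Imax
are read off the fitted curve on a 0.1 mV grid (signed, negative = inward;
a boundary minimum is flagged). The slow rundown is fitted as
`(I₀−I∞)e^{−λt}+I∞` on per-sweep summary values normalized to the first
sweep; constant input returns λ = 0 with a degenerate flag. Spike detection
is an upward threshold crossing (default −10 mV on the axon trace, 2 ms
refractory); burst metrics anchor spikes to the synaptic-conductance peak
of each cycle.

## Synthetic recordings

The generator emulates the two-condition recording structure: a background
membrane (leak + a generic delayed-rectifier stand-in — removed exactly by
the subtraction, included only so the subtraction step is exercised), plus
the modulator model in the test condition, plus per-condition Gaussian
noise (default sd 2% of the true peak) and slow sinusoidal baseline drift
(default 1% of peak, period 30 s, independent phase per condition). A
single seed determines everything; regeneration is bit-identical. The
calcium-blocked condition removes the calcium-carried channels and the
pool, leaving the persistent current untouched — reproducing the loss of
both the positive-ramp slope dependence and the slow rundown.

The surrogate slow-wave shape is piecewise linear: trough plateau 40% of
the cycle (the inhibited phase), linear rise 30%, depolarized plateau 10%,
fall 20%. Its maximum depolarization rate is exactly ∝ 1/period (≈67 mV/s
at 2 s to ≈533 mV/s at 0.25 s when spanning 40 mV). It reproduces the
trajectory *class* — a long inhibited trough, gradual rebound, brief
depolarized phase — but not spikes riding on the wave, cycle-to-cycle
variability, or recording artifacts (series resistance, electrode offset),
so passing tests demonstrate pipeline correctness on idealized recordings,
not robustness to every pathology of real ones.

## Numerics

* Gates: exponential Euler, exact for frozen voltage, unconditionally
  stable, keeps gates in [0, 1]; iterating n steps at constant V equals one
  n·dt step to machine precision.
* Clamp integration at the command rate (default 5 kHz); halving dt changes
  the total current by < 0.5% of peak.
* Neuron voltages: backward Euler on the linear conductance, coupling and
  synaptic terms with gates frozen per step (2×2 solve per step); GHK
  currents enter explicitly. Default dt = 0.025 ms. Halving dt never
  changes spike counts; absolute spike times shift by up to a few ms
  (first-order stepping; burst-onset crossings are shallow), so spike-time
  agreement is asserted at the millisecond, not sub-0.1 ms, level.
* GHK flux: the removable singularity at ζ = 0 is evaluated by the series
  `ζ/(1−e^{−ζ}) = 1 + ζ/2 + ζ²/12` for |ζ| < 10⁻⁴; the branch switch is
  continuous to ~10⁻¹⁰ relative, and the reversal equals the Nernst
  potential by construction.
* Calcium floor 10⁻⁶ mM with a warning rather than an error, so long runs
  survive extreme parameters detectably.
* Protocol corners are sample-aligned (ramp durations rounded to the
  nearest sample): commands are bit-reproducible and piecewise-linear
  reconstruction is exact.

## Known limitations

* The transient current's τ_h has its maximum at ≈808 ms (at −28.3 mV), a
  hair above the nominal 800 ms bound: with the sech and logistic terms
  sharing the −30 mV centre, the value at the centre is exactly 800 and the
  logistic slope pushes the true maximum slightly higher. Every grouping
  consistent with the printed three-term shape has this property.
* Steady-state negative-ramp peaks under the periodic ramp-and-hold are
  *not* slope-independent in this model (spread ≈40% ohmic, ≈26% GHK
  across 100–400 mV/s): at 400 mV/s the depolarized hold lasts 0.25 s
  while τ_h(+20 mV) ≥ 100 ms, so inactivation is incomplete, and m-gate
  lag through the slow-τ_m window amplifies the residual on the way down.
  Full separation of the two currents requires long conditioning holds.
* At the published conductances the calcium-permeability comparison at
  1 Hz shows the larger I_K(Ca) but not fewer spikes or an earlier burst
  end: the across-cycle (slow-pool) action of calcium dominates its
  within-burst action at this operating point. Raising the flux scale
  activates the within-burst brake but costs the reference model its
  seventh spike.
* No series resistance, space-clamp attenuation (beyond the shifted
  parameterization), temperature dependence, stochastic channels, or
  network context (single cell, prescribed synaptic drive).
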