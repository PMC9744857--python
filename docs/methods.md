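# Methods

## Model

`sonoline` treats 1-D longitudinal ultrasound propagation through layered,
branching tissue as a network of ideal lossless electrical transmission
lines — the electro-acoustic analogy.  Pressure maps to voltage through a
hydrophone calibration constant, p(t) = V(t)/M, so every acoustic quantity
has an exact electrical counterpart:

| acoustic | electrical | relation |
|---|---|---|
| pressure p (Pa) | voltage V | p = V/M, M = 70 nV/Pa default |
| tissue layer | ideal transmission line | Z = ρc, τ = d/c |
| interface / bifurcation | impedance step / parallel junction | Γ = (Z_load − Z_in)/(Z_load + Z_in) |
| absorbing boundary | matched resistor R = Z | Γ = 0 |

The model is linear, lossless and non-dispersive: there is no per-length
absorption, no frequency dependence, no nonlinearity and no geometry beyond
path length.  All attenuation in the dB sense arises from impedance-mismatch
reflection and from amplitude division at bifurcations (a symmetric N-way
branch transmits 2/(N+1) of the incident amplitude into each branch).
Energy is conserved at every junction: Γ² + (1+Γ)²·Z_in/Z_load = 1.

## Traveling-wave engine

Each segment carries two circular delay-line buffers (forward and backward
voltage waves) of length round(τ/Δt) samples.  Per time step, every node
applies the parallel-junction update

v = 2·Σₖ aₖ/Zₖ / (Σₖ 1/Zₖ + 1/R),   outgoing wave on line k = v − aₖ,

with R the terminal load where present.  This multi-incident form reduces to
the single-wave Γ formulas and makes junction scattering exact for
simultaneous arrivals from both directions.  The source node is an ideal
voltage source: its voltage is clamped to the pulse waveform, so returning
echoes re-reflect off the source with coefficient −1 superposed on the
injection — the behaviour of an ideal pulsed source in a circuit simulator.
A `matched` source mode instead injects the waveform directly as the forward
wave and absorbs returns; it exists for analytic cross-checks (the direct
injection, rather than a half-amplitude Thévenin divider, keeps the two
modes amplitude-compatible).

Numerical choices:

* **Time step** Δt = 10 ns default.  Segment delays are rounded to the
  nearest integer sample, bounding per-segment timing error at 5 ns — two
  orders below the 0.01 µs precision used in reports.  A segment whose delay
  falls below Δt is rejected with instructions to reduce the step.
* **Pulse** rectangular, amplitude from the source pressure via p = V/M,
  period 500 µs (pulsed-transducer repetition), width 1 µs by default.  The
  width is not a published quantity; amplitude-normalised outputs
  (attenuation dB, arrival times) are insensitive to it.  A 1.1 MHz
  tone-burst option mirrors the physical transducer's centre frequency.
  Rise/fall are one sample; no band-limiting, matching ideal-element
  behaviour with sharp A-scan peaks.
* **Durations** 800 µs (cervical) and 100 µs (site-focused) by default —
  slightly longer than the longest first-arrival path in each model.
  First-peak detection is windowed to [0, period) so the second source pulse
  can never masquerade as a first arrival.
* **Determinism** the engine has no random state; identical inputs give
  identical traces.

An independent oracle, `analytic_cascade_response`, validates the engine on
linear chains: it enumerates every reflection path (as a time-ordered
dynamic program that merges waves meeting at the same interface and sample,
keeping the path sum polynomial) and sums shifted copies of the source
waveform.  Engine and oracle agree to ~1e-14 on random short cascades; the
test suite asserts < 1e-9.

## Peak reading and dosimetry

A "peak" is a sample-level local maximum of |v| above a noise floor
(default 10⁻⁶ × source amplitude); flat-topped arrivals report the first
sample of the plateau, so rectangular pulses are timed at their leading
edge.  The reported amplitude is the signed voltage at that sample although
selection is on |v| — a convention choice, documented here because the
alternative (signed-waveform maxima) differs only for inverted echoes.
Echo trains take all maxima separated by at least the pulse width.

Per terminal, the dosimetry chain is: first-peak voltage → pressure
(p = V/M) → intensity p²/(2ρc) in W/cm², using the terminal tissue's own ρc
(the intensity as if the transducer sat directly on that tissue) →
attenuation 20·log₁₀(V/V_incident) relative to the skin-surface amplitude.
Internal arithmetic is strict SI; conversion to mV/MPa/µs/W·cm⁻² and
two-decimal half-away-from-zero rounding happen only at the report layer.
Attenuation is computed from full-precision voltages by default; a
`rounded` convention (voltages rounded to 0.01 mV before the ratio) is
exposed because reports derived from printed tables effectively use it —
the two differ by ≲0.015 dB at the amplitudes involved.

Safety flags: excitation at I ≥ 0.1 W/cm² (inclusive — the threshold is a
minimum that suffices), FDA violation at I > 3 W/cm², thermal-burn risk at
I > 35 W/cm² (strict exceedances of ceilings).

## Tissue data and what the defaults represent

The packaged `tissue_properties.csv` is an editable estimate, not a
measured dataset: densities and sound speeds are standard literature values
for skin, fat, muscle, connective tissue, spleen and nerve, and the nerve
segment lengths are approximated from human anatomy (e.g. the recurrent
laryngeal loop is the longest cervical path).  Consequently the *absolute*
simulated voltages and arrival times are indicative only — with these
estimates the cervical first arrivals land at roughly 240–450 µs and the
site-focused arrival at ~83 µs, the right regimes but not reference values.
Quantities that do not depend on the length estimates — the conversion
chain, junction physics, dB invariance under amplitude scaling, terminal
counts, and the ordering "site-focused delivers far more splenic intensity
than cervical stimulation from the same source pressure" — are the tested
claims.  Users with measured per-segment constants can substitute their own
CSV without touching code.

## Known limitations

* No absorption (dB·cm⁻¹·MHz⁻¹), dispersion, nonlinearity, beam focusing,
  mode conversion or thermal modelling: attenuation here is purely
  reflective/divisive, so real-tissue losses are underestimated.
* 1-D only; bifurcation geometry enters solely through impedance parallels.
* The intensity formula is the plane-wave temporal-peak expression and no
  duty-cycle factor is applied to the pulsed source; reported intensities
  are therefore conservative (upper bounds) for a pulsed regime.
* The pulse width, rise time and source impedance of the original pulsed
  sources are not published; absolute echo patterns are reproducible only
  up to those choices, which is why acceptance rests on amplitude-normalised
  and analytic quantities.
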