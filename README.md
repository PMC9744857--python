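# sonoline

**Electro-acoustic transmission-line simulation of ultrasonic neurostimulation
through branched tissue networks.**

`sonoline` models how a pulsed therapeutic ultrasound beam propagates from the
skin through layered and branching tissue — in particular the vagus-nerve
pathways targeted by anti-inflammatory neurostimulation — using the classic
electro-acoustic analogy: acoustic pressure maps to voltage through the
hydrophone sensitivity *M*,

```
p(t) = V(t) / M            (M = 70 nV/Pa by default)
```

and each tissue layer becomes an ideal lossless transmission line with
characteristic impedance and one-way delay

```
Z = ρ c,        τ = d / c
```

(ρ density, c speed of sound, d layer thickness).  At every interface or
branch point the incident wave scatters with the reflection coefficient
Γ = (Z_load − Z_in)/(Z_load + Z_in), where Z_load is the parallel combination
of the downstream lines; matched resistors terminate every branch so terminal
arrivals are absorbed.  The simulated voltage-vs-time waveforms are 1-D
ultrasound **A-scans**; the first peak at each terminal gives the delivered
voltage and propagation time, from which the per-terminal dosimetry follows:

```
I_SPTA = p² / (2 ρ c)                       (W/cm², terminal tissue's ρc)
Attenuation = 20·log₁₀(V_terminal / V_incident)   (dB)
```

Intensities are classified against three safety bounds: 0.1 W/cm² (minimum
for intramembrane-cavitation action-potential excitation), 3 W/cm² (FDA
ceiling for therapeutic ultrasound) and 35 W/cm² (thermal-burn bound).

Two anatomical models are built in:

* **cervical** — transducer at the neck; the pulse crosses epidermis, dermis
  and subcutaneous tissue, runs down the vagus trunk and bifurcates into the
  left recurrent laryngeal nerve, cardiac, hepatic, gastric and splenic
  pathways (5 measured terminals, lines T1–T18);
* **site_focused** — transducer directly over the spleen; a linear chain of
  skin, intercostal muscle, diaphragm, spleen capsule, spleen and splenic
  nerve (1 terminal, lines T1–T8).

The packaged tissue table (`src/sonoline/data/tissue_properties.csv`) holds
literature acoustic constants with anatomy-approximated segment lengths; it
is an editable CSV (`name,density_kg_m3,speed_m_s,length_m[,reference]`), and
arbitrary topologies can be described in a small YAML dialect (see
`src/sonoline/data/cervical_vagus.yaml` for the format).

## Worked example

```bash
sonoline simulate --pressure-mpa 0.25 --model site_focused --output report.csv
cat report.csv
```

prints

```
Tissue,Terminal,Propagation_time_us,Voltage_mV,Pressure_MPa,Intensity_W_cm2,Attenuation_dB,Safety_flags
Initial value at epidermis surface,T1:A+,0.0,17.5,0.25,1.62,0.0,AP
Splenic Nerve,T8:B+,82.96,16.44,0.23,1.65,-0.54,AP
```

Reading the rows: a 0.25 MPa source pressure corresponds to a 17.5 mV
incident amplitude at the skin (p = V/M with M = 70 nV/Pa).  The first
arrival reaches the splenic nerve 82.96 µs later carrying 16.44 mV
(−0.54 dB), i.e. 0.23 MPa and 1.65 W/cm² evaluated with the nerve's own ρc.
The `AP` flag marks intensities at or above the 0.1 W/cm² excitation floor;
`FDA` and `THERMAL` would mark exceedances of 3 and 35 W/cm².  Absolute
voltages and arrival times depend on the tissue table's estimated lengths;
amplitude-normalised quantities (dB column, flag logic) do not depend on the
source amplitude.

The same study is available from Python:

```python
from sonoline import run_study, write_report
records = run_study(0.25, "site_focused")
write_report(records, "report.csv")
```

`sonoline netlist --model cervical --output cervical.cir` exports any model
as a SPICE netlist (one ideal transmission-line card per segment, a pulsed
source, matched terminal resistors) for cross-validation in a circuit
simulator.

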