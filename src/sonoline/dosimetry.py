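"""End-to-end dosimetry: run a stimulation model, measure every terminal,
assemble report rows, and classify acoustic safety.

For each measured terminal the chain is: A-scan first-peak voltage ->
mechanical pressure (p = V/M) -> plane-wave intensity p^2/(2 rho c) using
the terminal tissue's own constants (i.e. as if the transducer sat
directly on that tissue) -> attenuation 20 log10(V/V_incident) relative
to the incident amplitude at the skin surface.

Safety is judged against three intensity thresholds (W/cm^2): 0.1, the
minimum for intramembrane-cavitation action-potential excitation; 3, the
FDA ceiling for therapeutic ultrasound; and 35, the thermal-burn bound
quoted by the in vivo study the source pressures come from.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from .acoustic import (
    DEFAULT_CALIBRATION,
    HydrophoneCalibration,
    attenuation_db,
    intensity_spta,
    pressure_to_voltage,
    round_report,
    voltage_to_pressure,
)
from .analysis import PeakMeasurement, first_peak
from .network import (
    NetworkModel,
    TissueSegment,
    TissueTable,
    build_network,
    cervical_vagus_model,
    default_tissue_table,
    site_focused_model,
)
from .simulate import AScanTrace, SimConfig, SourcePulse, simulate

__all__ = [
    "SafetyThresholds",
    "SafetyFlags",
    "DosimetryRecord",
    "DEFAULT_THRESHOLDS",
    "DEFAULT_DURATIONS",
    "classify_safety",
    "terminal_dosimetry",
    "run_study",
    "write_report",
    "read_report",
    "reference_dosimetry",
]

REPORT_COLUMNS = [
    "Tissue",
    "Terminal",
    "Propagation_time_us",
    "Voltage_mV",
    "Pressure_MPa",
    "Intensity_W_cm2",
    "Attenuation_dB",
    "Safety_flags",
]

#: default run durations per built-in model (s)
DEFAULT_DURATIONS = {"cervical": 800e-6, "site_focused": 100e-6}


@dataclass(frozen=True)
class SafetyThresholds:
    """Intensity bounds in W/cm^2 (excitation floor < FDA < thermal burn)."""

    action_potential_min: float = 0.1
    fda_max: float = 3.0
    thermal_burn_max: float = 35.0

    def __post_init__(self) -> None:
        if not (0 < self.action_potential_min < self.fda_max < self.thermal_burn_max):
            raise ValueError(
                "thresholds must satisfy 0 < action_potential_min < fda_max < thermal_burn_max"
            )


DEFAULT_THRESHOLDS = SafetyThresholds()


@dataclass(frozen=True)
class SafetyFlags:
    excites_action_potential: bool
    exceeds_fda: bool
    exceeds_thermal: bool

    def __str__(self) -> str:
        parts = []
        if self.excites_action_potential:
            parts.append("AP")
        if self.exceeds_fda:
            parts.append("FDA")
        if self.exceeds_thermal:
            parts.append("THERMAL")
        return "|".join(parts)

    @classmethod
    def from_string(cls, s: str) -> "SafetyFlags":
        parts = set(filter(None, s.split("|")))
        return cls("AP" in parts, "FDA" in parts, "THERMAL" in parts)


@dataclass(frozen=True)
class DosimetryRecord:
    """One report row, held at full precision in report units."""

    tissue_name: str
    terminal_label: str
    propagation_time_us: float
    voltage_mv: float
    pressure_mpa: float
    intensity_w_cm2: float
    attenuation_db: float
    safety: SafetyFlags

    def rounded(self, ndigits: int = 2) -> "DosimetryRecord":
        """Two-decimal report view (half-away-from-zero)."""
        return replace(
            self,
            propagation_time_us=round_report(self.propagation_time_us, ndigits),
            voltage_mv=round_report(self.voltage_mv, ndigits),
            pressure_mpa=round_report(self.pressure_mpa, ndigits),
            intensity_w_cm2=round_report(self.intensity_w_cm2, ndigits),
            attenuation_db=round_report(self.attenuation_db, ndigits),
        )


def classify_safety(
    intensity_w_cm2: float, thresholds: SafetyThresholds = DEFAULT_THRESHOLDS
) -> SafetyFlags:
    """Flag an intensity against the excitation / FDA / thermal bounds.

    Excitation is inclusive (I >= floor); the two harm bounds are strict
    exceedances (I > limit).
    """
    if not (math.isfinite(intensity_w_cm2) and intensity_w_cm2 >= 0):
        raise ValueError(f"intensity must be non-negative, got {intensity_w_cm2!r}")
    return SafetyFlags(
        excites_action_potential=intensity_w_cm2 >= thresholds.action_potential_min,
        exceeds_fda=intensity_w_cm2 > thresholds.fda_max,
        exceeds_thermal=intensity_w_cm2 > thresholds.thermal_burn_max,
    )


def terminal_dosimetry(
    peak: PeakMeasurement,
    incident_voltage: float,
    terminal_tissue: TissueSegment,
    cal: HydrophoneCalibration = DEFAULT_CALIBRATION,
    thresholds: SafetyThresholds = DEFAULT_THRESHOLDS,
    tissue_name: str = "",
    terminal_label: str = "",
    attenuation_convention: Literal["full", "rounded"] = "full",
) -> DosimetryRecord:
    """Chain the voltage -> pressure -> intensity -> attenuation conversions
    for one measured terminal.

    ``attenuation_convention="rounded"`` rounds both voltages to 0.01 mV
    before the dB ratio, mimicking reports computed from printed values;
    the default uses full precision.
    """
    v = abs(peak.amplitude)
    p = voltage_to_pressure(v, cal)
    i = intensity_spta(p, terminal_tissue.medium).i_spta
    if attenuation_convention == "rounded":
        att = attenuation_db(round_report(v * 1e3), round_report(incident_voltage * 1e3))
    elif attenuation_convention == "full":
        att = attenuation_db(v, incident_voltage)
    else:
        raise ValueError(f"unknown attenuation convention {attenuation_convention!r}")
    return DosimetryRecord(
        tissue_name=tissue_name,
        terminal_label=terminal_label,
        propagation_time_us=peak.arrival_time * 1e6,
        voltage_mv=v * 1e3,
        pressure_mpa=p * 1e-6,
        intensity_w_cm2=i,
        attenuation_db=att,
        safety=classify_safety(i, thresholds),
    )


def run_study(
    pressure_mpa: float,
    model_choice: Literal["cervical", "site_focused", "custom"] = "cervical",
    table: TissueTable | None = None,
    config: SimConfig | None = None,
    cal: HydrophoneCalibration = DEFAULT_CALIBRATION,
    thresholds: SafetyThresholds = DEFAULT_THRESHOLDS,
    topology_spec=None,
    source: SourcePulse | None = None,
    attenuation_convention: Literal["full", "rounded"] = "full",
    return_traces: bool = False,
):
    """Simulate one stimulation scenario and assemble its dosimetry table.

    Emits the incident row (skin surface, t = 0, 0 dB) followed by one
    row per measured terminal, in the model's declared terminal order.
    First peaks are searched within ``[0, period)`` so the second source
    pulse cannot masquerade as a first arrival.
    """
    if not pressure_mpa > 0:
        raise ValueError(f"source pressure must be positive, got {pressure_mpa!r}")
    if table is None:
        table = default_tissue_table()
    if model_choice == "cervical":
        model = cervical_vagus_model(table)
    elif model_choice == "site_focused":
        model = site_focused_model(table)
    elif model_choice == "custom":
        if topology_spec is None:
            raise ValueError("model_choice='custom' requires a topology_spec")
        model = build_network(table, topology_spec)
    else:
        raise ValueError(f"unknown model choice {model_choice!r}")

    incident_v = pressure_to_voltage(pressure_mpa * 1e6, cal)
    if source is None:
        source = SourcePulse(amplitude=incident_v)
    if config is None:
        config = SimConfig(duration=DEFAULT_DURATIONS.get(model_choice, 800e-6))

    traces = simulate(model, source, config)
    window = min(config.duration, source.period)
    noise_floor = 1e-6 * source.amplitude

    first_seg = next(iter(model.graph.succ[model.source].values()))["segment"]
    records = [
        DosimetryRecord(
            tissue_name=f"Initial value at {first_seg.tissue} surface",
            terminal_label="T1:A+",
            propagation_time_us=0.0,
            voltage_mv=incident_v * 1e3,
            pressure_mpa=pressure_mpa,
            intensity_w_cm2=intensity_spta(pressure_mpa * 1e6, first_seg.medium).i_spta,
            attenuation_db=0.0,
            safety=classify_safety(
                intensity_spta(pressure_mpa * 1e6, first_seg.medium).i_spta, thresholds
            ),
        )
    ]
    for label in model.terminal_names:
        trace = traces[label]
        n_win = min(int(round(window / config.time_step)), len(trace.voltages))
        windowed = AScanTrace(trace.node, trace.times[:n_win], trace.voltages[:n_win])
        peak = first_peak(windowed, noise_floor)
        if peak is None:
            raise RuntimeError(
                f"no arrival above the noise floor at terminal {label} within "
                f"{window * 1e6:.0f} us; extend the duration or lower the floor"
            )
        node = model.node_labels[label]
        records.append(
            terminal_dosimetry(
                peak,
                incident_v,
                model.upstream_segment(node),
                cal=cal,
                thresholds=thresholds,
                tissue_name=model.terminal_names[label],
                terminal_label=label,
                attenuation_convention=attenuation_convention,
            )
        )
    if return_traces:
        return records, traces
    return records


def write_report(records: Sequence[DosimetryRecord], path) -> None:
    """Write report rows to CSV (two-decimal cells, report column order)."""
    rows = []
    for r in records:
        rr = r.rounded()
        rows.append(
            {
                "Tissue": rr.tissue_name,
                "Terminal": rr.terminal_label,
                "Propagation_time_us": rr.propagation_time_us,
                "Voltage_mV": rr.voltage_mv,
                "Pressure_MPa": rr.pressure_mpa,
                "Intensity_W_cm2": rr.intensity_w_cm2,
                "Attenuation_dB": rr.attenuation_db,
                "Safety_flags": str(rr.safety),
            }
        )
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(path, index=False)


def read_report(path) -> list[DosimetryRecord]:
    """Read back a report written by :func:`write_report`."""
    frame = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in REPORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"report {path} missing columns: {missing}")
    return [
        DosimetryRecord(
            tissue_name=row["Tissue"],
            terminal_label=row["Terminal"],
            propagation_time_us=float(row["Propagation_time_us"]),
            voltage_mv=float(row["Voltage_mV"]),
            pressure_mpa=float(row["Pressure_MPa"]),
            intensity_w_cm2=float(row["Intensity_W_cm2"]),
            attenuation_db=float(row["Attenuation_dB"]),
            safety=SafetyFlags.from_string(str(row["Safety_flags"])),
        )
        for _, row in frame.iterrows()
    ]


def reference_dosimetry() -> pd.DataFrame:
    """Published reference dosimetry of the original PSpice implementation.

    Per-terminal propagation time, voltage, pressure, intensity and
    attenuation for both stimulation scenarios at 0.25 and 0.83 MPa.
    These printed values serve as inputs for consistency checks of the
    conversion chain (they are not produced by this package).
    """
    return pd.read_csv(Path(__file__).parent / "data" / "reference_dosimetry.csv")
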