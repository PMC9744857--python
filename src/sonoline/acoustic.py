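"""Core electro-acoustic relations shared by every other module.

The electro-acoustic analogy maps the acoustic pressure waveform onto a
voltage waveform through the hydrophone calibration constant M (V/Pa):

    p(t) = V(t) / M

A tissue layer is characterised by its acoustic impedance Z = rho * c
(rayl) and one-way propagation delay tau = d / c.  Plane-wave intensity is
I = p^2 / (2 rho c), reported in W/cm^2, and per-terminal attenuation is
20 log10(v_terminal / v_incident) in dB.

All functions here work in strict SI units (Pa, V, m, s, kg/m^3); the
report layer converts to MPa, mV, us and W/cm^2 only when formatting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

__all__ = [
    "HydrophoneCalibration",
    "AcousticMedium",
    "IntensityValue",
    "DEFAULT_CALIBRATION",
    "voltage_to_pressure",
    "pressure_to_voltage",
    "acoustic_impedance",
    "propagation_delay",
    "intensity_spta",
    "attenuation_db",
    "round_report",
]

#: m^2 per cm^2 — the only place the W/m^2 -> W/cm^2 conversion lives.
_M2_PER_CM2 = 1e-4


@dataclass(frozen=True)
class HydrophoneCalibration:
    """Needle-hydrophone calibration linking voltage to pressure.

    Parameters
    ----------
    sensitivity_M : float
        Sensitivity in volts per pascal.  The default, 70 nV/Pa, is the
        nominal sensitivity of the ONDA HNA-0400 needle hydrophone used to
        calibrate the 1.1 MHz therapeutic transducer this model emulates.
    """

    sensitivity_M: float = 70e-9

    def __post_init__(self) -> None:
        if not (math.isfinite(self.sensitivity_M) and self.sensitivity_M > 0):
            raise ValueError(
                f"hydrophone sensitivity must be a positive finite number, "
                f"got {self.sensitivity_M!r}"
            )


#: Module-wide default (70 nV/Pa).
DEFAULT_CALIBRATION = HydrophoneCalibration()


@dataclass(frozen=True)
class AcousticMedium:
    """Bulk acoustic constants of one tissue: density (kg/m^3), speed (m/s)."""

    density_rho: float
    speed_c: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.density_rho) and self.density_rho > 0):
            raise ValueError(f"density must be positive, got {self.density_rho!r}")
        if not (math.isfinite(self.speed_c) and self.speed_c > 0):
            raise ValueError(f"speed of sound must be positive, got {self.speed_c!r}")

    @property
    def impedance(self) -> float:
        """Characteristic acoustic impedance rho*c in rayl (kg m^-2 s^-1)."""
        return self.density_rho * self.speed_c


@dataclass(frozen=True)
class IntensityValue:
    """Spatial-peak temporal-average intensity in W/cm^2."""

    i_spta: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.i_spta) and self.i_spta >= 0):
            raise ValueError(f"intensity must be non-negative, got {self.i_spta!r}")


def voltage_to_pressure(v: float, cal: HydrophoneCalibration = DEFAULT_CALIBRATION) -> float:
    """Convert a hydrophone voltage (V) to acoustic pressure (Pa): p = V/M."""
    if not math.isfinite(v):
        raise ValueError(f"voltage must be finite, got {v!r}")
    return v / cal.sensitivity_M


def pressure_to_voltage(p: float, cal: HydrophoneCalibration = DEFAULT_CALIBRATION) -> float:
    """Convert an acoustic pressure (Pa) to hydrophone voltage (V): V = p*M.

    Exact algebraic inverse of :func:`voltage_to_pressure`.
    """
    if not math.isfinite(p):
        raise ValueError(f"pressure must be finite, got {p!r}")
    return p * cal.sensitivity_M


def acoustic_impedance(m: AcousticMedium) -> float:
    """Characteristic impedance Z = rho*c of a medium, in rayl."""
    return m.impedance


def propagation_delay(d: float, c: float) -> float:
    """One-way travel time t = d/c through a layer of thickness d (m)."""
    if not (math.isfinite(c) and c > 0):
        raise ValueError(f"speed of sound must be positive, got {c!r}")
    if not (math.isfinite(d) and d >= 0):
        raise ValueError(f"path length must be non-negative, got {d!r}")
    return d / c


def intensity_spta(p: float, m: AcousticMedium) -> IntensityValue:
    """Plane-wave intensity I = p^2 / (2 rho c), returned in W/cm^2.

    The quadratic pressure dependence means halving the pressure quarters
    the intensity; the medium's own rho*c is used, i.e. the intensity is
    evaluated as if the transducer sat directly on that tissue.
    """
    if not math.isfinite(p):
        raise ValueError(f"pressure must be finite, got {p!r}")
    w_per_m2 = p * p / (2.0 * m.density_rho * m.speed_c)
    return IntensityValue(w_per_m2 * _M2_PER_CM2)


def attenuation_db(v_terminal: float, v_incident: float) -> float:
    """Terminal attenuation 20*log10(v_terminal / v_incident) in dB.

    Negative for loss, positive for gain (constructive interference at the
    terminal can deliver more than the incident amplitude).  Both
    amplitudes must be strictly positive; the ratio of a terminal to
    itself is 0 dB.
    """
    if not (math.isfinite(v_terminal) and v_terminal > 0):
        raise ValueError(f"terminal amplitude must be positive, got {v_terminal!r}")
    if not (math.isfinite(v_incident) and v_incident > 0):
        raise ValueError(f"incident amplitude must be positive, got {v_incident!r}")
    return 20.0 * math.log10(v_terminal / v_incident)


def round_report(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention used in the report tables.

    Python's built-in round() is banker's rounding; report cells round
    0.125 -> 0.13 (and -0.125 -> -0.13) instead.
    """
    x = float(x)
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(x)).copy_abs().quantize(q, rounding=ROUND_HALF_UP)
    return float(d.copy_sign(Decimal(repr(x))))
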