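"""Peak extraction from simulated A-scan traces.

The per-terminal report quantities are read straight off the A-scan: the
first local maximum of the absolute voltage above a noise floor is the
primary arrival (its time is the propagation time, its amplitude the
delivered voltage); later maxima are the echo train produced by
impedance-mismatch reflections.

A "peak" is a sample-level local maximum of ``|v|``; flat-topped pulses
(rectangular excitation) report the *first* sample of the plateau, so a
clean rectangular arrival is timed at its leading edge.  The amplitude is
the signed voltage at that sample even though selection is on ``|v|``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .simulate import AScanTrace

__all__ = ["PeakMeasurement", "EchoTrain", "first_peak", "echo_train"]


@dataclass(frozen=True)
class PeakMeasurement:
    """One arrival: time (s), signed amplitude (V), and its sample index."""

    arrival_time: float
    amplitude: float
    peak_index: int


@dataclass(frozen=True)
class EchoTrain:
    """Ordered arrivals at one node (strictly increasing times)."""

    peaks: tuple[PeakMeasurement, ...]

    def __post_init__(self) -> None:
        times = [p.arrival_time for p in self.peaks]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("echo arrival times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.peaks)

    def __getitem__(self, i) -> PeakMeasurement:
        return self.peaks[i]


def _plateau_maxima(x: np.ndarray, floor: float, min_gap_samples: int) -> np.ndarray:
    """Left-edge indices of local maxima of x above floor, >= min_gap apart."""
    # pad so maxima touching either trace edge are still detected
    padded = np.concatenate([[-np.inf], x, [-np.inf]])
    _, props = find_peaks(
        padded,
        height=None if floor <= 0 else floor,
        distance=max(1, min_gap_samples),
        plateau_size=1,
    )
    idx = props["left_edges"] - 1
    if floor <= 0:
        return idx[x[idx] > 0]  # all-zero traces carry no arrival
    return idx


def first_peak(trace: AScanTrace, noise_floor: float = 0.0) -> PeakMeasurement | None:
    """First arrival on a trace, or ``None`` when nothing clears the floor."""
    if noise_floor < 0:
        raise ValueError(f"noise_floor must be non-negative, got {noise_floor!r}")
    idx = _plateau_maxima(np.abs(trace.voltages), noise_floor, 1)
    if idx.size == 0:
        return None
    i = int(idx[0])
    return PeakMeasurement(float(trace.times[i]), float(trace.voltages[i]), i)


def echo_train(
    trace: AScanTrace,
    noise_floor: float = 0.0,
    min_separation: float | None = None,
) -> EchoTrain:
    """All arrivals above the floor, separated by at least *min_separation*.

    ``min_separation`` defaults to one sample and must not be below the
    trace's time step.
    """
    if noise_floor < 0:
        raise ValueError(f"noise_floor must be non-negative, got {noise_floor!r}")
    dt = trace.time_step
    if min_separation is None:
        min_separation = dt
    if min_separation < dt:
        raise ValueError(f"min_separation {min_separation!r} is below the time step {dt!r}")
    gap = int(round(min_separation / dt))
    idx = _plateau_maxima(np.abs(trace.voltages), noise_floor, gap)
    return EchoTrain(
        tuple(
            PeakMeasurement(float(trace.times[i]), float(trace.voltages[i]), int(i))
            for i in idx
        )
    )
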