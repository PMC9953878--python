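"""Tissue conductivity from in vivo impedance and TEED stimulation dosimetry.

Two small calculations anchor the stimulation protocol to measurements:

* conductivity of the tissue between a bipolar microelectrode pair,
  K = D / (R * S), from the measured resistance R, pair separation D and
  microelectrode area S;
* total electrical energy delivered (TEED) by a pulse train,
  E_per_second = (I * R)^2 * pw * f / R = I^2 * R * pw * f,
  accumulated over the stimulation duration and checked against a safety
  limit (default 1.12e-2 J, the published energy equivalent of the
  30 uC/cm^2 charge-capacity ceiling; the conversion is taken as a constant
  because it is not derivable from the stated quantities).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .grid import InvalidParameterError

#: Energy equivalent of the 30 uC/cm^2 charge-capacity safety ceiling.
DEFAULT_SAFETY_LIMIT_J = 1.12e-2


@dataclass(frozen=True)
class ImpedanceMeasurement:
    """Two-electrode in vivo impedance measurement geometry."""

    resistance_ohm: float
    separation_m: float
    electrode_area_m2: float

    def __post_init__(self) -> None:
        if self.resistance_ohm <= 0 or self.separation_m <= 0 or self.electrode_area_m2 <= 0:
            raise InvalidParameterError("impedance measurement fields must be positive")


@dataclass(frozen=True)
class StimulationProtocol:
    """Rectangular DBS pulse train: amplitude, width, rate, train length."""

    current_a: float
    pulse_width_s: float = 0.4e-3
    frequency_hz: float = 3.0
    duration_s: float = 20.0

    def __post_init__(self) -> None:
        if min(self.current_a, self.pulse_width_s, self.frequency_hz, self.duration_s) < 0:
            raise InvalidParameterError("protocol fields must be non-negative")
        if self.pulse_width_s * self.frequency_hz > 1.0:
            raise InvalidParameterError("duty cycle pw * f must not exceed 1")


@dataclass(frozen=True)
class TEEDResult:
    energy_per_second_j: float
    total_energy_j: float
    safety_limit_j: float

    @property
    def within_limit(self) -> bool:
        return self.total_energy_j <= self.safety_limit_j


def electrode_area(radius_m: float, paper_pi: bool = False) -> float:
    """Disc microelectrode area pi * r^2 in m^2.

    With ``paper_pi=True`` pi is evaluated at three significant figures
    (3.14), reproducing the published 200.960 um^2 for the 8 um radius;
    the default uses full-precision pi (201.0619 um^2).
    """
    if radius_m < 0:
        raise InvalidParameterError("radius must be non-negative")
    pi = 3.14 if paper_pi else math.pi
    return pi * radius_m**2


def conductivity_from_impedance(meas: ImpedanceMeasurement) -> float:
    """Tissue conductivity K = D / (R * S) in S/m."""
    return meas.separation_m / (meas.resistance_ohm * meas.electrode_area_m2)


def resistance_from_conductivity(conductivity_s_per_m: float, separation_m: float,
                                 electrode_area_m2: float) -> float:
    """Inverse of :func:`conductivity_from_impedance`: R = D / (K * S)."""
    if min(conductivity_s_per_m, separation_m, electrode_area_m2) <= 0:
        raise InvalidParameterError("all arguments must be positive")
    return separation_m / (conductivity_s_per_m * electrode_area_m2)


def teed_per_second(protocol: StimulationProtocol, resistance_ohm: float) -> float:
    """Electrical energy delivered per second: I^2 * R * pw * f, in J."""
    if resistance_ohm <= 0:
        raise InvalidParameterError("resistance must be positive")
    i, r = protocol.current_a, resistance_ohm
    return (i * r) ** 2 * protocol.pulse_width_s * protocol.frequency_hz / r


def total_energy_and_check(protocol: StimulationProtocol, resistance_ohm: float,
                           safety_limit_j: float = DEFAULT_SAFETY_LIMIT_J) -> TEEDResult:
    """Energy over the full train, flagged against the safety limit."""
    e_per_s = teed_per_second(protocol, resistance_ohm)
    return TEEDResult(energy_per_second_j=e_per_s,
                      total_energy_j=e_per_s * protocol.duration_s,
                      safety_limit_j=safety_limit_j)
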