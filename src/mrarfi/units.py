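"""Displacement/phase conversions and transcranial mechanical-index arithmetic.

The motion-encoding gradient converts tissue displacement d (meters) into
image phase θ = 2π·42.58·G·T·d with G in mT/m and T in ms.  The mechanical
index (MI) is the derated peak negative pressure (MPa) divided by the
square root of the center frequency in MHz; its transcranial variant MItc
derates the free-field pressure by the skull transmission fraction.  The
FDA diagnostic-ultrasound limit is MI 1.9.

All conversions are pure functions returning full double precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .datamodel import AcquisitionParams, ValidationError


@dataclass(frozen=True)
class PressureSpec:
    """Free-field pressure derating inputs."""

    free_field_MPa: float
    transmission: float
    frequency_MHz: float

    def __post_init__(self) -> None:
        if not self.free_field_MPa > 0:
            raise ValidationError("free_field_MPa must be > 0")
        if not 0 < self.transmission <= 1:
            raise ValidationError("transmission must be in (0, 1]")
        if not self.frequency_MHz > 0:
            raise ValidationError("frequency_MHz must be > 0")


def displacement_to_phase(d_m: float, params: AcquisitionParams) -> float:
    """Phase (rad) accrued by a displacement of ``d_m`` meters."""
    return params.phase_per_meter * d_m


def phase_to_displacement(theta_rad: float, params: AcquisitionParams) -> float:
    """Displacement (meters) producing a phase of ``theta_rad`` rad."""
    return theta_rad / params.phase_per_meter


def derated_pressure(spec: PressureSpec) -> float:
    """Pressure at the focus (MPa) after skull transmission."""
    return spec.free_field_MPa * spec.transmission


def mechanical_index(spec: PressureSpec) -> float:
    """Transcranial mechanical index: derated pressure / sqrt(f_MHz)."""
    return derated_pressure(spec) / math.sqrt(spec.frequency_MHz)
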