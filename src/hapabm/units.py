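"""Unit conventions and conversions.

All internal computation uses micromolar (uM) for concentrations, micrometre
(um) for lengths, and seconds (s) for time.  Configuration files declare units
explicitly as strings; loaders convert to the internal system on entry, and
round-trip error is bounded by floating-point arithmetic (< 1e-12 relative).
"""

from __future__ import annotations

# Multiplicative factors mapping a declared unit to the internal system
# (uM, um, s and combinations thereof).  Dimensionless entries use 1.0.
_FACTORS: dict[str, float] = {
    # time
    "s": 1.0,
    "min": 60.0,
    "h": 3600.0,
    "d": 86400.0,
    # rates
    "1/s": 1.0,
    "s^-1": 1.0,
    "1/min": 1.0 / 60.0,
    "min^-1": 1.0 / 60.0,
    "1/h": 1.0 / 3600.0,
    "h^-1": 1.0 / 3600.0,
    # concentration
    "uM": 1.0,
    "mM": 1.0e3,
    "M": 1.0e6,
    "nM": 1.0e-3,
    # length
    "um": 1.0,
    "mm": 1.0e3,
    "cm": 1.0e4,
    "m": 1.0e6,
    # area
    "um^2": 1.0,
    "mm^2": 1.0e6,
    "cm^2": 1.0e8,
    # volume (internal um^3)
    "um^3": 1.0,
    "uL": 1.0e9,
    "mL": 1.0e12,
    "L": 1.0e15,
    # diffusivity
    "um^2/s": 1.0,
    "cm^2/s": 1.0e8,
    # potency constants (kill laws)
    "1/mM": 1.0e-3,            # -> uM^-1
    "mM^-1": 1.0e-3,
    "1/uM": 1.0,
    "uM^-1": 1.0,
    "1/(mM*s)": 1.0e-3,        # -> uM^-1 s^-1
    "mM^-1 s^-1": 1.0e-3,
    "uM^-1 s^-1": 1.0,
    # molar amounts / fluxes
    "mol": 1.0,
    "umol": 1.0e-6,
    "mol/cell/s": 1.0,
    "fraction": 1.0,
    "dimensionless": 1.0,
    "cells": 1.0,
    "": 1.0,
}


class UnknownUnitError(ValueError):
    """Raised when a configuration file declares a unit not in the table."""


def to_internal(value: float, units: str) -> float:
    """Convert ``value`` expressed in ``units`` to the internal system."""
    key = units.strip()
    if key not in _FACTORS:
        raise UnknownUnitError(f"unknown units {units!r}")
    return value * _FACTORS[key]


def from_internal(value: float, units: str) -> float:
    """Inverse of :func:`to_internal`."""
    key = units.strip()
    if key not in _FACTORS:
        raise UnknownUnitError(f"unknown units {units!r}")
    return value / _FACTORS[key]


def known_units() -> tuple[str, ...]:
    return tuple(_FACTORS)
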