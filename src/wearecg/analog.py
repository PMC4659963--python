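"""Analog front-end design arithmetic.

A wearable ECG front end uses a band-pass filter (0.5–250 Hz) to reject
out-of-band noise and a twin-T style notch (50/60 Hz) to reject mains
interference.  This module is the tiny, self-checking calculator for those
two designs: resonant frequency, bandwidth and Q of the band-pass, and the
resistor choice for a notch at a given frequency and capacitance,

    F_r = sqrt(F_h * F_l),   Q = F_r / (F_h - F_l),   F_notch = 1 / (2*pi*R*C).

All quantities are SI internally (Hz, ohm, farad).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import DomainError

__all__ = [
    "BandPassSpec",
    "NotchSpec",
    "band_pass_characteristics",
    "notch_resistor",
    "notch_frequency",
]


@dataclass(frozen=True)
class BandPassSpec:
    """Characteristics of a band-pass stage with cutoffs ``f_low``/``f_high``."""

    f_high: float
    f_low: float
    bandwidth: float
    f_resonant: float
    q_factor: float


@dataclass(frozen=True)
class NotchSpec:
    """An RC notch: ``f_notch = 1 / (2*pi*R*C)``."""

    f_notch: float
    resistance: float
    capacitance: float


def band_pass_characteristics(f_high: float, f_low: float) -> BandPassSpec:
    """Bandwidth, resonant frequency and quality factor of a band-pass filter.

    The resonant frequency is the geometric mean of the two cutoffs and the
    quality factor measures how sharp the passband is relative to it.

    Parameters
    ----------
    f_high, f_low
        Upper and lower cutoff frequencies in Hz; ``f_high > f_low > 0``.
    """
    if not (f_high > f_low > 0):
        raise DomainError(
            f"need f_high > f_low > 0, got f_high={f_high}, f_low={f_low}"
        )
    bandwidth = f_high - f_low
    f_resonant = math.sqrt(f_high * f_low)
    return BandPassSpec(
        f_high=f_high,
        f_low=f_low,
        bandwidth=bandwidth,
        f_resonant=f_resonant,
        q_factor=f_resonant / bandwidth,
    )


def notch_resistor(f_notch: float, capacitance: float) -> NotchSpec:
    """Resistor required for an RC notch at ``f_notch`` given the capacitance.

    ``R = 1 / (2*pi*f_notch*C)``; e.g. a 60 Hz notch with C = 0.1 uF needs
    roughly 26.5 kOhm.
    """
    if f_notch <= 0 or capacitance <= 0:
        raise DomainError("f_notch and capacitance must be positive")
    resistance = 1.0 / (2.0 * math.pi * f_notch * capacitance)
    return NotchSpec(f_notch=f_notch, resistance=resistance, capacitance=capacitance)


def notch_frequency(resistance: float, capacitance: float) -> float:
    """Inverse of :func:`notch_resistor`: the notch frequency of an RC pair."""
    if resistance <= 0 or capacitance <= 0:
        raise DomainError("resistance and capacitance must be positive")
    return 1.0 / (2.0 * math.pi * resistance * capacitance)
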