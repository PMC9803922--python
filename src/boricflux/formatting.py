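"""Display-layer rounding.

Internal computation never rounds; these helpers reproduce the rounding
conventions used when reporting results (one decimal for millimolar
species concentrations, nearest integer millivolt for potentials, two
significant figures for fold changes).
"""

from __future__ import annotations

import math


def molar_to_mM(value_M: float, decimals: int = 1) -> float:
    """mol/L -> mM rounded to ``decimals`` places (display only)."""
    return round(value_M * 1e3, decimals)


def volts_to_mV(value_V: float) -> int:
    """V -> nearest integer mV (display only)."""
    return round(value_V * 1e3)


def sig_figs(value: float, figures: int = 2) -> float:
    """Round to a number of significant figures (e.g. 333.3 -> 330)."""
    if value == 0 or not math.isfinite(value):
        return value
    exponent = math.floor(math.log10(abs(value)))
    return round(value, figures - 1 - exponent)
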