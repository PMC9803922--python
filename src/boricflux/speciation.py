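"""Boric acid / borate speciation at equilibrium.

In aqueous solution boric acid B(OH)3 (pKa 9.24) interconverts with the
borate anion B(OH)4-:

    Ka = [B(OH)4-][H+] / [B(OH)3]        Kw = [H+][OH-]

Given a total boric acid concentration (the sum of both forms, which is
what "boric acid" means in most physiological work) and a pH, the split is
uniquely determined. These functions convert total concentrations and pH
into molecular-species concentrations; everything downstream — transport
thermodynamics, the oocyte simulator, current-sign predictions — consumes
the resulting :class:`SpeciationState`.

Concentrations are mol/L throughout; values are never rounded here (the
formatting layer reproduces display rounding).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import DEFAULT_CONSTANTS, PhysicalConstants


@dataclass(frozen=True)
class SpeciationState:
    """Equilibrium composition of one compartment.

    Invariants (enforced at construction):
    conc_B_OH3 + conc_B_OH4 == total_boric_acid;
    conc_B_OH4 / conc_B_OH3 == 10**(pH - pKa);
    conc_H * conc_OH == 10**(-pKw).
    """

    total_boric_acid: float  # mol/L, B(OH)3 + B(OH)4-
    pH: float
    conc_B_OH3: float  # mol/L
    conc_B_OH4: float  # mol/L
    conc_H: float  # mol/L
    conc_OH: float  # mol/L

    def __post_init__(self) -> None:
        for name in ("total_boric_acid", "conc_B_OH3", "conc_B_OH4", "conc_H", "conc_OH"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.total_boric_acid > 0:
            balance = (self.conc_B_OH3 + self.conc_B_OH4) / self.total_boric_acid
            if abs(balance - 1.0) > 1e-12:
                raise ValueError("species do not sum to the total boric acid")


def hydroxide_and_proton(
    pH: float, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> tuple[float, float]:
    """Proton and hydroxide concentrations (mol/L) at a given pH.

    [H+] = 10^-pH and [OH-] = 10^(pH - pKw), so their product is always
    10^-pKw regardless of pH.
    """
    if not math.isfinite(pH):
        raise ValueError(f"pH must be finite, got {pH!r}")
    conc_h = 10.0 ** (-pH)
    conc_oh = 10.0 ** (pH - constants.pKw)
    return conc_h, conc_oh


def speciate(
    total: float, pH: float, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> SpeciationState:
    """Split a total boric acid concentration into B(OH)3 and B(OH)4-.

    Parameters
    ----------
    total : float
        Total boric acid (both forms), mol/L. Must be >= 0.
    pH : float
        Compartment pH, in (0, 14).
    constants : PhysicalConstants
        Source of pKa and pKw.

    Returns
    -------
    SpeciationState
        The unique equilibrium split; concentrations unrounded.

    Notes
    -----
    The borate fraction is 1 / (1 + 10^(pKa - pH)), the Henderson-
    Hasselbalch relation for a monoprotic acid. At pH == pKa each form is
    exactly half the total.
    """
    if not (math.isfinite(total) and total >= 0):
        raise ValueError(f"total boric acid must be finite and >= 0, got {total!r}")
    if not (math.isfinite(pH) and 0 < pH < 14):
        raise ValueError(f"pH must lie in (0, 14), got {pH!r}")
    borate_fraction = 1.0 / (1.0 + 10.0 ** (constants.pKa_boric - pH))
    conc_b_oh4 = total * borate_fraction
    conc_b_oh3 = total - conc_b_oh4
    conc_h, conc_oh = hydroxide_and_proton(pH, constants)
    return SpeciationState(
        total_boric_acid=total,
        pH=pH,
        conc_B_OH3=conc_b_oh3,
        conc_B_OH4=conc_b_oh4,
        conc_H=conc_h,
        conc_OH=conc_oh,
    )


def intracellular_concentration(
    boron_content: float, oocyte_volume: float = 0.7e-6, cytoplasm_fraction: float = 0.10
) -> float:
    """Convert a whole-cell boron content into a cytoplasmic concentration.

    A Xenopus oocyte is mostly yolk; the aqueous cytoplasm in which
    transported boric acid distributes is roughly 10% of the ~0.7 uL cell
    volume, so content / (volume * fraction). 0.1 nmol in a 0.7 uL oocyte
    at 10% cytoplasm gives ~1.4 mM.

    Parameters are mol, L and a dimensionless fraction in (0, 1];
    the result is mol/L.
    """
    if boron_content < 0:
        raise ValueError("boron content must be >= 0")
    if not (oocyte_volume > 0):
        raise ValueError("oocyte volume must be positive")
    if not (0 < cytoplasm_fraction <= 1):
        raise ValueError("cytoplasm fraction must lie in (0, 1]")
    return boron_content / (oocyte_volume * cytoplasm_fraction)
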