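"""Physical constants and dissociation constants used throughout the package.

All quantities are SI (J, C, mol, K). Concentration work elsewhere is in
mol/L; millimolar appears only at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Any, Mapping


@dataclass(frozen=True)
class PhysicalConstants:
    """Thermodynamic constants plus the equilibrium constants of the
    boric acid / borate and water systems.

    ``pKa_boric`` (9.24) governs the B(OH)3 / B(OH)4- split and is treated
    as temperature- and ionic-strength-independent (ideal solution,
    activity coefficients of 1). ``pKw`` defaults to 14.0. The default
    temperature, 291.15 K (18 degrees C), is the standard oocyte recording
    temperature.
    """

    gas_constant: float = 8.31446261815324  # R, J mol^-1 K^-1
    faraday: float = 96485.33212331001  # F, C mol^-1
    avogadro: float = 6.02214076e23  # N_A, mol^-1
    elementary_charge: float = 1.602176634e-19  # e, C
    default_temperature: float = 291.15  # K (18 degrees C)
    pKa_boric: float = 9.24
    pKw: float = 14.0

    def __post_init__(self) -> None:
        for name in (
            "gas_constant",
            "faraday",
            "avogadro",
            "elementary_charge",
            "default_temperature",
            "pKa_boric",
            "pKw",
        ):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be finite and positive, got {value!r}")
        # e * N_A is F by definition; guard against inconsistent overrides.
        if abs(self.elementary_charge * self.avogadro / self.faraday - 1.0) > 1e-6:
            raise ValueError("elementary_charge * avogadro must equal faraday to 1e-6")

    @property
    def Ka(self) -> float:
        """Acid dissociation constant of boric acid, 10^(-pKa)."""
        return 10.0 ** (-self.pKa_boric)

    @property
    def Kw(self) -> float:
        """Ion product of water, 10^(-pKw)."""
        return 10.0 ** (-self.pKw)

    def rt(self, temperature: float | None = None) -> float:
        """R*T in J/mol at ``temperature`` (default recording temperature)."""
        T = self.default_temperature if temperature is None else temperature
        if not (math.isfinite(T) and T > 0):
            raise ValueError(f"temperature must be positive, got {T!r}")
        return self.gas_constant * T

    def with_overrides(self, overrides: Mapping[str, Any]) -> "PhysicalConstants":
        """Return a copy with fields replaced from a config mapping.

        Unknown keys are rejected so typos in YAML configs fail loudly.
        """
        known = set(self.__dataclass_fields__)
        unknown = set(overrides) - known
        if unknown:
            raise KeyError(f"unknown constants: {sorted(unknown)}")
        return replace(self, **dict(overrides))


DEFAULT_CONSTANTS = PhysicalConstants()
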