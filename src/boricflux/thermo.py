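"""Transport thermodynamics for the three candidate boric acid transport modes.

An electrogenic boric acid transporter moving one net negative charge into
the cell per cycle can operate as a B(OH)4- uniporter, a B(OH)3-OH-
cotransporter, or a B(OH)3/H+ exchanger. With 1:1 stoichiometry the
electrochemical potential difference per mole of cycles is

    uniport:      dmu = RT ln([B(OH)4-]i / [B(OH)4-]o)            - F dPsi
    cotransport:  dmu = RT ln([B(OH)3]i [OH-]i / [B(OH)3]o [OH-]o) - F dPsi
    exchange:     dmu = RT ln([B(OH)3]i [H+]o / [B(OH)3]o [H+]i)   - F dPsi

where dPsi is the membrane potential (inside minus outside). The three
concentration ratios are algebraically identical via Ka and Kw, so the
three modes are thermodynamically indistinguishable: a single dmu and a
single equilibrium potential describe all of them. dmu < 0 favours the
inward cycle (anion influx), which the voltage clamp reads out as a
positive outward current.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .speciation import SpeciationState


class TransportMode(Enum):
    """The three candidate transport cycles; each moves net charge -1 inward."""

    B_OH4_UNIPORT = "B(OH)4- uniport"
    B_OH3_OH_COTRANSPORT = "B(OH)3-OH- cotransport"
    B_OH3_H_EXCHANGE = "B(OH)3/H+ exchange"


#: Net charge moved into the cell per transport cycle, identical for all modes.
NET_CHARGE_PER_CYCLE = -1


@dataclass(frozen=True)
class MembraneState:
    """Two fully speciated compartments separated by a membrane.

    ``delta_psi`` is the membrane potential in volts, inside minus outside.
    """

    inside: SpeciationState
    outside: SpeciationState
    delta_psi: float  # V
    temperature: float = DEFAULT_CONSTANTS.default_temperature  # K

    def __post_init__(self) -> None:
        if not (math.isfinite(self.temperature) and self.temperature > 0):
            raise ValueError("temperature must be positive")
        if not math.isfinite(self.delta_psi):
            raise ValueError("delta_psi must be finite")


@dataclass(frozen=True)
class DrivingForce:
    """Electrochemical potential difference for one mode (J/mol of cycles).

    ``delta_mu`` < 0 favours the inward cycle as written (influx);
    > 0 favours efflux; 0 is equilibrium.
    """

    delta_mu: float  # J/mol
    mode: TransportMode
    concentration_ratio: float


def concentration_ratio(state: MembraneState, mode: TransportMode) -> float:
    """Mode-specific in/out concentration ratio entering the RT ln() term.

    All three modes yield the identical number — the uniport ratio
    [B(OH)4-]i/[B(OH)4-]o equals the cotransport and exchange ratios by the
    definitions of Ka and Kw — but each is computed from its own species so
    the identity can be checked numerically.
    """
    i, o = state.inside, state.outside
    if mode is TransportMode.B_OH4_UNIPORT:
        num, den = i.conc_B_OH4, o.conc_B_OH4
    elif mode is TransportMode.B_OH3_OH_COTRANSPORT:
        num, den = i.conc_B_OH3 * i.conc_OH, o.conc_B_OH3 * o.conc_OH
    elif mode is TransportMode.B_OH3_H_EXCHANGE:
        num, den = i.conc_B_OH3 * o.conc_H, o.conc_B_OH3 * i.conc_H
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(f"unknown mode {mode!r}")
    if den <= 0:
        raise ValueError(f"outside concentrations for {mode} must be positive")
    if num <= 0:
        raise ValueError(f"inside concentrations for {mode} must be positive")
    return num / den


def delta_mu(
    state: MembraneState,
    mode: TransportMode = TransportMode.B_OH4_UNIPORT,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> DrivingForce:
    """Electrochemical potential difference for one transport cycle.

    dmu = RT ln(ratio) + z F dPsi with z = -1 for every candidate mode,
    i.e. RT ln(ratio) - F dPsi. Identical across modes for the same state.
    """
    ratio = concentration_ratio(state, mode)
    rt = constants.rt(state.temperature)
    dmu = rt * math.log(ratio) + NET_CHARGE_PER_CYCLE * constants.faraday * state.delta_psi
    return DrivingForce(delta_mu=dmu, mode=mode, concentration_ratio=ratio)


def equilibrium_potential(
    state: MembraneState, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Membrane potential (V) at which the driving force vanishes.

    Setting dmu = 0 gives dPsi_eq = (RT/F) ln(ratio) for the -1 charge
    cycle. ``state.delta_psi`` is ignored. For an oocyte with ~1.4 mM total
    boric acid at pH 7.1 inside facing 20 mM at pH 7.5 outside, the ratio
    is ~0.028 and dPsi_eq is about -89.5 mV at 18 degrees C.
    """
    ratio = concentration_ratio(state, TransportMode.B_OH4_UNIPORT)
    rt = constants.rt(state.temperature)
    return rt * math.log(ratio) / (-NET_CHARGE_PER_CYCLE * constants.faraday)


def predicted_current_sign(
    state: MembraneState,
    mode: TransportMode = TransportMode.B_OH4_UNIPORT,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> int:
    """Sign of the whole-cell current the transporter produces.

    Influx of the -1 cycle (dmu < 0) is an anion influx, read by the clamp
    as a positive outward current (+1); efflux gives -1; equilibrium 0.
    """
    dmu = delta_mu(state, mode, constants).delta_mu
    if dmu < 0:
        return 1
    if dmu > 0:
        return -1
    return 0
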