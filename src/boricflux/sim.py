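"""Synthetic oocyte and cohort data generator.

A minimal whole-cell model of an oocyte expressing an electrogenic boric
acid transporter, used to produce every input the analysis pipeline
consumes with known ground truth:

* membrane: a linear leak conductance plus the transporter current,
* transporter: saturable in external boric acid (Michaelis-Menten with
  the published K_m and I_max) and thermodynamically reversible — the
  current is an odd, bounded function of the electrochemical driving
  force, ``I = I_max * [B]o/(K_m+[B]o) * tanh(-dmu/(2RT))``, which
  vanishes exactly at equilibrium and saturates at I_max,
* bookkeeping: every transported charge carries one boric acid molecule
  and one base equivalent, so boron content rises as I/F and
  intracellular pH rises as the base flux divided by the buffering power,
* unclamped epochs integrate C dVm/dt = -(I_leak + I_transporter), so the
  membrane relaxes to the potential at which the net current vanishes
  (the transporter's equilibrium potential when the leak is small),
* cohorts: lognormal concentration samples moment-matched to target
  group means and SDs.

The tanh force-flux relation is a modelling choice: the data constrain
only saturation in substrate and reversal at dmu = 0, and any bounded,
monotone odd function of dmu satisfies both. NMDG inhibition is empirical
(I_max scaled by IC50/(IC50+[NMDG])). All randomness flows from an
explicit seed; identical seeds and scripts give bit-identical outputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .ephys import CurrentTrace, SolutionSwitch
from .flux import ContentTimeSeries, CohortTable
from .speciation import intracellular_concentration, speciate
from .thermo import MembraneState, TransportMode, delta_mu


@dataclass(frozen=True)
class OocyteModelParams:
    """Ground-truth parameters of the synthetic oocyte.

    Defaults describe a healthy transporter-expressing oocyte at 18 C:
    0.2 uF membrane capacitance, 1 uS linear leak reversing at -30 mV,
    the published transport kinetics (K_m 6.5 mM, I_max 1.5 uA, NMDG
    IC50 67 mM), a 0.7 uL cell with 10% cytoplasm initially holding
    0.1 nmol boron (~1.4 mM) at pH 7.1, an intracellular buffering power
    of 20 mM per pH unit (literature-typical for oocytes), and 0.02 uA
    RMS recording noise.
    """

    membrane_capacitance: float = 0.2e-6  # F
    leak_conductance: float = 1.0e-6  # S
    leak_reversal: float = -0.030  # V
    K_m: float = 6.5e-3  # mol/L
    I_max: float = 1.5e-6  # A
    nmdg_ic50: float = 67e-3  # mol/L
    buffering_power: float = 20.0  # mM per pH unit
    oocyte_volume: float = 0.7e-6  # L
    cytoplasm_fraction: float = 0.10
    temperature: float = 291.15  # K
    initial_boron_content: float = 0.1e-9  # mol
    initial_ph_i: float = 7.1
    initial_vm: float = -0.060  # V
    noise_sd_current: float = 0.02e-6  # A
    noise_sd_ph: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "membrane_capacitance",
            "leak_conductance",
            "K_m",
            "buffering_power",
            "oocyte_volume",
            "temperature",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.cytoplasm_fraction <= 1):
            raise ValueError("cytoplasm_fraction must lie in (0, 1]")
        if self.noise_sd_current < 0 or self.noise_sd_ph < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass(frozen=True)
class Epoch:
    """One bath/clamp condition held for a fixed duration."""

    duration: float  # s
    boric_acid: float = 0.0  # mol/L total in the bath
    bath_ph: float = 7.5
    inhibitor: float = 0.0  # mol/L NMDG
    holding_potential: float | None = None  # V; None = unclamped
    rate: float = 1.0  # Hz recording rate
    label: str = ""

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("epoch duration must be positive")
        if self.boric_acid < 0 or self.inhibitor < 0:
            raise ValueError("bath concentrations must be >= 0")
        if not (0 < self.bath_ph < 14):
            raise ValueError("bath pH must lie in (0, 14)")
        if not self.rate > 0:
            raise ValueError("recording rate must be positive")


@dataclass(frozen=True)
class ExperimentScript:
    """Ordered sequence of epochs applied to one oocyte."""

    epochs: tuple[Epoch, ...]

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("a script needs at least one epoch")

    @classmethod
    def from_dicts(cls, items: Sequence[dict]) -> "ExperimentScript":
        """Build from YAML-style dicts (concentrations in mM, potentials mV)."""
        epochs = []
        for item in items:
            item = dict(item)
            vh = item.pop("holding_potential_mV", None)
            epochs.append(
                Epoch(
                    duration=item.pop("duration_s"),
                    boric_acid=item.pop("boric_acid_mM", 0.0) * 1e-3,
                    bath_ph=item.pop("bath_ph", 7.5),
                    inhibitor=item.pop("inhibitor_mM", 0.0) * 1e-3,
                    holding_potential=None if vh is None else vh * 1e-3,
                    rate=item.pop("rate_Hz", 1.0),
                    label=item.pop("label", ""),
                )
            )
            if item:
                raise KeyError(f"unknown epoch keys: {sorted(item)}")
        return cls(tuple(epochs))


def transporter_current(
    state: MembraneState,
    params: OocyteModelParams,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Transporter current (A, outward positive) for a membrane state.

    ``I = I_max * sat([B]o) * tanh(-dmu / (2RT))`` where sat is the
    Michaelis-Menten occupancy of external total boric acid. The current
    is exactly zero at dmu = 0, has the sign of the favoured direction
    (influx -> positive outward current) and approaches I_max at
    saturating substrate and strongly favourable driving force. With no
    external substrate the carrier is silent (sat = 0).
    """
    b_out = state.outside.total_boric_acid
    if b_out <= 0:
        return 0.0
    saturation = b_out / (params.K_m + b_out)
    if state.inside.total_boric_acid <= 0:
        # empty cell: the inward cycle is maximally favoured
        force_factor = 1.0
    else:
        dmu = delta_mu(state, TransportMode.B_OH4_UNIPORT, constants).delta_mu
        force_factor = math.tanh(-dmu / (2.0 * constants.rt(state.temperature)))
    return params.I_max * saturation * force_factor


@dataclass
class EpochResult:
    """Recorded samples and ground truth for one epoch."""

    epoch: Epoch
    times: np.ndarray  # s, absolute
    current: np.ndarray  # A, recorded (leak + transporter + noise)
    vm: np.ndarray  # V
    ph: np.ndarray  # recorded intracellular pH
    content: np.ndarray  # mol boron, noise-free ground truth
    transporter_current_clean: np.ndarray  # A, noise-free
    transporter_charge: float  # C, integral of the clean transporter current
    moles_transported: float  # mol


@dataclass
class SimResult:
    """Output of :func:`simulate`: per-epoch recordings plus ground truth."""

    epochs: list[EpochResult]
    params: OocyteModelParams

    @property
    def transporter_charge(self) -> float:
        return sum(e.transporter_charge for e in self.epochs)

    @property
    def moles_transported(self) -> float:
        return sum(e.moles_transported for e in self.epochs)

    def current_trace(self, indices: Sequence[int] | None = None) -> CurrentTrace:
        """Concatenate clamped epochs into a :class:`CurrentTrace`.

        All selected epochs must share a holding potential and rate.
        """
        selected = [self.epochs[i] for i in indices] if indices is not None else self.epochs
        clamped = [e for e in selected if e.epoch.holding_potential is not None]
        if not clamped:
            raise ValueError("no clamped epochs to build a trace from")
        vh = {e.epoch.holding_potential for e in clamped}
        rates = {e.epoch.rate for e in clamped}
        if len(vh) != 1 or len(rates) != 1:
            raise ValueError("epochs in one trace must share holding potential and rate")
        times = np.concatenate([e.times for e in clamped])
        currents = np.concatenate([e.current for e in clamped])
        annotations = [
            SolutionSwitch(
                time=float(e.times[0]),
                label=e.epoch.label or f"epoch {i}",
                boric_acid=e.epoch.boric_acid,
                inhibitor=e.epoch.inhibitor,
            )
            for i, e in enumerate(clamped)
        ]
        return CurrentTrace(
            time=times,
            current=currents,
            holding_potential=vh.pop(),
            sampling_rate=rates.pop(),
            annotations=annotations,
        )

    def content_series(self, label: str = "simulated") -> ContentTimeSeries:
        times = np.concatenate([e.times for e in self.epochs])
        contents = np.concatenate([e.content for e in self.epochs])
        return ContentTimeSeries(times=times, contents=contents, label=label)

    def ph_series(self) -> tuple[np.ndarray, np.ndarray]:
        times = np.concatenate([e.times for e in self.epochs])
        ph = np.concatenate([e.ph for e in self.epochs])
        return times, ph


def _stable_step(params: OocyteModelParams, constants: PhysicalConstants) -> float:
    """Conservative explicit-Euler step bound for the unclamped voltage ODE."""
    slope_conductance = params.I_max * constants.faraday / (2.0 * constants.rt(params.temperature))
    g_eff = params.leak_conductance + slope_conductance
    return 0.2 * params.membrane_capacitance / g_eff


def simulate(
    script: ExperimentScript,
    params: OocyteModelParams,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    dt: float | None = None,
) -> SimResult:
    """Integrate the oocyte model through a script of epochs.

    Clamped epochs record ``I_total = I_leak + I_transporter + noise`` at
    the epoch's rate; unclamped epochs integrate the membrane-potential
    ODE. Boron content advances as dB/dt = I_transporter / F and
    intracellular pH as the base-equivalent flux over (buffering power x
    cytoplasmic volume). Fixed-step explicit integration with at least
    100 steps per epoch; an explicitly requested step size that is too
    coarse for the voltage ODE raises with a suggested step. Fully
    reproducible: the only randomness is recording noise drawn from
    ``params.rng_seed``.
    """
    rng = np.random.default_rng(params.rng_seed)
    dt_stable = _stable_step(params, constants)
    if dt is not None and dt > dt_stable and any(
        e.holding_potential is None for e in script.epochs
    ):
        raise ValueError(
            f"step size {dt:g} s is unstable for the unclamped voltage ODE; "
            f"use dt <= {dt_stable:.3g} s"
        )

    v_cyto = params.oocyte_volume * params.cytoplasm_fraction
    beta_molar = params.buffering_power * 1e-3  # mol/L per pH unit
    content = params.initial_boron_content
    ph_i = params.initial_ph_i
    vm = params.initial_vm
    t_start = 0.0
    results: list[EpochResult] = []

    for epoch in script.epochs:
        clamped = epoch.holding_potential is not None
        dt_rec = 1.0 / epoch.rate
        n_rec = max(1, round(epoch.duration * epoch.rate))
        requested = dt if dt is not None else dt_rec
        if not clamped:
            requested = min(requested, dt_stable)
        # at least 100 integration steps per epoch
        requested = min(requested, epoch.duration / 100.0)
        k_sub = max(1, math.ceil(dt_rec / requested))
        dt_int = dt_rec / k_sub

        outside = speciate(epoch.boric_acid, epoch.bath_ph, constants) \
            if epoch.boric_acid > 0 else None
        inhibition = params.nmdg_ic50 / (params.nmdg_ic50 + epoch.inhibitor)

        rec_t = np.empty(n_rec)
        rec_i = np.empty(n_rec)
        rec_vm = np.empty(n_rec)
        rec_ph = np.empty(n_rec)
        rec_content = np.empty(n_rec)
        rec_it = np.empty(n_rec)
        epoch_charge = 0.0
        epoch_moles = 0.0

        for j in range(n_rec):
            for _ in range(k_sub):
                v_now = epoch.holding_potential if clamped else vm
                if outside is not None:
                    conc_i = intracellular_concentration(
                        content, params.oocyte_volume, params.cytoplasm_fraction
                    )
                    inside = speciate(conc_i, min(max(ph_i, 1.0), 13.0), constants)
                    state = MembraneState(
                        inside=inside,
                        outside=outside,
                        delta_psi=v_now,
                        temperature=params.temperature,
                    )
                    i_trans = transporter_current(state, params, constants) * inhibition
                else:
                    i_trans = 0.0
                i_leak = params.leak_conductance * (v_now - params.leak_reversal)
                flux = i_trans / constants.faraday  # mol/s of boric acid and base
                content += flux * dt_int
                ph_i += flux / (beta_molar * v_cyto) * dt_int
                epoch_charge += i_trans * dt_int
                epoch_moles += flux * dt_int
                if not clamped:
                    vm += -(i_leak + i_trans) / params.membrane_capacitance * dt_int
            rec_t[j] = t_start + (j + 1) * dt_rec
            rec_it[j] = i_trans
            rec_i[j] = i_leak + i_trans
            rec_vm[j] = epoch.holding_potential if clamped else vm
            rec_ph[j] = ph_i
            rec_content[j] = content

        if params.noise_sd_current > 0:
            rec_i = rec_i + rng.normal(0.0, params.noise_sd_current, n_rec)
        if params.noise_sd_ph > 0:
            rec_ph = rec_ph + rng.normal(0.0, params.noise_sd_ph, n_rec)

        results.append(
            EpochResult(
                epoch=epoch,
                times=rec_t,
                current=rec_i,
                vm=rec_vm,
                ph=rec_ph,
                content=rec_content,
                transporter_current_clean=rec_it,
                transporter_charge=epoch_charge,
                moles_transported=epoch_moles,
            )
        )
        t_start += n_rec * dt_rec

    return SimResult(epochs=results, params=params)


def control_params(params: OocyteModelParams | None = None) -> OocyteModelParams:
    """Water-injected control oocyte: same membrane, no transporter."""
    base = params or OocyteModelParams()
    return replace(base, I_max=0.0)


def generate_mm_currents(
    doses: Sequence[float],
    k_m: float,
    i_max: float,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Dose-response currents from the Michaelis-Menten model plus noise.

    ``doses`` and ``k_m`` in mol/L, ``i_max`` and ``noise_sd`` in A
    (additive Gaussian noise, the recording-noise model).
    """
    doses = np.asarray(doses, dtype=float)
    currents = i_max * doses / (k_m + doses)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("an rng is required when noise_sd > 0")
        currents = currents + rng.normal(0.0, noise_sd, doses.shape)
    return currents


def generate_inhibition_currents(
    doses: Sequence[float],
    ic50: float,
    i_0: float,
    noise_fraction: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Inhibition currents I_0 * IC50/(IC50+[N]) with multiplicative noise."""
    doses = np.asarray(doses, dtype=float)
    currents = i_0 * ic50 / (ic50 + doses)
    if noise_fraction > 0:
        if rng is None:
            raise ValueError("an rng is required when noise_fraction > 0")
        currents = currents * (1.0 + rng.normal(0.0, noise_fraction, doses.shape))
    return currents


@dataclass(frozen=True)
class CohortGroupSpec:
    """Target moments for one cohort group."""

    species: str
    acclimation: str
    fluid: str
    mean: float  # mol/L
    sd: float  # mol/L
    n: int

    def __post_init__(self) -> None:
        if not self.mean > 0:
            raise ValueError("group mean must be positive")
        if self.sd < 0:
            raise ValueError("group SD must be >= 0")
        if self.n < 1:
            raise ValueError("group size must be >= 1")


def generate_cohort(
    group_specs: Sequence[CohortGroupSpec], seed: int
) -> CohortTable:
    """Sample positive-valued cohort concentrations, moment-matched.

    Each group is drawn from a lognormal with parameters chosen so the
    distribution's mean and SD equal the targets (sigma^2 =
    ln(1 + sd^2/mean^2), mu = ln(mean) - sigma^2/2). SD = 0 degenerates
    to the constant mean. A SD of 3x the mean or more triggers a
    heavy-tail warning.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for spec in group_specs:
        if spec.sd >= 3 * spec.mean:
            warnings.warn(
                f"group {(spec.species, spec.acclimation, spec.fluid)}: "
                "SD >= 3x mean gives a very heavy-tailed lognormal",
                stacklevel=2,
            )
        if spec.sd == 0:
            values = np.full(spec.n, spec.mean)
        else:
            sigma2 = math.log(1.0 + (spec.sd / spec.mean) ** 2)
            mu = math.log(spec.mean) - sigma2 / 2.0
            values = rng.lognormal(mu, math.sqrt(sigma2), spec.n)
        for v in values:
            rows.append(
                {
                    "species": spec.species,
                    "acclimation": spec.acclimation,
                    "fluid": spec.fluid,
                    "conc": float(v),
                }
            )
    return CohortTable(pd.DataFrame(rows))


def printed_cohort_specs() -> list[CohortGroupSpec]:
    """Cohort group specs matching the printed fluid concentration table."""
    from .flux import load_printed_cohort

    frame = load_printed_cohort()
    return [
        CohortGroupSpec(
            species=row["species"],
            acclimation=row["acclimation"],
            fluid=row["fluid"],
            mean=row["mean"],
            sd=row["sd"],
            n=int(row["n"]),
        )
        for _, row in frame.iterrows()
    ]
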