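"""Voltage-clamp trace analysis.

Covers the standard two-electrode voltage clamp workflow for an
electrogenic transporter expressed in oocytes:

* steady-state elicited currents (substrate minus substrate-free),
* I-V relationships from step protocols and interpolated reversal
  potentials,
* charge integration and the charge-count / molecule-count stoichiometry
  that ties electrical charge movement to ICP-MS boron uptake,
* Michaelis-Menten dose-response and single-site inhibition (IC50) fits,
* intracellular pH drift slopes.

Currents are amperes with outward positive, potentials volts, time
seconds. CSV I/O uses ``time_s,current_uA`` (or ``time_s,ph``) columns
with a JSON sidecar for the holding potential, sampling rate and
solution-switch annotations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .constants import DEFAULT_CONSTANTS, PhysicalConstants

#: Fraction of an epoch/step treated as "steady state" (its terminal part).
DEFAULT_STEADY_FRACTION = 0.25


class FitError(RuntimeError):
    """A dose-response fit could not be performed or did not converge."""


@dataclass(frozen=True)
class SolutionSwitch:
    """A bath-change annotation on a trace."""

    time: float  # s
    label: str
    boric_acid: float = 0.0  # mol/L total boric acid after the switch
    inhibitor: float = 0.0  # mol/L inhibitor (NMDG) after the switch


@dataclass
class CurrentTrace:
    """A sampled whole-cell current (or pH) recording.

    ``current`` is outward-positive amperes. ``sampling_rate`` must agree
    with the median time spacing to 1%; annotations must fall inside the
    recorded span.
    """

    time: np.ndarray  # s, strictly increasing
    current: np.ndarray  # A
    holding_potential: float  # V
    sampling_rate: float  # Hz
    annotations: list[SolutionSwitch] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.time.shape != self.current.shape:
            raise ValueError("time and current must have the same length")
        if self.time.size < 2:
            raise ValueError("a trace needs at least two samples")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        spacing = float(np.median(np.diff(self.time)))
        if abs(spacing * self.sampling_rate - 1.0) > 0.01:
            raise ValueError("sampling_rate inconsistent with time spacing (>1%)")
        for ann in self.annotations:
            if not (self.time[0] <= ann.time <= self.time[-1]):
                raise ValueError(f"annotation at {ann.time} s outside the trace")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def window(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask for samples with t0 <= t <= t1."""
        if t1 <= t0:
            raise ValueError("window must satisfy t0 < t1")
        if t0 < self.time[0] - 1e-9 or t1 > self.time[-1] + 1e-9:
            raise ValueError("window outside the trace span")
        return (self.time >= t0) & (self.time <= t1)

    def to_csv(self, csv_path: str | Path, value_column: str = "current_uA") -> None:
        """Write the trace as CSV plus a JSON metadata sidecar."""
        csv_path = Path(csv_path)
        scale = 1e6 if value_column == "current_uA" else 1.0
        pd.DataFrame({"time_s": self.time, value_column: self.current * scale}).to_csv(
            csv_path, index=False
        )
        sidecar = {
            "holding_potential_mV": self.holding_potential * 1e3,
            "sampling_rate_Hz": self.sampling_rate,
            "annotations": [
                {
                    "time_s": a.time,
                    "label": a.label,
                    "boric_acid_mM": a.boric_acid * 1e3,
                    "inhibitor_mM": a.inhibitor * 1e3,
                }
                for a in self.annotations
            ],
        }
        csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, csv_path: str | Path, value_column: str = "current_uA") -> "CurrentTrace":
        csv_path = Path(csv_path)
        frame = pd.read_csv(csv_path)
        sidecar = json.loads(csv_path.with_suffix(".json").read_text())
        scale = 1e-6 if value_column == "current_uA" else 1.0
        return cls(
            time=frame["time_s"].to_numpy(),
            current=frame[value_column].to_numpy() * scale,
            holding_potential=sidecar["holding_potential_mV"] * 1e-3,
            sampling_rate=sidecar["sampling_rate_Hz"],
            annotations=[
                SolutionSwitch(
                    time=a["time_s"],
                    label=a["label"],
                    boric_acid=a.get("boric_acid_mM", 0.0) * 1e-3,
                    inhibitor=a.get("inhibitor_mM", 0.0) * 1e-3,
                )
                for a in sidecar.get("annotations", [])
            ],
        )


@dataclass
class IVProtocol:
    """Voltage-step protocol: 200 ms steps, -160 to +60 mV in 20 mV steps.

    ``step_traces`` maps each step potential (V) to the current samples
    recorded during that step; all steps must be equally long.
    """

    step_potentials: np.ndarray  # V, strictly increasing
    step_traces: list[np.ndarray]  # A, one equal-length array per step
    step_duration: float = 0.2  # s

    def __post_init__(self) -> None:
        self.step_potentials = np.asarray(self.step_potentials, dtype=float)
        if not np.all(np.diff(self.step_potentials) > 0):
            raise ValueError("step potentials must be strictly increasing")
        if len(self.step_traces) != self.step_potentials.size:
            raise ValueError("one trace per step potential required")
        lengths = {len(t) for t in self.step_traces}
        if len(lengths) != 1:
            raise ValueError("all step traces must have equal length")


@dataclass(frozen=True)
class IVCurve:
    """Steady-state current at each step potential.

    ``reversal_potential`` is the linearly interpolated zero crossing, or
    None when the currents never change sign (never extrapolated).
    """

    potentials: np.ndarray  # V
    currents: np.ndarray  # A
    reversal_potential: float | None


@dataclass(frozen=True)
class ChargeAccounting:
    """Charge-movement vs boron-content bookkeeping for one uptake run.

    E_boric_acid = E_total - E_leak is the substrate-elicited charge;
    dividing by the elementary charge counts transported charges (A), and
    the ICP-MS boron increase times Avogadro's number counts transported
    molecules (B). For a 1:1 electrogenic transporter A/B is 1.
    """

    e_total: float  # C
    e_leak: float  # C
    e_boric_acid: float  # C
    charge_count: float  # dimensionless (A)
    molecule_count: float | None  # dimensionless (B); None when no uptake measured
    ratio: float | None  # A/B; None when undefined
    boron_decreased: bool = False  # flagged when an uptake run lost boron


@dataclass(frozen=True)
class MMFitResult:
    """Michaelis-Menten fit I = I_max [B] / (K_m + [B])."""

    K_m: float  # mol/L
    I_max: float  # A
    K_m_stderr: float
    I_max_stderr: float
    residual_norm: float


@dataclass(frozen=True)
class InhibitionFitResult:
    """Single-site inhibition fit I = I_0 IC50 / (IC50 + [N]), Hill = 1.

    ``ic50`` is None when the data show no inhibition (IC50 unbounded).
    """

    ic50: float | None  # mol/L
    I_0: float  # A
    residual_norm: float


def steady_state_current(
    trace: CurrentTrace,
    t0: float | None = None,
    t1: float | None = None,
    steady_fraction: float = DEFAULT_STEADY_FRACTION,
) -> float:
    """Mean current over a terminal window.

    With no explicit window the final ``steady_fraction`` of the trace is
    used.
    """
    if t0 is None or t1 is None:
        span = trace.duration
        t1 = float(trace.time[-1])
        t0 = t1 - steady_fraction * span
    mask = trace.window(t0, t1)
    if not mask.any():
        raise ValueError("steady-state window contains no samples")
    return float(trace.current[mask].mean())


def elicited_current(
    trace_with: CurrentTrace,
    trace_without: CurrentTrace | None = None,
    baseline_window: tuple[float, float] | None = None,
    steady_fraction: float = DEFAULT_STEADY_FRACTION,
) -> float:
    """Substrate-elicited current: I(boric acid) - I(no boric acid).

    The reference is either a matched substrate-free trace (holding
    potentials must agree) or a pre-application baseline window on the
    same trace. Steady-state values are terminal-window means.
    """
    i_with = steady_state_current(trace_with, steady_fraction=steady_fraction)
    if trace_without is not None:
        if abs(trace_without.holding_potential - trace_with.holding_potential) > 1e-9:
            raise ValueError("holding potentials of the paired traces differ")
        i_without = steady_state_current(trace_without, steady_fraction=steady_fraction)
    elif baseline_window is not None:
        if trace_with.annotations:
            first_switch = min(a.time for a in trace_with.annotations)
            if baseline_window[1] > first_switch:
                raise ValueError("baseline window must precede the solution switch")
        i_without = steady_state_current(trace_with, *baseline_window)
    else:
        raise ValueError("provide a substrate-free trace or a baseline window")
    return i_with - i_without


def _steady_step_currents(protocol: IVProtocol, steady_fraction: float) -> np.ndarray:
    n = len(protocol.step_traces[0])
    start = max(0, n - max(1, int(round(steady_fraction * n))))
    return np.array([float(np.mean(t[start:])) for t in protocol.step_traces])


def _interpolated_reversal(potentials: np.ndarray, currents: np.ndarray) -> float | None:
    sign = np.sign(currents)
    for k in range(len(currents) - 1):
        if currents[k] == 0.0:
            return float(potentials[k])
        if sign[k] * sign[k + 1] < 0:
            v0, v1 = potentials[k], potentials[k + 1]
            i0, i1 = currents[k], currents[k + 1]
            return float(v0 - i0 * (v1 - v0) / (i1 - i0))
    if currents[-1] == 0.0:
        return float(potentials[-1])
    return None


def build_iv(
    protocol: IVProtocol,
    reference: IVProtocol | None = None,
    steady_fraction: float = DEFAULT_STEADY_FRACTION,
) -> IVCurve:
    """Steady-state I-V curve, optionally as an elicited-current curve.

    When a substrate-free ``reference`` protocol is given, the per-step
    currents are subtracted pointwise before the reversal potential is
    located. The reversal is found by linear interpolation between the
    bracketing sign change; if the curve never crosses zero the reversal
    is reported as absent rather than extrapolated.
    """
    currents = _steady_step_currents(protocol, steady_fraction)
    if reference is not None:
        if not np.allclose(reference.step_potentials, protocol.step_potentials):
            raise ValueError("paired protocols must use identical step potentials")
        currents = currents - _steady_step_currents(reference, steady_fraction)
    reversal = _interpolated_reversal(protocol.step_potentials, currents)
    return IVCurve(
        potentials=protocol.step_potentials.copy(),
        currents=currents,
        reversal_potential=reversal,
    )


def integrate_charge(trace: CurrentTrace, window: tuple[float, float] | None = None) -> float:
    """Trapezoidal integral of current over time (coulombs)."""
    if window is None:
        mask = np.ones_like(trace.time, dtype=bool)
    else:
        mask = trace.window(*window)
    return float(np.trapezoid(trace.current[mask], trace.time[mask]))


def leak_charge(
    trace: CurrentTrace, baseline_window: tuple[float, float], application_duration: float
) -> float:
    """Leak-charge estimate: mean pre-application current x duration.

    Mirrors the cohort-mean leak convention; a per-oocyte alternative is
    to integrate the oocyte's own substrate-free window.
    """
    mask = trace.window(*baseline_window)
    return float(trace.current[mask].mean()) * application_duration


def charge_accounting(
    e_total: float,
    e_leak: float,
    boron_before: float,
    boron_after: float | None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> ChargeAccounting:
    """Fill the charge/molecule stoichiometry table for one uptake run.

    Parameters are coulombs (total and leak charge movements) and mol
    (ICP-MS boron content before/after; ``boron_after=None`` when no
    uptake was measured). A boron decrease in an uptake experiment is
    flagged but the ratio is still computed.
    """
    e_boric = e_total - e_leak
    charge_count = abs(e_boric) / constants.elementary_charge
    if boron_after is None:
        return ChargeAccounting(e_total, e_leak, e_boric, charge_count, None, None)
    if boron_after < 0 or boron_before < 0:
        raise ValueError("boron contents must be >= 0")
    delta_mol = boron_after - boron_before
    molecule_count = abs(delta_mol) * constants.avogadro
    ratio = charge_count / molecule_count if molecule_count > 0 else None
    return ChargeAccounting(
        e_total=e_total,
        e_leak=e_leak,
        e_boric_acid=e_boric,
        charge_count=charge_count,
        molecule_count=molecule_count,
        ratio=ratio,
        boron_decreased=delta_mol < 0,
    )


def charge_accounting_from_trace(
    trace: CurrentTrace,
    application_window: tuple[float, float],
    baseline_window: tuple[float, float],
    boron_before: float,
    boron_after: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> ChargeAccounting:
    """Charge accounting with E_total and E_leak taken from the trace itself."""
    e_total = integrate_charge(trace, application_window)
    duration = application_window[1] - application_window[0]
    e_leak = leak_charge(trace, baseline_window, duration)
    return charge_accounting(e_total, e_leak, boron_before, boron_after, constants)


def michaelis_menten(conc: np.ndarray, i_max: float, k_m: float) -> np.ndarray:
    """Saturable dose-response I = I_max [B] / (K_m + [B])."""
    conc = np.asarray(conc, dtype=float)
    return i_max * conc / (k_m + conc)


def fit_michaelis_menten(doses: Sequence[float], currents: Sequence[float]) -> MMFitResult:
    """Least-squares Michaelis-Menten fit of elicited currents vs dose.

    Starting values are deterministic: K_m at the median dose, I_max at
    the current of largest magnitude (signed, so efflux data fit with a
    negative I_max). K_m is constrained positive.
    """
    doses = np.asarray(doses, dtype=float)
    currents = np.asarray(currents, dtype=float)
    if np.unique(doses).size < 3:
        raise FitError("at least 3 distinct doses are required")
    if np.allclose(currents, 0.0):
        raise FitError("all currents are zero: I_max = 0 and K_m is unidentifiable")
    # fit in rescaled units (doses ~1e-3 M, currents ~1e-6 A are badly
    # conditioned for the optimizer's default tolerances)
    dose_scale = float(np.median(doses[doses > 0]))
    i_scale = float(np.max(np.abs(currents)))
    i0 = float(currents[np.argmax(np.abs(currents))]) / i_scale
    try:
        popt, pcov = optimize.curve_fit(
            michaelis_menten,
            doses / dose_scale,
            currents / i_scale,
            p0=(i0, 1.0),
            bounds=([-np.inf, 1e-12], [np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:  # pragma: no cover
        raise FitError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    stderr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(2, np.nan)
    residuals = currents - i_scale * michaelis_menten(doses / dose_scale, *popt)
    return MMFitResult(
        K_m=float(popt[1]) * dose_scale,
        I_max=float(popt[0]) * i_scale,
        K_m_stderr=float(stderr[1]) * dose_scale,
        I_max_stderr=float(stderr[0]) * i_scale,
        residual_norm=float(np.linalg.norm(residuals)),
    )


def inhibition_model(conc: np.ndarray, i_0: float, ic50: float) -> np.ndarray:
    """Single-site inhibition I = I_0 IC50 / (IC50 + [N]) (Hill = 1)."""
    conc = np.asarray(conc, dtype=float)
    return i_0 * ic50 / (ic50 + conc)


def fit_inhibition(
    inhibitor_doses: Sequence[float], currents: Sequence[float]
) -> InhibitionFitResult:
    """Least-squares IC50 fit of currents vs inhibitor concentration.

    The dose set must include 0 (the uninhibited current). Flat data —
    no measurable inhibition — yield an unbounded IC50, reported as
    absent (None) rather than a number.
    """
    doses = np.asarray(inhibitor_doses, dtype=float)
    currents = np.asarray(currents, dtype=float)
    if np.unique(doses).size < 3:
        raise FitError("at least 3 distinct inhibitor doses are required")
    if not np.any(doses == 0):
        raise FitError("the dose set must include 0 (uninhibited current)")
    max_dose = float(doses.max())
    i_scale = float(np.max(np.abs(currents)))
    if i_scale == 0:
        raise FitError("all currents are zero: I_0 = 0 and IC50 is unidentifiable")
    i0_guess = float(currents[np.argmax(np.abs(currents))]) / i_scale
    try:
        popt, _ = optimize.curve_fit(
            inhibition_model,
            doses / max_dose,
            currents / i_scale,
            p0=(i0_guess, 0.5),
            bounds=([-np.inf, 1e-12], [np.inf, 1e6]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover
        raise FitError(f"inhibition fit did not converge: {exc}") from exc
    residuals = currents - i_scale * inhibition_model(doses / max_dose, *popt)
    ic50: float | None = float(popt[1]) * max_dose
    # an IC50 far above the tested range means <5% inhibition at the top
    # dose: no measurable inhibition, reported as absent
    if ic50 >= 20 * max_dose:
        ic50 = None
    return InhibitionFitResult(
        ic50=ic50, I_0=float(popt[0]) * i_scale, residual_norm=float(np.linalg.norm(residuals))
    )


def ph_slope(
    time: Sequence[float], ph: Sequence[float], window: tuple[float, float] | None = None
) -> float:
    """OLS slope of intracellular pH vs time (pH units per second).

    Requires at least 10 samples in the window; this is the alkalinization
    rate readout for base-equivalent influx.
    """
    time = np.asarray(time, dtype=float)
    ph = np.asarray(ph, dtype=float)
    if window is not None:
        mask = (time >= window[0]) & (time <= window[1])
        time, ph = time[mask], ph[mask]
    if time.size < 10:
        raise ValueError("pH slope estimation needs at least 10 samples")
    result = stats.linregress(time, ph)
    return float(result.slope)
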