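"""Boron content and cohort concentration analysis.

ICP-MS boron contents of single oocytes over time give uptake/efflux
rates; fluid concentrations across fish cohorts (serum, urine, rectal
fluid, environment) acclimated to fresh, brackish or sea water give the
fold-ratio picture of renal boric acid excretion. Everything here is
mean/SD summarisation and ratio arithmetic — no hypothesis testing.

Concentrations are mol/L internally; the printed-values fixture and CSV
interfaces use mM.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
from scipy import stats

from .formatting import sig_figs

GROUP_COLUMNS = ["species", "acclimation", "fluid"]
VALID_ACCLIMATIONS = {"FW", "BW", "SW"}
VALID_FLUIDS = {"serum", "urine", "rectal_fluid", "environment"}


@dataclass
class ContentTimeSeries:
    """Per-cell boron content over time for one experimental group."""

    times: np.ndarray  # s (or any consistent unit)
    contents: np.ndarray  # mol per cell
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.contents = np.asarray(self.contents, dtype=float)
        if self.times.shape != self.contents.shape:
            raise ValueError("times and contents must have the same length")
        if np.any(self.times < 0):
            raise ValueError("times must be non-negative")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.contents < 0):
            raise ValueError("contents must be non-negative")


@dataclass
class CohortTable:
    """Individual concentration measurements labelled by group.

    Columns: species, acclimation (FW/BW/SW), fluid (serum/urine/
    rectal_fluid/environment), conc (mol/L). Non-negative concentrations
    only; below-detection values must be excluded before construction.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in GROUP_COLUMNS + ["conc"] if c not in self.frame.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        if (self.frame["conc"] < 0).any():
            raise ValueError("concentrations must be non-negative")
        bad_acc = set(self.frame["acclimation"]) - VALID_ACCLIMATIONS
        if bad_acc:
            raise ValueError(f"unknown acclimation labels: {sorted(bad_acc)}")
        bad_fluid = set(self.frame["fluid"]) - VALID_FLUIDS
        if bad_fluid:
            raise ValueError(f"unknown fluid labels: {sorted(bad_fluid)}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortTable":
        """Read a cohort CSV with header species,acclimation,fluid,conc_mM."""
        frame = pd.read_csv(path)
        frame = frame.rename(columns={"conc_mM": "conc"})
        frame["conc"] = frame["conc"] * 1e-3
        return cls(frame)

    def to_csv(self, path: str | Path) -> None:
        out = self.frame[GROUP_COLUMNS].copy()
        out["conc_mM"] = self.frame["conc"] * 1e3
        out.to_csv(path, index=False)


@dataclass(frozen=True)
class FoldChangeReport:
    """Ratio of one group mean to another, with publication-style display."""

    numerator: tuple[str, str, str]
    denominator: tuple[str, str, str]
    fold: float
    formatted: float  # 2 significant figures


def flux_rate(series: ContentTimeSeries) -> float:
    """Boron flux as the OLS slope of content vs time (mol per time unit).

    Positive slope = influx, negative = efflux. A single time point has no
    slope and is rejected.
    """
    if series.times.size < 2:
        raise ValueError("flux rate needs at least 2 time points")
    if series.times.size == 2:
        dt = series.times[1] - series.times[0]
        return float((series.contents[1] - series.contents[0]) / dt)
    return float(stats.linregress(series.times, series.contents).slope)


def summarize_cohort(table: CohortTable) -> pd.DataFrame:
    """Per-group mean, sample SD (n-1) and n.

    Groups with a single measurement get an absent (NaN) SD. Units are
    preserved (mol/L in, mol/L out).
    """
    if table.frame.empty:
        raise ValueError("cohort table is empty")
    grouped = table.frame.groupby(GROUP_COLUMNS, sort=False)["conc"]
    summary = grouped.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count").reset_index()
    return summary


def _group_mean(summary: pd.DataFrame, group: tuple[str, str, str]) -> float:
    mask = (
        (summary["species"] == group[0])
        & (summary["acclimation"] == group[1])
        & (summary["fluid"] == group[2])
    )
    rows = summary[mask]
    if rows.empty:
        raise KeyError(f"group {group} not found in cohort summary")
    return float(rows["mean"].iloc[0])


def fold_ratio(
    summary: pd.DataFrame,
    numerator: tuple[str, str, str],
    denominator: tuple[str, str, str],
) -> FoldChangeReport:
    """Fold change between two group means, displayed to 2 significant figures.

    Groups are (species, acclimation, fluid) keys into a cohort summary
    (either computed by :func:`summarize_cohort` or the printed-values
    fixture). Fold changes are ratios of group means, not per-animal
    pairings.
    """
    num = _group_mean(summary, numerator)
    den = _group_mean(summary, denominator)
    if den <= 0:
        raise ValueError(f"denominator group {denominator} has non-positive mean")
    fold = num / den
    return FoldChangeReport(
        numerator=numerator,
        denominator=denominator,
        fold=fold,
        formatted=sig_figs(fold, 2),
    )


def load_printed_cohort() -> pd.DataFrame:
    """Printed cohort summary fixture (group means, SDs and n; mol/L).

    These are the published fluid boron/boric-acid concentrations for
    river and tiger pufferfish under FW/BW/SW acclimation, shipped with
    the package so the fold-ratio analysis runs without any download.
    """
    resource = importlib.resources.files("boricflux.data") / "fig1_printed_values.csv"
    with importlib.resources.as_file(resource) as path:
        frame = pd.read_csv(path)
    frame["mean"] = frame.pop("mean_mM") * 1e-3
    frame["sd"] = frame.pop("sd_mM") * 1e-3
    return frame
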