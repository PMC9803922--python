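# boricflux

Analysis toolkit for **electrogenic boric acid transport** across cell
membranes, built around the renal boric-acid excretion system of seawater
fish. Marine teleosts drink seawater (~0.4 mM boric acid) and concentrate
boric acid into their urine by up to three orders of magnitude; the
apical transporter responsible (an Slc4a11 paralog) moves one net negative
charge per boric acid molecule, so its flux is both measurable as a
whole-cell current and driven by membrane potential. This package is for
membrane-transport physiologists who want to work quantitatively with
that system: speciation chemistry, transport thermodynamics, two-electrode
voltage-clamp analysis, ICP-MS flux/cohort analysis, and a synthetic
oocyte simulator so every stage is testable without any recordings.

## The model

Boric acid B(OH)₃ (pKa 9.24) equilibrates with borate B(OH)₄⁻:

    Ka = [B(OH)₄⁻][H⁺]/[B(OH)₃],   Kw = [H⁺][OH⁻]

A transporter carrying one net −1 charge inward per cycle can be a
B(OH)₄⁻ uniporter, a B(OH)₃–OH⁻ cotransporter, or a B(OH)₃/H⁺ exchanger.
With 1:1 stoichiometry the electrochemical potential difference per mole
of cycles is

    Δμ = RT·ln(r) − F·ΔΨ,   ΔΨ = Ψᵢₙ − Ψₒᵤₜ

where the concentration ratio `r` is `[B(OH)₄⁻]ᵢ/[B(OH)₄⁻]ₒ` for the
uniporter and the corresponding product/quotient forms for the other two
modes — all three are algebraically identical via Ka and Kw, so the modes
are thermodynamically indistinguishable. Δμ < 0 favours influx, which the
voltage clamp reads as a positive outward current; Δμ = 0 defines the
equilibrium potential ΔΨ_eq = (RT/F)·ln(r). Transport kinetics follow
saturable Michaelis–Menten dose–response `I = I_max·[B]/(K_m+[B])` and
single-site inhibition `I = I₀·IC₅₀/(IC₅₀+[N])`.

## Worked example

An oocyte a few minutes into a 20 mM boric acid bath holds ~0.1 nmol
boron; in a 0.7 μL cell whose cytoplasm is ~10% of cell volume that is
~1.4 mM at pH 7.1, facing 20 mM at pH 7.5 outside:

```sh
$ boricflux thermo --in-total 1.4 --in-ph 7.1 --out-total 20 --out-ph 7.5
{
 "concentration_ratio": 0.028170529663769338,
 "delta_mu_kJ_per_mol": {
  "B(OH)4- uniport": -8.640836706579199,
  "B(OH)3-OH- cotransport": -8.640836706579199,
  "B(OH)3/H+ exchange": -8.640836706579199
 },
 "equilibrium_potential_mV": -89.55596168271518
}
```

The three candidate modes give the identical ratio (≈0.028, prints as
0.03) and driving force; the concentration gradient is equivalent to a
membrane potential of ≈ −89.5 mV at 18 °C, so a cell resting more
positive than that takes boric acid up, and a cell more negative (or
facing acidic urine) secretes it. `boricflux speciate --total-mm 20
--ph 7.5` shows the underlying split: 19.64 mM B(OH)₃ and 0.36 mM
B(OH)₄⁻.

The numbered drivers under `analysis/` run the full story and write
their tables to `results/`:

| script | what it computes |
|---|---|
| `01_speciation_thermo.py` | worked-example speciation, mode-invariant ratio, ΔΨ_eq |
| `02_cohort_folds.py` | cohort fold ratios (950-, 330-, 31-, 9.5-fold) from the printed group means, plus a moment-matched synthetic cohort |
| `03_charge_stoichiometry.py` | charge-count/molecule-count ratio from the printed accounting (1.1) and from a simulated uptake run (1.000) |
| `04_kinetics_recovery.py` | K_m/I_max and IC₅₀ recovery from synthetic dose–response data, noiseless and noisy |
| `05_end_to_end.py` | full simulate→analyse round trip for transporter and control oocytes |

For example `python analysis/04_kinetics_recovery.py` prints

```
noiseless MM fit: K_m 6.5000 mM, I_max 1.5000 uA (exact recovery)
200 noisy replicates (sigma 0.05 uA): K_m 6.79 +/- 1.35 mM, I_max 1.520 +/- 0.122 uA
noiseless IC50 fit: 67.0000 mM (exact recovery)
200 noisy replicates (5%): IC50 66.7 +/- 7.7 mM
```

i.e. the fitting pipeline recovers the generating half-saturation
constant (6.5 mM), saturating current (1.5 μA) and inhibition constant
(67 mM) exactly on clean data and without bias at realistic noise.

## Layout

- `src/boricflux/` — the library: `speciation`, `thermo`, `ephys`,
  `flux`, `sim`, `pipeline`, plus the `boricflux` CLI (`speciate`,
  `thermo`, `iv`, `charge`, `fit-mm`, `fit-ic50`, `ph-slope`,
  `cohort-summary`, `fold`, `flux-rate`, `simulate`, `make-cohort`,
  `reproduce`, `e2e`).
- `src/boricflux/data/` — printed-value fixtures (cohort means,
  charge-accounting table, kinetic parameters).
- `analysis/` — the numbered narrative drivers above.
- `docs/methods.md` — model assumptions, parameter choices, numerical
  details and limitations.
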