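"""Speciation and thermodynamics of the oocyte worked example.

Speciates both sides of the membrane (1.4 mM/pH 7.1 cytoplasm vs
20 mM/pH 7.5 bath), shows the three transport-mode concentration ratios
collapse to one number, and computes the equilibrium potential at 18 C.
Writes results/01_thermo.json.
"""

import json
from pathlib import Path

from boricflux.speciation import intracellular_concentration, speciate
from boricflux.thermo import (
    MembraneState,
    TransportMode,
    concentration_ratio,
    delta_mu,
    equilibrium_potential,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    # the cytoplasmic concentration follows from ~0.1 nmol in a 0.7 uL
    # oocyte whose cytoplasm is ~10% of cell volume
    conc_in = intracellular_concentration(0.1e-9, 0.7e-6, 0.10)
    print(f"cytoplasmic total boric acid: {conc_in * 1e3:.2f} mM")

    inside = speciate(1.4e-3, 7.1)
    outside = speciate(20e-3, 7.5)
    print(f"outside: B(OH)3 {outside.conc_B_OH3 * 1e3:.1f} mM, "
          f"B(OH)4- {outside.conc_B_OH4 * 1e3:.1f} mM")
    print(f"inside:  B(OH)3 {inside.conc_B_OH3 * 1e3:.2f} mM, "
          f"B(OH)4- {inside.conc_B_OH4 * 1e3:.2f} mM")

    state = MembraneState(inside=inside, outside=outside, delta_psi=0.0)
    ratios = {mode.value: concentration_ratio(state, mode) for mode in TransportMode}
    print("concentration ratios (all modes agree):",
          {k: f"{v:.4f}" for k, v in ratios.items()})

    psi_eq = equilibrium_potential(state)
    print(f"equilibrium potential: {psi_eq * 1e3:.1f} mV "
          "(the membrane hyperpolarizes toward this value when the "
          "transporter dominates)")

    mus = {mode.value: delta_mu(state, mode).delta_mu for mode in TransportMode}

    OUT.mkdir(exist_ok=True)
    (OUT / "01_thermo.json").write_text(json.dumps({
        "inside_mM": {"B_OH3": inside.conc_B_OH3 * 1e3, "B_OH4": inside.conc_B_OH4 * 1e3},
        "outside_mM": {"B_OH3": outside.conc_B_OH3 * 1e3, "B_OH4": outside.conc_B_OH4 * 1e3},
        "concentration_ratio": ratios,
        "delta_mu_kJ_per_mol_at_0mV": {k: v / 1e3 for k, v in mus.items()},
        "equilibrium_potential_mV": psi_eq * 1e3,
    }, indent=1))
    print(f"wrote {OUT / '01_thermo.json'}")


if __name__ == "__main__":
    main()
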