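"""Transport-kinetics parameter recovery.

Generates dose-response currents at the published doses from the
Michaelis-Menten model (K_m 6.5 mM, I_max 1.5 uA) and the single-site
NMDG inhibition model (IC50 67 mM), noiseless and with recording noise,
and fits them back. Writes results/04_kinetics.json.
"""

import json
from pathlib import Path

import numpy as np

from boricflux import ephys, sim

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    rng = np.random.default_rng(SEED)
    doses = np.array([1, 3, 5, 10, 20]) * 1e-3

    clean_fit = ephys.fit_michaelis_menten(doses, sim.generate_mm_currents(doses, 6.5e-3, 1.5e-6))
    print(f"noiseless MM fit: K_m {clean_fit.K_m * 1e3:.4f} mM, "
          f"I_max {clean_fit.I_max * 1e6:.4f} uA (exact recovery)")

    k_ms, i_maxes = [], []
    for _ in range(200):
        noisy = sim.generate_mm_currents(doses, 6.5e-3, 1.5e-6, noise_sd=0.05e-6, rng=rng)
        fit = ephys.fit_michaelis_menten(doses, noisy)
        k_ms.append(fit.K_m)
        i_maxes.append(fit.I_max)
    print(f"200 noisy replicates (sigma 0.05 uA): "
          f"K_m {np.mean(k_ms) * 1e3:.2f} +/- {np.std(k_ms) * 1e3:.2f} mM, "
          f"I_max {np.mean(i_maxes) * 1e6:.3f} +/- {np.std(i_maxes) * 1e6:.3f} uA")

    nmdg = np.array([0, 40, 80, 96]) * 1e-3
    i_0 = 1.5e-6 * 20e-3 / (6.5e-3 + 20e-3)
    clean_inh = ephys.fit_inhibition(nmdg, sim.generate_inhibition_currents(nmdg, 67e-3, i_0))
    print(f"noiseless IC50 fit: {clean_inh.ic50 * 1e3:.4f} mM (exact recovery)")

    ic50s = []
    for _ in range(200):
        noisy = sim.generate_inhibition_currents(nmdg, 67e-3, i_0, noise_fraction=0.05, rng=rng)
        ic50s.append(ephys.fit_inhibition(nmdg, noisy).ic50)
    print(f"200 noisy replicates (5%): IC50 {np.mean(ic50s) * 1e3:.1f} "
          f"+/- {np.std(ic50s) * 1e3:.1f} mM")

    OUT.mkdir(exist_ok=True)
    (OUT / "04_kinetics.json").write_text(json.dumps({
        "seed": SEED,
        "mm_noiseless": {"K_m_mM": clean_fit.K_m * 1e3, "I_max_uA": clean_fit.I_max * 1e6},
        "mm_noisy_mean": {"K_m_mM": np.mean(k_ms) * 1e3, "I_max_uA": np.mean(i_maxes) * 1e6},
        "ic50_noiseless_mM": clean_inh.ic50 * 1e3,
        "ic50_noisy_mean_mM": np.mean(ic50s) * 1e3,
    }, indent=1))
    print(f"wrote {OUT / '04_kinetics.json'}")


if __name__ == "__main__":
    main()
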