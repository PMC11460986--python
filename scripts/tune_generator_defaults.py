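"""Calibration scan behind the synthetic generator's default share-model
parameters.

For a grid of (tiger_share_slope, tiger_share_noise_sd) values this script
evaluates the generator's large-sample (population) statistics — canonical
correlation, predator-side coefficients, single-species slopes and margin
slopes — so the defaults can be chosen to resemble the study system: a
canonical correlation near 0.8, both predator-side coefficients positive,
and a tiger-only slope clearly above the leopard-only slope. The frozen
defaults are slope = 1.0, noise sd = 1.2 (see docs/methods.md).

Run:  python scripts/tune_generator_defaults.py
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import replace

import numpy as np

from predprey import SyntheticConfig, decompose_predators, fit_cca, generate_biomass, margins


def population_stats(slope: float, noise: float, n_obs: int = 100_000, seed: int = 999) -> dict:
    cfg = SyntheticConfig(tiger_share_slope=slope, tiger_share_noise_sd=noise, seed=seed)
    bio = generate_biomass(replace(cfg, n_parks=n_obs, n_years=1))
    decomp = decompose_predators(bio)
    cca = fit_cca(decomp)
    marg = margins(cca)
    lx = decomp.log_prey
    k_tiger = float(np.polyfit(lx, decomp.log_tiger, 1)[0])
    k_leopard = float(np.polyfit(lx, np.log10([r.L for r in bio]), 1)[0])
    return {
        "rho": cca.rho, "alpha1": cca.alpha1, "alpha2": cca.alpha2,
        "k_tiger_only": k_tiger, "k_leopard_only": k_leopard,
        "tiger_margin": marg.tiger_slope, "leopard_margin": marg.leopard_slope,
    }


def main() -> None:
    warnings.filterwarnings("ignore")
    print("reference (study system): rho~0.81, alpha1~0.83, alpha2~0.93, "
          "tiger-only k~0.95 > leopard-only k~0.40")
    header = ("slope", "noise", "rho", "alpha1", "alpha2", "k_t", "k_l", "m_t", "m_l")
    print(("{:>7}" * len(header)).format(*header))
    for slope, noise in itertools.product([0.5, 0.8, 1.0, 1.3], [0.3, 0.6, 0.9, 1.2]):
        s = population_stats(slope, noise)
        print(f"{slope:7.2f}{noise:7.2f}{s['rho']:7.2f}{s['alpha1']:7.2f}"
              f"{s['alpha2']:7.2f}{s['k_tiger_only']:7.2f}{s['k_leopard_only']:7.2f}"
              f"{s['tiger_margin']:7.2f}{s['leopard_margin']:7.2f}")


if __name__ == "__main__":
    main()
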