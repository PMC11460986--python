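"""Joint two-predator analysis: canonical correlation, Wilks' test, margins
and the competition gap.

First reproduces the closed-form results implied by the published
coefficients (no data needed), then runs the full joint analysis on a
synthetic survey.
"""

import warnings

import numpy as np

from predprey import (
    CCAFit,
    McmcConfig,
    SyntheticConfig,
    competition_gap,
    decompose_predators,
    densities_to_biomass,
    fit_all_three,
    fit_cca,
    generate_dataset,
    margins,
    wilks_test,
)

warnings.filterwarnings("ignore")

# --- algebra from the published coefficients ------------------------------
w = wilks_test(rho=0.81, n=15)
print(f"published rho = 0.81, n = 15:  Wilks' Lambda = {w.lambda_:.4f}, "
      f"chi2({w.df}) = {w.chisq:.1f}, p = {w.pvalue:.4f}")
published = CCAFit(alpha1=0.83, alpha2=0.93, rho=0.81, k=0.71, n=15,
                   mean_log_tiger=0.5, mean_log_ratio=0.2, mean_log_prey=3.5,
                   sd_log_prey=0.4, log_prey_range=(3.0, 3.9))
m = margins(published)
print(f"margins from rho*k/alpha: tiger {m.tiger_slope:.3f}, "
      f"leopard {m.leopard_slope:.3f}  (the published 0.70 and 0.62)\n")

# --- full joint analysis on a synthetic survey ----------------------------
biomass = densities_to_biomass(generate_dataset(SyntheticConfig(seed=3)))
fits = fit_all_three(biomass, mcmc=McmcConfig(seed=1))
decomp = decompose_predators(biomass)
cca = fit_cca(decomp, k=fits["total"].k_mean)
w = wilks_test(cca.rho, cca.n)
marg = margins(cca, fits["total"])

print(f"synthetic survey (n = {cca.n}): rho = {cca.rho:.2f}, "
      f"alpha1 = {cca.alpha1:.2f}, alpha2 = {cca.alpha2:.2f}")
print(f"Wilks' Lambda = {w.lambda_:.3f}, chi2({w.df}) = {w.chisq:.1f}, "
      f"p = {w.pvalue:.4f}")
print(f"tiger margin slope = {marg.tiger_slope:.2f} "
      f"(leopards absent), leopard margin slope = {marg.leopard_slope:.2f} "
      f"(tigers held at {marg.tiger_reference:g} kg/km^2)")

x_hi = 10.0 ** cca.log_prey_range[1]
comp = competition_gap(marg, fits["leopard"], np.array([x_hi]), species="leopard")
row = comp.grid.iloc[0]
print(f"\nAt prey biomass {x_hi:.0f} kg/km^2 the leopard margin (tigers near "
      f"absent) predicts {row.margin_pred:.1f} kg/km^2 of leopard biomass vs "
      f"{row.regression_pred:.1f} kg/km^2 from the leopard-only regression "
      "(tigers present): the gap is read as leopard biomass forgone to tiger "
      "competition at prey-rich sites. At n = 15 the margin coefficients are "
      "noisy, so gaps should be interpreted over many surveys, not one.")
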