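# predprey

Predator–prey biomass power-law scaling and two-predator competition
margins for protected-area survey data.

Conservation surveys of Nepal's lowland national parks report tiger and
leopard densities (per 100 km²) and pooled wild-prey densities (per km²).
This package turns such park-year records into biomass densities and asks
whether predators are proportionally sustained by their prey: it fits the
trophic power law

```
y = c · x^k        ⇔        log y = log c + k · log x
```

(`y` predator biomass, `x` prey biomass, both kg/km²) by Bayesian linear
regression with a conjugate Gibbs sampler, and analyses the two predators
jointly with canonical correlation analysis (CCA). The total predator
biomass is split multiplicatively, `log(T+L) = log T + log((T+L)/T)`, and
the fitted relation

```
α₁·log T + α₂·log((T+L)/T) = ρ·k·log x + const
```

yields Wilks' Λ significance for ρ, *margins* — the prey-scaling slope of
one predator with its competitor held at a minimum, `ρ·k/α₁` for tigers
(no leopards) and `ρ·k/α₂` for leopards (tigers at 1 kg/km²) — and the
margin-vs-regression *competition gap*, the biomass a species is predicted
to forgo to its competitor. A seeded synthetic-survey generator makes every
stage testable without field data. Audience: quantitative ecologists and
conservation analysts working with multi-park carnivore/prey survey tables.

## Worked example

`examples/` contains one short script per capability. Converting the
printed 2022 survey table (`examples/01_biomass_conversion.py`):

```
mean prey body mass: 54.43 kg (arithmetic mean of the seven principal prey species)

park  year  tiger_biomass_kg_km2  ...  prey_biomass_kg_km2
 PNP  2022                  3.13  ...              4082.14
 CNP  2022                  7.31  ...              5442.86
BaNP  2022                  1.75  ...              1796.14
 BNP  2022                 12.87  ...              4898.57
ShNP  2022                  3.58  ...              7946.57
```

Tiger biomass (tiger density / 100 × 180 kg) spans 1.75–12.87 kg/km²
against prey biomass (prey density × 54.43 kg) of ≈ 1,800–7,900 kg/km².
Fitting a 15-record synthetic survey generated with exponent k = 0.75
(`examples/02_power_law_fit.py`):

```
total    k = 0.77  (95% CI 0.53-1.02, R-hat 1.000)
tiger    k = 0.89  (95% CI 0.66-1.12, R-hat 1.000)
leopard  k = 0.33  (95% CI -0.31-0.96, R-hat 1.000)
```

The total-predator exponent recovers the generating value; k < 1 is a
biomass pyramid growing more bottom-heavy as prey biomass rises (a
fivefold prey increase yields ≈ 3.5-fold predator biomass here). The
tiger-only slope exceeds the leopard-only slope because the generator, like
the study system, lets the dominant predator take a larger share where prey
are abundant. The joint analysis (`examples/03_joint_competition_analysis.py`)
prints the closed-form results implied by the published coefficients —

```
published rho = 0.81, n = 15:  Wilks' Lambda = 0.3439, chi2(2) = 12.8, p = 0.0017
margins from rho*k/alpha: tiger 0.693, leopard 0.618  (the published 0.70 and 0.62)
```

— then fits CCA, Wilks' test, margins and the competition gap on a
synthetic survey. `examples/04_parameter_recovery.py` runs the
simulate-and-recover study.

The same pipeline is scriptable from the shell:

```
predprey simulate dens.csv --seed 4
predprey report dens.csv out/ --seed 1 --plot
```

writes biomass tables, the three fit summaries, CCA/Wilks/margin results, a
competition grid, a run manifest (input hash, config hash, seed, per-stage
status) and optionally the log-log scaling figure. Re-running with the same
seed and config reproduces every file byte for byte.

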