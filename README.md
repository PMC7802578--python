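# fermkin

Kinetic modelling of batch fermentations that produce l-arabinose
isomerase (l-AI) — the enzyme used industrially to isomerise d-galactose
into the rare sugar d-tagatose. The package was built around the
*Lactobacillus plantarum* WU14 l-AI process: biomass (OD600), reducing
sugar (mg/ml) and enzyme activity (U/ml) sampled every 2 h over a 0–24 h
batch run, each observable described by a closed-form kinetic model
fitted by nonlinear least squares.

## Models

Four model families, each with a closed form, analytic derivative and
(where needed) integral:

* **Boltzmann sigmoid** (biomass, enzyme activity)

  y = (A₁ − A₂)/(1 + e^((t − x₀)/dx)) + A₂

  with early/late asymptotes A₁, A₂, inflection time x₀ and time scale dx.
* **Power-logistic** (reducing-sugar decline)

  y = (A₁ − A₂)/(1 + (t/x₀)^p) + A₂

* **Logistic growth** dX/dt = μₘ·X·(1 − X/Xmax), used in its closed-form
  solution X(t) = X₀·Xmax·e^(μₘt)/(Xmax − X₀ + X₀·e^(μₘt)).
* **Luedeking–Piret** product formation dP/dt = α·dX/dt + β·X, integrated
  in closed form against logistic growth; α is the growth-associated and
  β the non-growth-associated coefficient, and
  `growth_association_fraction` quantifies where a process sits between
  the two regimes.

On top of the models: least-squares fitting with data-driven
initialisation and parameter fixing (`fit_model`), model selection by R²
or AICc (`select_model`), seeded Monte-Carlo parameter-recovery studies
(`recovery_study`), a synthetic time-course generator mirroring the
2-h-interval experimental design (`simulate_timecourse`,
`paper_like_dataset`), and the calibration/yield arithmetic of the
d-tagatose workflow (standard curves, decolorization/recovery/conversion
rates).

## Worked example

Simulate a coherent three-observable dataset at 2% amplitude noise, then
fit and compare growth models for the biomass series:

```python
from fermkin import (
    ModelFamily, Observable, paper_like_dataset, select_model,
)

data = paper_like_dataset(seed=7, noise_sd_fractions=0.02)
biomass = data[Observable.BIOMASS_OD600]
sel = select_model(biomass, [ModelFamily.BOLTZMANN, ModelFamily.LOGISTIC_GROWTH])
print(sel.best.family.value)   # boltzmann
print(sel.best.equation)       # y = 2.62911 + (-2.86841)/(1 + e^((x - 5.36578)/2.16274))
print(f"{sel.best.r_squared:.5f}")  # 0.99844
```

The Boltzmann family wins (R² 0.99844 vs 0.99636 for logistic growth) and
its fitted asymptote A₂ ≈ 2.629 estimates the maximum biomass; the
generating curve had A₂ = 2.62428. The same workflow is available from
the shell:

```sh
fermkin simulate --out sim --seed 7
fermkin fit --biomass sim/biomass_od600.csv --substrate sim/reducing_sugar.csv \
            --enzyme sim/enzyme_activity.csv --out report
fermkin report report/fit_report.json
```

Yield arithmetic example — a conversion run producing 58 g/L d-tagatose
from a 0.8 M d-galactose feed (144.128 g/L):

```python
from fermkin import conversion_rate, molar_to_g_per_l
conversion_rate(58.0, molar_to_g_per_l(0.8, 180.16))  # 40.24 (%)
```

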