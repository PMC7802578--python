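# Methods

## Models and assumptions

The package treats a batch fermentation as three coupled observables on a
common time grid: biomass X(t) (OD600), reducing sugar S(t) (mg/ml) and
product P(t) (enzyme activity, U/ml). Each is modelled by a closed-form
curve; no mechanistic coupling (substrate limitation of growth, pH
effects, operon regulation) is modelled — the families are descriptive
kinetic forms fitted independently, which is how such batch data are
conventionally summarised.

* **Boltzmann sigmoid** `y = (A1 − A2)/(1 + e^((t − x0)/dx)) + A2`.
  A1 and A2 are the early and late asymptotes in the observable's units,
  x0 the inflection time (hr) and dx the transition time scale (hr,
  positive when fitted). The value at t = x0 is exactly (A1 + A2)/2.
* **Power-logistic** `y = (A1 − A2)/(1 + (t/x0)^p) + A2` on t ≥ 0, with
  half-transition time x0 > 0 (y(x0) = (A1 + A2)/2) and dimensionless
  shape exponent p. Negative times are rejected: fractional powers of
  negative reals are undefined.
* **Logistic growth** `dX/dt = μm·X·(1 − X/Xmax)` used via its closed
  form `X(t) = X0·Xmax·e^(μm·t)/(Xmax − X0 + X0·e^(μm·t))`, with
  0 < X0 < Xmax and μm > 0 (1/hr).
* **Luedeking–Piret** `dP/dt = α·dX/dt + β·X` integrated in closed form:
  `P(t) = P0 + α·(X(t) − X0) + β·(Xmax/μm)·ln(1 + X0·(e^(μm·t) − 1)/Xmax)`.
  α (product per biomass) is the growth-associated and β (product per
  biomass per hr) the non-growth-associated coefficient.
  `growth_association_fraction` returns α·X′/(α·X′ + β·X) ∈ [0, 1]; it
  decays to 0 in stationary phase whenever β > 0, the signature of
  non-growth-coupled production.

Numerical guards: sigmoid and growth exponents are clamped to |z| ≤ 700
so extreme times return the exact asymptote instead of overflowing, and
the growth integral uses `log1p/expm1` to keep precision at small t.

## Reference parameter sets

The WU14 fits ship as named constants (`WU14_GROWTH_BOLTZMANN`,
`WU14_LAI_BOLTZMANN`, `WU14_SUBSTRATE_POWER_LOGISTIC`,
`WU14_GROWTH_LOGISTIC`, `WU14_LAI_LUEDEKING_PIRET`, plus the rejected
`WU14_SUBSTRATE_BOLTZMANN_REJECTED`). Conventions and caveats:

* The published parameter *lists* are canonical. Two published equation
  strings disagree with their own lists in the last digits (substrate
  exponent 1.14414 in the list vs 1.14141 in the equation; l-AI A2
  41.94723 vs 41.94732). The constants carry the list values; the
  discrepancy is noted here rather than silently resolved.
* X0 = 0.2 (order of the earliest OD600 reading) and P0 = 0 are this
  package's conventions — the source fits never state them, but the
  closed forms require both. They are explicit required fields, not
  hidden defaults.
* The substrate Boltzmann fit (A1 ≈ 11297, x0 ≈ −31.6) is numerically
  extreme — a flat ridge where only the product of tail parameters is
  identified. It exists only as the rejected alternative and is used by
  no default.
* The published logistic-growth Xmax = 37.77377 far exceeds the observed
  OD plateau (~2.5); it is reproduced as printed for self-consistency,
  not "corrected".

## Fitting

`fit_model` minimises Σ(yᵢ − model(θ, tᵢ))² with
`scipy.optimize.least_squares` (trust-region reflective, bounded), with
xtol = ftol = gtol = 1e−12 and at most 1000 function evaluations. These
settings recover noise-free generating parameters to ~1e−14 relative
while capping the time spent on ridge-shaped misfits (a Boltzmann fitted
to power-logistic-shaped data walks the same flat ridge as the rejected
substrate fit above; the cap stops that walk after a bounded effort and
the fit is reported with `converged = False`). Bounds: dx > 0
(Boltzmann); x0, p > 0 (power-logistic); positivity for growth
parameters and P0 ≥ 0; α, β unbounded — their published values are
positive but the model does not require it.

Initialisation (`default_init`) is data-driven: sigmoids anchor A1/A2 at
the first/last readings, put x0 at the interpolated crossing of
(A1+A2)/2 and scale dx (or p) from the 25–75% transition span
(dx ≈ span/(2·ln 3)); logistic growth starts at the first reading,
1.05× the maximum, and the early log-slope; Luedeking–Piret solves a
non-negative linear least-squares problem for α, β given growth
parameters. A series whose range is below 1e−12 of its magnitude is
degenerate and rejected. The Luedeking–Piret initialiser requires growth
parameters from the caller: the product curve alone cannot separate
μm/Xmax/X0 from α/β, so the workflow fits the biomass series first. By
default the product fit holds {X0, Xmax, μm, P0} fixed and estimates
only α and β — the published product fit reports exactly the growth-fit
μm and Xmax, implying the same scheme; pass `fixed=()` for joint
estimation.

Goodness of fit is plain (not adjusted) R² = 1 − SSres/SStot.
`select_model` ranks converged candidates by R² (default, mirroring the
conventional "fitting degree" comparison) or by AICc — offered because
R² cannot penalise the Boltzmann family's fourth parameter. Scores tied
within 1e−9 go to the family with fewer free parameters, then to list
order; the tie-break matters in practice because logistic growth is a
special case of the Boltzmann sigmoid (A1 → 0, A2 = Xmax, dx = 1/μm),
so both reach R² = 1 on exact logistic data.

## Synthetic data

`simulate_timecourse` draws `model mean + i.i.d. N(0, noise_sd²)` on a
uniform grid, default t = 0, 2, …, 24 hr (13 points) — the sampling
design of the WU14 experiment. Noise is untruncated: negative noisy
readings are preserved because truncation would bias recovery studies.
`paper_like_dataset` produces the three coherent series (biomass from
the Boltzmann growth fit, sugar from the power-logistic fit, activity
from the Luedeking–Piret fit sharing the logistic growth record); pH is
not simulated, as no kinetic model exists for it. One master seed
expands into per-series child seeds via `SeedSequence.spawn` in fixed
series order, so adding a series never changes existing draws. The
default noise level, 2% of each series' amplitude, is a package choice
of realistic assay noise — the true residual level of the WU14 data is
not published.

What the generator does **not** emulate: replicate structure and
pipetting-style heteroscedasticity, measurement rounding, shared-sample
correlation between observables, and any model misspecification — so
passing recovery tests demonstrate correctness of the estimation
machinery under the stated noise model, not robustness of the models to
real fermentation data.

## Bioprocess arithmetic

Standard curves are affine models `absorbance = slope·conc + intercept`
(cysteine–carbazole d-tagatose curve y = 0.0239x + 0.0244; DNS reducing
sugar y = 1.1719x − 0.0194; Coomassie protein y = 8.0597x + 0.0502).
Inverse prediction returns (A − intercept)/slope; readings below the
blank give negative concentrations returned *with a warning* rather
than clamped, keeping the transform invertible and surfacing blank
problems. Decolorization/protein-removal rates are
(before − after)/before × 100; recovery is out/in × 100 and composes
multiplicatively across chained steps; conversion is product/substrate
feed × 100 on a g/L basis. `convert_volumetric_rate` applies the exact
unit identity mg/(ml·hr) × 24 = g/(L·d); note the WU14 report prints
2.5338 mg/(ml·hr) alongside 49.68 g/(L·d), which are mutually
inconsistent by ~1.22 — the converter reproduces the algebra, not the
printed pairing. One enzyme unit (U) is never defined in the source
workflow, so no operation converts absorbance directly to U/ml; activity
quantification stays at calibration plus user-supplied normalisation.

## Validation scale

The test suite validates closed forms against independent oracles
(arbitrary-precision evaluation via sympy; Runge–Kutta ODE integration
and adaptive quadrature via scipy) over 100 random parameter draws,
noise-free self-consistency recovery of every reference parameter set
on the 13-point grid at 1e−6 relative tolerance, and stochastic
properties (RMSE monotonicity in noise, ≥95% correct family selection
at 1% amplitude noise) with 200 seeded replicates — sizes chosen to
make Monte-Carlo outcomes stable under the fixed seeds.

## Known limitations

* Single-response least squares only: no confidence intervals, no
  heteroscedastic or correlated error models, no joint multi-observable
  fitting.
* R² selection cannot penalise complexity; AICc is provided but the
  default mirrors the conventional comparison.
* The closed-form Luedeking–Piret requires logistic growth; it cannot be
  paired with the Boltzmann biomass description (no closed-form
  integral with nonzero lower asymptote is provided).
* Time is hours everywhere; unit conversions live in the metrics module.
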