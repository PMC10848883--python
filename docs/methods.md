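# Methods

## The model

`spectralife` couples three standard pieces of quantitative fish ecology into
one optimization:

1. **Size-spectrum trophic environment.** In aquatic communities the
   abundance of organisms scales inversely with body mass
   (N(w) = κ w^λ, λ ≈ −1). For an individual of structural mass w (kg) this
   fixes both its prey field and its predator field. Integrating the prey
   side of the spectrum gives monthly available prey biomass
   B_prey(w) = 3 κ w^0.05 (kg); integrating the predator side gives an
   instantaneous predation mortality μ_p(w) = 0.07 h w^(−0.25). κ scales the
   whole spectrum and is read as ecosystem productivity; h scales predator
   capture efficiency. The exponents and the coefficients 3 and 0.07 are
   literature constants of those derivations and are not meant to be tuned
   (they are exposed for stress-testing only).

2. **Metabolic costs.** Monthly maintenance follows the metabolic theory of
   ecology: C(w, τ) = c w^θ exp(−E/(k_B τ)) joules, with mass exponent
   θ = 0.66 and normalization c calibrated for tunas, activation energy
   E = 1.04e−19 J, and τ in Kelvin. Public interfaces take Celsius and
   convert internally (+273.15); `metabolic_cost` itself rejects τ < 200 K
   to catch unit mistakes.

3. **State-dependent allocation.** The individual's state is body length l
   (cm, irreversible) and lipid stores s (J). Structural mass is w = a l³.
   Each month, fractions g and r of the stores are allocated to growth and
   reproduction (g + r ≤ 1; the remainder is carried forward). Growth
   converts energy to structural mass via the tissue energy density ρ:
   l' = (l³ + g s/(a ρ))^(1/3). The store balance is
   s' = (1 − g − r)s + ρ B_prey(w) − C(w, τ), floored at zero and capped at
   60% of structural-mass energy; reproduction is capped by gonad capacity,
   r s ≤ φ w ρ. Starvation survival is a logistic in s' around the critical
   level υ w ρ; predation survival multiplies in as exp(−μ_p/12) per month
   (see "Mortality timescale" below). Fitness is expected lifetime
   reproductive energy; the optimal policy is found by backward induction of
   V(l,s,t) = max_{g,r} [ r s + γ_pred γ_s V(l',s',t+1) ] with
   V(·,·,T) = 0, and a cohort is then iterated forward from birth.

Current-month reproduction is credited before the month's survival is
applied (it sits outside the survival product in the recursion). A visible
consequence is a terminal "spawn-dump": in the last months of the horizon
the optimal policy spends the starvation buffer on reproduction and accepts
death, since there is no future to protect.

## Parameters

| symbol | field | default | units | meaning |
|---|---|---|---|---|
| κ | `SpectrumParams.kappa` | varies | kg/month | spectrum scale = ecosystem productivity |
| h | `SpectrumParams.h` | 8 | – | predator capture efficiency (presets use 8 or 12) |
| c | `MetabolicParams.c` | 5e16 | J | metabolic normalization (tuna) |
| θ | `MetabolicParams.theta` | 0.66 | – | metabolic mass exponent (tuna) |
| E | `MetabolicParams.E` | 1.04e−19 | J | activation energy |
| k_B | `MetabolicParams.kB` | 1.3e−23 | J/K | Boltzmann constant, truncated to match the calibration of c |
| a | `BodyParams.a` | 1e−5 | kg/cm³ | length–mass coefficient |
| ρ | `BodyParams.rho` | 4.2e6 | J/kg | tissue energy density |
| υ | `BodyParams.upsilon` | 0.1 | – | starvation threshold (fraction of structural-mass energy) |
| φ | `BodyParams.phi` | 0.2 | – | monthly gonad-capacity fraction |
| – | `BodyParams.store_cap_frac` | 0.6 | – | lipid-store ceiling (fraction of structural mass) |
| – | `BodyParams.birth_length` | 10 | cm | natal state (age-0 juvenile recruit) |
| – | `BodyParams.birth_store_frac` | 0.1 | – | natal stores (at the starvation threshold) |
| T | `BodyParams.t_max` | 216 | months | horizon / maximum lifespan |
| – | `BodyParams.max_length` | 400 | cm | hard length ceiling |

Temperatures in scenario interfaces are Celsius; the factorial experiment
spans 11.85–26.85 °C (285–300 K) in 5 °C steps, productivity κ in 0.25–5.

### Mortality timescale

The mortality allometry 0.07 h w^(−0.25) is treated as accumulating over a
year: monthly predation survival is exp(−μ_p/12)
(`SpectrumParams.mort_timescale_months`, configurable). Read instead as a
purely monthly rate, a 16 kg fish with h = 8 would have 3.5% *annual*
survival and a juvenile recruit a monthly mortality near 1; no fish life
history with multi-year lifespans exists in that regime, and solving the
model there confirms it (sub-year cohort lifespans, essentially zero
lifetime reproduction). Under the annual reading the same coefficients give
monthly survivals of 0.86 (10 cm juvenile) to 0.99 (400 cm adult) and
realistic decade-scale lifespans. Emergent body size is only weakly
sensitive to this choice (~20% in length between the two extreme readings);
lifespans and reproductive output are strongly sensitive, and only the
annual reading produces biologically meaningful ones.

### Starvation sigmoid steepness

The steepness q of the starvation sigmoid is scale-relative by default: the
survival probability rises from 0.01 to 0.99 over 1% of the threshold energy
υ w ρ (`BodyParams.sigmoid_rel_width`), evaluated at the post-transition
length. This approximates a step function equally sharply at all body sizes,
which is the intended limit of the smooth penalty; an absolute q (J⁻¹) can
be supplied instead.

### Natal state

Cohorts start at 10 cm with stores at the starvation threshold. The monthly
timestep and kg-scale allometries cannot resolve mm-scale larvae, and the
predation allometry extrapolated to a 1 cm fish gives monthly mortality
rates near 1, which would truncate every cohort within months. Emergent
maximum size is a property of the policy, not the natal state (verified: a
1 cm start changes asymptotic length by < 0.1%); lifespan and survivorship
do depend on it.

## Numerical scheme

- **State grid.** 200 geometrically spaced lengths from birth length to
  400 cm × 51 uniform store fractions on [0, 0.6]. Stores are gridded as a
  fraction of structural-mass energy so every node is meaningful at every
  length. Defaults solve one scenario in a few seconds; doubling the
  resolution changes emergent maximum lengths by well under 1% (checked at
  200×51, 300×101 and 400×151).
- **Allocation set.** A simplex lattice of (g, r) pairs at 0.05 resolution
  (231 pairs), plus two state-exact pairs at the gonad-capacity cap,
  (0, r_cap) and (1 − r_cap, r_cap) with r_cap = min(φwρ/s, 1). Without the
  cap pairs the value function is saw-toothed in stores — a state with more
  stores can be unable to spawn the same absolute amount on the lattice —
  with dips of tens of percent near the horizon; with them the residual
  non-monotonicity is bounded by ordinary lattice granularity (a few percent
  at n_alloc = 5, shrinking with refinement).
- **Interpolation.** Successor states are evaluated by bilinear
  interpolation in (length, store fraction). On-grid successors reproduce
  nodal values bit-exactly, which is what makes exact oracle comparisons
  possible (below).
- **Tie-breaking.** Allocations within 1e−12 relative of the maximum are
  resolved toward higher r, then higher g — deterministic policies, no
  fitness effect.
- **Infeasible states.** Allocations violating the spawning mask or gonad
  cap are excluded from the maximization (−inf candidates); states whose
  store balance is negative even at g = r = 0 are inviable and carry V = 0.
- **Determinism.** There is no stochastic component anywhere; identical
  configurations produce byte-identical outputs.

## Verification strategy

The backward induction is verified against an independent brute-force
oracle: on 6-month toy instances with a 3-point allocation set, every
allocation sequence is enumerated recursively on the continuous state and
the maximum compared with the grid solution. Toy grids are built by closing
the reachable state set under all sequences, so every successor of a
reachable node lands exactly on a node and interpolation is exact; the two
computations then agree to 1e−12 relative. The forward pass is checked
against per-month energy conservation (ρ B_prey = C + growth energy +
reproduction + Δstores whenever no cap binds) and against the dynamic
program itself (lifetime reproductive output accumulated forward matches
V at the birth state to interpolation error, typically < 0.5%).

## What the scenario suite does and does not emulate

The environment schedules are idealized 12-month step functions: constant
scenarios, two-season scenarios (a warm block and a cold remainder), and
three tuna-lifestyle presets. Seasonal contrast scenarios hold yearly-mean
temperature and productivity fixed while varying what fluctuates and how
long spawning is permitted; winter temperatures are chosen so the 12-month
mean matches the 16.85 °C constant baseline, and winter productivity is
threefold summer with the stated yearly mean. Real seasonality is smooth,
spatially structured, and correlated with temperature through mechanisms
(activity, encounter rates) deliberately excluded here; passing scenario
tests therefore demonstrates properties of the idealized model, not
forecasts for real stocks. Offspring size–number allocation, migration cost
accounting beyond its inclusion in reproductive output, temperature effects
on encounter/clearance rates, and fishing mortality are all out of scope.

## Emergent results the tests pin down

- Asymptotic growth emerges without being assumed: monthly length increments
  fall below 0.1% and stay there, after fast early growth.
- Maximum length, lifetime reproductive output and lifespan all increase
  with κ; a 10 °C warming step shrinks maximum length by at most ~10%
  (largest losses in the least productive environments).
- Allocation shifts from growth to reproduction with age; maturation timing
  emerges (first reproduction late in year 1 to year 2).
- Restricting spawning to 3 months of the year produces strictly larger
  maximum sizes than 6-month or year-round spawning at matched yearly-mean
  conditions — the seasonal-gigantism result; the temperate preset shows
  emergent capital breeding (stores accumulate to the cap over winter and
  are spent across the spawning window).

## Known limitations

- The three constant-environment lifestyle presets underpredict the
  emergent maximum sizes relative to their nominal targets (≈52 vs 62 cm;
  ≈155 vs 214 cm; the seasonal preset lands within 15%: ≈310 vs 361 cm).
  The shortfall is robust to grid and allocation refinement and to the
  mortality-timescale reading, so it reflects some unstated detail of the
  original calibration rather than discretization; all coefficients here
  are fixed a priori and none is fitted to the targets.
- Under the annual mortality reading, cumulative predation hazard over the
  full 216-month horizon still exceeds 3 even for the largest fish, so very
  late survivorship (e.g. >10% of a temperate cohort alive at 18 years)
  is not attainable at any natal state.
- The value function is non-decreasing in stores only up to allocation
  granularity (see Numerical scheme).
- Mortality enters fitness and survivorship as expected-value discounting;
  there is no individual-level Monte Carlo mode.
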