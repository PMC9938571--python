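# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## Multimorbidity-weighted burden index and state discretisation

The burden index of a person at a wave is the sum of positive severity
weights over the chronic conditions reported by then (conditions are
reported cumulatively, so the index is non-decreasing over a person's
waves). The weights are configuration input (`DiseaseWeightTable`, YAML or
two-column CSV): the package deliberately ships no literature weights. A
synthetic 14-disease table (`morbistate.simulate.default_weight_table`)
exists for tests and examples only; its names mirror the chronic-condition
checklist of a CHARLS-like survey, its weights are invented.

All `2^d` disease subsets ("clusters") are enumerated exhaustively (refused
above d = 20) and the index line is split into `k = 5` ordered states by an
exact one-dimensional k-means. Because optimal 1-D clusters are contiguous
in sorted order, the global minimum of the within-cluster sum of squares is
found by dynamic programming over split points on the distinct values with
multiplicity weights — deterministic, no seed, unlike Lloyd iterations.
State boundaries are midpoints between adjacent-cluster extremes; intervals
are half-open `[lower, upper)` with a value exactly on a boundary assigned
to the higher (more severe) state — an arbitrary but fixed tie rule.

Two clustering bases are supported: the enumerated cluster index values
(each distinct attainable value once) or the observed person-wave values.
The pipeline defaults to **observed** values: on realistic cohorts the
attainable range (sum of all weights, ≈ 44 in the synthetic table) extends
far beyond the range people actually occupy (≲ 15), so boundaries fitted on
cluster values would place nearly everyone in S1 and leave the progression
model without events. Fitting on observed values spreads the cohort over
S1–S5. `kmeans_fit_on="clusters"` restores the other convention.

Multimorbidity itself is defined as ≥ 2 concurrent conditions, independent
of the weights.

## Time-to-multimorbidity survival analysis

Event time is the years from baseline to the first wave at which ≥ 2
conditions are reported — the wave offset itself, not an imputed midpoint,
because diseases are dated by report wave. Participants multimorbid at
baseline are excluded (incident-case analysis); participants never reaching
two conditions are censored at the last observation alive; death before
multimorbidity censors at the exact death time.

The Cox model is fitted by lifelines (Efron tie correction — ties are heavy
on the wave grid — Newton iterations run to a step-norm precision of 1e-14
so that the score at the optimum vanishes to ~1e-6, which the tests
assert via the Schoenfeld-residual sum). Kaplan–Meier curves use Greenwood
variance with exponential-Greenwood (log-log) bands. Proportionality is
tested on Schoenfeld residuals against the event-time *rank* transform by
default (identity and log available): per-covariate 1-df score tests from
lifelines, plus a global p-df test in the Grambsch–Therneau form
`T = z' Var(z)^{-1} z` with `z = Σ_k (g_k − ḡ) u_k` and
`Var(z) ≈ Σ(g−ḡ)² · I(β̂)/m`, which lifelines does not provide.

## Progressive multistate model

States S1 … S5 are ordered burden levels, S6 is absorbing death. The model
is a continuous-time Markov chain whose allowed moves are forward-only:
default is every `r < s` living pair plus death from every living state; a
restricted stepwise set (`S_i → S_{i+1}` plus deaths) is one switch away,
and transitions without a single supporting observed pair are dropped with
a warning. The progressivity assumption mirrors retrospective disease
histories: reported burden can only stay or rise.

Intensities are log-linear in covariates, `q_rs(z) = q0_rs exp(β_rs·z)`,
i.e. proportional intensities with per-transition effects, so `exp(β_rs)`
is a per-transition hazard ratio. The likelihood is the standard panel
(interval-censored) form: consecutive living observations contribute
`P_{s_i s_{i+1}}(Δt; z)` with `P(t) = expm(Q t)`; an exactly dated death at
`T` contributes `Σ_s P_{r s}(T − t_last) q_{s,death}(z)` (the state just
before death is unobserved). Death can instead be treated as
interval-censored via `exact_death_times=False`.

Age enters as a covariate updated annually: each observation interval is
split at whole years since baseline and the intensities are held constant
within each one-year segment (a piecewise-constant approximation rather
than a genuinely time-inhomogeneous model). Internally age is centred at
60 and measured in decades — pure reparameterisations that condition the
optimisation; all public interfaces take raw age in years.

Numerics: for speed the likelihood stacks one generator per distinct
covariate vector and takes a single vectorised eigendecomposition
(progressive generators are triangular, so eigenvalues are the diagonal);
any matrix whose decomposition fails to reconstruct the generator to
near machine precision (defective cases, e.g. tied diagonal rates) falls
back to scipy's scaling-and-squaring `expm`, which is also the
implementation behind the public `transition_probability`. Log-intensities
are capped at 5 (annual rates ≤ e^5) to keep line-search excursions from
overflowing the exponential; the cap is far above any plausible rate.
Optimisation is L-BFGS-B with central-difference gradients and box
constraints (log-rates in [−15, 5], effects in [−10, 10]): the boxes stop
monotone-likelihood directions — a transition with no events in one
exposure group has its MLE at infinity — at a finite boundary, which
surfaces as a hazard ratio ≈ 0 (or huge) with an unbounded Wald interval.
Standard errors come from the inverse observed information, computed by
central finite differences (relative step 1e-5) on the working scale;
a singular information matrix triggers a pseudo-inverse with per-parameter
flags. Starting values are crude occurrence/exposure rates with null
covariate effects.

## Multistate life table

For each age `x` in `[45, ω)` (closure age ω = 110), the one-year matrix
`P_x = expm(Q(z, age = x))` advances a synthetic cohort of `radix = 100,000`
persons starting (by default) all in S1 at 45. Person-years use the linear
within-interval convention `L(x, s) = (l(x, s) + l(x+1, s))/2`; survivors at
ω are credited `a_ω = 0.5` further years. Then

    LE(x)  = Σ_{y ≥ x} Σ_{s living} L(y, s) / Σ_{s living} l(x, s)
    HLE(x) = same with s restricted to the healthy set,

and years of healthy life lost is `LE − HLE ≥ 0`. All of radix, ω, `a_ω`,
starting distribution and healthy set are configurable. The healthy set
defaults to `{S1}`; since the survey concept behind "healthy" is not
intrinsic to the model, summaries can be produced for any candidate set
(`{S1}`, `{S1,S2}`, …) and the tests check `HLE ≤ LE` for all of them.
Discretisation error is controlled by the exact `expm` within each one-year
step; LE under a constant hazard μ agrees with 1/μ to within the half-year
convention. No interval estimates are attached to LE/HLE: only
seed-replicate spread is available (bootstrap is out of scope).

The cross-check for the whole recursion is a 100,000-path microsimulation
(`microsimulate_occupancy`) stepping each path through the same annual
matrices and accumulating person-years with the same trapezoid convention
— a stochastic route that shares no code with the matrix recursion.

## Synthetic-cohort generator

The generator defines the study conditions the package is validated under:
6,800 participants by default (500 in the smoke run), baseline ages drawn
from `45 + 45·Beta(1.5, 6)` (right-skewed, ≈ 95% below 65, matching the
age structure of the motivating cohort), a two-way-relationship probability
of 0.60 (the observed 40/60 split), waves at 0/2/4/7 years, binary and
categorical covariates with plausible marginals, deaths exactly dated, all
other transitions interval-censored.

*State mode* draws each participant's path from a known `IntensityModel`
by competing exponential clocks (next-jump time exponential at the total
outflow rate, destination categorical in proportion to the intensities),
optionally with annually updated age to match the fitting convention; it
is the parameter-recovery workhorse. *Disease mode* draws per-disease
onsets from constant annual hazards (multiplied by 0.83 for the two-way
group by default — the study's effect size used as a simulation setting),
baseline prevalences for prevalent conditions, and a Gompertz-like
mortality `λ(t) = λ0 exp(0.09·(age−60) + 0.12·n_conditions)` with
λ0 = 0.008/yr, sampled piecewise-constantly between whole years and onset
times. Hazards and prevalences are chosen for structural realism (roughly
half the at-risk cohort develops a second condition within seven years);
no attempt is made to match published per-disease prevalences.

Reproducibility: one root seed per cohort, split per participant by counter
(`default_rng([seed, i])`), so participant draws are independent of cohort
size and ordering; the same config and seed give byte-identical CSVs.

Participants with prevalent conditions at baseline simply start in a higher
burden state; the multistate likelihood conditions on the first observed
state, so both "exclude prevalent" and "start higher" conventions are
supported downstream (`exclude_baseline_multimorbid_from_msm`).

What passing tests do *not* show about real data: the generator has
time-constant onset hazards, independent diseases, no recovery or
misreporting, no dropout other than death, and exposure effects that act
exactly through the assumed log-linear form — so recovery results
demonstrate correctness of the estimators under the model, not robustness
to the many ways real survey data violate it.

## Descriptives and inclusion filtering

Baseline covariate-by-group tables report counts, column percentages (one
decimal) and chi-square tests: Yates-corrected Pearson for 2×2 tables,
plain Pearson otherwise — the convention that reproduces the published
two-group descriptive statistics from their printed counts. Inclusion
criteria are applied in order with a per-criterion attrition log
(25,586 → 6,799 eligible → −23 abnormal outcomes → −8 missing covariates
→ 6,768 in the reference flow).

## Problem sizes

The test suite and acceptance script use: 2,000–4,000 participants for
single-fit recovery checks; 100 seeded replicates at n = 3,000 on a
three-state progressive space (S1 → S2 carrying the 0.83 exposure hazard
ratio, death from both living states) for Wald coverage; 200 replicates at
n = 250 for the Schoenfeld type-I error; 100,000 paths for the life-table
microsimulation; a 500-participant cohort for the end-to-end pipeline run
and 1,500 for the acceptance pipeline. These sizes make the Monte-Carlo
standard errors small relative to the tolerances tested while keeping each
block in the minutes range on one CPU.

## Known limitations

- No survey weights, left truncation, time-varying covariates (beyond
  annually updated age), frailty, or hidden-state misclassification.
- Breslow tie handling is not exposed (Efron only, via lifelines).
- Wald inference throughout; no profile likelihood or bootstrap.
- The piecewise-annual age update approximates a time-inhomogeneous
  process; within-year age effects are ignored.
- LE/HLE carry no uncertainty intervals.
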