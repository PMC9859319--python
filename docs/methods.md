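# Methods

This note records the modelling choices behind `ecohealth`: the estimators,
their assumptions, the parameters that matter, what the synthetic data do
and do not emulate, and the numerical details a maintainer would need.

## Eco-efficiency: non-oriented SBM with undesirable outputs

Each region-year is a decision-making unit (DMU) with m = 3 inputs (labor,
capital, energy), s₁ = 1 desirable output (GDP) and s₂ = 3 undesirable
outputs (SO₂, wastewater, solid waste).  The score of unit *o* is the
optimum of the fractional program

    min ρ = [1 − (1/m) Σ sᵢ⁻/xᵢₒ] / [1 + 1/(s₁+s₂)(Σ sᵣᵍ/yᵣₒᵍ + Σ sᵣᵇ/yᵣₒᵇ)]
    s.t.  xₒ = Xλ + s⁻,   yₒᵍ = Yᵍλ − sᵍ,   yₒᵇ = Yᵇλ + sᵇ,   λ, s ≥ 0,

solved after the Charnes–Cooper substitution (multiply all variables by a
scalar t ≥ 0 chosen so the denominator equals 1) as a single LP with HiGHS.
Properties that the test suite verifies: ρ ∈ (0, 1]; ρ = 1 exactly for
undominated units; invariance to rescaling any column across all DMUs;
weak monotonicity in inputs and undesirable outputs.

Choices:

- **Returns to scale** — constant by default; variable (convexity
  constraint Σλ = 1) by flag.  Regional efficiency studies use both; CRS is
  the simpler baseline and the fixtures are constructed to be
  frontier-exact under either.
- **Frontier pooling** — per-year cross-sectional frontiers by default, so
  the efficiency series of a region is comparable year by year against its
  contemporaries; a pooled (all region-years) frontier is available.
- **Numerical zero** — a relative slack below 1e−7 is treated as zero and
  the score snapped to exactly 1, so "efficient" is a decidable predicate.
- The SBM LP can have alternate optima (different slack patterns with the
  same ρ); only ρ and the slack/score consistency identity are contractual.

## LS-SVM regression

Training solves the bordered KKT system

    [0  1ᵀ       ] [b]   [0]
    [1  Ω + I/γ  ] [α] = [y],    Ω_ij = exp(−‖xᵢ−xⱼ‖²/2σ²),

by block elimination on the symmetric positive-definite A = Ω + I/γ
(Cholesky; with A ν = 1 and A η = y, b = 1ᵀη / 1ᵀν and α = η − b ν).  The
test suite checks the result against an independent dense solve of the full
bordered system on random instances, and checks Σα = 0 and the KKT residual
to 1e−8 relative.  A condition estimate above 1e12 triggers a warning; the
γ → ∞ interpolation limit is only numerically reachable when the Gram
matrix itself is well conditioned (closely spaced 1-D designs are not).

Leave-one-out residuals are computed in closed form, yᵢ − ŷᵢ^(−i) =
αᵢ/(M⁻¹)ᵢᵢ from a single factorization of the bordered matrix M
(Cawley–Talbot identity); the explicit n-refit path serves as its oracle in
the tests.

**Feature scaling.**  Predictors are standardized to zero mean / unit
variance using the training years only (holdout years are transformed with
the training statistics); targets stay on their original scale.  An RBF
kernel over raw units spanning four orders of magnitude would be
meaningless.

## Hyperparameter search

The tuning objective G(σ, γ) is the mean squared forecast residual,
computed in one of three modes:

- `train` — residuals of the fit on its own training points: the literal
  minimized-average-of-squared-errors objective;
- `holdout` — residuals on the last block of training years;
- `loocv` — exact leave-one-out residuals (default in the pipeline).

The search is a stochastic hill-climb from (σ₀, γ₀) = (1, 10): propose a
random additive step, accept iff G does not increase (ties accepted), stop
when G ≤ ε (default 0) or after `max_iter` (default 300) iterations.  Two
proposal modes:

- `one_sided` — both steps drawn from U(0, 1), the formulation the
  procedure was originally stated with; strictly positive steps can only
  ever *increase* σ and γ, a one-directional drift.
- `symmetric` (default) — steps from U(−δσ, δσ) × U(−δγ, δγ) with proposals
  outside the positive orthant rejected.  Default half-widths (0.5, 50):
  on standardized predictors useful kernel widths live in an O(1) range,
  while the objective is flat in γ over hundreds of units, so γ steps must
  be able to cross that plateau within the iteration budget.

**Why LOOCV is the pipeline default.**  With ~12 training years the
training-error objective is degenerate: it is non-increasing in γ and
shrinks with σ, so the climb drifts toward an interpolating fit whose
kernel width does not generalize.  Measured on the default synthetic study
(30 regions × 15 years, 5% noise, outcomes on all 7 predictors), train-mode
tuning left the 7-predictor model barely ahead of the single-predictor one,
whereas leave-one-out tuning selects σ ≈ 3–5 in the 7-D standardized space,
halves holdout error, and makes the multi-factor advantage uniform across
outcomes and seeds.  The train-mode objective remains available (and is
itself a tested contract).

The acceptance check compares the symmetric search (2000 iterations)
against a 100×100 log-grid oracle on a 12-point toy with sharp structure
plus noise, whose leave-one-out objective has an interior optimum; the
search matches the grid minimum within 5% on ≥ 4 of 5 seeds.

## Forecasting experiment

Per (region, outcome, variant) cell: split chronologically (default last 3
years held out, ≥ 4 training years enforced), standardize predictors on the
training years, search (σ, γ), refit, predict the holdout, and report

    MPE = (1/T) Σ (yₜ − ŷₜ)/yₜ       (signed — no absolute value),
    MSE = (1/T) Σ (yₜ − ŷₜ)²,   SDE = √MSE.

Each of the five outcomes is an independent scalar model; the three
predictor sets are nested (1 ⊂ 2 ⊂ 3, with 1, 4 and 7 predictors).  Every
cell derives its RNG stream from (seed, region, outcome, variant), so
results are independent of panel row order and reruns are bit-identical.
Aggregate rows are arithmetic means over regions; an optional national
aggregate series is forecast like a region but excluded from the means.

**Stability analysis.**  "Average degree" and "variation degree" are
interpreted as follows: for each error criterion, form the per-region
series of single-year errors over the holdout horizon (percentage error
for MPE, squared error for MSE, absolute error for SDE), take absolute
year-over-year changes, and report their mean (average degree) and
population standard deviation (variation degree) pooled over regions.
Lower values mean the forecast error drifts less over time.  This is a
declared interpretation — the quantities are named but not formalized in
the literature the pipeline follows — and is flagged as such here.

## Synthetic panels

The generator emulates a provincial yearbook panel: a balanced P × N grid
(default 30 × 15, starting 2002) in which each region draws its own
trajectory and response parameters from seeded distributions.

- **Eco-efficiency** follows a smooth path in (0, 1): base U(0.30, 0.70),
  mild trend U(−0.05, 0.15) over the period, and a low-frequency
  oscillation of amplitude U(0.05, 0.15), clipped to [0.05, 0.99].
- **Controls** combine a mild exponential growth trend (rate ≤ 0.25 over
  the period) with a dominant oscillation (relative amplitude 0.08–0.18).
  The oscillation is deliberate: it keeps late-sample values on the support
  of the training years, so the generating dependence is recoverable by a
  kernel method.  A pure growth trend would make every holdout year an
  extrapolation and no method could demonstrate recovery.
- **Outcomes** are y = scale · exp(0.5 g) with
  g = β·sat(REE) + c·Σⱼ γⱼ zⱼ (centered), where sat(r) = r/(0.3+r) is a
  monotone saturating link (a `linear` option exists for oracle tests),
  zⱼ are the region's standardized controls, β ~ U(0.6, 1.4),
  γⱼ ~ N(0, 0.25), and c is `control_strength` (0 makes outcomes depend on
  REE alone).  Noise is multiplicative, y·(1 + noise_sd·ε) with ε standard
  normal truncated at ±4σ; default noise_sd = 0.05.  Outcome scales are
  loosely matched to the field's reporting units (10⁸ visits, 10⁴ persons).
- **DEA columns** are independent smooth positive trends; the frontier
  fixture (`generate_dea_frontier_panel`) instead builds each year's units
  on a single efficiency ray (positive rescalings of one base unit, which
  no conic or convex combination can dominate) plus dominated copies with
  inputs and undesirable outputs inflated by known factors.

What the generator does **not** emulate: spatial correlation between
regions, structural breaks, inflation in monetary series, or any
distributional match to real provincial data.  Passing recovery tests
therefore show that the pipeline identifies the structure it assumes —
not that real health-demand series are this predictable.

## Problem sizes and runtime

Default experiment: 30 regions × 15 years, 5 outcomes, 3 variants
(450 cells), search capped at 300 iterations — a few seconds per variant
on one CPU with the closed-form LOOCV objective.  The SBM stage solves one
LP per region-year (450 LPs for the default panel).  The acceptance script
runs every stage, including a 10,000-point grid oracle, in well under a
minute.

## Known limitations

- The SBM LP reports one optimal slack pattern among possibly many;
  downstream code must not attach meaning to individual slacks of
  efficient-adjacent units.
- The stochastic search is a local optimizer; with additive steps it
  cannot traverse σ–γ valleys that require correlated multi-scale moves.
  The grid-oracle acceptance bounds its practical gap on a representative
  toy, not in general.
- With 12 training years, holdout errors on noisy multi-predictor panels
  remain large in absolute terms (tens of percent); the scientific claim
  the pipeline supports is comparative (more predictors, lower error), not
  absolute accuracy.
- Percentage errors require strictly positive outcome series; the
  generator guarantees this only for noise_sd ≲ 0.2 (noise is truncated at
  four standard deviations).
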