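# ecohealth

Forecasting regional public-health demand from eco-efficiency.

`ecohealth` implements a complete panel-forecasting workflow for the
question: *how well does a region's eco-efficiency predict the demand for
its health services?*  Demand is proxied by five hospital-activity series —
visits to hospitals (VTH), outpatients with emergency treatment (OWET),
inpatients (NI), health examinations (NOHE) and patients discharged (PD) —
observed for P regions over N years.  The workflow has four stages:

1. **Eco-efficiency (REE).**  Each region-year is a decision-making unit
   converting inputs (labor, capital, energy) into a desirable output (GDP)
   and undesirable outputs (SO₂, wastewater, solid waste).  The non-oriented
   slacks-based measure (SBM) with undesirable outputs scores each unit

   ρ = [1 − (1/m) Σᵢ sᵢ⁻/xᵢ₀] / [1 + 1/(s₁+s₂) (Σᵣ sᵣᵍ/yᵣ₀ᵍ + Σᵣ sᵣᵇ/yᵣ₀ᵇ)] ∈ (0, 1],

   linearized with the Charnes–Cooper transform and solved as one linear
   program per unit (HiGHS).

2. **Kernel regression.**  Per region and outcome, a least-squares support
   vector machine with RBF kernel K(x, x′) = exp(−‖x−x′‖²/2σ²) is trained by
   solving the dual KKT system [[0, 1ᵀ], [1, Ω + I/γ]]·[b; α] = [0; y];
   prediction is ŷ(x) = Σᵢ αᵢ K(x, xᵢ) + b.

3. **Hyperparameter search.**  (σ, γ) are tuned by a seeded stochastic
   hill-climb: propose additive random steps, accept whenever the squared-
   error objective G(σ, γ) does not increase, stop at tolerance ε or the
   iteration cap.  G can be the training mean squared residual (the literal
   objective), a holdout error, or the exact closed-form leave-one-out
   error (the pipeline default).

4. **Evaluation.**  The last 3 years per region are held out.  Forecast
   accuracy over the holdout horizon T is reported as MPE (signed mean
   percentage error), MSE and SDE = √MSE, for three nested predictor sets:
   variant 1 = {REE}; variant 2 = + GDP per capita, urbanization, population
   density; variant 3 = + medical personnel, licensed doctors, health-care
   institutions (7 predictors).  A stability analysis summarizes the
   year-over-year movement of each error series (average degree = mean
   absolute change, variation degree = its standard deviation).

Real yearbook panels of this kind are not redistributable, so the package
ships a seeded synthetic-panel generator with the same structure — smooth
region-heterogeneous trends, a known (optionally nonlinear) dependence of
each outcome on REE and the controls, multiplicative noise — and records
the noiseless truth so that every stage can be validated by recovery tests.

## Worked example

```python
import numpy as np
from ecohealth import (
    DEAProblem, sbm_efficiency, PanelConfig, generate_panel,
    ModelVariant, HoldoutSplit, SearchConfig, run_experiment,
)

# SBM: unit B needs twice A's input for the same output -> half as efficient
prob = DEAProblem(
    units=("A", "B"),
    inputs=np.array([[1.0], [2.0]]),
    good_outputs=np.array([[1.0], [1.0]]),
    bad_outputs=np.empty((2, 0)),
)
print("rho(A) =", sbm_efficiency(prob, "A").rho)   # rho(A) = 1.0
print("rho(B) =", sbm_efficiency(prob, "B").rho)   # rho(B) = 0.5

# Forecast hospital visits on a synthetic 6-region panel
panel = generate_panel(PanelConfig(n_regions=6, n_years=10, noise_sd=0.05, seed=42))
result = run_experiment(
    panel,
    variants=[ModelVariant.variant(1), ModelVariant.variant(3)],
    outcomes=["vth"],
    split=HoldoutSplit(3),
    search_cfg=SearchConfig(seed=0, objective_mode="loocv"),
)
print(result.aggregates.round(5))
```

```
  outcome  variant      mpe      mse      sde
0     vth        1 -0.22775  0.35715  0.50383
1     vth        3  0.00305  0.04111  0.17268
```

The single-predictor model (variant 1) misses the control-variable signal
in this panel and under-predicts the held-out years by ~23% on average,
while the 7-predictor model (variant 3) brings the mean percentage error to
a fraction of a percent — the multi-factor-beats-single-factor pattern the
pipeline is built to quantify.

The same workflow is available from the shell:

```sh
ecohealth simulate --regions 30 --years 15 --seed 1 -o panel.csv
ecohealth ree -i panel.csv -o panel_ree.csv        # SBM eco-efficiency
ecohealth forecast -i panel_ree.csv -c config.yaml -o results/
ecohealth report --cells results/cells.csv -o tables/
```

## Layout

- `src/ecohealth/panel.py` — synthetic panel generator and CSV I/O
- `src/ecohealth/sbm.py` — SBM-DEA efficiency with undesirable outputs
- `src/ecohealth/lssvm.py` — LS-SVM dual solve, prediction, LOO residuals
- `src/ecohealth/search.py` — stochastic (σ, γ) search
- `src/ecohealth/pipeline.py` — experiments, MPE/MSE/SDE, stability
- `src/ecohealth/reporting.py`, `src/ecohealth/cli.py` — tables, manifests, CLI
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
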