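# panelmsm

Continuous-time multistate Markov models for interval-censored panel data,
built around a four-state cognitive-ageing structure: no cognitive
impairment (1, NOCI) ⇄ cognitive impairment no dementia (2, CIND), both
feeding dementia (3) and death (4, absorbing), with dementia → death.
Seven allowed transitions in total.

Features:

- **Proportional transition intensities** `q_rs(z) = q_rs⁰ · exp(β_rs' z)`
  with piecewise-constant age-band offsets; hazard ratios are `exp(β)`.
- **Panel likelihood** via batched matrix exponentials, with optional
  exactly observed death times (`log Σ_u P_ru(dt)·q_u,death` contributions).
  Observation intervals are split at age-band boundaries.
- **Maximum likelihood** by L-BFGS-B with exact reverse-mode gradients
  (adjoint of the matrix exponential); standard errors from a
  finite-difference Hessian at the optimum.
- **Derived summaries**: hazard-ratio tables with delta-method CIs,
  state-occupancy curves, expected total length of stay `∫₀ᵀ P_rs(u) du`,
  sojourn times `−1/q_rr`, and observed-vs-expected prevalence
  goodness-of-fit.
- **Synthetic cohorts**: baseline covariate sampling (education /
  occupation / wealth / sex / marital status, ages truncated-normal from
  50), exact Gillespie trajectories under the fitted intensity model, and
  degradation to biennial panel observations with monotone dropout.

## Command-line pipeline

```sh
# 1. simulate a cohort from the bundled calibrated scenario
panelmsm simulate --n 2000 --seed 1 --out runs/sim

# 2. fit the model (writes fit.json, hazard_ratios.csv, report.txt, ...)
panelmsm fit runs/sim/dataset.csv --seed 1 --out runs/fit

# 3. derived summaries for covariate patterns at given ages
panelmsm derive runs/fit/fit.json \
    --pattern "education=low,occupation=manual,wealth=low" \
    --pattern "education=high,occupation=professional,wealth=high" \
    --age 60 --age 80 --horizon 10 --out runs/derive

# 4. prevalence goodness-of-fit
panelmsm gof runs/fit/fit.json runs/sim/dataset.csv --out runs/gof
```

Data are long-format CSV (`subject_id, time_years, age, state`, covariate
columns, optional `exact_death` flag); model configurations are YAML
(`panelmsm.save_model` / `load_model`). Exit codes: 0 success, 2 validation
failure, 3 non-convergence. Each stage writes a `manifest.json` (config
hash, seed, versions); deterministic stages reproduce byte-for-byte.

## Python API sketch

```python
import panelmsm as pm

model = pm.calibrated_model()                    # bundled scenario
cfg = pm.CohortConfig(n_subjects=4000, seed=1)
data, cohort, paths = pm.simulate_dataset(model, cfg)

init = pm.crude_initial_values(data, model.structure, model.spec)
result = pm.fit(data, init)                      # FitResult
pm.hazard_ratio_table(result)                    # HR (95% CI) per transition
pm.total_length_of_stay(model, {"education": "high", "occupation": "manual",
                                "wealth": "low"}, 60.0, 1, 10.0)
```

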