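# nlmetest

Treatment-effect testing for longitudinal two-arm trials with nonlinear
mixed-effects models (NLMEM). The package implements seven testing
approaches in one framework, a synthetic natural-history cohort generator
(ADAS-cog-like trajectories with a baseline covariate), and an evaluation
battery for type I error, power, and RMSE of treatment-effect estimates.

## The seven approaches

| id      | description |
|---------|-------------|
| `stds`  | standard selection: AIC-best drug model vs the placebo-only model, chi-square LRT (df = extra parameters) |
| `sss`   | structural-similarity selection: the drug model is fitted to *all* subjects under H0; H1 duplicates the drug parameters per arm |
| `clrt`  | combined LRT: the cutoff is the empirical 5% quantile of the selected-model dOFV over datasets simulated under the fitted H0 |
| `rclrt` | randomized cLRT: the cutoff comes from permuting the treatment allocation of the observed cohort |
| `mad`   | model averaging across drug models: Akaike weights `exp(-dAIC/2)`; the reported statistic is the total weight on drug-containing models |
| `mapd`  | model averaging across placebo *and* drug models (5 placebo forms x {no drug, 4 drug models}) |
| `ima`   | individual model averaging: a subject-level mixture of placebo and placebo+drug with an arm-dependent mixing probability; 1-df LRT on the mixing parameter; effect reported as `(2*th_mix - 1) * th_de` |

The test statistic is `dOFV = OFV(H1) - OFV(H0)` (OFV = -2 log marginal
likelihood); negative values favor H1, and rejection happens below the
(negative) critical value.

Estimation uses an exact closed-form marginal likelihood for models linear
in Gaussian random effects (with the linear fixed effects concentrated out
by GLS), a Laplace approximation for the nonlinear models (Boxcox or
t-distributed random effects, IIV on the residual error, the
disease-modifying drug model with IIV), and an optional first-order (`fo`)
linearization of the latter for fast replicate batteries.

## Python API in one minute

```python
import nlmetest as nt

cfg = nt.GeneratorConfig(n_subjects=200,
                         misspec=nt.MisspecConfig(enabled=True))
cohort = nt.generate_natural_history(cfg, seed=1)
cohort = nt.randomize_allocation(cohort, seed=2)
cohort = nt.inject_treatment_effect(
    cohort, nt.EffectScenario("offset", typical_effect=8.0), seed=3)

res = nt.run_rclrt(cohort, nt.CandidateSet.power(), n=100, seed=4,
                   options=nt.FitOptions(route="fo"))
print(res.decision, res.dofv, res.critical_value, res.effect_estimate)
```

## Command line

```bash
nlmetest generate -n 200 --seed 1 --misspec -o cohort.csv
nlmetest fit -d cohort.csv -m pub+offset_iiv
nlmetest test -d cohort.csv -a rclrt --n-null 100 --seed 2
nlmetest battery -c battery.yaml -o results/
```

Cohort tables are NONMEM-style flat files (columns `ID,TIME,DV,TRT,BMMS`,
comma- or whitespace-delimited). Battery configurations are YAML; see
`RunConfig` for the schema. Every random draw derives from the master seed
and the trial/replicate index, so any single trial is reproducible in
isolation. `run_scenario_grid` repeats a battery over the eight-scenario
treatment-effect grid ({offset, time-linear} x {2, 8 points} x
{no IIV, 30% CV}) and stacks the summaries.

## Notes

* The Akaike weight is the standard `exp(-dAIC/2)`, normalized over the
  candidate set.
* Model-averaging "type I error / power" entries are the mean over trials
  of the per-trial H1 weight fraction.
* Fits that fail to converge are excluded from rate computations and
  counted (`excluded_fits` / `excluded` fields).
* RMSE is computed with the square root and divides by the number of
  non-excluded trials.
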