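# vlsupp

Bayesian longitudinal analysis of HIV viral-load suppression across
antiretroviral-therapy (ART) regimens, plus a seeded synthetic-cohort
generator so the whole chain is testable end to end.

## The problem

Cohorts of people living with HIV on first-line efavirenz-based ART (EFV) or
second-line atazanavir/ritonavir- (ATV/r) or dolutegravir-based (DTG) ART
have viral loads measured on a fixed schedule (weeks 12, 24, 48, 72, 96
after start/switch). The scientific questions: how does the probability of
viral-load suppression (< 50 copies/mL) evolve by regimen and time, and how
do the regimens compare once within-person correlation and the very
different case mixes of first- and second-line patients are accounted for?

`vlsupp` implements the full analysis for users of such cohort data
(biostatisticians and HIV epidemiologists):

1. **Data preparation** — visit-window assignment (week *w* covers days
   7*w* ± 28), nearest-measurement selection, conservative "sandwich"
   imputation of missing windows (only when the flanking measurements agree
   on the < 50 dichotomy — no blip can be imputed), age/CD4 binning, and a
   complete-case sensitivity path.
2. **Inference** — the random-intercept logistic model

       y_ij ~ Bernoulli( expit( x_ij' β + u_i ) ),   u_i ~ N(0, σ_u²),
       β_p ~ N(0, 2.5²),   σ_u ~ half-Normal(1)

   fitted by a self-implemented, exact Pólya-Gamma Gibbs sampler (Devroye
   PG(1, z) variates, collapsed β update, interweaved σ_u update), with
   split-R̂ / ESS diagnostics.
3. **Interaction selection** — two-step search over two-way interactions by
   expected log pointwise predictive density (ELPD, WAIC form) with the
   2-standard-error eligibility rule.
4. **Population-averaged estimates** — marginal adjusted odds ratios and
   standardized (g-computation) / non-standardized predicted suppression
   proportions, integrating over the random-effect distribution by
   Gauss–Hermite quadrature; crude proportions with Beta credible intervals.
5. **Reporting** — baseline-characteristics table, estimate tables and
   point-and-interval figures, all orchestrated by a seeded, manifest-writing
   CLI.

See `docs/methods.md` for the model, all rules and defaults, and what the
synthetic data do and do not emulate.

## Worked example

```python
from vlsupp import (SimulationConfig, build_analysis_table, build_design,
                    fit_posterior, standardized_predictions, ModelSpec)
from vlsupp.simulate import simulate_dataset

cfg = SimulationConfig(n_per_regimen={"EFV": 400, "ATVr": 300, "DTG": 150}, seed=1)
cohort, vl = simulate_dataset(cfg)                  # persons + dated viral loads
table, report = build_analysis_table(cohort, vl)    # per-week binary outcomes
print(f"{report.n_observed_rows} observed + {report.n_imputed_rows} imputed rows")

spec = ModelSpec(interactions=(("regimen", "week"),))
sample = fit_posterior(build_design(table, spec), table["suppressed"].to_numpy(),
                       spec, n_chains=2, n_iter=1500, n_warmup=500, seed=1)
for est in standardized_predictions(sample, table, weeks=[48]):
    lbl = est.labels
    print(f"week {lbl['week']} {lbl['regimen']:>4}: "
          f"{est.point:.3f} ({est.lower:.3f}-{est.upper:.3f})")
```

prints (exact values from this seed):

```
2836 observed + 435 imputed rows
week 48  EFV: 0.902 (0.869-0.931)
week 48 ATVr: 0.775 (0.722-0.821)
week 48  DTG: 0.730 (0.640-0.804)
```

i.e. at week 48, after standardizing all 850 persons' covariates to each
counterfactual regimen and averaging over the random-intercept distribution,
first-line EFV shows ~90% suppression versus ~73–78% for the second-line
regimens, with 95% credible intervals from the posterior draws.

Or run the whole pipeline from a shell:

```bash
vlsupp run-all --config configs/demo.yaml --seed 1 --out demo_run
```

which persists every intermediate (`analysis_table.csv`, posterior draws,
`selection_report.json`, `estimates.csv`, descriptives, figures) plus a
manifest with content hashes; re-running the same config and seed reproduces
the tables byte-for-byte.

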