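# spatlc — spatially extended Bayesian Poisson Lee–Carter mortality modelling

Small-area mortality estimation has to fight small numbers: death counts
by single year of age, calendar year and province fluctuate wildly where
populations are small, and naive rate estimates hide real geographic
structure under noise.  `spatlc` implements a spatial extension of the
Lee–Carter model for exactly this setting — analysts of subnational
mortality who want age- and sex-specific trends at province level with
honest uncertainty.

Deaths are modelled as `Y_xts | λ_xts ~ Poisson(E_xts λ_xts)` with

    log λ_xts = α_x + β_x κ_t + ω_{s,g_x[,p_t]} + u_{r_s} + z_xts

* `α_x` — age profile, `κ_t` — RW2-smoothed period index, `β_x` — age
  loading (classic Lee–Carter, with `Σβ = 1`, `Σκ = 0`);
* `ω_{s,g}` — BYM2 province effect per 10-year age class `g`, mixing an
  iid and a scaled-Besag (ICAR) component on the province adjacency
  graph, `ω = σ_ω(√(1−φ) v + √φ u)`, with per-component scaling and
  sum-to-zero constraints so the model behaves on disconnected graphs;
  optionally split into two calendar periods to detect changing
  geography (`ω_{s,g,p}`);
* `u_r` — Gaussian region effect, `z_xts` — Gaussian overdispersion;
* penalized-complexity priors on all standard deviations
  (`P(σ > 3) = 0.05` by default) and on the mixing parameter
  (`P(φ < 0.5) = 2/3`).

The package provides the model densities and constraint projection as
pure functions, a NUTS sampling engine with analytic gradients, a
synthetic-data generator that emulates provincial mortality registers
(the real register data such analyses use is typically access-restricted),
a classic SVD Lee–Carter baseline, and a three-command CLI pipeline.
See `docs/methods.md` for the full model account, numerical choices and
known limitations.

## Worked example

```python
import warnings
import spatlc as sl

cfg = sl.SimConfig(seed=42, n_provinces=12, n_regions=3, max_age=30, n_years=6)
graph, spec, truth, data = sl.simulate(cfg)
print(f"simulated {data.deaths.sum()} deaths over "
      f"{data.n_ages} ages x {data.n_years} years x {data.n_provinces} provinces")

fit_cfg = sl.FitConfig(seed=1, draws=300, warmup=300, chains=2, target_accept=0.95)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")          # short chains trip the Rhat warning
    summary = sl.fit(data, graph, spec, fit_cfg)

print(f"posterior mean sigma_omega: {float(summary.mean('sigma_omega')):.3f} (truth 0.15)")
print(f"posterior mean phi:         {float(summary.mean('phi')):.2f} (truth 0.6)")
for block, m in sl.recovery_metrics(truth, summary).items():
    print(f"{block:10s} corr={m['correlation']: .3f}  rmse={m['rmse']:.4f}  "
          f"coverage={m['coverage']:.2f}")
```

Output (about a minute on one CPU):

```
simulated 18816 deaths over 31 ages x 6 years x 12 provinces
posterior mean sigma_omega: 0.132 (truth 0.15)
posterior mean phi:         0.57 (truth 0.6)
alpha      corr= 0.998  rmse=0.1278  coverage=1.00
beta       corr= 0.272  rmse=0.2552  coverage=0.84
kappa      corr= 0.994  rmse=2.1774  coverage=0.00
omega      corr= 0.898  rmse=0.0530  coverage=1.00
u_region   corr= 0.714  rmse=0.1034  coverage=1.00
```

Reading the numbers: the spatial field `ω` — the quantity this model
exists for — is recovered with correlation 0.90 and full interval
coverage, and the hyperparameters land near their true values.  The
*shape* of the period index `κ` is exact (correlation 0.994) but at
this small data volume its overall scale is only weakly identified
against `β` and the overdispersion term, so the chains sit at an
attenuated `κ` with a compensating `β` — hence the large `κ` RMSE and
the poor `β`/`κ` pointwise metrics.  This is a documented property of
the model at desk-scale counts, flagged by the R-hat warning; see
"Known limitation" in `docs/methods.md`.  At register-scale data
volumes the likelihood pins the scale.

## CLI pipeline

```sh
spatlc simulate --config sim.yaml --out data/
spatlc fit --data data/mortality.csv --graph data/graph.txt \
           --config fit.yaml --out post/ [--cutpoint 2014]
spatlc recovery-report --truth data/truth.json --summary post/ --out report/
```

`simulate` writes the mortality CSV (one row per age-year-province
cell), the adjacency graph in neighbour-list format, the ground-truth
parameter state and a manifest; `fit` writes tidy posterior-summary
CSVs (κ trend, β, compound `β_xκ_t`, spatial surfaces, hyperparameters);
`recovery-report` compares a fit against simulated truth
(correlation / RMSE / coverage per parameter block).  All outputs are
plain text; exit codes are 0/1/2 for ok / validation error / runtime
error.

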