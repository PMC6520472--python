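# n2oflux

Bayesian and trapezoidal estimation of nitrous-oxide (N₂O) emission
factors from static-chamber flux campaigns on fertilised grassland.

After a nitrogen application, the spatial mean N₂O flux is modelled as a
log-normal-shaped pulse in time — location `Δ` (log days to peak), scale
`k`, total emitted fraction `Ω` of the applied nitrogen `N_in` — with
log-normal plot-to-plot scatter (`σ_log`) around it. The cumulative
emission to day *t* then has the closed form
`Φ((ln t − Δ)/k) · N_in · Ω`, so posterior draws of the parameters give
cumulative fluxes and emission factors (EFs) with full uncertainty. A
piecewise-linear (trapezoid) integral of the daily mean fluxes is
provided as the conventional comparator.

## Modules

| module | what it does |
| --- | --- |
| `n2oflux.chamber_flux` | flux from a chamber headspace concentration series (`F = dC/dt · ρ V / A`) |
| `n2oflux.lognormal_model` | spatial log-normal density, temporal pulse, closed-form cumulative, censored likelihood |
| `n2oflux.bayes_inference` | random-walk Metropolis-within-Gibbs posterior sampling, Gelman–Rubin diagnostics |
| `n2oflux.linear_baseline` | trapezoidal cumulative flux with explicit edge conventions |
| `n2oflux.ef_pipeline` | per-event EFs (both methods), background subtraction, cross-event aggregation, method comparison, pooled posterior EF pdfs |
| `n2oflux.synthetic_data` | seeded chamber-campaign generator (site presets EB/HF/NW/UJ) |
| `n2oflux.io_cli` | CSV formats, YAML config, `n2oflux` command-line interface |

A published per-event results table from an 11-event, three-fertiliser
(AN / urea / urea+inhibitor) UK grassland trial is bundled at
`n2oflux/data/reported_event_results.csv` and backs the aggregation and
method-comparison checks.

## Command line

```sh
# synthetic campaign for the EB site preset (byte-identical per seed)
n2oflux simulate --preset EB --seed 1 --out campaign/

# chamber fluxes from raw concentration series
n2oflux fluxes --concentrations conc.csv --chambers chambers.csv --out fluxes.csv

# full per-event analysis: trapezoid + Bayesian EFs per treatment
n2oflux ef --input campaign/fluxes.csv --events campaign/events.csv --out results/

# aggregate report (means/SDs/medians, R², slopes); defaults to the bundled table
n2oflux report --out report/
n2oflux compare --out comparison.json
```

Flux tables are long-format CSV
(`site,event,treatment,plot,day,flux_nmol_m2_s`); rows with
`treatment == "control"` supply the background. Events tables carry
`site,event,date,n_in_kg_ha`. MCMC settings, priors, the integration
window and edge handling are configurable through a YAML file passed
with `--config`; every run writes a `provenance.json` beside its
outputs.

## Notes

- Background fluxes enter the likelihood as a constant additive offset
  to the model's mean flux (estimated from the control plots), and are
  subtracted from cumulative totals when EFs are formed.
- Measured fluxes at or below a configurable floor (default
  `1e-4 nmol m⁻² s⁻¹`) are treated as left-censored, keeping the
  likelihood finite for zero/negative chamber fluxes.
- The sampler adapts proposal scales during burn-in only; chains are
  reproducible for a fixed seed, and R̂ plus per-block acceptance rates
  are reported with every fit.
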