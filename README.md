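# pigspread

Counterfactual forecasting of invasive wild-pig spread across a
county/watershed landscape, plus valuation of the resources safeguarded
when that spread is prevented — implemented as a fully synthetic,
desk-scale pipeline.

Two forecasting frameworks are run side by side on a generated landscape:

* **Boosted-tree step-ahead forecasts** (`pigspread.brt`): least-squares
  boosted regression trees fit to per-county pre-program mean spread
  rates (four variants A–D: proportion vs. km² response, with/without
  the previous-year focal status covariate; persistent and transient
  county strata fit separately), rolled forward deterministically one
  year at a time with bounding and adjacent-occupancy updates.
* **Stochastic watershed occupancy simulation** (`pigspread.occsim`): a
  six-predictor logistic-binomial invasion model (fixed-effects,
  regional-intercept, and regional-slope variants) drives a replicate
  simulator in which annual invasion/extinction counts are drawn from
  beta distributions fit to observed rate series, invasions are assigned
  by probability-weighted sampling without replacement, and distances
  and coarse-watershed proportions are updated every year.

Forecast occupancy in excess of observed occupancy is converted into
safeguarded resource amounts (acres and head) and dollar values
(`pigspread.valuation`), with unweighted mean/min/max summaries across
the eight-model ensemble.

Because the real national mapping, census, and land-cover data are not
publicly packaged, `pigspread.synth` generates synthetic inputs with the
same statistical structure (persistent core plus transient fringe,
zero-inflated right-skewed spread deltas, county↔watershed overlap
weights, resource/price/yield/rent tables) and known-truth scenarios for
parameter-recovery testing.

## CLI

```sh
pigspread run-all --seed 1 --out out/            # full 8-model pipeline
pigspread synth   --seed 1 --out out/            # synthetic inputs only
pigspread prep    --seed 1 --out out/            # rates, strata, responses
pigspread brt     --model A --seed 1 --out out/  # one boosted-tree forecast
pigspread occsim  --variant fixed --reps 1000 --seed 1 --out out/
pigspread value   --models all --seed 1 --out out/
pigspread report  --out out/                     # print ensemble summary
```

All commands accept `--config cfg.yaml` (see `RunConfig` in
`pigspread.pipeline` for every knob; a `config_used.yaml` echo and a
`manifest.json` with SHA-256 checksums are written into the output
directory). Runs are fully deterministic given `--seed`.

## Layout

```
src/pigspread/
  synth.py      synthetic landscape, histories, covariates, resources
  rates.py      occupancy deltas, strata, watershed responses, rate series
  brt.py        least-squares boosting + deterministic step-ahead forecasts
  occsim.py     invasion model + stochastic replicate simulator
  valuation.py  safeguarded amounts, dollar values, ensemble statistics
  pipeline.py   orchestration, config, manifest, report tables
  cli.py        click command group
tests/          unit, property, and acceptance suites
scripts/acceptance.py
```
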