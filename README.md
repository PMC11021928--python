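# phenomoult

Individual-level moult phenology from longitudinal sighting tables: a
hierarchical Bayesian logistic model of moult progression with derived
event dates, detection-corrected arrival/departure estimation, population
synchrony statistics, variance partitioning across individuals, and a
seeded synthetic-colony generator that emulates the observation process so
the whole pipeline is testable without field data.

## Modules

| module | role |
| --- | --- |
| `phenomoult.synthdata` | latent moult/haul-out schedules per animal-year plus the survey/detection/scoring process that degrades them into sighting CSVs |
| `phenomoult.moultfit` | hierarchical logistic moult-progression model (custom adaptive MCMC, ArviZ diagnostics); inclusion filters; draw-wise start/mid/end/duration summaries |
| `phenomoult.haulout` | detection-corrected arrival/departure dates and haul-out durations (geometric-gap model, empirical-Bayes detection probability by year) |
| `phenomoult.synchrony` | daily cumulative curves, occupancy/moulting fractions, peaks and population event windows |
| `phenomoult.compare` | gamma log-link mixed-model category comparisons with grouping letters, variance partitioning, compensation regression, annual-cycle variance chain |
| `phenomoult.pipeline` / `phenomoult.cli` | configuration, CSV/JSON I/O with config-hash provenance, end-to-end pipeline |

## CLI

One executable with a subcommand per stage:

```bash
phenomoult synthdata --out sightings.csv --seed 42          # + .surveys.csv sidecars
phenomoult moultfit  --in sightings.csv --draws 1000 --out fit/
phenomoult haulout   --sightings sightings.csv --surveys sightings.surveys.csv \
                     --fits fit/moult_events.csv --out haulout.csv
phenomoult synchrony --events events.csv --out schedule.csv --peaks peaks.json
phenomoult compare   --events events.csv --which variance,compensation,chain --out tables/
phenomoult pipeline  --config cfg.yaml --out runs/demo/ --seed 42
```

`pipeline` executes generate (or ingest a user sightings CSV) → moult fit →
haul-out → synchrony → compare, writing every stage's CSV/JSON outputs and a
`manifest.json` with versions, seed and config hash. Reruns with the same
config and seed are byte-identical.

The pipeline YAML mirrors `PipelineConfig`: `generator` (categories,
variances, survey coverage, detection, scoring noise), `sampler` (chains,
draws, warmup, seed), `detection` (prior window, draws), `thresholds`
(min observations 6, early <10%, late >90%) and `ci_width_max` (6 days).

## Data formats

Sightings CSV: `animal_id,year,category,date,percent_moulted` with
`date` an integer day-of-year and `percent_moulted` an integer 0–100;
categories are `adult_reproductive`, `adult_skip`, `juvenile_female`,
`juvenile_male`. Survey calendars are CSVs of `year,date`. Stage outputs
begin with a `# config_hash=...` comment line; read them with
`phenomoult.pipeline.read_csv` (or `pandas.read_csv(..., comment="#")`).
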