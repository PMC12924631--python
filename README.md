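# swinesim

An agent-based, daily-timestep simulator of growing–finishing pigs
(20 → 130 kg). Each pig is an independent agent with its own RNG substream;
every simulated day the model computes body-weight gain (with configurable
stochastic variation), body composition (protein, lipid, water, ash, gut
fill, backfat), metabolizable energy and feed intake under a thermal
environment, and the full set of daily nutrient requirements (SID lysine
chain, amino-acid expansion by fixed ratios, STTD phosphorus, calcium, and
log-linear mineral/vitamin requirements). Replication statistics
(mean/SD/95% CI trajectories) and an r² verification against the
deterministic reference equations are built in.

## Layout

| module | role |
|---|---|
| `swinesim.params` | coefficient tables, run configuration, least-squares fits (gain polynomial, log-linear micronutrients) |
| `swinesim.growth` | daily gain, weight update, body-composition bookkeeping |
| `swinesim.energy` | energy/feed intake curves, lower critical temperature, maintenance energy, intake ceiling |
| `swinesim.requirements` | lysine chain, amino acids, phosphorus/calcium, minerals, vitamins |
| `swinesim.herd` | agent scheduler: stocking, daily loop, removal at target weight, replications |
| `swinesim.reporting` | replication summaries, r² verification, CSV/JSON export, optional plots |

## CLI

```bash
# full stochastic herd run: records, summaries, verification, metadata
swinesim simulate --config config.json --seed 42 --replications 500 \
    --out results/run1 --snapshot-day 130 --plot

# noise-free reference run
swinesim simulate --out results/reference --deterministic

# regenerate the fitted mineral/vitamin coefficient table
swinesim write-coefficients --out micronutrient_coeffs.csv
```

The configuration file is a flat JSON or YAML key-value document; every key
of `swinesim.params.HerdConfig` (lower_snake_case) is accepted and unknown
keys are an error. An empty file runs the defaults (5 barns, 3 sexes,
140 days, 20 → 130 kg, 3300 kcal/kg feed, 5% wastage, 88% dry matter,
20 °C, gain-noise CV 0.05, 500 replications).

Outputs: `records.csv` (one row per pig-day), `summary.csv` (per-day
mean/SD/95% CI per sex and variable), `verification.csv` (r², slope,
intercept of simulated vs deterministic gain), `requirements_day130.csv`
(snapshot table of all requirements per sex), `run_meta.json`.

## Notes

- Boars have no published feed-intake curve; their feed intake is derived
  from energy, `FI = MEI / (me_content × (1 − feed_wastage))`, overridable
  via `boar_fi_coeffs`.
- Feed intake is capped at the environmental maximum; when the cap binds,
  energy intake is rescaled so the feed and energy books stay consistent.
- The body-weight account and the composition account (empty body weight +
  gut fill) are parallel; their drift is reported in the
  `bw_vs_ebw_drift` diagnostic column rather than reconciled.
- Reproducibility: every pig draws from a substream keyed by
  (seed, replication, pig id), so results are bit-identical across runs and
  independent of scheduling order.
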