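# mobiscope

Smartphone-derived real-life mobility metrics for older-adult cohorts, with
the full statistical association chain and a seeded synthetic-cohort
generator for end-to-end validation.

## What it computes

From **GPS fix streams** (CSV or GPX 1.1), per participant:

- **Life-space area** [km²] — area of the convex hull of each day's fixes
  (on a home-centred azimuthal-equidistant projection), averaged over days;
- **Total distance** [km] — cumulative daily path length, averaged over days
  (a net-displacement mode is available via `--distance-mode net`);
- **Maximum action range (AR-max)** [km] — largest straight-line distance
  from home over the whole registration period.

Only fixes within 15 km of home (inclusive) enter any metric, focusing the
measures on habitual mobility.

From **classified activity intervals** (gait / active / other bouts with MET
intensity and step counts), per participant:

- **Active-&-Gait Time (AGT)** [h] — gait/active time strictly above 3 METs;
- **Steps** — daily step totals.

Days are clipped to 07:00–21:00 local time (steps prorated), days with under
9 h of registration are discarded, and daily values are rescaled to a 12-h
day (`value * 12 / registration hours`) before averaging.

The **analysis chain** then mirrors a standard multi-domain association
workflow: square-root transform of the spatial outcomes → Lilliefors KS
normality screening (α=0.10) → Tukey fence outlier filtering → Little's MCAR
test → column-mean imputation → Spearman correlation screening (α=0.05) →
per-outcome stepwise multiple regression (p-to-enter 0.05, p-to-remove 0.10)
with standardized betas, adjusted R², VIF and Shapiro–Wilk residual checks.

The **synthetic generator** builds cohorts whose latent outcomes follow a
known linear model on the square-root scale, with tracks and activity days
constructed so the recomputed metrics hit their targets exactly — giving the
whole chain a testable ground truth.

## CLI

```bash
# generate a seeded synthetic study bundle
mobiscope simulate --out study/ --seed 1 --n 150

# per-day + per-participant metrics only
mobiscope metrics --bundle study/ [--distance-mode path|net] [--radius-km 15]

# metrics + association analysis + reports
mobiscope analyze --bundle study/ [--outlier-mode cell|case]

# everything (simulates the bundle first if absent)
mobiscope run --bundle study/ --config cfg.toml --seed 1
```

A bundle directory holds `participants.csv`, `gps/<id>_<date>.csv` (or
`.gpx`), `activity/<id>_<date>.csv` and optionally `truth.json`.  Outputs are
`participant_metrics.csv`, `gps_days.csv`, `activity_days.csv`,
`report.json`, `report.md` (correlation matrix and model blocks, with a
recovery-versus-truth section when `truth.json` is present) and
`runlog.json`.  Reports are byte-identical for identical inputs.

Config files are TOML or YAML with `[simulation]` and `[analysis]` tables;
see `mobiscope.synthetic_data.SimulationConfig` and
`mobiscope.stats_pipeline.AnalysisConfig` for the accepted keys.

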