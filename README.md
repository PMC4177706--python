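# olsim

An agent-based simulation of opinion-leader emergence on a nursing unit,
with the verification harnesses used to check that the model reproduces its
posited relationships.

A *unit* holds staff nurses, educators and a manager. Each discrete tick a
randomly chosen agent announces a piece of evidence (a 1–100 probability
score); every other agent assesses the evidence against its prior belief
and the announcer's credibility against the unit's credibility bar,
possibly seeks advice from an available (visible and credible) colleague,
and then adopts or ignores the evidence, revising its belief by a
credibility-weighted step toward the announcement. Between ticks, revised
beliefs replace priors and visibility/credibility are recomputed, so agents
whose beliefs strengthen can surface as advice givers — and repeatedly
sought-out advisors are candidate opinion leaders.

## Layout

- `olsim.model_core` — agent/unit state and every per-tick procedure
  (sampling, visibility, credibility, assessments, uncertainty, advice,
  belief revision, commit).
- `olsim.experiments` — the two verification experiments: a 288-cell
  full-factorial parameter sweep (replicated single-tick runs) and a
  20-tick, 106-agent individual time series with advice-network export.
- `olsim.verification_stats` — per-cell descriptive aggregation,
  directional OLS sign checks of the posited relationships (A–G), and a
  logistic regression for advisor availability.
- `olsim.io_cli` — YAML config loading, named random substreams, CSV/TSV
  writers with a reproducibility manifest, and the `olsim` CLI.

## CLI

```sh
olsim run --seed 1 --ticks 5 --out out/            # one unit, chained ticks
olsim sweep --replicates 50 --seed 1 --out sweep.csv
olsim timeseries --seed 1 --out ts.csv --edges-out edges.tsv
olsim verify sweep.csv --summary-out summary.csv --report-out checks.json
```

All commands accept `--config cfg.yaml` (flat keys mirroring the config
dataclasses; flags win) and share `--seed`. Identical seeds give
byte-identical output files; each run records a manifest JSON capturing the
config, master seed and substream labels.

## Reproducibility notes

Randomness flows through named substreams hashed from the master seed, so
any (cell, replicate) or tick can be reproduced in isolation. Sweep
substreams are keyed by the unit-composition factors only, so cells that
differ solely in the credibility threshold share their agent draws —
making availability exactly monotone in the threshold under matched seeds.
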