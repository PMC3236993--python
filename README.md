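# aclcea

Cohort decision-tree cost-utility analysis of surgical reconstruction versus
conservative treatment after rupture of the anterior cruciate ligament (ACL).

The package implements the full analysis pipeline as tested, config-driven
components:

- **evidence** — pooling of study-level activity-class counts (Gottlob
  classes I–V) into arm-specific activity distributions and sample-size
  weighted summary statistics.
- **costing** — arm-level and complication-level direct costs from resource
  line items, with CHF→USD conversion.
- **utilities** — activity-class→utility mapping, the one-class-down shift
  rule after treatment failure, and constrained least-squares calibration of
  an unobserved monotone utility key against published arm-level aggregates.
- **tree** — a generic chance-node decision-tree engine (validation,
  expected-value rollback, exhaustive path-enumeration oracle) plus the two
  strategy trees (reconstruction / conservative).
- **cea** — incremental cost-effectiveness tables with dominance and
  extended-dominance handling, net monetary benefit, and the no-sequelae
  worst-case scenario.
- **psa** — Monte Carlo probabilistic sensitivity analysis over utilities
  (truncated-normal draws, common random numbers), CEAC/acceptability
  frontier and cost-effectiveness plane scatter exports.
- **synthdata** — seeded synthetic study tables, expert-survey draws and
  cost line items so every stage is testable without external data.

The shipped baseline configuration (`src/aclcea/data/baseline.yaml`)
reproduces the published analysis: expected costs 16,038 / 15,466 USD,
effects 0.78 / 0.66, ICER ≈ 4,890 USD/QALY, and a worst-case (no-sequelae)
ICER of ≈ 68,715 USD/QALY. Calibration constants are documented in the
config header and recomputable from the recorded anchors.

## CLI

```sh
aclcea pool                      # pool the shipped study table (or --evidence CSV)
aclcea costs                     # sum the shipped resource table (or --resources CSV)
aclcea run                       # baseline incremental cost-effectiveness table
aclcea run --set p_fail=0.05     # override any scalar model parameter
aclcea worst-case                # scenario with sequelae probabilities = 0
aclcea psa --iterations 10000 --seed 2011   # PSA: summary, CEAC, scatter CSVs
aclcea synth --studies 4 --seed 7           # synthetic study-arm table
```

All commands write CSV/JSON reports plus a provenance block (config hash,
seed, version) into `--out-dir` and log to stderr only. Configs are YAML or
JSON; see `src/aclcea/data/baseline.yaml` for the schema.

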