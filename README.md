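# hrgap

Workload-based estimation of the gap between the **available** and the
**ideal** supply of primary-care human resources (physicians, nurses, health
promoters) needed to deliver a 99-activity guaranteed prevention and
health-promotion package.

Per facility and cadre the pipeline computes:

- **Available supply (As)** — annual contracted hours:
  `headcount x 200 working days x 6 h/day`;
- **Ideal supply (Is)** — annual hours needed for the attended population:
  per-person annual minutes x population, summed over age groups, / 60 —
  estimated twice, from *time used* (minutes staff actually spend) and *time
  required* (minutes staff deem suitable);
- **FTE conversion** — annual hours / 1200 — and the gap `As - Is`
  (negative = shortage).

Available vs ideal supply is compared across facilities with the Wilcoxon
matched-pairs signed-rank test (normal approximation, no continuity
correction) and the three supply channels jointly with the Friedman test.
A gamma-shape sensitivity analysis (`S = 1/(1 - alpha)`, median-safe iff
`alpha >= 1.33`) validates median-based summaries of the right-skewed time
data. A seeded synthetic-data generator emulates the study structure
(12 urban + 8 rural facilities, ~87/13 urban/rural split of 268 527 attended
individuals, gamma-distributed service times) so the whole pipeline is
testable without external data.

## CLI

```bash
hrgap simulate --seed 7 --out data/           # synthetic study CSVs + manifest.yaml
hrgap validate data/                          # schema & integrity checks
hrgap estimate data/ --out out/               # supply, FTE, gaps per facility x cadre
hrgap compare  data/ --out out/               # Wilcoxon / Friedman by stratum
hrgap sensitivity data/ --out out/            # gamma fits + median-safety verdict
hrgap report   data/ --out out/               # all tables + rendered report.txt
hrgap run --seed 7 --out out/                 # simulate + full analysis in one go
```

Inputs are plain CSVs (`facilities.csv`, `population.csv`, `times.csv`,
optional `activities.csv`); a YAML config passed via `--config` overrides the
estimation constants (working days, hours/day, FTE hours, utilization) and
the generator knobs.

## Package layout

| module | contents |
| --- | --- |
| `hrgap.domain` | data model + supply/gap arithmetic (hours, FTE, medians) |
| `hrgap.stats` | Wilcoxon signed-rank, Friedman, Wald proportion CIs |
| `hrgap.gamma` | gamma MLE/moments fits, sensitivity index, skew check |
| `hrgap.synth` | seeded synthetic-study generator + degenerate fixtures |
| `hrgap.calibration` | published reference/calibration constants |
| `hrgap.io`, `hrgap.pipeline`, `hrgap.cli` | CSV/YAML IO, stage orchestration, CLI |

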