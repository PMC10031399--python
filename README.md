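# welfarelca

LCA-compatible animal-welfare quantification for breed-to-finish pig
systems.

The package converts stage-level Welfare Quality (WQ) principle scores
(good health, good feeding, appropriate behaviour, good housing; each
0–100) and annualized production records into welfare impact measures
expressed per functional unit (1 kg deadweight):

* **Overall WQ score** — the sows-and-piglets and fattening-stage scores
  are principle-weighted and combined using the proportion of life-years
  each stage contributes per finished pig. Cull-sow deadweight is folded
  into the functional unit by economic allocation.
* **Welfare-cost metric family** — each principle-stage term counts as a
  cost `(100 − p)·w·y` or a benefit `−p·w·y` depending on a cost-to-benefit
  transition rule. The canonical grid has 30 variants: transitions
  `T ∈ {100, 90, 80, 70, 60, 50, 40}`, the WQ `excellent` / `enhanced`
  classifications, and behaviour-as-benefit, each crossed with three
  principle weightings (standard / equal / extreme).
* **Robustness analysis** — tie-corrected Kruskal–Wallis tests, Dunn's
  post hoc z-tests with Holm adjustment, compact letter displays, and
  Spearman rank correlations of system rankings across all metric
  variants. Statistics run on an independent subset with one system per
  cluster of systems sharing breeding and/or rearing farms.
* **Synthetic populations** — a calibrated generator produces 74-system
  populations (six label types, Table-1 counts; 43 independent clusters;
  overall-WQ vs life-years correlation ≈ 0.57) so the whole pipeline is
  testable without external data.

## CLI

```bash
# generate a synthetic population
welfarelca simulate --seed 1 --out systems.csv

# overall WQ scores (choose a weighting preset)
welfarelca score --systems systems.csv --weighting standard --out scores.csv

# the 30-variant welfare-cost grid (or a subset of metric ids)
welfarelca cost --systems systems.csv --out costs.csv
welfarelca cost --systems systems.csv --metrics T100/standard,behaviour/equal --out costs.csv

# full statistics bundle (omnibus, post hoc, letters, rank correlations)
welfarelca robustness --systems systems.csv --seed 1 --out results/

# everything plus a plain-text report
welfarelca report --systems systems.csv --seed 1 --out results/
```

Metric ids follow `T<value>/<weighting>`, `excellent/<weighting>`,
`enhanced/<weighting>` and `behaviour/<weighting>`. All randomness flows
through `--seed`; omitting it generates and logs one. `simulate --config
overrides.yaml` accepts a YAML mapping of `GeneratorConfig` field
overrides.

## Layout

| module | contents |
| --- | --- |
| `welfarelca.domain` | label/husbandry vocabularies, system model, validation |
| `welfarelca.production` | life-years per kg DW, economic allocation, stage proportions |
| `welfarelca.aggregation` | WQ score weighting, overall score, classifications |
| `welfarelca.metrics` | welfare-cost metric family and the 30-variant grid |
| `welfarelca.stats` | Kruskal–Wallis, Dunn/Holm, letters, Spearman, subset selection |
| `welfarelca.synth` | calibrated synthetic population generator |
| `welfarelca.io` / `welfarelca.cli` | CSV schemas, pipeline, results bundle, CLI |
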