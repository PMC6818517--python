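# hmarules

Association-rule mining of somatic mutation profiles to find multi-gene
biomarkers of resistance to hypomethylating agents (HMAs, azacitidine and
decitabine) in myelodysplastic syndromes (MDS).

Only 30–40% of patients with MDS respond to HMAs, and it can take six
cycles of therapy to call a failure, so up-front resistance biomarkers have
real clinical value. Single-gene association tests have been inconclusive;
this package instead treats each patient as a market-basket *transaction* —
one item per mutated gene in a 29-gene myeloid panel plus one outcome item
(responder / nonresponder under IWG criteria) — and mines the transactions
with the Apriori algorithm for rules of the form

```
{geneA mutated, geneB mutated, ...} -> nonresponse
```

Each rule is scored by

- **support** — count of patients carrying the antecedent and the outcome,
- **confidence** — P(outcome | antecedent) = support(antecedent ∪ outcome) / support(antecedent),
- **lift** — confidence / P(outcome); lift 1 means independence.

Rules are kept when confidence ≥ 0.95, support ≥ a minimum count, and lift
≥ 1.5, with a most-general-antecedent redundancy filter. The selected rule
set is then evaluated the way a clinical biomarker panel is: prevalence
among patients with ≥ 3 mutations, accuracy (fraction of rule-positive
patients who are truly nonresponders) on training and on an independent
validation cohort, and Kaplan-Meier / log-rank survival comparisons across
rule-positive, high-burden rule-negative, and low-burden strata.

Because no patient-level dataset is public, the package ships a calibrated
synthetic-cohort generator (`hmarules.simulate`) that reproduces the
published cohort descriptors — marginal gene frequencies (ASXL1 31%, SRSF2
23%, TET2 22%, ...), pairwise co-mutation enrichment (ASXL1∧TET2 in 10% of
patients), a 43% overall response rate, ~41% of patients with ≥ 3
mutations, planted high-penetrance resistance rules, and stratum survival
medians of 14.6 / 22.8 / 28.2 months — so every pipeline stage is testable
end to end.

## Worked example

```python
import hmarules as h

cfg = h.RunConfig(simulation=h.SimulationConfig(n_patients=433),
                  seed=7, outdir="demo_run")
report = h.run_discovery(cfg)
print(open("demo_run/report.txt").read())
```

prints (abridged):

```
Cohort
  patients: 433
  median mutations/sample: 2 (max 7)
  fraction with >= 3 mutations: 39.3%
  overall response rate: 42.3%

Selected resistance rules (13)
  {ASXL1:mut, RUNX1:mut, TET2:mut} -> OUTCOME:NONRESP  conf=1.000 lift=1.73 support=12
  {ASXL1:mut, RUNX1:mut, SRSF2:mut} -> OUTCOME:NONRESP  conf=1.000 lift=1.73 support=11
  ...
  {ASXL1:mut, TET2:mut} -> OUTCOME:NONRESP  conf=0.953 lift=1.65 support=41

Evaluation (training cohort)
  high-burden patients (>= 3 mutations): 170
  rule-positive: 66 (58 high-burden)
  prevalence among high-burden: 34.1%
  accuracy (all rule-positive): 97.0%

Survival (KM medians, months)
  rule_status: rule_positive=16.2, high_burden_no_rule=23, low_burden=29.2  (log-rank p=0.0296)
```

Reading this: at n = 433 the miner recovers the planted resistance rules
(`{ASXL1, TET2}`, `{ASXL1, SRSF2, RUNX1}`, `{TET2, SF3B1}` and supersets of
them) alongside a handful of small-support rules that pass the 0.95
confidence threshold by chance — the report's note about the absence of
multiple-testing control is there for exactly this reason. Rule-positive
patients are almost all nonresponders (97% accuracy) and have the shortest
median survival of the three strata.

The same pipeline is available from the shell:

```sh
hmarules simulate --seed 7 --n-patients 433 --out sim
hmarules run-all --matrix sim/cohort_mutations.tsv \
                 --clinical sim/cohort_clinical.tsv --out run
hmarules validate --rules run/rules.json --sim-config my_validation.yaml
```

Input formats are plain TSV: a binary patient × gene matrix (or long-form
`sample_id / gene / vaf` calls) plus a clinical table with IWG response,
overall-survival months and event flag, IPSS-R category, and therapy arm.

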