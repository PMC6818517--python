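# Methods

## Problem and pipeline

The package asks whether combinations of somatic mutations — not single
genes — predict resistance to hypomethylating agents in MDS. Each patient
with an evaluable IWG response becomes a transaction containing one token
per mutated panel gene (`ASXL1:mut`, ...) and exactly one outcome token
(`OUTCOME:RESP` for CR/PR/HI, `OUTCOME:NONRESP` for SD/PD). Frequent
itemsets are mined with Apriori, itemsets containing the outcome token are
converted to rules, rules are filtered on confidence/support/lift, and the
surviving rule set is evaluated as a biomarker panel and against overall
survival. Patients with an unevaluable (UNKNOWN) response are excluded
from mining and from every accuracy denominator; patients missing survival
fields are excluded from survival analyses only.

## Mining and rule selection

`mine_frequent` is a classic level-wise Apriori: level k+1 candidates are
generated by joining level-k itemsets that share a (k−1)-prefix, pruned by
downward closure, then counted against a boolean transaction matrix.
Output is exactly the itemsets of size ≤ `max_len` with support count ≥
`min_support_count`, deterministically ordered by (size, lexicographic
items). An exhaustive-enumeration twin (`brute_force_frequent`, guarded to
≤ 20 items) shares the output contract and serves as the test oracle.

Rule metrics are exact integer ratios: confidence = support(antecedent ∪
outcome)/support(antecedent); lift = confidence / outcome base rate.
Selection defaults:

| parameter | default | why |
|---|---|---|
| `min_support_count` | 5 | ~1% of a 433-patient cohort; a rule seen fewer than 5 times is noise at this scale |
| `min_confidence` | 0.95 | the biomarker bar: a rule should almost always be right |
| `min_lift` | 1.5 | confidence alone cannot flag near-independence when the nonresponse base rate is high (~0.57) |
| `max_len` | 5 | antecedents of ≤ 4 genes; larger rules are unsupportable at n ≈ 433 |
| wild-type tokens | off | presence/absence of mutations is the default item vocabulary; `GENE:wt` items are available behind a flag |

Redundancy: a rule whose antecedent strictly contains a kept rule's
antecedent without exceeding its confidence is dropped (most general
sufficient antecedent wins); otherwise every superset of a strong rule
floods the output. Final ordering is (lift desc, confidence desc, support
desc, lexicographic antecedent), which makes rule JSON byte-reproducible.

Only outcome tokens may be consequents; gene→gene rules are never emitted.
Both consequents are supported so the absence of response-predicting rules
is itself checkable. No multiple-testing control is applied across the
rule lattice — deliberately, since the procedure evaluated here does not
use one — and the run report flags this; small-support chance rules at
confidence 1.0 do appear at n ≈ 433.

## Evaluation quantities

`evaluate_ruleset` counts, over evaluable patients: rule-positive =
matches ≥ 1 rule; prevalence among high-burden = rule-positive with ≥ 3
mutations / all with ≥ 3 mutations; accuracy = rule-positive nonresponders
/ rule-positive. Matching a rule does **not** require the burden
threshold, so a 2-gene-rule carrier with 2 total mutations is
rule-positive yet outside the high-burden prevalence denominator; because
the two conventions genuinely differ, both `accuracy` (all rule-positive)
and `accuracy_high_burden` are reported. IPSS-R subgroups are lower (very
low + low), higher (intermediate + high + very high) and unknown risk,
with biomarker presence among each stratum's high-burden nonresponders
carried alongside.

Univariate gene tests are two-sided Fisher exact tests
(probability-ordering convention: the p-value sums hypergeometric table
probabilities not exceeding the observed table's) on the 2×2
mutated/wild-type × responder/nonresponder table, computed by
`scipy.stats.fisher_exact` and cross-checked in the tests against direct
hypergeometric enumeration of every table with n ≤ 40.

## Survival

Kaplan-Meier curves, medians and log-rank tests are computed with
lifelines behind the package's own domain types. The median is the
smallest t with S(t) ≤ 0.5 (undefined if S never reaches 0.5); its CI
inverts the log-transformed Greenwood confidence band
(Brookmeyer-Crowley-style). Deaths precede censorings at tied times. The
k-group log-rank statistic is referred to chi-square with k−1 df; the
tests compare it against a hand-rolled statistic and a 2,000-permutation
reference. The rule-status stratifier is three-way: matches ≥ 1 rule /
≥ 3 mutations without a rule / < 3 mutations.

## Synthetic cohort generator

The generator emulates an HMA-treated MDS cohort at the descriptor level:

- **Panel & marginals.** 29 recurrently mutated myeloid genes. The six
  most frequent follow the reference distribution (ASXL1 0.31, SRSF2 0.23,
  TET2 0.22, RUNX1 0.15, DNMT3A 0.14, SF3B1 0.12); the remaining 23 are
  fixed at 0.02–0.10, chosen once so the Poisson-binomial mutation count
  gives ~41% of patients ≥ 3 mutations and ~15% with none. (A cohort
  median of exactly 3 mutations is arithmetically incompatible with 41%
  ≥ 3; the generator targets the ≥ 3 fraction and the emergent median
  is 2.)
- **Co-mutation.** Statuses are drawn as independent Bernoullis, then for
  each configured pair (ASXL1 with TET2/SRSF2/RUNX1/U2AF1/DNMT3A at target
  joint fractions 0.10/0.09/0.08/0.06/0.05) the partner gene is moved from
  patients carrying it without ASXL1 onto patients carrying ASXL1 without
  it until the target joint count is reached. Each move preserves both
  genes' marginal counts exactly; higher-order structure beyond the
  configured pairs is not modelled, and real clonal architecture (mutual
  exclusivity, VAF hierarchies) is out of scope — passing tests say the
  pipeline handles data with these descriptors, not that it has seen
  realistic genomes.
- **Response.** A patient matching any planted rule is a nonresponder with
  that rule's penetrance (max over matched rules, default 0.97); everyone
  else responds with `baseline_response_prob` = 0.492, calibrated so the
  default three planted rules (~13% carriers: {ASXL1, TET2},
  {ASXL1, SRSF2, RUNX1}, {TET2, SF3B1}) give a cohort ORR ≈ 0.43.
  Responders split CR/PR/HI 109:16:59 and nonresponders SD/PD 142:107,
  matching the reference response mix.
- **Survival.** Exponential per stratum — the one-parameter family is
  fully determined by the three published stratum medians (rule-positive
  14.6, ≥ 3 mutations without a rule 22.8, otherwise 28.2 months); planted
  rules can additionally scale a carrier's hazard. Censoring: with
  probability 0.25 a patient receives an independent Uniform(0, 111.7
  months) censoring time and contributes min(death, censor); this is
  independent censoring, so KM medians stay consistent. VAFs are
  decorative Uniform(0.05, 0.60) draws.
- **Determinism.** One `numpy` Generator seeded from the config drives
  every draw in a fixed order; identical configs give bitwise-identical
  cohorts.

## Recovery-experiment design

The planted-rule recovery test (20 seeds, n = 2,000, penetrance 0.97,
default marginals) uses two pair rules on boosted pairs (joint 0.19 each)
with baseline response 0.70 and min support 40 (2% of n). These settings
are a power calculation, fixed in advance: with ~380 carriers per rule,
the probability that a penetrance-0.97 rule's observed confidence drops
below the 0.95 threshold is < 1% per seed; the high baseline response
keeps the nonresponse base rate low enough that lift ≥ 1.5 is attainable
and that any antecedent overlapping the planted carriers strongly enough
to pass the confidence bar necessarily has generator-true penetrance
≥ 0.8, making the false-discovery guard meaningful rather than vacuous.

## Numerical and interface choices

- Gene symbols are uppercased; no alias resolution. VAF is carried through
  I/O but unused by the default analysis (a VAF floor can be applied by
  filtering before matrix construction).
- TSV everywhere, UTF-8, header required, `.`/empty = missing; binary
  matrix and clinical tables round-trip bit-exactly.
- Degenerate inputs: zero-overlap profile/clinical join is an error;
  empty rule sets are legal (accuracy reported as undefined, flagged, not
  0); a consequent absent from all transactions is an error; the
  brute-force miner refuses universes > 20 items.
- Problem sizes: calibration checks use simulated cohorts of 5,000–50,000
  patients; recovery experiments 20 × 2,000; oracle equivalence uses ≤ 12
  items × ≤ 200 transactions and all 2×2 tables with n ≤ 40.

## Known limitations

- The mined rule list at n ≈ 433 contains chance rules; without a
  held-out cohort or resampling, confidence at small support is an
  optimistic estimate. `run_validation` (frozen rules, independent
  cohort) is the supported mitigation.
- The generator's joint mutation distribution is pairwise-only and its
  survival is exponential; neither claims biological realism beyond the
  calibrated descriptors.
- IPSS-R categories and therapy arms are simulated independently of
  genotype, so subgroup breakdowns on synthetic data test counting logic,
  not epidemiology.
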