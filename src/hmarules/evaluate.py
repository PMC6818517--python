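"""Biomarker evaluation: prevalence, predictive accuracy, subgroups, and
univariate gene-response tests.

The headline quantities mirror how rule-based genomic biomarkers are
reported in the HMA-resistance setting: prevalence among patients with a
high mutation burden (>= 3 mutations by default), and accuracy — the
fraction of rule-positive patients who are indeed nonresponders.  Because
2-gene rules can match patients below the burden threshold, both the
burden-conditioned and unconditioned versions of each quantity are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .cohort import Cohort, CohortError, IPSSRCategory
from .rules import RuleSet, rule_positive_mask

__all__ = [
    "EvaluationReport",
    "evaluate_ruleset",
    "subgroup_breakdown",
    "univariate_gene_test",
    "univariate_all",
]


@dataclass(frozen=True)
class EvaluationReport:
    """Counting results of applying a rule set to one cohort (or stratum).

    All denominators are restricted to patients with an evaluable
    (non-UNKNOWN) response.  ``accuracy`` uses every rule-positive patient;
    ``accuracy_high_burden`` restricts to rule-positive patients at or above
    the burden threshold.  Accuracies are ``None`` (undefined, flagged) when
    their denominator is zero.
    """

    n_total: int
    n_evaluable: int
    n_high_burden: int
    n_rule_positive: int
    n_rule_positive_high_burden: int
    n_correct: int
    n_correct_high_burden: int
    burden_threshold: int
    label: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (
            0
            <= self.n_correct
            <= self.n_rule_positive
            <= self.n_evaluable
            <= self.n_total
        ):
            raise CohortError("inconsistent evaluation counts")

    @property
    def prevalence_high_burden(self) -> Optional[float]:
        if self.n_high_burden == 0:
            return None
        return self.n_rule_positive_high_burden / self.n_high_burden

    @property
    def prevalence_overall(self) -> Optional[float]:
        if self.n_evaluable == 0:
            return None
        return self.n_rule_positive / self.n_evaluable

    @property
    def accuracy(self) -> Optional[float]:
        if self.n_rule_positive == 0:
            return None
        return self.n_correct / self.n_rule_positive

    @property
    def accuracy_high_burden(self) -> Optional[float]:
        if self.n_rule_positive_high_burden == 0:
            return None
        return self.n_correct_high_burden / self.n_rule_positive_high_burden

    @property
    def accuracy_defined(self) -> bool:
        return self.n_rule_positive > 0

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_total": self.n_total,
            "n_evaluable": self.n_evaluable,
            "n_high_burden": self.n_high_burden,
            "n_rule_positive": self.n_rule_positive,
            "n_rule_positive_high_burden": self.n_rule_positive_high_burden,
            "n_correct": self.n_correct,
            "n_correct_high_burden": self.n_correct_high_burden,
            "burden_threshold": self.burden_threshold,
            "prevalence_high_burden": self.prevalence_high_burden,
            "prevalence_overall": self.prevalence_overall,
            "accuracy": self.accuracy,
            "accuracy_high_burden": self.accuracy_high_burden,
            "accuracy_defined": self.accuracy_defined,
            **({"extra": self.extra} if self.extra else {}),
        }


def _evaluate_masked(
    cohort: Cohort,
    rules: RuleSet,
    keep: np.ndarray,
    burden_threshold: int,
    label: str = "",
) -> EvaluationReport:
    evaluable = cohort.evaluable_mask() & keep
    counts = cohort.mutation_counts()
    high = evaluable & (counts >= burden_threshold)
    positive = rule_positive_mask(cohort, rules) & evaluable
    nonresp = cohort.nonresponder_mask()
    return EvaluationReport(
        n_total=int(keep.sum()),
        n_evaluable=int(evaluable.sum()),
        n_high_burden=int(high.sum()),
        n_rule_positive=int(positive.sum()),
        n_rule_positive_high_burden=int((positive & high).sum()),
        n_correct=int((positive & nonresp).sum()),
        n_correct_high_burden=int((positive & high & nonresp).sum()),
        burden_threshold=burden_threshold,
        label=label,
    )


def evaluate_ruleset(
    cohort: Cohort, rules: RuleSet, burden_threshold: int = 3
) -> EvaluationReport:
    """Apply the rule set to the whole cohort.

    Rule matching does not itself require the burden threshold: a 2-gene
    rule carrier with only those 2 mutations is rule-positive but sits
    outside the high-burden prevalence denominator.
    """
    return _evaluate_masked(
        cohort, rules, np.ones(len(cohort), dtype=bool), burden_threshold
    )


_LOWER_RISK = {IPSSRCategory.VERY_LOW, IPSSRCategory.LOW}
_HIGHER_RISK = {
    IPSSRCategory.INTERMEDIATE,
    IPSSRCategory.HIGH,
    IPSSRCategory.VERY_HIGH,
}


def subgroup_breakdown(
    cohort: Cohort, rules: RuleSet, burden_threshold: int = 3
) -> dict[str, EvaluationReport]:
    """Per-IPSS-R-stratum evaluation: lower (very low + low), higher
    (intermediate + high + very high), and unknown risk.

    Each stratum report additionally carries, under ``extra``, the biomarker
    presence among that stratum's high-burden nonresponders — the subgroup
    quantity reported alongside overall prevalence.
    """
    ipssr = np.array([c.ipssr for c in cohort.clinical], dtype=object)
    strata = {
        "lower_risk": np.array([x in _LOWER_RISK for x in ipssr]),
        "higher_risk": np.array([x in _HIGHER_RISK for x in ipssr]),
        "unknown_risk": np.array([x is IPSSRCategory.UNKNOWN for x in ipssr]),
    }
    counts = cohort.mutation_counts()
    nonresp = cohort.nonresponder_mask()
    positive = rule_positive_mask(cohort, rules)
    out = {}
    for name, mask in strata.items():
        if not mask.any():
            continue
        rep = _evaluate_masked(cohort, rules, mask, burden_threshold, label=name)
        nr_high = mask & nonresp & (counts >= burden_threshold)
        extra = {
            "n_nonresponders_high_burden": int(nr_high.sum()),
            "n_nonresponders_high_burden_rule_positive": int(
                (nr_high & positive).sum()
            ),
        }
        out[name] = EvaluationReport(
            **{
                **{
                    k: getattr(rep, k)
                    for k in (
                        "n_total",
                        "n_evaluable",
                        "n_high_burden",
                        "n_rule_positive",
                        "n_rule_positive_high_burden",
                        "n_correct",
                        "n_correct_high_burden",
                        "burden_threshold",
                        "label",
                    )
                },
                "extra": extra,
            }
        )
    assert sum(int(m.sum()) for m in strata.values()) == len(cohort)
    return out


def univariate_gene_test(cohort: Cohort, gene: str):
    """Two-sided Fisher's exact test of one gene against response.

    Returns ``(p_value, table)`` where ``table`` is the 2x2 array
    [[mut & responder, mut & nonresponder],
     [wt & responder,  wt & nonresponder]] over evaluable patients.  The
    p-value follows the probability-ordering two-sided convention (sum of
    hypergeometric table probabilities not exceeding the observed table's).
    """
    g = str(gene).upper()
    if g not in cohort.panel:
        raise CohortError(f"gene {g} not in panel")
    evaluable = cohort.evaluable_mask()
    if not evaluable.any():
        raise CohortError("no evaluable patients")
    mut = np.array([p.has(g) for p in cohort.profiles])
    resp = cohort.responder_mask()
    table = np.array(
        [
            [int((mut & resp & evaluable).sum()), int((mut & ~resp & evaluable).sum())],
            [int((~mut & resp & evaluable).sum()), int((~mut & ~resp & evaluable).sum())],
        ]
    )
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p), table


def univariate_all(cohort: Cohort):
    """Fisher's exact test for every panel gene; returns a DataFrame
    (gene, n_mut, n_wt, resp_mut, resp_wt, p) sorted by p."""
    import pandas as pd

    rows = []
    for g in cohort.panel:
        p, t = univariate_gene_test(cohort, g)
        rows.append(
            {
                "gene": g,
                "n_mut": int(t[0].sum()),
                "n_wt": int(t[1].sum()),
                "resp_mut": int(t[0, 0]),
                "resp_wt": int(t[1, 0]),
                "p": p,
            }
        )
    return pd.DataFrame(rows).sort_values("p", kind="stable").reset_index(drop=True)
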