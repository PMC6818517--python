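"""Association rules with outcome-restricted consequents.

Rules take the form {gene tokens} -> outcome token, scored by support,
confidence (P(outcome | antecedent)) and lift (confidence over the outcome
base rate).  Selection applies the confidence / support / lift thresholds
and a most-general-antecedent redundancy policy, then orders rules by
(lift desc, confidence desc, support desc, antecedent lexicographic).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .cohort import CohortError, GenePanel, MutationProfile
from .mining import (
    OUTCOME_NONRESP,
    OUTCOME_RESP,
    FrequentItemset,
    Transaction,
)

__all__ = [
    "AssociationRule",
    "RuleSet",
    "generate_rules",
    "select_rules",
    "match_rule",
    "rule_positive_mask",
]

_OUTCOMES = {OUTCOME_RESP, OUTCOME_NONRESP}


@dataclass(frozen=True)
class AssociationRule:
    """antecedent (gene tokens) -> consequent (outcome token), with counts.

    ``support_count`` counts transactions containing antecedent and
    consequent; ``antecedent_count`` those containing the antecedent;
    ``consequent_count`` the consequent's base count over ``n_transactions``.
    """

    antecedent: frozenset[str]
    consequent: str
    support_count: int
    antecedent_count: int
    consequent_count: int
    n_transactions: int

    def __post_init__(self):
        object.__setattr__(self, "antecedent", frozenset(self.antecedent))
        if not self.antecedent:
            raise ValueError("antecedent must be non-empty")
        if self.consequent not in _OUTCOMES:
            raise ValueError(f"consequent must be an outcome token, got {self.consequent}")
        if not (0 < self.support_count <= self.antecedent_count):
            raise ValueError("need 0 < support_count <= antecedent_count")
        if self.consequent_count <= 0:
            raise ValueError("consequent_count must be positive")

    @property
    def confidence(self) -> float:
        return self.support_count / self.antecedent_count

    @property
    def base_rate(self) -> float:
        return self.consequent_count / self.n_transactions

    @property
    def lift(self) -> float:
        return self.confidence / self.base_rate

    @property
    def support_frac(self) -> float:
        return self.support_count / self.n_transactions

    def sort_key(self):
        return (
            -self.lift,
            -self.confidence,
            -self.support_count,
            tuple(sorted(self.antecedent)),
        )

    def to_dict(self) -> dict:
        return {
            "antecedent": sorted(self.antecedent),
            "consequent": self.consequent,
            "support_count": self.support_count,
            "antecedent_count": self.antecedent_count,
            "consequent_count": self.consequent_count,
            "n_transactions": self.n_transactions,
            "confidence": self.confidence,
            "lift": self.lift,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AssociationRule":
        return cls(
            antecedent=frozenset(d["antecedent"]),
            consequent=d["consequent"],
            support_count=int(d["support_count"]),
            antecedent_count=int(d["antecedent_count"]),
            consequent_count=int(d["consequent_count"]),
            n_transactions=int(d["n_transactions"]),
        )


@dataclass(frozen=True)
class RuleSet:
    """An ordered list of selected rules plus the selection criteria used."""

    rules: tuple[AssociationRule, ...]
    criteria: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "rules", tuple(self.rules))

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    def to_json(self, path=None) -> str:
        payload = {
            "criteria": self.criteria,
            "rules": [r.to_dict() for r in self.rules],
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source) -> "RuleSet":
        if isinstance(source, (str, Path)) and Path(source).exists():
            payload = json.loads(Path(source).read_text(encoding="utf-8"))
        else:
            payload = json.loads(source)
        return cls(
            rules=tuple(AssociationRule.from_dict(d) for d in payload["rules"]),
            criteria=payload.get("criteria", {}),
        )

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(
                "antecedent\tconsequent\tsupport_count\tantecedent_count\t"
                "confidence\tlift\n"
            )
            for r in self.rules:
                fh.write(
                    f"{'|'.join(sorted(r.antecedent))}\t{r.consequent}\t"
                    f"{r.support_count}\t{r.antecedent_count}\t"
                    f"{r.confidence:.4f}\t{r.lift:.4f}\n"
                )


def generate_rules(
    frequent: Sequence[FrequentItemset],
    transactions: Sequence[Transaction],
    consequent: str = OUTCOME_NONRESP,
) -> list[AssociationRule]:
    """One rule per frequent itemset containing the consequent token.

    The antecedent is the itemset minus the consequent (size >= 1); the
    antecedent's own support is looked up among the frequent itemsets, where
    downward closure guarantees it is present.
    """
    if consequent not in _OUTCOMES:
        raise ValueError(f"consequent must be an outcome token, got {consequent}")
    n = len(transactions)
    consequent_count = sum(1 for t in transactions if consequent in t.items)
    if consequent_count == 0:
        raise CohortError(f"consequent {consequent} appears in no transaction")
    support = {s.items: s.support_count for s in frequent}
    rules = []
    for s in frequent:
        if consequent not in s.items or len(s.items) < 2:
            continue
        antecedent = s.items - {consequent}
        rules.append(
            AssociationRule(
                antecedent=antecedent,
                consequent=consequent,
                support_count=s.support_count,
                antecedent_count=support[antecedent],
                consequent_count=consequent_count,
                n_transactions=n,
            )
        )
    return sorted(rules, key=AssociationRule.sort_key)


def select_rules(
    rules: Sequence[AssociationRule],
    min_confidence: float = 0.95,
    min_support_count: int = 1,
    min_lift: Optional[float] = 1.5,
    redundancy_policy: str = "most_general",
) -> RuleSet:
    """Apply the selection thresholds and redundancy policy.

    Thresholds: confidence >= min_confidence, support_count >=
    min_support_count and, when ``min_lift`` is not None, lift >= min_lift.
    Under the default "most_general" redundancy policy, a rule is dropped
    when its antecedent is a strict superset of a kept rule's antecedent and
    its confidence does not exceed that rule's: the most general sufficient
    antecedent wins.  ``redundancy_policy="none"`` keeps every passing rule.
    """
    if not (0.0 < min_confidence <= 1.0):
        raise ValueError("min_confidence must be in (0, 1]")
    if redundancy_policy not in ("most_general", "none"):
        raise ValueError(f"unknown redundancy policy {redundancy_policy!r}")
    passing = [
        r
        for r in rules
        if r.confidence >= min_confidence
        and r.support_count >= min_support_count
        and (min_lift is None or r.lift >= min_lift)
    ]
    if redundancy_policy == "most_general":
        kept: list[AssociationRule] = []
        for r in sorted(passing, key=lambda r: (len(r.antecedent), r.sort_key())):
            dominated = any(
                k.antecedent < r.antecedent and r.confidence <= k.confidence
                for k in kept
            )
            if not dominated:
                kept.append(r)
    else:
        kept = list(passing)
    kept.sort(key=AssociationRule.sort_key)
    return RuleSet(
        rules=tuple(kept),
        criteria={
            "min_confidence": min_confidence,
            "min_support_count": min_support_count,
            "min_lift": min_lift,
            "redundancy_policy": redundancy_policy,
        },
    )


def _split_token(token: str) -> tuple[str, bool]:
    if ":" not in token:
        return token, True  # bare gene symbol means mutated
    gene, _, state = token.rpartition(":")
    if state not in ("mut", "wt") or not gene:
        raise CohortError(f"malformed antecedent token {token!r}")
    return gene, state == "mut"


def match_rule(
    profile: MutationProfile,
    rule: AssociationRule,
    panel: Optional[GenePanel] = None,
) -> bool:
    """True iff the profile satisfies every antecedent token.

    ``GENE:mut`` requires the gene mutated, ``GENE:wt`` requires it
    wild-type.  When a panel is supplied, antecedent genes outside it raise.
    """
    for token in rule.antecedent:
        gene, want_mut = _split_token(token)
        if panel is not None and gene not in panel:
            raise CohortError(f"rule gene {gene} not in panel")
        if profile.has(gene) != want_mut:
            return False
    return True


def rule_positive_mask(cohort, rules):
    """Boolean mask over cohort patients matching >= 1 rule.

    Accepts a RuleSet or any iterable of objects with an ``antecedent`` of
    gene tokens (bare gene symbols are read as ``:mut``), e.g. the
    simulator's planted rules.
    """
    import numpy as np

    rule_list = rules.rules if isinstance(rules, RuleSet) else tuple(rules)
    return np.array(
        [
            any(match_rule(p, r, cohort.panel) for r in rule_list)
            for p in cohort.profiles
        ],
        dtype=bool,
    )
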