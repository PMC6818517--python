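"""Kaplan-Meier estimation and log-rank comparisons.

Thin domain layer over lifelines: product-limit curves with median OS and a
Brookmeyer-Crowley-style median CI (inversion of the log-transformed
Greenwood confidence band), plus the k-group log-rank test.  Strata can be
defined by response, mutation burden, a single gene, or rule-carrier status.

Convention for ties: deaths precede censorings at the same time (the
standard product-limit convention, as implemented by lifelines).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times

from .cohort import Cohort, CohortError
from .rules import RuleSet, rule_positive_mask

__all__ = [
    "SurvivalSample",
    "KMCurve",
    "LogrankResult",
    "km_fit",
    "logrank",
    "stratify_and_compare",
    "StratifiedComparison",
]


class SurvivalSample(NamedTuple):
    time: float
    event: int


@dataclass(frozen=True)
class KMCurve:
    """A fitted product-limit curve.

    ``times`` are the distinct observed times (events and censorings),
    ``survival`` the step-function values after each time, ``at_risk`` and
    ``n_events`` the risk-set size and death count at each time.  ``median``
    is the smallest time with S(t) <= 0.5, ``None`` when S never reaches
    0.5; ``median_ci`` bounds may be ``None`` when undefined.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    n_samples: int
    median: Optional[float]
    median_ci: tuple[Optional[float], Optional[float]]

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


class LogrankResult(NamedTuple):
    statistic: float
    df: int
    p_value: float


def _clean(x: Optional[float]) -> Optional[float]:
    if x is None or not math.isfinite(x):
        return None
    return float(x)


def km_fit(samples: Sequence[SurvivalSample], alpha: float = 0.05) -> KMCurve:
    """Product-limit estimate from (time, event) samples."""
    if not len(samples):
        raise CohortError("km_fit needs >= 1 sample")
    times = np.array([s[0] for s in samples], dtype=float)
    events = np.array([s[1] for s in samples], dtype=int)
    if (times < 0).any():
        raise CohortError("negative survival time")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(times, events)
    # event_table carries a t=0 anchor row; drop it unless data start at 0
    table = kmf.event_table
    if table.index[0] == 0.0 and 0.0 not in times:
        table = table.iloc[1:]
    grid = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(grid).to_numpy(dtype=float)
    median = _clean(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo = _clean(ci.iloc[0, 0])
    hi = _clean(ci.iloc[0, 1])
    return KMCurve(
        times=grid,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(dtype=int),
        n_events=table["observed"].to_numpy(dtype=int),
        n_samples=len(samples),
        median=median,
        median_ci=(lo, hi),
    )


def logrank(groups: Sequence[Sequence[SurvivalSample]]) -> LogrankResult:
    """k-group log-rank test (chi-square with k-1 df)."""
    if len(groups) < 2:
        raise CohortError("logrank needs >= 2 groups")
    if any(len(g) == 0 for g in groups):
        raise CohortError("logrank groups must be non-empty")
    times, events, labels = [], [], []
    for i, g in enumerate(groups):
        for t, e in g:
            times.append(float(t))
            events.append(int(e))
            labels.append(i)
    if sum(events) == 0:
        raise CohortError("logrank requires >= 1 event overall")
    res = multivariate_logrank_test(times, labels, events)
    return LogrankResult(
        statistic=float(res.test_statistic),
        df=len(groups) - 1,
        p_value=float(res.p_value),
    )


@dataclass(frozen=True)
class StratifiedComparison:
    stratifier: str
    curves: dict  # stratum label -> KMCurve
    logrank: Optional[LogrankResult]
    dropped_strata: tuple[str, ...] = ()

    def medians(self) -> dict:
        return {k: v.median for k, v in self.curves.items()}

    def to_dict(self) -> dict:
        return {
            "stratifier": self.stratifier,
            "strata": {
                k: {
                    "n": int(v.n_samples),
                    "median": v.median,
                    "median_ci": list(v.median_ci),
                }
                for k, v in self.curves.items()
            },
            "logrank": (
                None
                if self.logrank is None
                else {
                    "statistic": self.logrank.statistic,
                    "df": self.logrank.df,
                    "p_value": self.logrank.p_value,
                }
            ),
            "dropped_strata": list(self.dropped_strata),
        }


_COUNT_BINS = (
    ("0", lambda c: c == 0),
    ("1-2", lambda c: (c >= 1) & (c <= 2)),
    ("3-5", lambda c: (c >= 3) & (c <= 5)),
    (">5", lambda c: c > 5),
)


def _strata_masks(
    cohort: Cohort,
    stratifier: str,
    rules: Optional[RuleSet],
    gene: Optional[str],
    burden_threshold: int,
) -> dict[str, np.ndarray]:
    counts = cohort.mutation_counts()
    if stratifier == "response":
        return {
            "responder": cohort.responder_mask(),
            "nonresponder": cohort.nonresponder_mask(),
        }
    if stratifier == "mutation_count":
        return {label: fn(counts) for label, fn in _COUNT_BINS}
    if stratifier == "gene":
        if gene is None:
            raise CohortError("gene stratifier requires gene=")
        g = str(gene).upper()
        if g not in cohort.panel:
            raise CohortError(f"gene {g} not in panel")
        mut = np.array([p.has(g) for p in cohort.profiles])
        return {f"{g}_mut": mut, f"{g}_wt": ~mut}
    if stratifier == "rule_status":
        if rules is None:
            raise CohortError("rule_status stratifier requires rules=")
        positive = rule_positive_mask(cohort, rules)
        high = counts >= burden_threshold
        return {
            "rule_positive": positive,
            "high_burden_no_rule": ~positive & high,
            "low_burden": ~positive & ~high,
        }
    raise CohortError(f"unknown stratifier {stratifier!r}")


def stratify_and_compare(
    cohort: Cohort,
    stratifier: str,
    rules: Optional[RuleSet] = None,
    gene: Optional[str] = None,
    burden_threshold: int = 3,
) -> StratifiedComparison:
    """KM curve per stratum plus a log-rank comparison.

    Strata are exhaustive and disjoint over patients with survival data
    (the response stratifier drops UNKNOWN responses).  Empty strata are
    dropped and reported in ``dropped_strata``; the log-rank test is run
    when >= 2 strata remain with >= 1 event overall.
    """
    has_surv = np.array([c.has_survival for c in cohort.clinical])
    masks = _strata_masks(cohort, stratifier, rules, gene, burden_threshold)
    curves: dict[str, KMCurve] = {}
    groups: list[list[SurvivalSample]] = []
    dropped = []
    for label, mask in masks.items():
        mask = mask & has_surv
        if not mask.any():
            dropped.append(label)
            continue
        samples = [
            SurvivalSample(c.os_months, c.os_event)
            for c, m in zip(cohort.clinical, mask)
            if m
        ]
        curves[label] = km_fit(samples)
        groups.append(samples)
    lr = None
    if len(groups) >= 2 and sum(e for g in groups for _, e in g) > 0:
        lr = logrank(groups)
    return StratifiedComparison(
        stratifier=stratifier,
        curves=curves,
        logrank=lr,
        dropped_strata=tuple(dropped),
    )


def write_curves_tsv(path, comparison: StratifiedComparison) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("stratum\ttime\tsurvival\tat_risk\tn_events\n")
        for label, curve in comparison.curves.items():
            for t, s, r, e in zip(
                curve.times, curve.survival, curve.at_risk, curve.n_events
            ):
                fh.write(f"{label}\t{t:g}\t{s:.6g}\t{r}\t{e}\n")
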