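"""End-to-end orchestration: simulate/load -> encode -> mine -> select ->
evaluate -> survival, with every intermediate written to disk so the report
is recomputable."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .cohort import Cohort, CohortError, GenePanel
from .evaluate import evaluate_ruleset, subgroup_breakdown, univariate_all
from .io import read_cohort, write_cohort
from .mining import (
    OUTCOME_NONRESP,
    encode_transactions,
    mine_frequent,
    write_itemsets_tsv,
)
from .rules import RuleSet, generate_rules, select_rules
from .simulate import PlantedRule, SimulationConfig, simulate_cohort
from .survival import stratify_and_compare, write_curves_tsv

__all__ = ["RunConfig", "RunReport", "run_discovery", "run_validation"]

logger = logging.getLogger("hmarules")

EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3
EXIT_INTERNAL_ERROR = 4


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one discovery run.

    Exactly one of (``matrix_path`` + ``clinical_path``) or ``simulation``
    must be set.
    """

    simulation: Optional[SimulationConfig] = None
    matrix_path: Optional[str] = None
    clinical_path: Optional[str] = None
    min_support_count: int = 5
    min_confidence: float = 0.95
    min_lift: Optional[float] = 1.5
    max_len: int = 5
    burden_threshold: int = 3
    include_wildtype: bool = False
    seed: int = 0
    outdir: str = "hmarules_run"

    def __post_init__(self):
        has_paths = self.matrix_path is not None and self.clinical_path is not None
        if has_paths == (self.simulation is not None):
            raise CohortError(
                "exactly one of input paths or a simulation config must be set"
            )
        if not (0.0 < self.min_confidence <= 1.0):
            raise CohortError("min_confidence must be in (0, 1]")
        if self.min_lift is not None and self.min_lift <= 0:
            raise CohortError("min_lift must be positive")
        if self.min_support_count < 1:
            raise CohortError("min_support_count must be >= 1")
        if self.max_len < 2:
            raise CohortError("max_len must be >= 2 (antecedent + outcome)")


@dataclass
class RunReport:
    config: dict
    cohort_summary: dict
    n_frequent_itemsets: int
    ruleset: RuleSet
    evaluation: dict
    subgroups: dict
    survival: dict
    version: str = __version__


def _resolve_cohort(config: RunConfig) -> Cohort:
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        logger.info(
            "simulating cohort: n=%d, seed=%d", sim.n_patients, sim.seed
        )
        return simulate_cohort(sim)
    logger.info(
        "loading cohort: %s + %s", config.matrix_path, config.clinical_path
    )
    return read_cohort(config.matrix_path, config.clinical_path)


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.simulation is not None:
        sim = d["simulation"]
        sim["panel"] = list(config.simulation.panel)
        sim["pairwise_targets"] = {
            f"{a}|{b}": t
            for (a, b), t in config.simulation.pairwise_targets.items()
        }
        sim["planted_rules"] = [
            {
                "antecedent": sorted(r.antecedent),
                "penetrance": r.penetrance,
                "hazard_multiplier": r.hazard_multiplier,
            }
            for r in config.simulation.planted_rules
        ]
    return d


def run_discovery(config: RunConfig) -> RunReport:
    """Execute every stage and write all artifacts under ``config.outdir``.

    Deterministic given the config and seed; a stage failure leaves a
    FAILED marker naming the stage next to any partial outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "cohort"
        cohort = _resolve_cohort(config)
        write_cohort(outdir, cohort)
        from .simulate import empirical_summary

        summary = empirical_summary(cohort)
        cohort_summary = {
            "n_patients": summary["n_patients"],
            "count_median": summary["count_median"],
            "count_max": summary["count_max"],
            "frac_ge3": summary["frac_ge3"],
            "orr": summary["orr"],
        }

        stage = "encode"
        transactions = encode_transactions(
            cohort, include_wildtype=config.include_wildtype
        )
        logger.info("encoded %d transactions", len(transactions))
        with open(outdir / "transactions.tsv", "w", encoding="utf-8") as fh:
            fh.write("sample_id\titems\n")
            for t in transactions:
                fh.write(f"{t.sample_id}\t{'|'.join(sorted(t.items))}\n")

        stage = "mine"
        frequent = mine_frequent(
            transactions, config.min_support_count, config.max_len
        )
        logger.info(
            "mined %d frequent itemsets (min_support_count=%d, max_len=%d)",
            len(frequent),
            config.min_support_count,
            config.max_len,
        )
        write_itemsets_tsv(outdir / "frequent_itemsets.tsv", frequent)

        stage = "rules"
        rules = generate_rules(frequent, transactions, OUTCOME_NONRESP)
        ruleset = select_rules(
            rules,
            min_confidence=config.min_confidence,
            min_support_count=config.min_support_count,
            min_lift=config.min_lift,
        )
        logger.info(
            "selected %d resistance rules (min_confidence=%.2f, min_lift=%s)",
            len(ruleset),
            config.min_confidence,
            config.min_lift,
        )
        for r in ruleset:
            logger.debug(
                "rule %s -> %s: conf=%.3f lift=%.2f support=%d",
                sorted(r.antecedent),
                r.consequent,
                r.confidence,
                r.lift,
                r.support_count,
            )
        ruleset.to_json(outdir / "rules.json")
        ruleset.write_tsv(outdir / "rules.tsv")

        stage = "evaluate"
        evaluation = evaluate_ruleset(cohort, ruleset, config.burden_threshold)
        subgroups = subgroup_breakdown(cohort, ruleset, config.burden_threshold)
        eval_payload = {
            "training": evaluation.to_dict(),
            "subgroups": {k: v.to_dict() for k, v in subgroups.items()},
        }
        (outdir / "evaluation.json").write_text(
            json.dumps(eval_payload, indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        univariate_all(cohort).to_csv(
            outdir / "univariate_gene_tests.tsv", sep="\t", index=False
        )

        stage = "survival"
        survival_payload = {}
        for strat, kwargs in (
            ("response", {}),
            ("mutation_count", {}),
            ("rule_status", {"rules": ruleset}),
        ):
            comp = stratify_and_compare(
                cohort, strat, burden_threshold=config.burden_threshold, **kwargs
            )
            survival_payload[strat] = comp.to_dict()
            write_curves_tsv(outdir / f"km_{strat}.tsv", comp)
        (outdir / "survival.json").write_text(
            json.dumps(survival_payload, indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )

        stage = "report"
        report = RunReport(
            config=_config_dict(config),
            cohort_summary=cohort_summary,
            n_frequent_itemsets=len(frequent),
            ruleset=ruleset,
            evaluation=eval_payload["training"],
            subgroups=eval_payload["subgroups"],
            survival=survival_payload,
        )
        _write_text_report(outdir / "report.txt", report)
        return report
    except Exception as exc:
        (outdir / "FAILED").write_text(
            f"stage: {stage}\nerror: {exc}\n", encoding="utf-8"
        )
        raise


def run_validation(
    rules_path,
    matrix_path=None,
    clinical_path=None,
    simulation: Optional[SimulationConfig] = None,
    burden_threshold: int = 3,
    outdir=None,
):
    """Apply a frozen rule set to an independent cohort (no re-mining).

    The rule set is read from a prior run's ``rules.json`` and is never
    modified or re-ranked; antecedent genes missing from the cohort's panel
    are an error.
    """
    ruleset = RuleSet.from_json(rules_path)
    if simulation is not None:
        cohort = simulate_cohort(simulation)
    else:
        cohort = read_cohort(matrix_path, clinical_path)
    missing = sorted(
        {
            token.rpartition(":")[0]
            for r in ruleset.rules
            for token in r.antecedent
        }
        - set(cohort.panel)
    )
    if missing:
        raise CohortError(
            f"rule genes missing from the validation panel: {missing}"
        )
    report = evaluate_ruleset(cohort, ruleset, burden_threshold)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "validation_evaluation.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
    return report


def _fmt(x, pct=False):
    if x is None:
        return "undefined"
    return f"{100 * x:.1f}%" if pct else f"{x:.3g}"


def _write_text_report(path, report: RunReport) -> None:
    lines = [
        f"hmarules v{report.version} discovery report",
        "=" * 44,
        "",
        "Cohort",
        f"  patients: {report.cohort_summary['n_patients']}",
        f"  median mutations/sample: {report.cohort_summary['count_median']:g} "
        f"(max {report.cohort_summary['count_max']})",
        f"  fraction with >= 3 mutations: {_fmt(report.cohort_summary['frac_ge3'], pct=True)}",
        f"  overall response rate: {_fmt(report.cohort_summary['orr'], pct=True)}",
        "",
        "Mining",
        f"  frequent itemsets: {report.n_frequent_itemsets}",
        f"  thresholds: min_support_count={report.config['min_support_count']}, "
        f"min_confidence={report.config['min_confidence']}, "
        f"min_lift={report.config['min_lift']}, max_len={report.config['max_len']}",
        "  note: no multiple-testing control is applied over the rule lattice;",
        "  confidence thresholds are raw training-cohort fractions.",
        "",
        f"Selected resistance rules ({len(report.ruleset)})",
    ]
    for r in report.ruleset:
        lines.append(
            f"  {{{', '.join(sorted(r.antecedent))}}} -> {r.consequent}  "
            f"conf={r.confidence:.3f} lift={r.lift:.2f} support={r.support_count}"
        )
    ev = report.evaluation
    lines += [
        "",
        "Evaluation (training cohort)",
        f"  high-burden patients (>= {ev['burden_threshold']} mutations): "
        f"{ev['n_high_burden']}",
        f"  rule-positive: {ev['n_rule_positive']} "
        f"({ev['n_rule_positive_high_burden']} high-burden)",
        f"  prevalence among high-burden: "
        f"{_fmt(ev['prevalence_high_burden'], pct=True)}",
        f"  accuracy (all rule-positive): {_fmt(ev['accuracy'], pct=True)}",
        f"  accuracy (high-burden rule-positive): "
        f"{_fmt(ev['accuracy_high_burden'], pct=True)}",
        "",
        "Survival (KM medians, months)",
    ]
    for strat, payload in report.survival.items():
        meds = ", ".join(
            f"{k}={_fmt(v['median'])}" for k, v in payload["strata"].items()
        )
        p = payload["logrank"]["p_value"] if payload["logrank"] else None
        lines.append(f"  {strat}: {meds}  (log-rank p={_fmt(p)})")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
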