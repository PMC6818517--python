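"""Kaplan-Meier estimation and log-rank comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hmarules import (
    AssociationRule,
    CohortError,
    OUTCOME_NONRESP,
    RuleSet,
    SimulationConfig,
    km_fit,
    logrank,
    simulate_cohort,
    stratify_and_compare,
)

from conftest import build_cohort, make_patient


class TestKMFit:
    def test_hand_product_limit(self):
        """Three deaths at t=1,2,3: S = 2/3, 1/3, 0; median 2."""
        km = km_fit([(1, 1), (2, 1), (3, 1)])
        assert km.times.tolist() == [1, 2, 3]
        assert km.survival == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert km.median == 2
        assert km.at_risk.tolist() == [3, 2, 1]

    def test_all_censored_flat_curve(self):
        km = km_fit([(5, 0), (8, 0), (11, 0)])
        assert (km.survival == 1.0).all()
        assert km.median is None

    def test_uncensored_km_equals_empirical_survival(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(10, size=40)
        km = km_fit([(t, 1) for t in times])
        for t in km.times:
            assert km.survival_at(t) == pytest.approx((times > t).mean())
        # with no censoring the S(t) <= 0.5 rule picks the sample median
        sorted_t = np.sort(times)
        assert km.median == pytest.approx(sorted_t[19])  # n=40, S hits 0.5 at k=20

    @given(st.lists(st.tuples(st.floats(0, 100), st.integers(0, 1)), min_size=1, max_size=50))
    @settings(max_examples=30, deadline=None)
    def test_monotone_nonincreasing(self, samples):
        km = km_fit(samples)
        assert (np.diff(km.survival) <= 1e-12).all()
        assert km.survival[0] <= 1.0 + 1e-12


def _two_group_logrank_stat(times, events, in_group1):
    """Hand-rolled two-group log-rank chi-square, independent of the
    implementation under test."""
    order = np.argsort(times, kind="stable")
    t, e, g1 = times[order], events[order], in_group1[order]
    uniq = np.unique(t[e == 1])
    o_minus_e, var = 0.0, 0.0
    for tj in uniq:
        at_risk = t >= tj
        nj = at_risk.sum()
        n1j = (at_risk & g1).sum()
        dj = ((t == tj) & (e == 1)).sum()
        d1j = ((t == tj) & (e == 1) & g1).sum()
        o_minus_e += d1j - dj * n1j / nj
        if nj > 1:
            var += dj * (n1j / nj) * (1 - n1j / nj) * (nj - dj) / (nj - 1)
    return o_minus_e**2 / var if var > 0 else 0.0


def _permutation_logrank_p(groups, n_perm=2000, seed=0):
    """Permutation oracle: resample group labels, compare chi-square stats."""
    rng = np.random.default_rng(seed)
    pooled = groups[0] + groups[1]
    times = np.array([t for t, _ in pooled], dtype=float)
    events = np.array([e for _, e in pooled], dtype=int)
    labels = np.array([True] * len(groups[0]) + [False] * len(groups[1]))
    observed = _two_group_logrank_stat(times, events, labels)
    count = 0
    for _ in range(n_perm):
        if (
            _two_group_logrank_stat(times, events, rng.permutation(labels))
            >= observed - 1e-12
        ):
            count += 1
    return (count + 1) / (n_perm + 1)


class TestLogrank:
    def test_identical_groups_null(self):
        g = [(i + 1.0, 1) for i in range(10)]
        res = logrank([g, list(g)])
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_label_swap_invariance(self):
        a = [(i + 1.0, 1) for i in range(8)]
        b = [(i + 3.0, i % 2) for i in range(12)]
        assert logrank([a, b]).statistic == pytest.approx(
            logrank([b, a]).statistic
        )

    def test_three_groups_df(self):
        groups = [[(1, 1), (2, 1)], [(3, 1), (4, 1)], [(5, 1), (6, 1)]]
        assert logrank(groups).df == 2

    def test_separated_groups_significant(self):
        a = [(t, 1) for t in np.linspace(1, 5, 20)]
        b = [(t, 1) for t in np.linspace(10, 20, 20)]
        res = logrank([a, b])
        assert res.p_value < 0.001
        assert _permutation_logrank_p([a, b]) < 0.005

    def test_agrees_with_permutation_oracle(self):
        """Chi-square p within Monte-Carlo error of a 2000-permutation
        reference on small two-group instances."""
        rng = np.random.default_rng(7)
        for trial in range(3):
            a = [(float(t), int(e)) for t, e in zip(
                rng.exponential(10, 18), rng.random(18) < 0.8)]
            b = [(float(t), int(e)) for t, e in zip(
                rng.exponential(16, 20), rng.random(20) < 0.8)]
            if sum(e for _, e in a + b) == 0:
                continue
            p_chi = logrank([a, b]).p_value
            stat_oracle = _two_group_logrank_stat(
                np.array([t for t, _ in a + b]),
                np.array([e for _, e in a + b]),
                np.array([True] * len(a) + [False] * len(b)),
            )
            assert logrank([a, b]).statistic == pytest.approx(stat_oracle)
            p_perm = _permutation_logrank_p([a, b], seed=trial)
            se = np.sqrt(p_perm * (1 - p_perm) / 2000)
            assert abs(p_chi - p_perm) < max(4 * se, 0.02)

    def test_zero_events_rejected(self):
        with pytest.raises(CohortError, match="event"):
            logrank([[(1, 0)], [(2, 0)]])


def _ruleset(*antecedents):
    return RuleSet(
        rules=tuple(
            AssociationRule(
                frozenset(f"{g}:mut" for g in ant), OUTCOME_NONRESP, 5, 5, 10, 20
            )
            for ant in antecedents
        ),
        criteria={},
    )


class TestStratify:
    def test_response_orders_medians(self, tiny_panel):
        patients = [
            make_patient(f"R{i}", [], "CR", 30.0 + i, 1) for i in range(5)
        ] + [make_patient(f"N{i}", [], "SD", 5.0 + i, 1) for i in range(5)]
        comp = stratify_and_compare(build_cohort(tiny_panel, patients), "response")
        assert comp.curves["responder"].median > comp.curves["nonresponder"].median

    def test_mutation_count_bins_partition(self, sim_cohort_small):
        comp = stratify_and_compare(sim_cohort_small, "mutation_count")
        n_with_survival = sum(
            1 for c in sim_cohort_small.clinical if c.has_survival
        )
        assert (
            sum(c.n_samples for c in comp.curves.values()) == n_with_survival
        )

    def test_rule_status_recovers_planted_median_order(self):
        cfg = SimulationConfig(n_patients=6000, seed=23)
        cohort = simulate_cohort(cfg)
        comp = stratify_and_compare(
            cohort, "rule_status", rules=cfg.planted_rules
        )
        meds = comp.medians()
        assert (
            meds["rule_positive"]
            < meds["high_burden_no_rule"]
            < meds["low_burden"]
        )
        assert comp.logrank.p_value < 0.001

    def test_gene_stratifier_and_empty_stratum_drop(self, tiny_panel):
        patients = [make_patient(f"P{i}", ["ASXL1"], "CR", 10.0 + i, 1) for i in range(4)]
        comp = stratify_and_compare(
            build_cohort(tiny_panel, patients), "gene", gene="ASXL1"
        )
        assert set(comp.curves) == {"ASXL1_mut"}
        assert comp.dropped_strata == ("ASXL1_wt",)
        assert comp.logrank is None
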