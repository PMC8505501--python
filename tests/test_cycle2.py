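"""Type-cycle filtering, percentile cut points, tri-state interpretation, per-type stats."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hadscreen.cycle1 import SelectedCutpoint
from hadscreen.cycle2 import (
    NO_USE,
    UNCERTAIN,
    USE,
    adjust_type_confusion,
    classify_type,
    filter_by_cutpoint,
    icd10_percent,
    interpret_type_confusion,
    percentile_cutpoints,
)
from hadscreen.readjust import HIGH, LOW, compute_had_percent
from hadscreen.registry import HAD_TYPES


def sort_interpolate_percentile(values, q):
    """Closed-form linear-interpolation percentile oracle (inclusive ranks)."""
    v = sorted(values)
    rank = (len(v) - 1) * q / 100.0
    lo = int(np.floor(rank))
    hi = int(np.ceil(rank))
    return v[lo] + (v[hi] - v[lo]) * (rank - lo)


class TestFilter:
    def test_strict_greater_boundary(self, visit_factory):
        visits = [visit_factory(txn=f"t{i}") for i in range(3)]
        inc, exc = filter_by_cutpoint(visits, [0.05, 0.06, 0.07], SelectedCutpoint(0.06, 0.5))
        assert [v.txn for v in inc] == ["t2"]
        assert len(inc) + len(exc) == 3

    def test_zero_cut_includes_all_positive_probs(self, visit_factory):
        visits = [visit_factory(txn=f"t{i}") for i in range(2)]
        inc, exc = filter_by_cutpoint(visits, [0.0, 0.4], SelectedCutpoint(0.0, 0.5))
        assert [v.txn for v in inc] == ["t1"]


class TestPercentiles:
    def test_closed_form_four_values(self):
        cuts = percentile_cutpoints({"ANS": [0.1, 0.2, 0.3, 0.4]})
        assert cuts.p25["ANS"] == pytest.approx(0.175)
        assert cuts.p75["ANS"] == pytest.approx(0.325)

    def test_constant_values_collapse(self):
        cuts = percentile_cutpoints({"BIG": [0.3, 0.3, 0.3]})
        assert cuts.p25["BIG"] == cuts.p75["BIG"] == pytest.approx(0.3)

    def test_single_value_fatal(self):
        with pytest.raises(ValueError):
            percentile_cutpoints({"CVS": [0.5]})

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=200))
    @settings(deadline=None, max_examples=60)
    def test_matches_sort_and_interpolate_oracle(self, values):
        cuts = percentile_cutpoints({"CNS": values})
        assert cuts.p25["CNS"] == pytest.approx(
            sort_interpolate_percentile(values, 25), abs=1e-12
        )
        assert cuts.p75["CNS"] == pytest.approx(
            sort_interpolate_percentile(values, 75), abs=1e-12
        )

    def test_pooled_option_shares_cuts(self):
        cuts = percentile_cutpoints(
            {"ANS": [0.0, 1.0], "BIG": [0.4, 0.6]}, pooled=True
        )
        assert cuts.p25["ANS"] == cuts.p25["BIG"]


class TestClassifyType:
    @pytest.mark.parametrize(
        "prob,expected", [(0.1, NO_USE), (0.2, NO_USE), (0.5, UNCERTAIN), (0.7, USE)]
    )
    def test_tri_state_rules(self, prob, expected):
        cuts = percentile_cutpoints({"ANS": [0.2, 0.2, 0.6, 0.6]})
        assert classify_type(prob, cuts, "ANS") == expected

    def test_collapsed_zone_has_no_uncertainty(self):
        cuts = percentile_cutpoints({"END": [0.4, 0.4]})
        assert classify_type(0.4, cuts, "END") == NO_USE
        assert classify_type(0.41, cuts, "END") == USE


class TestInterpretConfusion:
    def test_worked_two_type_visit(self):
        tristates = [
            {"CVS": USE, "CNS": USE, "BIG": NO_USE, "Tumor": NO_USE, "END": NO_USE,
             "ANS": UNCERTAIN}
        ]
        conf = interpret_type_confusion(tristates, [{"CVS", "BIG"}])
        c = conf.counts
        assert c["CVS"]["tp"] == 1
        assert c["CNS"]["fp"] == 1
        assert c["BIG"]["fn"] == 1
        assert c["Tumor"]["tn"] == 1 and c["END"]["tn"] == 1
        assert c["ANS"]["excluded"] == 1

    def test_all_uncertain_counts_nothing(self):
        conf = interpret_type_confusion([{t: UNCERTAIN for t in HAD_TYPES}], [set()])
        assert all(
            conf.counts[t]["tp"] + conf.counts[t]["fp"] + conf.counts[t]["fn"]
            + conf.counts[t]["tn"] == 0
            for t in HAD_TYPES
        )

    @given(seed=st.integers(0, 500))
    @settings(deadline=None, max_examples=40)
    def test_counts_match_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        states = [
            {t: [NO_USE, UNCERTAIN, USE][rng.integers(3)] for t in HAD_TYPES}
            for _ in range(n)
        ]
        actual = [{t for t in HAD_TYPES if rng.random() < 0.3} for _ in range(n)]
        conf = interpret_type_confusion(states, actual)
        for t in HAD_TYPES:
            tp = sum(1 for s, a in zip(states, actual) if s[t] == USE and t in a)
            ex = sum(1 for s in states if s[t] == UNCERTAIN)
            assert conf.counts[t]["tp"] == tp
            assert conf.counts[t]["excluded"] == ex
            assert sum(conf.counts[t].values()) == n  # tri-states partition the visits


class TestICD10Percent:
    def test_ninety_four_of_hundred(self, toy_registry, visit_factory):
        visits = [
            visit_factory(txn=f"t{i}", icd10s=("Z921",), drugs=("Warfarin",))
            for i in range(94)
        ] + [
            visit_factory(txn=f"u{i}", icd10s=("Z921",), drugs=("Paracetamol",))
            for i in range(6)
        ]
        pct = icd10_percent(visits, toy_registry, "BIG")
        assert pct["Z921"] == pytest.approx(94.0)

    def test_code_never_with_type_is_zero(self, toy_registry, visit_factory):
        pct = icd10_percent([visit_factory(drugs=("Digoxin",))], toy_registry, "BIG")
        assert pct["X"] == 0.0

    def test_agrees_with_type_restricted_prevalence_table(self, toy_registry, visit_factory):
        rng = np.random.default_rng(7)
        pool = ["Paracetamol", "Warfarin", "Digoxin", "Morphine"]
        visits = [
            visit_factory(
                txn=f"t{i}",
                icd10s=tuple({"A", "B", "C"}.intersection(
                    {c for c in "ABC" if rng.random() < 0.6}) or {"A"}),
                drugs=tuple(rng.choice(pool, size=rng.integers(1, 4), replace=False)),
            )
            for i in range(150)
        ]
        pct = icd10_percent(visits, toy_registry, "BIG")
        table = compute_had_percent(visits, toy_registry, had_type="BIG")
        for code in pct.index:
            assert pct[code] == pytest.approx(table.percent(code))


class TestAdjustTypeConfusion:
    def test_eq_arithmetic_on_false_positives(self):
        n = 10
        states = [{"ANS": USE} for _ in range(n)]
        actual = [set() for _ in range(n)]
        likes = [{"ANS": HIGH if i < 7 else LOW} for i in range(n)]
        adj = adjust_type_confusion(states, actual, likes)["ANS"]
        assert adj.fp == 10 and adj.afp == 3 and adj.atp == 7

    def test_no_high_likelihood_errors_identity(self):
        states = [{"BIG": USE}, {"BIG": NO_USE}]
        actual = [{"BIG"}, set()]
        likes = [{"BIG": LOW}, {"BIG": HIGH}]
        adj = adjust_type_confusion(states, actual, likes)["BIG"]
        assert (adj.atp, adj.afp, adj.afn, adj.atn) == (adj.tp, adj.fp, adj.fn, adj.tn)

    @given(seed=st.integers(0, 300))
    @settings(deadline=None, max_examples=30)
    def test_per_type_conservation(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        states = [
            {t: [NO_USE, UNCERTAIN, USE][rng.integers(3)] for t in HAD_TYPES}
            for _ in range(n)
        ]
        actual = [{t for t in HAD_TYPES if rng.random() < 0.3} for _ in range(n)]
        likes = [
            {t: HIGH if rng.random() < 0.5 else LOW for t in HAD_TYPES} for _ in range(n)
        ]
        adjusted = adjust_type_confusion(states, actual, likes)
        for t, adj in adjusted.items():
            interpreted = sum(1 for s in states if s[t] != UNCERTAIN)
            assert adj.atp + adj.afp + adj.afn + adj.atn == interpreted
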