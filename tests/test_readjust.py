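"""HAD percent, likelihood classing, confusion readjustment and sFNR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hadscreen.readjust import (
    HIGH,
    LOW,
    LikelihoodClass,
    adjust_confusion,
    compute_had_percent,
    specific_fnr,
    visit_likelihood,
)
from hadscreen.registry import HAD, NON_HAD
from hadscreen.simulate import GeneratorConfig, generate, make_registry
from hadscreen.registry import aggregate_visits


class TestHadPercent:
    def test_two_of_four_visits_gives_fifty(self, toy_registry, visit_factory):
        visits = [
            visit_factory(txn="a", icd10s=("X",), drugs=("Digoxin",)),
            visit_factory(txn="b", icd10s=("X",), drugs=("Paracetamol", "Morphine")),
            visit_factory(txn="c", icd10s=("X",), drugs=("Paracetamol",)),
            visit_factory(txn="d", icd10s=("X",), drugs=("Paracetamol",)),
        ]
        table = compute_had_percent(visits, toy_registry)
        assert table.percent("X") == pytest.approx(50.0)

    def test_code_never_with_had_is_zero(self, toy_registry, visit_factory):
        table = compute_had_percent([visit_factory(icd10s=("Y",))], toy_registry)
        assert table.percent("Y") == 0.0

    def test_small_denominators_flagged_low_reliability(self, toy_registry, visit_factory):
        table = compute_had_percent([visit_factory()], toy_registry, min_visits=5)
        assert bool(table.table["low_reliability"].iloc[0])

    def test_nonpositive_sample_size_fatal(self, toy_registry, visit_factory):
        with pytest.raises(ValueError):
            compute_had_percent([visit_factory()], toy_registry, sample_size=0)

    def test_recovers_generative_association_within_binomial_error(self):
        cfg = GeneratorConfig(n_visits=500, pi={"X": 0.9}, comorbidity_mean=0.0, seed=11)
        rows, _ = generate(cfg)
        table = compute_had_percent(aggregate_visits(rows), make_registry(cfg))
        se3 = 3 * np.sqrt(0.9 * 0.1 / 500) * 100
        assert abs(table.percent("X") - 90.0) < se3

    def test_prescription_weighted_sampling_deterministic(self, toy_registry, visit_factory):
        visits = [
            visit_factory(txn=f"t{i}", icd10s=("X",), drugs=("Paracetamol",) * (i % 3 + 1))
            for i in range(30)
        ]
        a = compute_had_percent(visits, toy_registry, sample_size=20, seed=1)
        b = compute_had_percent(visits, toy_registry, sample_size=20, seed=1)
        assert a.table.equals(b.table)
        assert a.table["total_visits"].sum() <= 30


class TestVisitLikelihood:
    def test_any_code_at_or_above_threshold_is_high(self, toy_registry, visit_factory):
        visits = [
            visit_factory(txn="a", icd10s=("HIGHC",), drugs=("Digoxin",)),
            visit_factory(txn="b", icd10s=("HIGHC",), drugs=("Digoxin",)),
            visit_factory(txn="c", icd10s=("LOWC",), drugs=("Paracetamol",)),
        ]
        table = compute_had_percent(visits, toy_registry)
        v = visit_factory(icd10s=("HIGHC", "LOWC"))
        assert visit_likelihood(v, table).value == HIGH

    def test_all_codes_below_threshold_is_low(self, toy_registry, visit_factory):
        table = compute_had_percent(
            [visit_factory(icd10s=("LOWC",), drugs=("Paracetamol",))], toy_registry
        )
        assert visit_likelihood(visit_factory(icd10s=("LOWC",)), table).value == LOW

    def test_uncovered_visit_defaults_to_low(self, toy_registry, visit_factory):
        table = compute_had_percent([visit_factory(icd10s=("X",))], toy_registry)
        assert visit_likelihood(visit_factory(icd10s=("ZZZ",)), table).value == LOW


class TestAdjustConfusion:
    def test_130_false_negatives_with_97_low_gives_33_adjusted(self):
        records = [(NON_HAD, HAD, LikelihoodClass(LOW)) for _ in range(97)]
        records += [(NON_HAD, HAD, LikelihoodClass(HIGH)) for _ in range(33)]
        records += [(NON_HAD, NON_HAD, LikelihoodClass(LOW)) for _ in range(10)]
        adj = adjust_confusion(records)
        assert adj.fn == 130
        assert adj.afn == 33
        assert adj.atn == 10 + 97

    def test_high_likelihood_false_positives_become_true_positives(self):
        records = [(HAD, NON_HAD, LikelihoodClass(HIGH))] * 2 + [
            (HAD, HAD, LikelihoodClass(HIGH))
        ]
        adj = adjust_confusion(records)
        assert adj.afp == 0
        assert adj.atp == 1 + 2

    @given(
        st.lists(
            st.tuples(
                st.sampled_from([HAD, NON_HAD]),
                st.sampled_from([HAD, NON_HAD]),
                st.sampled_from([HIGH, LOW]),
            ),
            min_size=1,
            max_size=300,
        )
    )
    @settings(deadline=None, max_examples=80)
    def test_adjustment_conserves_total(self, recs):
        records = [(p, a, LikelihoodClass(l)) for p, a, l in recs]
        adj = adjust_confusion(records)
        assert adj.atp + adj.afp + adj.afn + adj.atn == len(records)
        assert adj.tp + adj.fp + adj.fn + adj.tn == len(records)

    def test_raising_threshold_moves_afp_up_and_afn_down(self, toy_registry, visit_factory):
        visits = [
            visit_factory(txn="a", icd10s=("M",), drugs=("Digoxin",)),
            visit_factory(txn="b", icd10s=("M",), drugs=("Digoxin",)),
            visit_factory(txn="c", icd10s=("M",), drugs=("Paracetamol",)),
        ]  # M sits at 66.7% prevalence
        table = compute_had_percent(visits, toy_registry)

        def adj_at(threshold):
            recs = [
                (HAD, NON_HAD, visit_likelihood(visits[2], table, threshold)),
                (NON_HAD, HAD, visit_likelihood(visits[0], table, threshold)),
            ]
            return adjust_confusion(recs)

        lo, hi = adj_at(50), adj_at(80)  # 66.7% is high at 50, low at 80
        assert hi.afp >= lo.afp
        assert hi.afn <= lo.afn

    def test_empty_fatal(self):
        with pytest.raises(ValueError):
            adjust_confusion([])


class TestSpecificFNR:
    def test_no_false_negatives_zero_ratio(self, visit_factory):
        recs = [(visit_factory(txn=f"t{i}", icd10s=("Z",)), HAD, HAD) for i in range(35)]
        frame = specific_fnr(recs)
        assert frame.loc["Z", "sfnr"] == 0.0

    def test_one_fn_among_four_visits(self, visit_factory):
        recs = [(visit_factory(txn=f"t{i}", icd10s=("Q",)), HAD, HAD) for i in range(3)]
        recs.append((visit_factory(txn="t3", icd10s=("Q",)), NON_HAD, HAD))
        frame = specific_fnr(recs)
        assert frame.loc["Q", "sfnr"] == pytest.approx(0.25)

    def test_matches_per_code_brute_force_count(self, visit_factory):
        rng = np.random.default_rng(3)
        codes = ["A", "B", "C"]
        recs = []
        for i in range(200):
            sub = [c for c in codes if rng.random() < 0.5] or ["A"]
            pred = HAD if rng.random() < 0.5 else NON_HAD
            act = HAD if rng.random() < 0.5 else NON_HAD
            recs.append((visit_factory(txn=f"t{i}", icd10s=tuple(sub)), pred, act))
        frame = specific_fnr(recs)
        for code in codes:
            total = sum(1 for v, p, a in recs if code in v.icd10_set)
            fn = sum(1 for v, p, a in recs if code in v.icd10_set and p == NON_HAD and a == HAD)
            assert frame.loc[code, "sfnr"] == pytest.approx(fn / total)
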