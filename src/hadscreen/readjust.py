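"""Post-hoc readjustment of the binary screen by diagnosis-level HAD prevalence.

"HAD percent" for an ICD10 code is the percentage of visits carrying that code
that were prescribed at least one high-alert drug.  A visit is classed as
high HAD-use likelihood when any of its codes reaches the threshold (default
50%).  The raw confusion matrix is then readjusted: false positives whose
diagnoses commonly use HADs become adjusted true positives, and false
negatives whose diagnoses rarely use HADs become adjusted true negatives —
the latter are the HAD-ICD10 mismatch candidates the protocol screens for.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .registry import HAD, HADRegistry, VisitRecord

logger = logging.getLogger(__name__)

HIGH = "high"
LOW = "low"


@dataclass(frozen=True)
class LikelihoodClass:
    value: str  # "high" | "low"
    threshold: float = 50.0

    def __post_init__(self) -> None:
        if self.value not in (HIGH, LOW):
            raise ValueError(f"likelihood must be '{HIGH}' or '{LOW}'")


@dataclass
class HADPercentTable:
    """Per-ICD10 HAD-use prevalence with sampling metadata.

    ``table`` is indexed by ICD10 with columns ``had_visits``, ``total_visits``,
    ``had_percent`` (0-100) and ``low_reliability`` (denominator below
    ``min_visits``; the prevalence of a code seen a handful of times says
    little, so such rows are flagged but still participate by default).
    """

    table: pd.DataFrame
    sample_size: Optional[int]
    seed: Optional[int]
    min_visits: int = 5
    had_type: Optional[str] = None

    def percent(self, icd10: str) -> Optional[float]:
        try:
            return float(self.table.at[icd10, "had_percent"])
        except KeyError:
            return None

    def __contains__(self, icd10: str) -> bool:
        return icd10 in self.table.index

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="icd10")


def compute_had_percent(
    visits: Sequence[VisitRecord],
    registry: HADRegistry,
    sample_size: Optional[int] = None,
    seed: int = 0,
    min_visits: int = 5,
    had_type: Optional[str] = None,
) -> HADPercentTable:
    """Per-ICD10 HAD-use prevalence: 100 x (HAD visits of code) / (total visits of code).

    When ``sample_size`` is below the total prescription count, that many
    prescriptions are sampled without replacement and aggregated back to the
    visits they touch (prescription-weighted sampling); full-data mode is the
    default.  With ``had_type`` set, only drugs of that HAD type count as HAD
    use (the per-type prevalence used in cycle 2).
    """
    if sample_size is not None and sample_size <= 0:
        raise ValueError("sample_size must be positive")
    chosen = list(visits)
    n_rx = sum(v.total_drugs for v in chosen)
    if sample_size is not None and sample_size < n_rx:
        owner = np.repeat(np.arange(len(chosen)), [v.total_drugs for v in chosen])
        picks = np.random.RandomState(seed).choice(n_rx, size=sample_size, replace=False)
        keep = sorted(set(owner[picks]))
        chosen = [chosen[i] for i in keep]

    def uses_had(v: VisitRecord) -> bool:
        if had_type is None:
            return any(registry.is_had(d) for d in v.drugs)
        return any(registry.had_type(d) == had_type for d in v.drugs)

    total: dict = {}
    had: dict = {}
    for v in chosen:
        is_had_visit = uses_had(v)
        for code in v.icd10_set:
            total[code] = total.get(code, 0) + 1
            if is_had_visit:
                had[code] = had.get(code, 0) + 1
    index = sorted(total)
    frame = pd.DataFrame(
        {
            "had_visits": [had.get(c, 0) for c in index],
            "total_visits": [total[c] for c in index],
        },
        index=pd.Index(index, name="icd10"),
    )
    frame["had_percent"] = 100.0 * frame["had_visits"] / frame["total_visits"]
    frame["low_reliability"] = frame["total_visits"] < min_visits
    return HADPercentTable(
        table=frame,
        sample_size=sample_size,
        seed=seed if sample_size is not None else None,
        min_visits=min_visits,
        had_type=had_type,
    )


def visit_likelihood(
    visit: VisitRecord, table: HADPercentTable, threshold: float = 50.0
) -> LikelihoodClass:
    """High HAD-use likelihood iff any of the visit's ICD10s reaches the threshold.

    Codes absent from the table contribute no evidence; a visit with no covered
    codes defaults to low (logged).
    """
    covered = False
    for code in visit.icd10_set:
        pct = table.percent(code)
        if pct is None:
            continue
        covered = True
        if pct >= threshold:
            return LikelihoodClass(HIGH, threshold)
    if not covered:
        logger.warning("visit %s has no ICD10 covered by the HAD-percent table", visit.txn)
    return LikelihoodClass(LOW, threshold)


@dataclass
class ConfusionAdjustment:
    """Raw and prevalence-adjusted confusion counts.

    aFP = FP - FP_high;  aTP = TP + FP_high;
    aFN = FN - FN_low;   aTN = TN + FN_low.
    The adjusted counts conserve the record total.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    fp_high: int
    fn_low: int

    @property
    def atp(self) -> int:
        return self.tp + self.fp_high

    @property
    def afp(self) -> int:
        return self.fp - self.fp_high

    @property
    def afn(self) -> int:
        return self.fn - self.fn_low

    @property
    def atn(self) -> int:
        return self.tn + self.fn_low

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if not 0 <= self.fp_high <= self.fp:
            raise ValueError("fp_high must lie in [0, FP]")
        if not 0 <= self.fn_low <= self.fn:
            raise ValueError("fn_low must lie in [0, FN]")

    def to_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "FN": self.fn, "TN": self.tn,
            "FP_high": self.fp_high, "FN_low": self.fn_low,
            "aTP": self.atp, "aFP": self.afp, "aFN": self.afn, "aTN": self.atn,
        }


def adjust_confusion(
    records: Iterable[Tuple[str, str, LikelihoodClass]]
) -> ConfusionAdjustment:
    """Readjust a confusion matrix from ``(predicted, actual, likelihood)`` records.

    High-likelihood false positives move to adjusted true positives (the
    diagnosis profile supports HAD use even though none was recorded in this
    sample); low-likelihood false negatives move to adjusted true negatives
    (the HAD prescription is unsupported by the diagnosis profile — these feed
    the mismatch report).
    """
    tp = fp = fn = tn = fp_high = fn_low = 0
    n = 0
    for predicted, actual, likelihood in records:
        n += 1
        like = likelihood.value if isinstance(likelihood, LikelihoodClass) else likelihood
        if predicted == HAD and actual == HAD:
            tp += 1
        elif predicted == HAD:
            fp += 1
            if like == HIGH:
                fp_high += 1
        elif actual == HAD:
            fn += 1
            if like == LOW:
                fn_low += 1
        else:
            tn += 1
    if n == 0:
        raise ValueError("adjust_confusion requires at least one record")
    return ConfusionAdjustment(tp=tp, fp=fp, fn=fn, tn=tn, fp_high=fp_high, fn_low=fn_low)


def specific_fnr(
    records: Iterable[Tuple[VisitRecord, str, str]],
    had_percent: Optional[HADPercentTable] = None,
) -> pd.DataFrame:
    """Per-ICD10 specific false-negative ratio: FN visits of a code over total visits of it.

    Each record is ``(visit, predicted, actual)``; a visit contributes to every
    ICD10 it carries.  When a HAD-percent table is supplied its prevalence is
    joined in so the report can be sorted by HAD percent.
    """
    fn_count: dict = {}
    total: dict = {}
    for visit, predicted, actual in records:
        is_fn = predicted != HAD and actual == HAD
        for code in visit.icd10_set:
            total[code] = total.get(code, 0) + 1
            if is_fn:
                fn_count[code] = fn_count.get(code, 0) + 1
    index = sorted(total)
    frame = pd.DataFrame(
        {
            "fn_count": [fn_count.get(c, 0) for c in index],
            "total_visits": [total[c] for c in index],
        },
        index=pd.Index(index, name="icd10"),
    )
    frame["sfnr"] = frame["fn_count"] / frame["total_visits"]
    if had_percent is not None:
        frame["had_percent"] = [had_percent.percent(c) for c in index]
        frame = frame.sort_values("had_percent", ascending=False)
    return frame
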