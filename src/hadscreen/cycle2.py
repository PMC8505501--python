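"""Cycle 2: HAD-type screening with percentile uncertainty zones.

Visits passing the cycle-1 cut point are re-screened with a seven-class model
(six HAD types plus non-HAD).  For each HAD type the 25th and 75th percentiles
of the test-set prediction distribution bound an uncertainty zone: predictions
at or below P25 are read as no use, above P75 as use, and in between are
excluded from interpretation.  The non-HAD column is never interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .cycle1 import SelectedCutpoint
from .readjust import HIGH, LOW, ConfusionAdjustment, LikelihoodClass
from .registry import HAD_TYPES, HADRegistry, VisitRecord

NO_USE = "no_use"
UNCERTAIN = "uncertain"
USE = "use"


def filter_by_cutpoint(
    visits: Sequence[VisitRecord],
    cycle1_probs: Sequence[float],
    cutpoint: SelectedCutpoint,
) -> Tuple[list, list]:
    """Partition visits by the cycle-1 screen: included iff probability > cut point.

    The excluded partition is retained — it is re-screened in evaluation mode
    (actual-HAD visits there are false negatives of the binary screen).
    """
    if len(visits) != len(cycle1_probs):
        raise ValueError("visits and cycle1_probs must be aligned")
    included, excluded = [], []
    for v, p in zip(visits, cycle1_probs):
        (included if p > cutpoint.value else excluded).append(v)
    return included, excluded


@dataclass
class TypeCutpoints:
    """Per-type P25/P75 cut points from the test-set prediction distribution."""

    p25: Dict[str, float]
    p75: Dict[str, float]
    convention: str = "linear"
    pooled: bool = False

    def __post_init__(self) -> None:
        for t in self.p25:
            if self.p25[t] > self.p75[t]:
                raise ValueError(f"P25 > P75 for type {t}")


def percentile_cutpoints(
    probs_by_type: Mapping[str, Sequence[float]], pooled: bool = False
) -> TypeCutpoints:
    """P25/P75 per HAD type, linear interpolation between closest ranks.

    With ``pooled=True`` the percentiles are computed once over all types'
    predictions and shared.  Fewer than two values for a type is fatal.
    """
    arrays = {t: np.asarray(v, dtype=float) for t, v in probs_by_type.items()}
    for t, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"need at least 2 prediction values for type {t}")
    if pooled:
        allv = np.concatenate(list(arrays.values()))
        lo, hi = np.percentile(allv, [25, 75], method="linear")
        return TypeCutpoints(
            p25={t: float(lo) for t in arrays},
            p75={t: float(hi) for t in arrays},
            pooled=True,
        )
    p25, p75 = {}, {}
    for t, arr in arrays.items():
        lo, hi = np.percentile(arr, [25, 75], method="linear")
        p25[t], p75[t] = float(lo), float(hi)
    return TypeCutpoints(p25=p25, p75=p75)


def classify_type(prob: float, cuts: TypeCutpoints, had_type: str) -> str:
    """Tri-state read of one type probability: no_use (<=P25) / uncertain / use (>P75).

    When P25 equals P75 the no-use rule applies first, so there is no
    uncertainty zone.
    """
    if prob <= cuts.p25[had_type]:
        return NO_USE
    if prob > cuts.p75[had_type]:
        return USE
    return UNCERTAIN


@dataclass
class TypeConfusion:
    """Per-type confusion counts with the uncertainty-zone exclusions."""

    counts: Dict[str, Dict[str, int]] = field(default_factory=dict)

    def metrics(self) -> pd.DataFrame:
        """Accuracy/precision/recall/F1 per type with N = actual positives interpreted."""
        rows = []
        for t in HAD_TYPES:
            c = self.counts.get(t, dict(tp=0, fp=0, fn=0, tn=0, excluded=0))
            tp, fp, fn, tn = c["tp"], c["fp"], c["fn"], c["tn"]
            denom = tp + fp + fn + tn
            precision = tp / (tp + fp) if tp + fp else 0.0
            recall = tp / (tp + fn) if tp + fn else 0.0
            f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
            rows.append(
                {
                    "type": t,
                    "accuracy": (tp + tn) / denom if denom else 0.0,
                    "precision": precision,
                    "recall": recall,
                    "f1": f1,
                    "n": tp + fn,
                    "excluded": c["excluded"],
                }
            )
        return pd.DataFrame(rows).set_index("type")


def interpret_type_confusion(
    tristates: Sequence[Mapping[str, str]],
    actual_types: Sequence[Set[str]],
) -> TypeConfusion:
    """Count TP/FP/FN/TN per HAD type from tri-state calls against actual type sets.

    use & actual -> TP; use & not actual -> FP; no_use & actual -> FN;
    no_use & not actual -> TN; uncertain -> excluded.  The non-HAD column must
    not appear in the tri-states (it is never interpreted).
    """
    if len(tristates) != len(actual_types):
        raise ValueError("tristates and actual_types must be aligned")
    counts = {t: dict(tp=0, fp=0, fn=0, tn=0, excluded=0) for t in HAD_TYPES}
    for states, actual in zip(tristates, actual_types):
        for t, state in states.items():
            if t not in counts:
                raise ValueError(f"unknown HAD type {t!r} in tri-states")
            is_actual = t in actual
            if state == UNCERTAIN:
                counts[t]["excluded"] += 1
            elif state == USE:
                counts[t]["tp" if is_actual else "fp"] += 1
            elif state == NO_USE:
                counts[t]["fn" if is_actual else "tn"] += 1
            else:
                raise ValueError(f"unknown tri-state {state!r}")
    return TypeConfusion(counts=counts)


def icd10_percent(
    visits: Sequence[VisitRecord], registry: HADRegistry, had_type: str
) -> pd.Series:
    """Percentage of a code's visits that carry at least one HAD of the given type.

    Direct counting over the visit list, independent of the prevalence-table
    machinery; values are on the 0-100 scale, indexed by ICD10.
    """
    if had_type not in HAD_TYPES:
        raise ValueError(f"unknown HAD type {had_type!r}")
    total: dict = {}
    with_type: dict = {}
    for v in visits:
        has_type = any(registry.had_type(d) == had_type for d in v.drugs)
        for code in v.icd10_set:
            total[code] = total.get(code, 0) + 1
            if has_type:
                with_type[code] = with_type.get(code, 0) + 1
    index = sorted(total)
    values = [100.0 * with_type.get(c, 0) / total[c] for c in index]
    return pd.Series(values, index=pd.Index(index, name="icd10"), name=f"icd10_percent_{had_type}")


def adjust_type_confusion(
    tristates: Sequence[Mapping[str, str]],
    actual_types: Sequence[Set[str]],
    likelihoods_by_type: Sequence[Mapping[str, object]],
) -> Dict[str, ConfusionAdjustment]:
    """Prevalence readjustment applied independently within each HAD type.

    ``likelihoods_by_type[i][t]`` is the i-th visit's high/low HAD-use
    likelihood under the type-t prevalence table.  Uncertain calls stay
    excluded; within each type the adjusted counts conserve the interpreted
    total.
    """
    if not (len(tristates) == len(actual_types) == len(likelihoods_by_type)):
        raise ValueError("inputs must be aligned")
    out: Dict[str, ConfusionAdjustment] = {}
    for t in HAD_TYPES:
        tp = fp = fn = tn = fp_high = fn_low = 0
        for states, actual, likes in zip(tristates, actual_types, likelihoods_by_type):
            state = states.get(t)
            if state is None or state == UNCERTAIN:
                continue
            like = likes.get(t, LikelihoodClass(LOW))
            like_val = like.value if isinstance(like, LikelihoodClass) else like
            is_actual = t in actual
            if state == USE and is_actual:
                tp += 1
            elif state == USE:
                fp += 1
                if like_val == HIGH:
                    fp_high += 1
            elif state == NO_USE and is_actual:
                fn += 1
                if like_val == LOW:
                    fn_low += 1
            else:
                tn += 1
        if tp + fp + fn + tn:
            out[t] = ConfusionAdjustment(
                tp=tp, fp=fp, fn=fn, tn=tn, fp_high=fp_high, fn_low=fn_low
            )
    return out
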