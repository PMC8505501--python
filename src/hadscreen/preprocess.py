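"""Feature matrices and labels for both screening cycles.

The cycle-1 feature schema is: a binary male indicator, integer age, one binary
indicator per ICD10 code observed at fit time, and the integer count of drugs
prescribed in the visit.  Cycle 2 appends the cycle-1 HAD probability as one
extra column.  Drug identities are never features — they are the label.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .registry import HAD, HAD_TYPES, NON_HAD, HADRegistry, VisitRecord

logger = logging.getLogger(__name__)

#: the seven cycle-2 classes, in fixed reporting order
TYPE_LABELS = HAD_TYPES + (NON_HAD,)


def label_binary(visit: VisitRecord, registry: HADRegistry) -> str:
    """``"HAD"`` iff the visit has at least one high-alert-drug prescription."""
    return HAD if any(registry.is_had(d) for d in visit.drugs) else NON_HAD


class FeatureBuilder:
    """Builds the visit-level feature matrix with an ICD10 vocabulary frozen at fit time.

    Unseen ICD10 codes at transform time map to all-zero indicators (dropped
    with a log message), so train/test matrices always share one column set.
    """

    def __init__(self) -> None:
        self.vocabulary_: Optional[list] = None

    def fit(self, visits: Sequence[VisitRecord]) -> "FeatureBuilder":
        vocab = sorted({code for v in visits for code in v.icd10_set})
        self.vocabulary_ = vocab
        return self

    @property
    def columns(self) -> list:
        if self.vocabulary_ is None:
            raise RuntimeError("FeatureBuilder not fitted")
        return ["male", "age", *self.vocabulary_, "total_drugs"]

    def transform(
        self,
        visits: Sequence[VisitRecord],
        cycle1_probs: Optional[Sequence[float]] = None,
    ) -> pd.DataFrame:
        if self.vocabulary_ is None:
            raise RuntimeError("FeatureBuilder not fitted")
        if cycle1_probs is not None and len(cycle1_probs) != len(visits):
            raise ValueError(
                f"cycle1_probs length {len(cycle1_probs)} != n visits {len(visits)}"
            )
        vocab_index = {c: i for i, c in enumerate(self.vocabulary_)}
        n, k = len(visits), len(vocab_index)
        icd = np.zeros((n, k), dtype=np.int8)
        male = np.zeros(n, dtype=np.int8)
        age = np.zeros(n, dtype=np.int64)
        total = np.zeros(n, dtype=np.int64)
        n_unseen = 0
        for i, v in enumerate(visits):
            male[i] = 1 if v.gender == "male" else 0
            age[i] = v.age
            total[i] = v.total_drugs
            for code in v.icd10_set:
                j = vocab_index.get(code)
                if j is None:
                    n_unseen += 1
                else:
                    icd[i, j] = 1
        if n_unseen:
            logger.info("dropped %d ICD10 occurrences outside the fitted vocabulary", n_unseen)
        data = {"male": male, "age": age}
        for code, j in vocab_index.items():
            data[code] = icd[:, j]
        data["total_drugs"] = total
        frame = pd.DataFrame(data, index=[v.txn for v in visits])
        if cycle1_probs is not None:
            probs = np.asarray(cycle1_probs, dtype=float)
            if probs.min() < 0 or probs.max() > 1:
                raise ValueError("cycle-1 probabilities must lie in [0, 1]")
            frame["had_prob"] = probs
        return frame


def build_features(
    visits: Sequence[VisitRecord],
    cycle1_probs: Optional[Sequence[float]] = None,
    builder: Optional[FeatureBuilder] = None,
) -> pd.DataFrame:
    """Convenience wrapper: fit a :class:`FeatureBuilder` (unless given) and transform."""
    if builder is None:
        builder = FeatureBuilder().fit(visits)
    return builder.transform(visits, cycle1_probs=cycle1_probs)


def expand_type_instances(
    visits: Sequence[VisitRecord], registry: HADRegistry
) -> tuple:
    """Expand visits into cycle-2 instances, one per distinct HAD type prescribed.

    A visit with no HAD prescriptions yields exactly one ``"non-HAD"`` instance;
    a visit prescribed drugs of m distinct HAD types yields m instances sharing
    the visit's feature row.  Returns ``(expanded_visits, labels)`` aligned
    element-wise; grouping by TXN recovers every input visit.
    """
    expanded: list = []
    labels: list = []
    for v in visits:
        types = registry.visit_types(v)
        if not types:
            expanded.append(v)
            labels.append(NON_HAD)
        else:
            for t in HAD_TYPES:  # fixed order keeps the expansion deterministic
                if t in types:
                    expanded.append(v)
                    labels.append(t)
    return expanded, labels


@dataclass(frozen=True)
class SplitResult:
    train: list
    test: list


def split_train_test(items: Sequence, ratio: float = 0.75, seed: int = 0) -> SplitResult:
    """Seeded shuffle and fixed split; the test set holds ``round-half-up(N * (1 - ratio))`` items.

    Deterministic for a given seed: the same partition on every call.
    """
    if not 0 < ratio < 1:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    n = len(items)
    if n < 2:
        raise ValueError("need at least 2 items to split")
    n_test = int(math.floor(n * (1.0 - ratio) + 0.5))
    n_test = min(max(n_test, 1), n - 1)
    perm = np.random.RandomState(seed).permutation(n)
    train_idx, test_idx = perm[: n - n_test], perm[n - n_test :]
    return SplitResult(
        train=[items[i] for i in train_idx],
        test=[items[i] for i in test_idx],
    )
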