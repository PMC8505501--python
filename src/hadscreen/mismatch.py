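"""HAD-ICD10 mismatch candidates and drug-level summary tables.

A visit with an actual high-alert-drug prescription that the model predicted
non-HAD splits on its diagnosis profile: low HAD-use likelihood makes it a
mismatch candidate (the prescription is unsupported by both the model and the
prevalence evidence — a probable prescription error for manual review), while
high likelihood makes it a model misclassification.  The final adjudication
among incomplete ICD10 records, incorrect ICD10 records and genuinely
incorrect prescriptions is a human step; the report carries the evidence, not
a verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence

import pandas as pd

from .readjust import HIGH, LOW, LikelihoodClass
from .registry import HAD, NON_HAD

MISMATCH_CANDIDATE = "mismatch_candidate"
MODEL_MISCLASSIFICATION = "model_misclassification"


@dataclass
class ScreenedVisit:
    """Per-visit evidence bundle entering the mismatch screen."""

    txn: str
    predicted: str  # "HAD" | "non-HAD"
    actual: str
    likelihood: LikelihoodClass
    had_drugs: Sequence  # (drug_code, drug_name) pairs actually prescribed
    icd10_percents: Dict[str, Optional[float]]
    cycle1_prob: float
    setting: str = "OPD"


@dataclass
class MismatchCandidate:
    txn: str
    drug_code: str
    drug_name: str
    icd10_percents: Dict[str, Optional[float]]
    cycle1_prob: float
    category: str
    setting: str = "OPD"

    def to_dict(self) -> dict:
        return {
            "txn": self.txn,
            "drug_code": self.drug_code,
            "drug_name": self.drug_name,
            "icd10_percents": self.icd10_percents,
            "cycle1_prob": self.cycle1_prob,
            "category": self.category,
            "setting": self.setting,
        }


def flag_candidates(records: Iterable[ScreenedVisit]) -> list:
    """Categorize every actual-HAD, predicted-non-HAD visit; other visits never appear.

    Low likelihood -> mismatch candidate; high likelihood -> model
    misclassification.  A visit with several distinct HAD drugs contributes one
    candidate row per drug (summaries tally drugs, not visits).
    """
    out: list = []
    for rec in records:
        if not (rec.actual == HAD and rec.predicted == NON_HAD):
            continue
        category = (
            MISMATCH_CANDIDATE if rec.likelihood.value == LOW else MODEL_MISCLASSIFICATION
        )
        seen = set()
        for drug_code, drug_name in rec.had_drugs:
            if drug_code in seen:
                continue
            seen.add(drug_code)
            out.append(
                MismatchCandidate(
                    txn=rec.txn,
                    drug_code=drug_code,
                    drug_name=drug_name,
                    icd10_percents=dict(rec.icd10_percents),
                    cycle1_prob=rec.cycle1_prob,
                    category=category,
                    setting=rec.setting,
                )
            )
    return out


def summarize(candidates: Sequence[MismatchCandidate]) -> pd.DataFrame:
    """Drug-level tally of mismatch candidates with outpatient/inpatient counts.

    Rows sorted by total count descending; ``proportion`` is the percentage of
    all candidates, rounded to one decimal.  A totals row closes the table.
    An empty candidate set yields a summary with zero totals.
    """
    counts: Dict[str, Dict[str, int]] = {}
    for c in candidates:
        row = counts.setdefault(c.drug_name or c.drug_code, {"OPD": 0, "IPD": 0})
        row[c.setting] += 1
    total = sum(r["OPD"] + r["IPD"] for r in counts.values())
    rows = []
    for drug, r in sorted(
        counts.items(), key=lambda kv: (-(kv[1]["OPD"] + kv[1]["IPD"]), kv[0])
    ):
        n = r["OPD"] + r["IPD"]
        rows.append(
            {
                "drug": drug,
                "OPD": r["OPD"],
                "IPD": r["IPD"],
                "proportion": round(100.0 * n / total, 1) if total else 0.0,
            }
        )
    rows.append(
        {
            "drug": "Total",
            "OPD": sum(r["OPD"] for r in counts.values()),
            "IPD": sum(r["IPD"] for r in counts.values()),
            "proportion": 100.0 if total else 0.0,
        }
    )
    return pd.DataFrame(rows, columns=["drug", "OPD", "IPD", "proportion"])
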