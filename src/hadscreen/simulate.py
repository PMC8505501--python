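"""Seeded synthetic prescription data with the association structure the screen exploits.

The generator emulates visit-level EHR extracts: each visit has a principal
diagnosis drawn from a power-law frequency distribution, optional comorbidity
codes, a variable number of ordinary drugs, and — with probability given by
the principal code's association strength pi — a high-alert drug of a
type characteristic for that diagnosis.  Ground truth records, per visit,
the principal code, the intended HAD status/type and any planted mismatch
(a HAD given to a visit whose diagnoses do not support it), so every pipeline
stage can be scored against a known answer.

Named scenario presets cover the screening-relevant failure modes: follow-up
visits of HAD-associated diagnoses issued without the drug (complex
diagnosis-stage relationships), heavy multi-drug accumulation, and planted
prescription errors.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .registry import HAD_TYPES, HADRegistry, PrescriptionRow, RegistryEntry

#: example drug names per HAD type, for readable demos (from the default registry)
_REAL_NAMES = {
    "ANS": ["Pseudoephedrine", "Norepinephrine", "Dopamine"],
    "BIG": ["Warfarin", "Heparin"],
    "CVS": ["Digoxin", "Magnesium sulfate", "Potassium chloride"],
    "CNS": ["Morphine", "Alprazolam", "Midazolam"],
    "END": ["Regular insulin", "Calcium gluconate"],
    "Tumor": ["Methotrexate", "Cisplatin", "Doxorubicin"],
}


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    ``pi`` maps each ICD10 token to the probability of HAD use given the code
    is the visit's principal diagnosis; when ``None`` a two-level map is drawn:
    a ``frac_high`` share of codes get pi uniform in ``pi_high_range`` and the
    rest uniform in ``pi_low_range``, spanning the ~0-0.98 spectrum seen in
    per-diagnosis HAD prevalence tables.
    """

    n_visits: int = 5000
    setting: str = "OPD"
    n_icd10: int = 60
    icd10_power: float = 1.2  # power-law exponent of code frequencies
    frac_high: float = 0.15
    pi_high_range: Tuple[float, float] = (0.8, 0.98)
    pi_low_range: Tuple[float, float] = (0.0, 0.1)
    pi: Optional[Dict[str, float]] = None
    type_dominance: float = 0.7  # weight of a code's characteristic HAD type
    comorbidity_mean: float = 0.8  # Poisson mean of extra ICD10s per visit
    nonhad_drug_mean: float = 2.5  # mean ordinary-drug count per visit (>= 1)
    n_nonhad_drugs: int = 150
    n_had_per_type: int = 3
    mismatch_rate: float = 0.0  # epsilon: planted random HAD on unrelated visits
    stage_mixing: float = 0.0  # follow-up visits of high-pi codes without HAD
    unrelated_pi_bound: float = 0.1
    male_fraction: float = 0.45
    age_mean: float = 50.0
    age_sd: float = 16.0
    use_real_names: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_visits < 1:
            raise ValueError("n_visits must be >= 1")
        if self.setting not in ("OPD", "IPD"):
            raise ValueError("setting must be OPD or IPD")
        if self.n_icd10 < 1:
            raise ValueError("n_icd10 must be >= 1")
        for name in ("frac_high", "mismatch_rate", "stage_mixing", "male_fraction",
                     "type_dominance", "unrelated_pi_bound"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("pi_high_range", "pi_low_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} must be an ordered pair within [0, 1]")
        if self.pi is not None and any(not 0 <= p <= 1 for p in self.pi.values()):
            raise ValueError("pi probabilities must lie in [0, 1]")
        if self.comorbidity_mean < 0 or self.nonhad_drug_mean < 1:
            raise ValueError("comorbidity_mean >= 0 and nonhad_drug_mean >= 1 required")


@dataclass
class VisitTruth:
    principal: str
    intended_had: bool
    intended_types: Tuple[str, ...]
    planted_mismatch: bool = False
    offending_drug: Optional[str] = None
    stage_mixed: bool = False


@dataclass
class GroundTruth:
    """Per-visit generative truth plus the association map used."""

    pi: Dict[str, float]
    visits: Dict[str, VisitTruth] = field(default_factory=dict)

    @property
    def planted_txns(self) -> list:
        return [t for t, v in self.visits.items() if v.planted_mismatch]

    def to_json(self, path) -> None:
        payload = {
            "pi": self.pi,
            "visits": {t: asdict(v) for t, v in self.visits.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @staticmethod
    def from_json(path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        visits = {
            t: VisitTruth(**{**v, "intended_types": tuple(v["intended_types"])})
            for t, v in payload["visits"].items()
        }
        return GroundTruth(pi=payload["pi"], visits=visits)


def make_registry(config: GeneratorConfig) -> HADRegistry:
    """The synthetic drug registry matching a generator configuration."""
    entries: Dict[str, RegistryEntry] = {}
    groups = {"ANS": "general", "BIG": "general", "CVS": "general",
              "CNS": "narcotic_psychotropic", "END": "general", "Tumor": "iv_cytotoxic"}
    for t in HAD_TYPES:
        for j in range(config.n_had_per_type):
            entries[f"H-{t}-{j:02d}"] = RegistryEntry(
                is_had=True, had_group=groups[t], had_type=t
            )
    # ordinary drugs are simply absent from the registry (default non-HAD),
    # but materialising them keeps the registry a complete formulary
    for j in range(config.n_nonhad_drugs):
        entries[f"N-{j:04d}"] = RegistryEntry(is_had=False)
    return HADRegistry(entries)


def _drug_name(code: str, config: GeneratorConfig) -> str:
    if not config.use_real_names or not code.startswith("H-"):
        return code
    _, t, j = code.split("-")
    names = _REAL_NAMES[t]
    return names[int(j) % len(names)]


def generate(config: GeneratorConfig) -> Tuple[list, GroundTruth]:
    """Generate prescription rows and ground truth; byte-identical for equal seeds.

    Row layout matches what the I/O layer reads: one drug per row, the visit's
    diagnoses cycled across its rows starting with the principal code (so the
    principal is never dropped).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    codes = [f"D{k:03d}" for k in range(config.n_icd10)]
    if config.pi is not None:
        pi = dict(config.pi)
        codes = sorted(pi)
    else:
        n_high = int(round(config.frac_high * config.n_icd10))
        high = set(rng.choice(config.n_icd10, size=n_high, replace=False).tolist())
        pi = {}
        for k, c in enumerate(codes):
            lo, hi = config.pi_high_range if k in high else config.pi_low_range
            pi[c] = float(rng.uniform(lo, hi))
    weights = np.array([(k + 1.0) ** (-config.icd10_power) for k in range(len(codes))])
    weights /= weights.sum()
    # each code's characteristic HAD type, cycled; off-type mass spread evenly
    dominant = {c: HAD_TYPES[k % len(HAD_TYPES)] for k, c in enumerate(codes)}
    type_probs = {}
    for c in codes:
        p = np.full(len(HAD_TYPES), (1.0 - config.type_dominance) / (len(HAD_TYPES) - 1))
        p[HAD_TYPES.index(dominant[c])] = config.type_dominance
        type_probs[c] = p

    had_pool = {t: [f"H-{t}-{j:02d}" for j in range(config.n_had_per_type)] for t in HAD_TYPES}
    all_had = [d for pool in had_pool.values() for d in pool]
    nonhad_pool = [f"N-{j:04d}" for j in range(config.n_nonhad_drugs)]

    rows: list = []
    truth = GroundTruth(pi=pi)
    for i in range(config.n_visits):
        txn = f"{config.setting}{i:06d}"
        gender = "male" if rng.random() < config.male_fraction else "female"
        age = int(np.clip(rng.normal(config.age_mean, config.age_sd), 0, 100))
        principal = codes[rng.choice(len(codes), p=weights)]
        n_comorb = min(int(rng.poisson(config.comorbidity_mean)), len(codes) - 1)
        icd10s = [principal]
        if n_comorb:
            others = [c for c in codes if c != principal]
            ow = np.array([weights[codes.index(c)] for c in others])
            ow /= ow.sum()
            picks = rng.choice(len(others), size=n_comorb, replace=False, p=ow)
            icd10s.extend(others[j] for j in picks)

        intended = bool(rng.random() < pi[principal])
        stage_mixed = False
        if intended and config.stage_mixing and rng.random() < config.stage_mixing:
            intended, stage_mixed = False, True  # follow-up visit: no HAD issued

        n_nonhad = max(1, int(rng.poisson(config.nonhad_drug_mean)))
        n_nonhad = min(n_nonhad, len(nonhad_pool))
        drugs = [nonhad_pool[j] for j in rng.choice(len(nonhad_pool), size=n_nonhad, replace=False)]

        intended_types: Tuple[str, ...] = ()
        if intended:
            t = HAD_TYPES[rng.choice(len(HAD_TYPES), p=type_probs[principal])]
            drugs.append(had_pool[t][rng.integers(len(had_pool[t]))])
            intended_types = (t,)

        planted = False
        offending = None
        # a planted error must be unsupported by the whole diagnosis profile:
        # a high-association comorbidity would make the HAD clinically plausible
        if (
            not intended
            and config.mismatch_rate
            and all(pi[c] <= config.unrelated_pi_bound for c in icd10s)
            and rng.random() < config.mismatch_rate
        ):
            offending = all_had[rng.integers(len(all_had))]
            drugs.append(offending)
            planted = True

        rng.shuffle(drugs)
        if planted:  # keep the offending drug identifiable after the shuffle
            drugs.remove(offending)
            drugs.append(offending)
        for j, d in enumerate(drugs):
            rows.append(
                PrescriptionRow(
                    txn=txn,
                    gender=gender,
                    age=age,
                    icd10=icd10s[j % len(icd10s)],
                    drug_code=d,
                    drug_name=_drug_name(d, config),
                )
            )
        truth.visits[txn] = VisitTruth(
            principal=principal,
            intended_had=intended,
            intended_types=intended_types,
            planted_mismatch=planted,
            offending_drug=offending,
            stage_mixed=stage_mixed,
        )
    return rows, truth


def scenario_presets() -> Dict[str, GeneratorConfig]:
    """Named study conditions for the protocol's failure modes."""
    base = GeneratorConfig(n_visits=20_000, n_icd10=60, seed=0)
    return {
        # association structure only: single-diagnosis visits, no planted errors
        "clean": replace(base, comorbidity_mean=0.0, mismatch_rate=0.0, stage_mixing=0.0),
        # planted prescription errors on unrelated diagnoses
        "mismatch_rich": replace(base, mismatch_rate=0.01),
        # follow-up visits of HAD-associated diagnoses issued without the drug
        "eacip": replace(base, stage_mixing=0.3),
        # heavy ordinary-drug accumulation (4+ drug types common)
        "eamu": replace(base, nonhad_drug_mean=5.0),
    }


def preset(name: str) -> GeneratorConfig:
    presets = scenario_presets()
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    return presets[name]
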