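"""End-to-end orchestration of the two-cycle screening protocol.

``run_cycle1`` trains the binary screen, selects the S-index cut point,
readjusts the confusion matrix by HAD percent and flags mismatch candidates
over the whole dataset (test-set false negatives plus the excluded evaluation
set).  ``run_cycle2`` filters by the cycle-1 cut point, trains the seven-class
type model, applies the P25/P75 tri-state interpretation and the per-type
readjustment.  Every run writes CSV/JSON artifacts plus a manifest (config,
seeds, package version) from which it can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .classifier import (
    ModelHandle,
    fit_binary,
    fit_types,
    predict_had_probability,
    predict_proba,
)
from .cycle1 import (
    CutpointScan,
    SelectedCutpoint,
    binary_metrics,
    classify_binary,
    scan_cutpoints,
    select_cutpoint,
)
from .cycle2 import (
    TypeCutpoints,
    TypeConfusion,
    adjust_type_confusion,
    classify_type,
    filter_by_cutpoint,
    icd10_percent,
    interpret_type_confusion,
    percentile_cutpoints,
)
from .mismatch import MismatchCandidate, ScreenedVisit, flag_candidates, summarize
from .preprocess import (
    FeatureBuilder,
    TYPE_LABELS,
    expand_type_instances,
    label_binary,
    split_train_test,
)
from .readjust import (
    ConfusionAdjustment,
    HADPercentTable,
    adjust_confusion,
    compute_had_percent,
    specific_fnr,
    visit_likelihood,
)
from .registry import (
    HAD,
    HAD_TYPES,
    NON_HAD,
    HADRegistry,
    VisitRecord,
    aggregate_visits,
    read_prescriptions,
    read_registry,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative configuration of one screening run.

    Defaults follow the protocol: 75:25 split, 0.01 cut-point grid, 50%
    likelihood threshold, linear percentile interpolation.
    """

    prescriptions: Optional[str] = None
    registry: Optional[str] = None
    setting: str = "OPD"
    split_ratio: float = 0.75
    seed: int = 0
    grid_step: float = 0.01
    likelihood_threshold: float = 50.0
    percentile_pooled: bool = False
    max_depth_grid: Tuple[int, ...] = (1, 2, 3)
    had_percent_sample_size: Optional[int] = None
    min_visits: int = 5
    outdir: Optional[str] = None

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "max_depth_grid" in payload:
            payload["max_depth_grid"] = tuple(payload["max_depth_grid"])
        return RunConfig(**payload)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["max_depth_grid"] = list(self.max_depth_grid)
        return d


def _manifest(config: RunConfig, stage: str) -> dict:
    cfg = config.to_dict()
    cfg.pop("outdir", None)  # where artifacts land does not change what they are
    digest = hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
    return {"stage": stage, "version": __version__, "config": cfg, "config_hash": digest}


def _load_inputs(config: RunConfig) -> Tuple[list, HADRegistry]:
    if config.prescriptions is None:
        raise ValueError("config.prescriptions is required")
    registry = (
        read_registry(config.registry) if config.registry else HADRegistry.default()
    )
    report = read_prescriptions(config.prescriptions)
    logger.info("read %d rows (%d rejected)", len(report.rows), report.n_rejected)
    visits = aggregate_visits(report.rows)
    logger.info("aggregated %d visits", len(visits))
    return visits, registry


@dataclass
class Cycle1Artifacts:
    model: ModelHandle
    builder: FeatureBuilder
    scan: CutpointScan
    cutpoint: SelectedCutpoint
    metrics: pd.DataFrame
    adjustment: ConfusionAdjustment
    had_percent: HADPercentTable
    sfnr: pd.DataFrame
    candidates: list
    summary: pd.DataFrame
    visits: list
    all_probs: np.ndarray
    test_visits: list


def screen_visits(
    visits: Sequence[VisitRecord],
    probs: Sequence[float],
    cutpoint: SelectedCutpoint,
    table: HADPercentTable,
    registry: HADRegistry,
    threshold: float = 50.0,
    setting: str = "OPD",
) -> list:
    """Flag mismatch candidates over a visit set given cycle-1 probabilities.

    Applies the cut point, the HAD-percent likelihood rule and the candidate
    definition in one pass; covers both the test-set false negatives and the
    excluded evaluation set when handed the full visit list.
    """
    screened = []
    for v, p in zip(visits, probs):
        actual = label_binary(v, registry)
        if actual != HAD:
            continue
        predicted = classify_binary(p, cutpoint)
        if predicted == HAD:
            continue
        like = visit_likelihood(v, table, threshold=threshold)
        had_drugs = [(d, d) for d in dict.fromkeys(v.drugs) if registry.is_had(d)]
        screened.append(
            ScreenedVisit(
                txn=v.txn,
                predicted=predicted,
                actual=actual,
                likelihood=like,
                had_drugs=had_drugs,
                icd10_percents={c: table.percent(c) for c in sorted(v.icd10_set)},
                cycle1_prob=float(p),
                setting=setting,
            )
        )
    return flag_candidates(screened)


def run_cycle1(
    config: RunConfig,
    visits: Optional[Sequence[VisitRecord]] = None,
    registry: Optional[HADRegistry] = None,
) -> Cycle1Artifacts:
    """Train the binary screen, select the cut point, readjust and flag mismatches."""
    if visits is None or registry is None:
        visits, registry = _load_inputs(config)
    visits = list(visits)
    labels_all = [label_binary(v, registry) for v in visits]
    split = split_train_test(list(range(len(visits))), ratio=config.split_ratio, seed=config.seed)
    train_v = [visits[i] for i in split.train]
    test_v = [visits[i] for i in split.test]
    y_train = [labels_all[i] for i in split.train]
    y_test = [labels_all[i] for i in split.test]

    builder = FeatureBuilder().fit(train_v)
    X_train = builder.transform(train_v)
    X_test = builder.transform(test_v)
    model = fit_binary(X_train, y_train, max_depth_grid=config.max_depth_grid, seed=config.seed)

    test_probs = predict_had_probability(model, X_test)
    scan = scan_cutpoints(test_probs, y_test, step=config.grid_step)
    cutpoint = select_cutpoint(scan)
    predicted = [classify_binary(p, cutpoint) for p in test_probs]
    metrics = binary_metrics(predicted, y_test)

    table = compute_had_percent(
        visits,
        registry,
        sample_size=config.had_percent_sample_size,
        seed=config.seed,
        min_visits=config.min_visits,
    )
    likelihoods = [
        visit_likelihood(v, table, threshold=config.likelihood_threshold) for v in test_v
    ]
    adjustment = adjust_confusion(list(zip(predicted, y_test, likelihoods)))
    sfnr = specific_fnr(list(zip(test_v, predicted, y_test)), had_percent=table)

    all_probs = predict_had_probability(model, builder.transform(visits))
    candidates = screen_visits(
        visits, all_probs, cutpoint, table, registry,
        threshold=config.likelihood_threshold, setting=config.setting,
    )
    summary = summarize(candidates)

    artifacts = Cycle1Artifacts(
        model=model, builder=builder, scan=scan, cutpoint=cutpoint, metrics=metrics,
        adjustment=adjustment, had_percent=table, sfnr=sfnr, candidates=candidates,
        summary=summary, visits=visits, all_probs=all_probs, test_visits=test_v,
    )
    if config.outdir:
        _write_cycle1(config, artifacts)
    return artifacts


def _write_cycle1(config: RunConfig, art: Cycle1Artifacts) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    art.scan.to_csv(out / "cutpoint_scan.csv")
    art.metrics.to_csv(out / "binary_metrics.csv")
    art.had_percent.to_csv(out / "had_percent.csv")
    art.sfnr.to_csv(out / "sfnr.csv")
    art.summary.to_csv(out / "mismatch_summary.csv", index=False)
    art.model.save(out / "model_cycle1.joblib")
    payload = {
        "cutpoint": art.cutpoint.value,
        "s_index_at_selection": art.cutpoint.s_index_at_selection,
        "confusion": art.adjustment.to_dict(),
        "n_candidates": len(art.candidates),
    }
    (out / "cycle1_results.json").write_text(json.dumps(payload, indent=1))
    (out / "candidates.json").write_text(
        json.dumps([c.to_dict() for c in art.candidates], indent=1)
    )
    (out / "manifest_cycle1.json").write_text(json.dumps(_manifest(config, "cycle1"), indent=1))


@dataclass
class Cycle2Artifacts:
    model: ModelHandle
    cutpoints: TypeCutpoints
    confusion: TypeConfusion
    type_metrics: pd.DataFrame
    adjusted: Dict[str, ConfusionAdjustment]
    icd10_percent: Dict[str, pd.Series]
    included: list
    excluded: list
    excluded_candidates: list


def run_cycle2(
    config: RunConfig,
    cycle1: Cycle1Artifacts,
    registry: Optional[HADRegistry] = None,
    visits: Optional[Sequence[VisitRecord]] = None,
) -> Cycle2Artifacts:
    """Filter by the cycle-1 cut point, train the type model and interpret per type."""
    if registry is None:
        registry = HADRegistry.default() if config.registry is None else read_registry(config.registry)
    if visits is None:
        visits = cycle1.visits
    probs = (
        cycle1.all_probs
        if visits is cycle1.visits
        else predict_had_probability(cycle1.model, cycle1.builder.transform(visits))
    )
    included, excluded = filter_by_cutpoint(visits, probs, cycle1.cutpoint)
    if len(included) < 8:
        raise ValueError("too few visits pass the cycle-1 cut point for type modelling")

    # evaluation mode: the excluded set is re-screened for mismatches
    excluded_probs = [p for p in probs if p <= cycle1.cutpoint.value]
    excluded_candidates = screen_visits(
        excluded, excluded_probs, cycle1.cutpoint, cycle1.had_percent, registry,
        threshold=config.likelihood_threshold, setting=config.setting,
    )

    inst_visits, inst_labels = expand_type_instances(included, registry)
    split = split_train_test(list(range(len(inst_visits))), ratio=config.split_ratio, seed=config.seed)
    prob_by_txn = {v.txn: float(p) for v, p in zip(visits, probs)}
    builder = FeatureBuilder().fit([inst_visits[i] for i in split.train])

    def matrix(idx):
        vs = [inst_visits[i] for i in idx]
        return builder.transform(vs, cycle1_probs=[prob_by_txn[v.txn] for v in vs])

    model = fit_types(
        matrix(split.train), [inst_labels[i] for i in split.train],
        max_depth_grid=config.max_depth_grid, seed=config.seed,
    )
    test_idx = split.test
    test_visits = [inst_visits[i] for i in test_idx]
    proba = predict_proba(model, matrix(test_idx))
    # one interpreted row per distinct test visit (instances share the feature row)
    seen: dict = {}
    for pos, v in enumerate(test_visits):
        seen.setdefault(v.txn, (pos, v))
    rows = list(seen.values())
    probs_by_type = {
        t: proba[t].iloc[[pos for pos, _ in rows]].to_numpy()
        for t in HAD_TYPES
        if t in proba.columns
    }
    for t in HAD_TYPES:  # types never predicted get a degenerate zero column
        probs_by_type.setdefault(t, np.zeros(len(rows)))
    cutpoints = percentile_cutpoints(probs_by_type, pooled=config.percentile_pooled)

    tristates = []
    actual_types = []
    likelihoods_by_type = []
    per_type_tables = {
        t: compute_had_percent(list(visits), registry, min_visits=config.min_visits, had_type=t)
        for t in HAD_TYPES
    }
    for k, (pos, v) in enumerate(rows):
        tristates.append(
            {t: classify_type(float(probs_by_type[t][k]), cutpoints, t) for t in HAD_TYPES}
        )
        actual_types.append(registry.visit_types(v))
        likelihoods_by_type.append(
            {
                t: visit_likelihood(v, per_type_tables[t], threshold=config.likelihood_threshold)
                for t in HAD_TYPES
            }
        )
    confusion = interpret_type_confusion(tristates, actual_types)
    adjusted = adjust_type_confusion(tristates, actual_types, likelihoods_by_type)
    icd10_pct = {t: icd10_percent(list(visits), registry, t) for t in HAD_TYPES}

    artifacts = Cycle2Artifacts(
        model=model, cutpoints=cutpoints, confusion=confusion,
        type_metrics=confusion.metrics(), adjusted=adjusted, icd10_percent=icd10_pct,
        included=included, excluded=excluded, excluded_candidates=excluded_candidates,
    )
    if config.outdir:
        _write_cycle2(config, artifacts)
    return artifacts


def _write_cycle2(config: RunConfig, art: Cycle2Artifacts) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    art.type_metrics.to_csv(out / "type_metrics.csv")
    art.model.save(out / "model_cycle2.joblib")
    pd.DataFrame(
        {"p25": art.cutpoints.p25, "p75": art.cutpoints.p75}
    ).to_csv(out / "type_cutpoints.csv", index_label="type")
    pd.DataFrame({t: s for t, s in art.icd10_percent.items()}).to_csv(
        out / "icd10_percent.csv", index_label="icd10"
    )
    payload = {
        "adjusted": {t: a.to_dict() for t, a in art.adjusted.items()},
        "n_included": len(art.included),
        "n_excluded": len(art.excluded),
        "n_excluded_candidates": len(art.excluded_candidates),
    }
    (out / "cycle2_results.json").write_text(json.dumps(payload, indent=1))
    (out / "manifest_cycle2.json").write_text(json.dumps(_manifest(config, "cycle2"), indent=1))
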