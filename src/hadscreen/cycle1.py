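"""Cycle 1: S-index cut-point scan, threshold selection and binary screening metrics.

The screening index (S-index) is the product of the HAD-class F1-score and
recall.  Weighting recall twice deliberately biases the selected threshold
toward catching every actual HAD visit — a missed high-alert prescription is
far costlier than a false alarm — while the F1 factor stops the scan from
collapsing to a recall-only threshold drowned in false positives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .registry import HAD, NON_HAD


def s_index(f1: float, recall: float) -> float:
    """Screening index: F1-score x recall, both on the HAD class."""
    if not (0 <= f1 <= 1 and 0 <= recall <= 1):
        raise ValueError("f1 and recall must lie in [0, 1]")
    return f1 * recall


@dataclass
class CutpointScan:
    """Per-cut-point precision/recall/F1/S-index arrays over an ascending grid."""

    cutpoints: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    s: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutpoint": self.cutpoints,
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
                "s_index": self.s,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def scan_cutpoints(
    probs: Sequence[float], labels: Sequence[str], step: float = 0.01
) -> CutpointScan:
    """Sweep cut points from 0 to 1 and compute the HAD-class metric set at each.

    A visit is predicted HAD iff its probability is strictly above the cut
    point.  Precision is defined as 0 when nothing is predicted positive, and
    recall as 0 when there are no actual positives, so the S-index is total on
    the grid.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.size == 0:
        raise ValueError("empty input")
    if len(labels) != probs.size:
        raise ValueError("probs and labels must be aligned")
    n_steps = 1.0 / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(f"step {step} must divide 1 evenly")
    grid = np.round(np.linspace(0.0, 1.0, int(round(n_steps)) + 1), 10)
    actual = np.asarray([lab == HAD for lab in labels], dtype=bool)

    pred = probs[None, :] > grid[:, None]  # (n_cuts, n_visits)
    tp = (pred & actual[None, :]).sum(axis=1).astype(float)
    fp = (pred & ~actual[None, :]).sum(axis=1).astype(float)
    fn = (~pred & actual[None, :]).sum(axis=1).astype(float)

    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(
            precision + recall > 0, 2 * precision * recall / (precision + recall), 0.0
        )
    return CutpointScan(
        cutpoints=grid, precision=precision, recall=recall, f1=f1, s=f1 * recall
    )


@dataclass(frozen=True)
class SelectedCutpoint:
    """The S-index-optimal cut point, floored to two decimal places."""

    value: float
    s_index_at_selection: float

    def __post_init__(self) -> None:
        if not 0 <= self.value < 1:
            raise ValueError("cut point must lie in [0, 1)")


def select_cutpoint(scan: CutpointScan) -> SelectedCutpoint:
    """Pick the grid point maximizing the S-index; ties break toward the smallest cut.

    The winning cut point is rounded down to two decimal places (screening
    errs toward including more visits).
    """
    if scan.cutpoints.size == 0:
        raise ValueError("empty scan")
    idx = int(np.argmax(scan.s))  # argmax returns the first (smallest) maximiser
    raw = float(scan.cutpoints[idx])
    floored = math.floor(raw * 100 + 1e-9) / 100.0
    return SelectedCutpoint(value=min(floored, 0.99), s_index_at_selection=float(scan.s[idx]))


def classify_binary(prob: float, cutpoint: SelectedCutpoint) -> str:
    """HAD iff the probability is strictly above the cut point; the boundary is non-HAD."""
    return HAD if prob > cutpoint.value else NON_HAD


def binary_metrics(predicted: Sequence[str], actual: Sequence[str]) -> pd.DataFrame:
    """Per-class accuracy, precision, recall and F1 with class counts.

    One row per class (non-HAD, HAD); accuracy is the overall fraction correct
    and is repeated on both rows for the standard report layout.  N is the
    number of actual visits of each class.
    """
    if len(predicted) == 0:
        raise ValueError("empty input")
    if len(predicted) != len(actual):
        raise ValueError("predicted and actual must be aligned")
    pred = np.asarray(predicted)
    act = np.asarray(actual)
    accuracy = float(np.mean(pred == act))
    rows = []
    for cls in (NON_HAD, HAD):
        tp = int(np.sum((pred == cls) & (act == cls)))
        fp = int(np.sum((pred == cls) & (act != cls)))
        fn = int(np.sum((pred != cls) & (act == cls)))
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        rows.append(
            {
                "class": cls,
                "accuracy": accuracy,
                "precision": precision,
                "recall": recall,
                "f1": f1,
                "n": int(np.sum(act == cls)),
            }
        )
    return pd.DataFrame(rows).set_index("class")


def plot_scan(scan: CutpointScan, selected: SelectedCutpoint, path=None):
    """Four metric series against the cut-point grid, with the selection marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    c = scan.cutpoints
    ax.plot(c, scan.precision, "--^", color="tab:orange", label="precision", markevery=5)
    ax.plot(c, scan.recall, "--o", color="tab:green", label="recall", markevery=5)
    ax.plot(c, scan.f1, "--s", color="tab:red", label="F1-score", markevery=5)
    ax.plot(c, scan.s, "-x", color="tab:purple", label="S-index", markevery=5)
    ax.axvline(selected.value, color="grey", linestyle=":", label=f"cut point {selected.value:.2f}")
    ax.set_xlabel("cut point")
    ax.set_ylabel("metric value")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
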