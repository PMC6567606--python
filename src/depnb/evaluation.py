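"""ROC construction, AUC, standard error, and the Z test against AUC = 0.5.

Diagnostic quality for one target disease is assessed one-vs-rest: each
record's score is its posterior for the target, its label is whether the
record's (first-listed) disease is the target.  The ROC sweeps a threshold
over the unique scores descending; each threshold yields a
(1 - specificity, sensitivity) = (FP/(TN+FP), TP/(TP+FN)) point, and (0,0) /
(1,1) are appended.  The AUC is computed with the pairwise-count (Mann-
Whitney) convention — ties between a positive and a negative score earn half
credit — which equals the trapezoidal integral of the ROC curve.

The standard error of the AUC uses the Hanley–McNeil formula with
Q1 = A/(2-A) and Q2 = 2A^2/(1+A); the test statistic is z = (A - 0.5)/SE and
the one-sided p-value is the standard normal upper tail (H0: AUC = 0.5,
H1: AUC > 0.5).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .cohort import Cohort

__all__ = [
    "RocResult",
    "binary_labels",
    "roc_curve",
    "auc",
    "auc_test",
    "train_test_split_cohort",
]


@dataclass
class RocResult:
    points: list[tuple[float, float]]       # (fpr, tpr), (0,0)..(1,1)
    thresholds: list[float]                 # aligned with interior points
    n_pos: int
    n_neg: int
    auc: float | None = None
    se: float | None = None
    z: float | None = None
    p_one_sided: float | None = None

    def summary_json(self) -> dict:
        return {
            "auc": self.auc,
            "se": self.se,
            "z": self.z,
            "p_one_sided": self.p_one_sided,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }

    def save_points_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("threshold\tfpr\ttpr\n")
            thr = [float("inf")] + list(self.thresholds) + [float("-inf")]
            for t, (fpr, tpr) in zip(thr, self.points):
                fh.write(f"{t}\t{fpr}\t{tpr}\n")
        return path


def binary_labels(cohort: Cohort, target_disease: str) -> np.ndarray:
    """1 iff the record's first-listed disease equals the target."""
    if target_disease not in cohort.disease_vocabulary:
        raise KeyError(f"unknown target disease {target_disease!r}")
    return np.array([1 if r.disease == target_disease else 0 for r in cohort])


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and the same length")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to build an ROC curve")
    return scores, labels, n_pos, n_neg


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """ROC points from a descending threshold sweep over unique scores."""
    scores, labels, n_pos, n_neg = _validate(scores, labels)
    thresholds = np.unique(scores)[::-1]
    points = [(0.0, 0.0)]
    for t in thresholds:
        predicted = scores >= t
        tp = int(np.sum(predicted & (labels == 1)))
        fp = int(np.sum(predicted & (labels == 0)))
        points.append((fp / n_neg, tp / n_pos))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
        # keep thresholds aligned with interior points only
    return RocResult(
        points=points,
        thresholds=[float(t) for t in thresholds],
        n_pos=n_pos,
        n_neg=n_neg,
    )


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Pairwise-count AUC: [#(pos > neg) + 0.5 #(pos == neg)] / (n_pos n_neg)."""
    scores, labels, n_pos, n_neg = _validate(scores, labels)
    ranks = rankdata(scores)  # average ranks implement the half-credit tie rule
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def trapezoid_auc(roc: RocResult) -> float:
    """Trapezoidal integral of the ROC curve (equals the pairwise-count AUC)."""
    fpr = np.array([p[0] for p in roc.points])
    tpr = np.array([p[1] for p in roc.points])
    return float(np.trapezoid(tpr, fpr))


def auc_test(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """Complete ROC result with Hanley–McNeil SE and one-sided Z test."""
    roc = roc_curve(scores, labels)
    A = auc(scores, labels)
    n_pos, n_neg = roc.n_pos, roc.n_neg
    q1 = A / (2.0 - A)
    q2 = 2.0 * A * A / (1.0 + A)
    var = (
        A * (1.0 - A)
        + (n_pos - 1) * (q1 - A * A)
        + (n_neg - 1) * (q2 - A * A)
    ) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    if se == 0.0:
        raise ValueError("degenerate ROC: standard error of the AUC is zero")
    z = (A - 0.5) / se
    roc.auc = A
    roc.se = se
    roc.z = float(z)
    roc.p_one_sided = float(norm.sf(z))
    return roc


def train_test_split_cohort(
    cohort: Cohort, test_fraction: float = 1 / 3, seed: int = 0
) -> tuple[Cohort, Cohort]:
    """Seeded record-level split preserving vocabularies on both sides."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    m = cohort.m
    perm = rng.permutation(m)
    n_test = int(round(m * test_fraction))
    test_idx = set(perm[:n_test].tolist())
    train = [r for i, r in enumerate(cohort) if i not in test_idx]
    test = [r for i, r in enumerate(cohort) if i in test_idx]
    return (
        Cohort(train, cohort.disease_vocabulary, cohort.symptom_vocabulary),
        Cohort(test, cohort.disease_vocabulary, cohort.symptom_vocabulary),
    )
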