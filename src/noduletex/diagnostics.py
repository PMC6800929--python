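"""Diagnostic evaluation: ROC/AUC with tie handling, Youden cut-off,
2x2-table statistics in exact rational arithmetic, and two-reader ICC.

The AUC is computed as the tie-corrected Mann-Whitney rank statistic (ties
count 1/2), which equals the trapezoidal area under the empirical ROC curve
whose diagonal segments are produced by tied scores.  The cut-off maximizes
the Youden index (sensitivity + specificity - 1), breaking ties toward the
higher-specificity operating point (a benign-sparing screen).  Inter-reader
reliability uses the two-way random-effects, absolute-agreement,
single-measure intraclass correlation, ICC(2,1), with 0.85 as the
acceptability bar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
import pingouin as pg
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

ICC_ACCEPTABLE = 0.85

#: cut-offs published for the study's patient cohorts; applied only in the
#: explicit "published cut-offs" mode, never derived from phantom data
PUBLISHED_CUTOFFS = {"KUR": 6.0, "SKW": 3.1}


@dataclass
class LabeledScores:
    """Feature values with benign/malignant labels (malignant = positive)."""

    scores: np.ndarray
    labels: np.ndarray   # boolean, True = malignant

    def __init__(self, scores, labels):
        self.scores = np.asarray(scores, dtype=float)
        lab = np.asarray(labels)
        if lab.dtype.kind in "OUS":
            lab = lab == "malignant"
        self.labels = lab.astype(bool)
        if len(self.scores) != len(self.labels):
            raise ValueError("scores and labels differ in length")


@dataclass
class ROCResult:
    points: np.ndarray        # (n, 2) array of (1-specificity, sensitivity)
    thresholds: np.ndarray
    auc: float
    cutoff: float
    cutoff_sensitivity: float
    cutoff_specificity: float
    positive_direction: str = "greater"


def rank_auc(data: LabeledScores) -> float:
    """Mann-Whitney AUC with ties counted 1/2 (direction: greater = positive)."""
    pos = data.labels
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(data.scores)  # average ranks handle ties
    r_pos = ranks[pos].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_curve(
    data: LabeledScores, positive_direction: str = "greater"
) -> ROCResult:
    """Empirical ROC curve with thresholds at distinct score values.

    Tied scores produce diagonal segments; the reported AUC is the
    Mann-Whitney rank statistic, which equals the trapezoidal area of the
    returned points.
    """
    if positive_direction not in ("greater", "less"):
        raise ValueError("positive_direction must be 'greater' or 'less'")
    scores = data.scores if positive_direction == "greater" else -data.scores
    oriented = LabeledScores(scores, data.labels)
    if oriented.labels.all() or not oriented.labels.any():
        raise ValueError("both classes must be present")
    fpr, tpr, thr = _sk_roc_curve(oriented.labels, oriented.scores,
                                  drop_intermediate=False)
    if positive_direction == "less":
        thr = -thr
    points = np.column_stack([fpr, tpr])
    auc = rank_auc(oriented)
    cutoff, sens, spec = _youden_cutoff(points, thr)
    return ROCResult(points=points, thresholds=thr, auc=auc, cutoff=cutoff,
                     cutoff_sensitivity=sens, cutoff_specificity=spec,
                     positive_direction=positive_direction)


def _youden_cutoff(points: np.ndarray, thresholds: np.ndarray):
    j = points[:, 1] - points[:, 0]          # sensitivity - (1 - specificity)
    best = j.max()
    candidates = np.nonzero(j >= best - 1e-12)[0]
    # ties broken toward higher specificity (lower false-positive rate)
    pick = candidates[np.argmin(points[candidates, 0])]
    return (float(thresholds[pick]), float(points[pick, 1]),
            float(1.0 - points[pick, 0]))


def best_cutoff(roc: ROCResult, method: str = "youden"):
    """(cutoff, sensitivity, specificity) maximizing the Youden index."""
    if method != "youden":
        raise ValueError("only the Youden method is implemented")
    return _youden_cutoff(roc.points, roc.thresholds)


@dataclass
class ConfusionTable:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("table entries must be non-negative")


@dataclass
class ConfusionStats:
    """2x2-table statistics as exact rationals (floats on demand)."""

    sensitivity: Fraction
    specificity: Fraction
    accuracy: Fraction
    ppv: Fraction
    npv: Fraction

    def as_floats(self) -> dict[str, float]:
        return {k: float(v) for k, v in self.__dict__.items()}


def confusion_stats(table: ConfusionTable) -> ConfusionStats:
    """Sensitivity, specificity, accuracy, PPV, NPV in exact arithmetic."""
    def ratio(num: int, den: int, name: str) -> Fraction:
        if den == 0:
            raise ZeroDivisionError(f"{name} undefined: zero denominator")
        return Fraction(num, den)

    t = table
    total = t.tp + t.fn + t.tn + t.fp
    return ConfusionStats(
        sensitivity=ratio(t.tp, t.tp + t.fn, "sensitivity"),
        specificity=ratio(t.tn, t.tn + t.fp, "specificity"),
        accuracy=ratio(t.tp + t.tn, total, "accuracy"),
        ppv=ratio(t.tp, t.tp + t.fp, "ppv"),
        npv=ratio(t.tn, t.tn + t.fn, "npv"),
    )


def shape_confusion(
    labels, shape_labels, positive_shape: str = "peak"
) -> ConfusionTable:
    """2x2 table from true benign/malignant labels vs peak/plateau calls
    (peak predicts malignant)."""
    lab = np.asarray(labels)
    if lab.dtype.kind in "OUS":
        lab = lab == "malignant"
    shp = np.asarray(shape_labels) == positive_shape
    return ConfusionTable(
        tp=int((lab & shp).sum()), fn=int((lab & ~shp).sum()),
        tn=int((~lab & ~shp).sum()), fp=int((~lab & shp).sum()))


def icc_two_reader(
    reader_a, reader_b, model: str = "ICC2"
) -> tuple[float, bool]:
    """Two-way random-effects, absolute-agreement, single-measure ICC.

    Returns (icc, acceptable) where acceptable means icc >= 0.85.  The
    readers are treated as a random sample of raters; a constant offset
    between readers therefore lowers the coefficient.
    """
    a = np.asarray(reader_a, dtype=float)
    b = np.asarray(reader_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("readers scored different numbers of subjects")
    if len(a) < 3:
        raise ValueError("need at least 3 subjects")
    if np.ptp(np.concatenate([a, b])) == 0:
        raise ValueError("degenerate input: zero total variance")
    n = len(a)
    df = pd.DataFrame({
        "subject": np.tile(np.arange(n), 2),
        "reader": np.repeat(["A", "B"], n),
        "score": np.concatenate([a, b]),
    })
    with np.errstate(divide="ignore", invalid="ignore"):
        res = pg.intraclass_corr(df, targets="subject", raters="reader",
                                 ratings="score")
    # pingouin labels the six forms either ICC1..ICC3k or ICC(1,1)..ICC(C,k);
    # two-way random, absolute agreement, single measures is ICC2 == ICC(A,1)
    aliases = {"ICC2": "ICC(A,1)", "ICC3": "ICC(C,1)", "ICC1": "ICC(1,1)"}
    types = res["Type"].tolist()
    wanted = model if model in types else aliases.get(model, model)
    icc = float(res.set_index("Type").loc[wanted, "ICC"])
    if not np.isfinite(icc):
        raise ValueError("ICC undefined for degenerate input")
    return icc, icc >= ICC_ACCEPTABLE
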