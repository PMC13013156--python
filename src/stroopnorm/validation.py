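"""Clinical validation of the norms: ROC analyses and ES frequency tables.

Demographically adjusted scores of a pathological group (AD or MCI) are
contrasted with controls.  The cut-point maximising the Youden index
J(c) = sensitivity(c) + specificity(c) - 1 is located by exhaustive scan over
all candidate cut-points (midpoints of adjacent distinct pooled values plus
the two infinities); a score strictly above the cut-point indicates
pathology.  AUC uses the rank-statistic definition
P(pos > neg) + 0.5 P(pos = neg), which equals the area under the empirical
ROC curve.  Ties in J are broken toward higher specificity (the normative
context favours specificity), then toward the lower cut-point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "RocReport",
    "auc",
    "youden_cutpoint",
    "confusion_metrics",
    "es_frequency_table",
    "percentile_table",
    "YoudenCutpoint",
]


@dataclass(frozen=True)
class RocReport:
    """Cut-point and classification metrics for one group contrast."""

    contrast: tuple[str, str]
    score_name: str
    cut_point: float
    youden: float
    auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    prevalence: float
    ppv: float          # nan when no subject is classified positive
    npv: float
    n_pos: int
    n_neg: int


def _clean(scores, who: str) -> np.ndarray:
    x = np.asarray(scores, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) == 0:
        raise ValueError(f"{who} group is empty")
    return x


def auc(scores_pos, scores_neg) -> float:
    """AUC = P(pos > neg) + 0.5 P(pos = neg) over all pairs.

    'pos' is the pathological group; higher scores indicate pathology.
    """
    pos = _clean(scores_pos, "positive")
    neg = _clean(scores_neg, "negative")
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0))
                 / (len(pos) * len(neg)))


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Standard classification metrics from a 2x2 table.

    Ratios with a zero denominator are reported as nan (missing), never 0.
    """
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    n_pos, n_neg = tp + fn, tn + fp
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative subject")
    total = n_pos + n_neg

    def ratio(num, den):
        return num / den if den > 0 else math.nan

    return {
        "sensitivity": ratio(tp, n_pos),
        "specificity": ratio(tn, n_neg),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "accuracy": (tp + tn) / total,
        "prevalence": n_pos / total,
    }


def youden_cutpoint(scores_pos, scores_neg, contrast=("pos", "neg"),
                    score_name: str = "") -> RocReport:
    """Locate the Youden-optimal cut-point by exhaustive candidate scan.

    Candidates are midpoints of adjacent distinct pooled values plus -inf and
    +inf, so degenerate optima at the boundaries (e.g. a contrast where no
    finite cut-point beats chance) are handled without error.
    """
    pos = _clean(scores_pos, "positive")
    neg = _clean(scores_neg, "negative")
    pooled = np.unique(np.concatenate([pos, neg]))
    candidates = [-math.inf]
    candidates += [0.5 * (a + b) for a, b in zip(pooled, pooled[1:])]
    candidates.append(math.inf)

    best = None
    for c in candidates:
        sens = float(np.mean(pos > c))
        spec = float(np.mean(neg <= c))
        j = sens + spec - 1.0
        key = (-j, -spec, c)       # max J, then max specificity, then low cut
        if best is None or key < best[0]:
            best = (key, c, sens, spec, j)
    _, cut, sens, spec, j = best

    tp = int(np.sum(pos > cut))
    fn = len(pos) - tp
    fp = int(np.sum(neg > cut))
    tn = len(neg) - fp
    metrics = confusion_metrics(tp, fp, tn, fn)
    return RocReport(
        contrast=tuple(contrast), score_name=score_name,
        cut_point=float(cut), youden=j, auc=auc(pos, neg),
        sensitivity=metrics["sensitivity"], specificity=metrics["specificity"],
        accuracy=metrics["accuracy"], prevalence=metrics["prevalence"],
        ppv=metrics["ppv"], npv=metrics["npv"],
        n_pos=len(pos), n_neg=len(neg),
    )


def es_frequency_table(es: pd.DataFrame, group: str | None = None,
                       group_column: str = "group") -> pd.DataFrame:
    """Counts and percentages of ES 0-4 per score for one group.

    ``es`` holds ES assignments (integers 0-4, nan = missing) in its score
    columns, plus optionally a group column to filter on.  Percentages are on
    the group's non-missing n per score, rounded to 2 d.p.
    """
    data = es
    if group is not None:
        data = es[es[group_column] == group]
    score_cols = [c for c in data.columns if c != group_column]
    rows = []
    for level in range(5):
        row_n, row_pct = {}, {}
        for col in score_cols:
            vals = data[col].dropna()
            n = int((vals == level).sum())
            row_n[col] = n
            row_pct[col] = round(100.0 * n / len(vals), 2) if len(vals) else 0.0
        rows.append({"es": level,
                     **{f"{c}_n": row_n[c] for c in score_cols},
                     **{f"{c}_pct": row_pct[c] for c in score_cols}})
    return pd.DataFrame(rows)


def percentile_table(healthy_adjusted, patient_adjusted: dict,
                     percentiles=(5, 10, 25, 50, 75, 90, 95),
                     direction: str = "higher_is_worse") -> pd.DataFrame:
    """Healthy-percentile cut-offs with the share of each patient group worse.

    For each requested percentile of the healthy adjusted distribution, the
    table reports the percentile value and, per patient group, the percentage
    of patients scoring worse than it (direction-aware; 'worse' is above the
    percentile for higher_is_worse scores, below otherwise).
    """
    healthy = _clean(healthy_adjusted, "healthy")
    sign = 1.0 if direction == "higher_is_worse" else -1.0
    rows = []
    for p in percentiles:
        pp = p if direction == "higher_is_worse" else 100 - p
        value = float(np.percentile(healthy, pp))
        row = {"percentile": p, "value": value}
        for name, scores in patient_adjusted.items():
            x = _clean(scores, name)
            row[f"{name}_pct_worse"] = float(np.mean(sign * x > sign * value) * 100)
        rows.append(row)
    return pd.DataFrame(rows)


class YoudenCutpoint(ClassifierMixin, BaseEstimator):
    """sklearn classifier wrapping the Youden-optimal cut-point.

    ``fit(X, y)`` takes a single score column and binary labels (1 =
    pathological); ``predict`` applies the strict ">" rule at the fitted
    cut-point.  The full :class:`RocReport` is exposed as ``report_``.
    """

    def __init__(self, score_name: str = ""):
        self.score_name = score_name

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y)
        self.classes_ = np.array([0, 1])
        self.report_ = youden_cutpoint(x[y == 1], x[y == 0],
                                       score_name=self.score_name)
        self.cut_point_ = self.report_.cut_point
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return (x > self.cut_point_).astype(int)
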