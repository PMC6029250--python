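"""EC-label ground truth, ROC/AUC, and configuration correlations.

Ground truth follows the enzyme-classification convention: two reactions
are labeled similar when their EC numbers agree through the third field
(sub-subclass). Thresholding is closed: a pair is called positive when its
score >= cutoff. AUC is computed by trapezoidal integration over the
(FPR, TPR) curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateLabelsError, IncompleteECError


@dataclass(frozen=True)
class LabeledPair:
    id_a: str
    id_b: str
    score: float
    label: bool


@dataclass
class RocCurve:
    """Per-cutoff classification statistics and the integrated AUC."""

    cutoffs: np.ndarray  # increasing
    tpr: np.ndarray
    fpr: np.ndarray
    precision: np.ndarray  # NaN where TP+FP == 0
    accuracy: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "tpr": self.tpr,
                "fpr": self.fpr,
                "precision": self.precision,
                "accuracy": self.accuracy,
            }
        )


def ec_similar(ec_a: str, ec_b: str, level: int = 3) -> bool:
    """True iff the first ``level`` dot-separated EC fields are equal."""
    if level < 1:
        raise ValueError(f"level must be >= 1, got {level}")
    fields_a = [f for f in ec_a.strip().split(".") if f]
    fields_b = [f for f in ec_b.strip().split(".") if f]
    if len(fields_a) < level or len(fields_b) < level:
        raise IncompleteECError(
            f"EC comparison at level {level} needs >= {level} fields: "
            f"{ec_a!r} vs {ec_b!r}"
        )
    return fields_a[:level] == fields_b[:level]


def label_pairs(
    scored: Sequence[tuple[str, str, float]],
    ec_by_id: dict[str, str],
    level: int = 3,
) -> list[LabeledPair]:
    """Attach EC-agreement labels to scored pairs; pairs with incomplete
    EC strings are excluded."""
    out = []
    for id_a, id_b, score in scored:
        try:
            label = ec_similar(ec_by_id[id_a], ec_by_id[id_b], level)
        except IncompleteECError:
            continue
        out.append(LabeledPair(id_a, id_b, float(score), label))
    return out


def roc(pairs: Sequence[LabeledPair]) -> RocCurve:
    """ROC over all distinct scores as cutoffs plus {0, 1}.

    Positive call: score >= cutoff. Precision at cutoffs with no positive
    calls is recorded as NaN (missing), never as 0.
    """
    scores = np.array([p.score for p in pairs], dtype=float)
    labels = np.array([p.label for p in pairs], dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError(
            f"ROC needs both classes; got {n_pos} positives, {n_neg} negatives"
        )
    cutoffs = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    cum_tp = np.cumsum(labels[order])
    cum_fp = np.cumsum(~labels[order])
    # number of calls at cutoff c = count(scores >= c)
    n_called = len(scores) - np.searchsorted(sorted_scores[::-1], cutoffs, "left")
    tp = np.where(n_called > 0, cum_tp[np.maximum(n_called - 1, 0)], 0)
    fp = np.where(n_called > 0, cum_fp[np.maximum(n_called - 1, 0)], 0)
    tpr = tp / n_pos
    fpr = fp / n_neg
    tn = n_neg - fp
    with np.errstate(invalid="ignore"):
        precision = np.where(n_called > 0, tp / np.maximum(n_called, 1), np.nan)
        precision[n_called == 0] = np.nan
    accuracy = (tp + tn) / (n_pos + n_neg)
    # integrate over FPR ascending (cutoff descending)
    fpr_asc = fpr[::-1] if fpr[0] > fpr[-1] else fpr
    tpr_asc = tpr[::-1] if fpr[0] > fpr[-1] else tpr
    grid = np.concatenate([[0.0], fpr_asc, [1.0]])
    vals = np.concatenate([[0.0], tpr_asc, [1.0]])
    srt = np.argsort(grid, kind="stable")
    auc = float(np.trapezoid(vals[srt], grid[srt]))
    return RocCurve(cutoffs, tpr, fpr, precision, accuracy, auc)


def pearson_matrix(score_tables: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between every pair of score columns (configurations).

    Columns with zero variance produce NaN (missing) off-diagonal entries;
    the diagonal is 1 by definition.
    """
    if score_tables.shape[1] < 2:
        raise ValueError("need at least two configurations to correlate")
    if score_tables.shape[0] < 3:
        raise ValueError("need at least three scored pairs")
    cols = list(score_tables.columns)
    k = len(cols)
    mat = np.full((k, k), np.nan)
    values = score_tables.to_numpy(dtype=float)
    stds = values.std(axis=0)
    for i in range(k):
        mat[i, i] = 1.0
        for j in range(i + 1, k):
            if stds[i] == 0 or stds[j] == 0:
                continue
            r = float(np.corrcoef(values[:, i], values[:, j])[0, 1])
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=cols, columns=cols)
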