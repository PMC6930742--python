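"""F-score feature ranking (filter stage).

For feature i with positive-group values x+ and negative-group values
x-, the discriminability score is

    F_i = [(mean(x+) - mean(x))^2 + (mean(x-) - mean(x))^2]
          / [var1(x+) + var1(x-)]

where mean(x) is the mean over the whole dataset and var1 denotes the
unbiased (n-1) sample variance within each group.  Larger F_i means a
more discriminative feature; features are ranked in descending order.
This is the two-group separation statistic of the SVM feature-selection
literature, not the F1 classification metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FScoreResult", "compute_fscore", "rank_features", "fscore_frame"]


@dataclass
class FScoreResult:
    """Per-feature scores and the descending-order ranking."""

    scores: np.ndarray
    ranking: np.ndarray

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.ranking):
            raise ValueError("scores and ranking length mismatch")


def compute_fscore(values: np.ndarray, labels: np.ndarray) -> FScoreResult:
    """F-score of every feature column.

    Parameters
    ----------
    values
        (n_subjects, n_features) matrix, no missing values.
    labels
        Per-subject class labels; 1/True = positive (patient),
        0/False = negative (control).  Each group needs >= 2 members
        (the denominator divides by n-1 within each group).

    Degenerate features (zero within-group variance in both groups) get
    F = 0 when the group means agree and +inf when they differ, so that
    "larger = more discriminative" is preserved.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    if values.ndim != 2:
        raise ValueError("values must be 2-D (subjects x features)")
    if len(labels) != values.shape[0]:
        raise ValueError("labels length != number of rows")
    if not np.isfinite(values).all():
        raise ValueError("values contain NaN or inf")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError(
            f"each group needs >= 2 members (got {n_pos} positive, "
            f"{n_neg} negative)"
        )
    pos = values[labels]
    neg = values[~labels]
    mean_all = values.mean(axis=0)
    mean_pos = pos.mean(axis=0)
    mean_neg = neg.mean(axis=0)
    num = (mean_pos - mean_all) ** 2 + (mean_neg - mean_all) ** 2
    den = pos.var(axis=0, ddof=1) + neg.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = num / den
    zero_den = den == 0
    scores[zero_den & (num == 0)] = 0.0
    scores[zero_den & (num > 0)] = np.inf
    return FScoreResult(scores, rank_features(scores))


def rank_features(scores: np.ndarray) -> np.ndarray:
    """Feature indices sorted by descending score, ties by ascending index."""
    scores = np.asarray(scores, dtype=np.float64)
    return np.argsort(-scores, kind="stable")


def fscore_frame(result: FScoreResult, feature_names) -> pd.DataFrame:
    """Ranked score table (feature, F, rank) for reporting."""
    order = result.ranking
    return pd.DataFrame(
        {
            "feature": [feature_names[i] for i in order],
            "fscore": result.scores[order],
            "rank": np.arange(1, len(order) + 1),
        }
    )
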