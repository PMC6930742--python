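"""Performance and association metrics.

Covers the evaluation side of the classification study: pooled
out-of-fold accuracy, ROC curve and AUC from continuous SVM decision
scores, THI severity banding, and per-band Pearson correlations between
THI score and regional gray-matter volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .tables import GROUP_PATIENT, FeatureTable

__all__ = [
    "ScoredSubjects",
    "ROCReport",
    "SeverityBand",
    "SEVERITY_BANDS",
    "CorrelationReport",
    "accuracy",
    "roc_report",
    "plot_roc",
    "get_band",
    "classify_severity",
    "thi_volume_correlation",
]


# ---------------------------------------------------------------------------
# scored subjects / accuracy / ROC


@dataclass
class ScoredSubjects:
    """Out-of-fold predictions: each subject scored exactly once.

    ``scores`` are continuous decision values (positive leans patient);
    ``labels`` and ``predictions`` use 1 = patient, 0 = control.
    """

    subject_ids: np.ndarray
    labels: np.ndarray
    predictions: np.ndarray
    scores: np.ndarray
    folds: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        for name in ("labels", "predictions", "scores", "folds"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != number of subjects")
        if len(np.unique(self.subject_ids)) != n:
            raise ValueError("a subject was scored more than once")


def accuracy(scored: ScoredSubjects, subset: np.ndarray | None = None) -> float:
    """Fraction of correct predictions, optionally over an index subset."""
    labels, preds = scored.labels, scored.predictions
    if subset is not None:
        labels, preds = labels[subset], preds[subset]
    if len(labels) == 0:
        raise ValueError("accuracy of an empty subset is undefined")
    return float(np.mean(labels == preds))


@dataclass
class ROCReport:
    """ROC curve points (fpr, tpr, thresholds) and trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def plot_roc(report: ROCReport, path) -> None:
    """Save a ROC curve figure (PNG/PDF by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(report.fpr, report.tpr, drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(f"AUC = {report.auc:.4f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def roc_report(scored: ScoredSubjects) -> ROCReport:
    """ROC over all distinct score thresholds; ties grouped into one step."""
    labels, scores = scored.labels, scored.scores
    if not np.isfinite(scores).all():
        raise ValueError("decision scores must be finite")
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = _roc_curve(labels, scores, drop_intermediate=False)
    return ROCReport(fpr, tpr, thr, float(_trapezoid_auc(fpr, tpr)))


# ---------------------------------------------------------------------------
# THI severity bands


@dataclass(frozen=True)
class SeverityBand:
    """One THI severity level with its inclusive score interval."""

    name: str
    lo: int
    hi: int

    def contains(self, thi: float) -> bool:
        return self.lo <= thi <= self.hi

    def even_scores(self) -> np.ndarray:
        """The even THI scores inside the band (THI items score 0/2/4)."""
        start = self.lo + (self.lo % 2)
        return np.arange(start, self.hi + 1, 2)


#: the five published severity levels (inclusive THI ranges)
SEVERITY_BANDS = (
    SeverityBand("mild", 1, 16),
    SeverityBand("light", 18, 36),
    SeverityBand("moderate", 38, 56),
    SeverityBand("severe", 58, 76),
    SeverityBand("catastrophic", 78, 100),
)

_BANDS_BY_NAME = {b.name: b for b in SEVERITY_BANDS}


def get_band(name: str) -> SeverityBand:
    try:
        return _BANDS_BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown severity band {name!r}; "
            f"expected one of {sorted(_BANDS_BY_NAME)}"
        ) from None


def classify_severity(thi: float) -> SeverityBand:
    """Map a THI score in [0, 100] to its severity band.

    Scores falling in the gaps between published bands (0 and the odd
    values 17/37/57/77) are assigned to the band of the nearest in-band
    score, ties resolved toward the lower band, with a warning.
    """
    if not 0 <= thi <= 100:
        raise ValueError(f"THI score {thi} outside [0, 100]")
    for band in SEVERITY_BANDS:
        if band.contains(thi):
            return band
    # gap policy: nearest band boundary, ties toward the lower band
    best = min(
        SEVERITY_BANDS,
        key=lambda b: min(abs(thi - b.lo), abs(thi - b.hi)),
    )
    warnings.warn(
        f"THI score {thi} falls between published bands; "
        f"assigned to nearest band {best.name!r}",
        stacklevel=2,
    )
    return best


# ---------------------------------------------------------------------------
# THI-volume correlation


@dataclass
class CorrelationReport:
    band: str
    region: str
    n: int
    pearson_r: float
    p_value: float


def thi_volume_correlation(
    table: FeatureTable, band: str | SeverityBand, region: str
) -> CorrelationReport:
    """Two-sided Pearson correlation between THI and a region's volume.

    Restricted to patients whose THI score lies in the given severity
    band.  The p-value is the exact two-sided t-distribution p of the
    sample correlation; no multiplicity correction is applied.
    """
    if isinstance(band, str):
        band = get_band(band)
    if region not in table.region_names:
        raise KeyError(f"unknown region {region!r}")
    pat = table.patients()
    thi = pat["thi"].to_numpy(dtype=np.float64)
    in_band = np.array([np.isfinite(t) and band.contains(t) for t in thi])
    thi_b = thi[in_band]
    vol_b = pat[region].to_numpy(dtype=np.float64)[in_band]
    if len(thi_b) < 3:
        raise ValueError(
            f"need >= 3 patients in band {band.name!r}, found {len(thi_b)}"
        )
    if np.std(thi_b) == 0 or np.std(vol_b) == 0:
        raise ValueError("zero variance in THI or volume within the band")
    r, p = stats.pearsonr(thi_b, vol_b)
    return CorrelationReport(band.name, region, len(thi_b), float(r), float(p))
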