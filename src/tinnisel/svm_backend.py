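"""Soft-margin RBF-SVM fitting on precomputed kernels.

The wrapper stage evaluates 121 (C, gamma) pairs x 5 inner folds for
every SFFS candidate, i.e. hundreds of thousands of SVM fits per
cohort on ~80-subject kernels.  The public ``sklearn.svm.SVC`` wrapper
spends ~25x more time on per-call validation than libsvm spends
solving a problem of this size, so the hot path calls scikit-learn's
bundled libsvm binding directly and reconstructs the decision values
with the public-API sign convention (positive decision -> class 1).
Equivalence with ``SVC`` is pinned by a regression test; if the
binding is unavailable the code falls back to ``SVC`` transparently.
"""

from __future__ import annotations

import numpy as np
from sklearn.svm import SVC

try:  # pragma: no cover - exercised implicitly everywhere
    from sklearn.svm import _libsvm as _libsvm

    _libsvm.set_verbosity_wrap(0)
    HAVE_FAST_BACKEND = True
except Exception:  # pragma: no cover
    _libsvm = None
    HAVE_FAST_BACKEND = False

__all__ = ["fit_decision", "HAVE_FAST_BACKEND"]


def _fit_decision_fast(
    kernel_train: np.ndarray,
    y_train: np.ndarray,
    kernel_test_rows: np.ndarray,
    c: float,
) -> np.ndarray:
    out = _libsvm.fit(
        kernel_train, y_train, svm_type=0, kernel="precomputed", C=float(c)
    )
    support, coef, intercept = out[0], out[3], out[4][0]
    # libsvm solves with the first-seen class positive; sklearn's binary
    # SVC negates dual coefficients and intercept so that positive
    # decision values map to classes_[1].
    return -(kernel_test_rows[:, support] @ coef.ravel() + intercept)


def _fit_decision_svc(
    kernel_train: np.ndarray,
    y_train: np.ndarray,
    kernel_test_rows: np.ndarray,
    c: float,
) -> np.ndarray:
    svc = SVC(kernel="precomputed", C=float(c))
    svc.fit(kernel_train, y_train)
    return svc.decision_function(kernel_test_rows)


def fit_decision(
    kernel_train: np.ndarray,
    y_train: np.ndarray,
    kernel_test_rows: np.ndarray,
    c: float,
    fast: bool = True,
) -> np.ndarray:
    """Fit a binary SVM on a precomputed kernel; return test decisions.

    ``y_train`` must contain the labels 0 and 1 (both present) as
    float64; ``kernel_test_rows`` has one row per test point over the
    training columns.  Positive decision values predict class 1,
    matching ``SVC(kernel="precomputed").decision_function``.
    """
    if fast and HAVE_FAST_BACKEND:
        return _fit_decision_fast(kernel_train, y_train, kernel_test_rows, c)
    return _fit_decision_svc(kernel_train, y_train, kernel_test_rows, c)
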