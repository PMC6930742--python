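"""Hybrid filter+wrapper feature selection with nested cross-validation.

The procedure, per outer fold of a class-stratified 5-fold split:

1. rank all features by F-score computed on the outer training set only;
2. visit features in rank order, tentatively adding each to the current
   set; after every addition, re-search the RBF-SVM hyperparameters
   (C, gamma) over an 11 x 11 log2 grid by inner 5-fold cross-validation
   on the outer training set;
3. keep the feature only if the best inner-CV accuracy strictly
   increases (sequential forward selection with conditional rejection;
   a full floating variant with backward removal steps is available
   behind ``floating=True``);
4. refit the final classifier on the whole outer training set with the
   selected features and best (C, gamma), and score the held-out fold.

Outer-test subjects never influence the ranking, the SFFS decisions or
the standardization statistics of their fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .fscore import compute_fscore
from .svm_backend import fit_decision
from .tables import FeatureTable
from .util import derive_seed

__all__ = [
    "ClassifierConfig",
    "FoldPlan",
    "make_fold_plan",
    "GridSearchResult",
    "grid_search_svm",
    "TraceEntry",
    "SelectionState",
    "sffs_select",
    "FoldOutcome",
    "SelectionResult",
    "run_nested_selection",
    "FittedClassifier",
    "train_final_classifier",
]


# ---------------------------------------------------------------------------
# configuration and fold plans


@dataclass(frozen=True)
class ClassifierConfig:
    """RBF-SVM hyperparameter grid and preprocessing flags.

    The kernel is K(x, y) = exp(-gamma ||x - y||^2); the grid spans
    log2 C and log2 gamma over the inclusive integer ranges given
    (default -5..5, i.e. 11 x 11 = 121 pairs).
    """

    log2_c_range: tuple[int, int] = (-5, 5)
    log2_gamma_range: tuple[int, int] = (-5, 5)
    standardize: bool = True

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("log2_c_range", self.log2_c_range),
            ("log2_gamma_range", self.log2_gamma_range),
        ):
            if hi < lo:
                raise ValueError(f"{name} is empty")

    @property
    def c_grid(self) -> np.ndarray:
        lo, hi = self.log2_c_range
        return 2.0 ** np.arange(lo, hi + 1)

    @property
    def gamma_grid(self) -> np.ndarray:
        lo, hi = self.log2_gamma_range
        return 2.0 ** np.arange(lo, hi + 1)


@dataclass(frozen=True)
class FoldPlan:
    """Class-stratified k-fold partition.

    ``patient_folds`` / ``control_folds`` hold positional indices within
    each class (0..n_class-1); :meth:`test_rows` maps them onto the row
    order of a label vector.
    """

    patient_folds: tuple[tuple[int, ...], ...]
    control_folds: tuple[tuple[int, ...], ...]
    n_patients: int
    n_controls: int
    k: int
    seed: int

    def __post_init__(self) -> None:
        for folds, n, what in (
            (self.patient_folds, self.n_patients, "patient"),
            (self.control_folds, self.n_controls, "control"),
        ):
            flat = sorted(i for f in folds for i in f)
            if flat != list(range(n)):
                raise ValueError(f"{what} folds do not partition 0..{n - 1}")
            sizes = [len(f) for f in folds]
            if max(sizes) - min(sizes) > 1:
                raise ValueError(f"{what} fold sizes differ by more than 1")

    @property
    def fold_sizes(self) -> list[int]:
        return [
            len(p) + len(c)
            for p, c in zip(self.patient_folds, self.control_folds)
        ]

    def test_rows(self, labels: np.ndarray) -> list[np.ndarray]:
        """Row indices of each fold's test group, given 0/1 labels."""
        labels = np.asarray(labels)
        pat_rows = np.flatnonzero(labels == 1)
        ctl_rows = np.flatnonzero(labels == 0)
        if len(pat_rows) != self.n_patients or len(ctl_rows) != self.n_controls:
            raise ValueError("labels inconsistent with fold plan counts")
        return [
            np.sort(
                np.concatenate(
                    [pat_rows[list(p)], ctl_rows[list(c)]]
                ).astype(np.intp)
            )
            for p, c in zip(self.patient_folds, self.control_folds)
        ]


def make_fold_plan(
    n_patients: int, n_controls: int, k: int = 5, seed: int = 0
) -> FoldPlan:
    """Random class-stratified k-fold partition, deterministic in seed.

    Fold sizes within each class differ by at most one, with the larger
    folds first — for 46 patients / 56 controls and k = 5 this gives
    patient groups of 10, 9, 9, 9, 9 and control groups of 12, 11, 11,
    11, 11 (combined 22, 20, 20, 20, 20) for every seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if min(n_patients, n_controls) < k:
        raise ValueError(
            f"each class needs >= k={k} members "
            f"(got {n_patients} patients, {n_controls} controls)"
        )
    rng = np.random.default_rng(seed)
    pats = [tuple(int(i) for i in f)
            for f in np.array_split(rng.permutation(n_patients), k)]
    ctls = [tuple(int(i) for i in f)
            for f in np.array_split(rng.permutation(n_controls), k)]
    return FoldPlan(tuple(pats), tuple(ctls), n_patients, n_controls, k, seed)


# ---------------------------------------------------------------------------
# inner grid-search engine


class _GridEngine:
    """Inner-CV grid search over additive per-feature distance matrices.

    For standardized features, the squared Euclidean distance of a
    feature subset is the sum of per-feature squared-difference
    matrices, so SFFS candidates reuse precomputed per-feature matrices
    and each (C, gamma) evaluation works on a precomputed kernel slice.
    """

    def __init__(
        self,
        x_std: np.ndarray,
        y: np.ndarray,
        fold_test_rows: list[np.ndarray],
        config: ClassifierConfig,
        fast: bool = True,
    ) -> None:
        n, p = x_std.shape
        self.config = config
        self.fast = fast
        self.c_grid = config.c_grid
        self.gamma_grid = config.gamma_grid
        diff = x_std[:, None, :] - x_std[None, :, :]
        self.d_feat = np.ascontiguousarray(
            np.moveaxis(diff**2, -1, 0)
        )  # (p, n, n)
        self.folds = []
        all_rows = np.arange(n)
        for te in fold_test_rows:
            tr = np.setdiff1d(all_rows, te)
            ytr = np.ascontiguousarray(y[tr], dtype=np.float64)
            if len(np.unique(ytr)) < 2:
                raise ValueError(
                    "an inner training fold contains one class only; "
                    "re-seed or stratify the inner fold plan"
                )
            self.folds.append(
                (np.ix_(tr, tr), np.ix_(te, tr), ytr, y[te].astype(np.float64))
            )

    def majority_baseline(self) -> float:
        accs = []
        for _, _, ytr, yte in self.folds:
            maj = 1.0 if ytr.mean() > 0.5 else 0.0
            accs.append(float(np.mean(yte == maj)))
        return float(np.mean(accs))

    def accuracy_grid(self, d_total: np.ndarray) -> np.ndarray:
        """Mean inner-CV accuracy for every (C, gamma); shape (nC, ngamma)."""
        acc = np.zeros((len(self.c_grid), len(self.gamma_grid)))
        for gi, gamma in enumerate(self.gamma_grid):
            kernel = np.exp(-gamma * d_total)
            for ix_tr, ix_te, ytr, yte in self.folds:
                k_tr = np.ascontiguousarray(kernel[ix_tr])
                k_te = np.ascontiguousarray(kernel[ix_te])
                for ci, c in enumerate(self.c_grid):
                    dec = fit_decision(k_tr, ytr, k_te, c, fast=self.fast)
                    acc[ci, gi] += np.mean((dec > 0) == (yte == 1.0))
        acc /= len(self.folds)
        return acc

    def best_pair(self, d_total: np.ndarray) -> tuple[float, float, float]:
        """(C, gamma, accuracy) maximizing inner-CV accuracy.

        Ties prefer the smallest C, then the smallest gamma (the
        smoother, less complex model).
        """
        acc = self.accuracy_grid(d_total)
        ci, gi = np.argwhere(acc == acc.max())[0]
        return float(self.c_grid[ci]), float(self.gamma_grid[gi]), float(
            acc[ci, gi]
        )


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    return (x - mean) / sd_safe, mean, sd_safe


@dataclass
class GridSearchResult:
    c: float
    gamma: float
    accuracy: float
    n_pairs_evaluated: int
    accuracy_grid: np.ndarray


def grid_search_svm(
    values: np.ndarray,
    labels: np.ndarray,
    feature_set: list[int],
    config: ClassifierConfig,
    inner_plan: FoldPlan,
    fast: bool = True,
) -> GridSearchResult:
    """Exhaustive (C, gamma) search by inner k-fold CV on a feature set."""
    if len(feature_set) == 0:
        raise ValueError("feature_set must be non-empty")
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    x = values[:, list(feature_set)]
    if config.standardize:
        x, _, _ = _standardize(x)
    engine = _GridEngine(
        x, labels.astype(np.float64), inner_plan.test_rows(labels),
        config, fast=fast,
    )
    d_total = engine.d_feat.sum(axis=0)
    acc = engine.accuracy_grid(d_total)
    ci, gi = np.argwhere(acc == acc.max())[0]
    return GridSearchResult(
        float(engine.c_grid[ci]),
        float(engine.gamma_grid[gi]),
        float(acc[ci, gi]),
        acc.size,
        acc,
    )


# ---------------------------------------------------------------------------
# SFFS


@dataclass(frozen=True)
class TraceEntry:
    """One SFFS decision: a tentative addition or a floating removal."""

    action: str  # "add" or "remove"
    feature: int
    accepted: bool
    accuracy_before: float
    accuracy_after: float
    c: float
    gamma: float


@dataclass
class SelectionState:
    """Outcome of one SFFS pass over the ranked features."""

    features: list[int]
    accuracy: float
    c: float | None
    gamma: float | None
    baseline_accuracy: float
    trace: list[TraceEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise ValueError("selected features are not unique")
        accepted_add = [
            t.accuracy_after
            for t in self.trace
            if t.accepted and t.action == "add"
        ]
        history = [self.baseline_accuracy] + accepted_add
        if any(not (b > a) for a, b in zip(history, history[1:])):
            raise ValueError(
                "inner-CV accuracy over accepted steps must strictly increase"
            )


def sffs_select(
    values: np.ndarray,
    labels: np.ndarray,
    ranking: np.ndarray,
    config: ClassifierConfig,
    inner_plan: FoldPlan,
    floating: bool = False,
    fast: bool = True,
) -> SelectionState:
    """Forward selection over the F-score ranking with strict acceptance.

    Starts from the empty set at the inner-CV majority-class baseline;
    every ranked feature is tentatively added, (C, gamma) re-searched,
    and the feature kept only if the best inner-CV accuracy strictly
    increases (a tie rejects).  With ``floating=True``, each acceptance
    is followed by backward passes that drop any previously accepted
    feature whose removal strictly improves accuracy.  All features are
    visited exactly once.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    ranking = np.asarray(ranking)
    if sorted(ranking.tolist()) != list(range(values.shape[1])):
        raise ValueError("ranking must be a permutation of all features")
    x = values
    if config.standardize:
        x, _, _ = _standardize(x)
    engine = _GridEngine(
        x, labels.astype(np.float64), inner_plan.test_rows(labels),
        config, fast=fast,
    )
    baseline = engine.majority_baseline()
    n = x.shape[0]
    d_cur = np.zeros((n, n))
    features: list[int] = []
    cur_acc, cur_c, cur_gamma = baseline, None, None
    trace: list[TraceEntry] = []

    for f in ranking:
        f = int(f)
        c, gamma, acc = engine.best_pair(d_cur + engine.d_feat[f])
        accepted = acc > cur_acc
        trace.append(
            TraceEntry("add", f, accepted, cur_acc, acc, c, gamma)
        )
        if not accepted:
            continue
        d_cur = d_cur + engine.d_feat[f]
        features.append(f)
        cur_acc, cur_c, cur_gamma = acc, c, gamma
        if floating:
            improved = True
            while improved and len(features) > 1:
                improved = False
                for g in list(features[:-1]):
                    d_try = d_cur - engine.d_feat[g]
                    c2, gamma2, acc2 = engine.best_pair(d_try)
                    removed = acc2 > cur_acc
                    trace.append(
                        TraceEntry(
                            "remove", g, removed, cur_acc, acc2, c2, gamma2
                        )
                    )
                    if removed:
                        features.remove(g)
                        d_cur = d_try
                        cur_acc, cur_c, cur_gamma = acc2, c2, gamma2
                        improved = True
                        break
    return SelectionState(
        features, cur_acc, cur_c, cur_gamma, baseline, trace
    )


# ---------------------------------------------------------------------------
# final classifier


@dataclass
class FittedClassifier:
    """A refit RBF-SVM over a selected feature subset.

    Exposes continuous decision scores (positive leans patient) for
    ROC analysis; standardization uses the training statistics stored
    at fit time.
    """

    svc: SVC
    feature_idx: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    c: float
    gamma: float

    def _transform(self, values: np.ndarray) -> np.ndarray:
        x = np.asarray(values, dtype=np.float64)[:, self.feature_idx]
        return (x - self.mean) / self.sd

    def decision_scores(self, values: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(self._transform(values))

    def predict(self, values: np.ndarray) -> np.ndarray:
        return (self.decision_scores(values) > 0).astype(np.int64)


def train_final_classifier(
    values,
    labels=None,
    feature_idx=(),
    c: float = 1.0,
    gamma: float = 1.0,
    standardize: bool = True,
) -> FittedClassifier:
    """Fit the soft-margin RBF-SVM on a feature subset.

    ``values`` may be a (subjects x features) array with explicit
    ``labels``, or a :class:`FeatureTable` (labels taken from it;
    ``feature_idx`` may then also be region names).
    """
    if isinstance(values, FeatureTable):
        table = values
        labels = table.labels
        feature_idx = [
            table.region_names.index(f) if isinstance(f, str) else f
            for f in feature_idx
        ]
        values = table.volumes
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels).astype(np.int64)
    feature_idx = np.asarray(list(feature_idx), dtype=np.intp)
    if len(feature_idx) == 0:
        raise ValueError("cannot train on an empty feature set")
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")
    x = values[:, feature_idx]
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = feature_idx[sd == 0].tolist()
        raise ValueError(f"degenerate constant feature column(s): {bad}")
    mean = x.mean(axis=0)
    if not standardize:
        mean, sd = np.zeros_like(mean), np.ones_like(sd)
    svc = SVC(C=c, gamma=gamma, kernel="rbf")
    svc.fit((x - mean) / sd, labels)
    return FittedClassifier(svc, feature_idx, mean, sd, c, gamma)


# ---------------------------------------------------------------------------
# the nested procedure


@dataclass
class FoldOutcome:
    fold_index: int
    test_rows: np.ndarray
    ranking: np.ndarray
    selected_features: list[int]
    selected_names: list[str]
    c: float | None
    gamma: float | None
    train_accuracy: float
    test_accuracy: float
    decision_scores: np.ndarray
    predictions: np.ndarray
    trace: list[TraceEntry]


@dataclass
class SelectionResult:
    """Aggregated outcome of the nested selection over all outer folds."""

    folds: list[FoldOutcome]
    feature_names: list[str]
    mean_train_accuracy: float
    mean_test_accuracy: float
    selection_frequencies: dict[str, int]
    consensus_features: list[str]
    seed: int

    def pooled(self):
        """Pooled out-of-fold scores: every subject scored exactly once."""
        order = np.concatenate([f.test_rows for f in self.folds])
        return order

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "mean_train_accuracy": self.mean_train_accuracy,
            "mean_test_accuracy": self.mean_test_accuracy,
            "selection_frequencies": self.selection_frequencies,
            "consensus_features": self.consensus_features,
            "folds": [
                {
                    "fold_index": f.fold_index,
                    "test_rows": f.test_rows.tolist(),
                    "selected_features": f.selected_names,
                    "c": f.c,
                    "gamma": f.gamma,
                    "train_accuracy": f.train_accuracy,
                    "test_accuracy": f.test_accuracy,
                    "decision_scores": f.decision_scores.tolist(),
                    "predictions": f.predictions.tolist(),
                    "trace": [
                        {
                            "action": t.action,
                            "feature": self.feature_names[t.feature],
                            "accepted": t.accepted,
                            "accuracy_before": t.accuracy_before,
                            "accuracy_after": t.accuracy_after,
                            "c": t.c,
                            "gamma": t.gamma,
                        }
                        for t in f.trace
                    ],
                }
                for f in self.folds
            ],
        }


def _residualize_on_age(
    x_train: np.ndarray,
    x_test: np.ndarray,
    age_train: np.ndarray,
    age_test: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Remove the linear age trend, estimated on the training rows only."""
    a0 = age_train.mean()
    var = ((age_train - a0) ** 2).sum()
    if var == 0:
        return x_train, x_test
    slope = (age_train - a0) @ (x_train - x_train.mean(axis=0)) / var
    return (
        x_train - np.outer(age_train - a0, slope),
        x_test - np.outer(age_test - a0, slope),
    )


def run_nested_selection(
    table: FeatureTable,
    config: ClassifierConfig,
    plan: FoldPlan,
    floating: bool = False,
    age_control: bool = False,
    fast: bool = True,
) -> SelectionResult:
    """Run the full hybrid procedure over every outer fold of a plan.

    Per fold, the F-score ranking, the SFFS decisions and the
    standardization statistics are computed on the training subjects
    only; the held-out fold yields the test accuracy and the continuous
    decision scores pooled later for the ROC.  Fully deterministic given
    the plan's seed.
    """
    labels = table.labels
    volumes = table.volumes
    if plan.n_patients != table.n_patients or (
        plan.n_controls != table.n_controls
    ):
        raise ValueError("fold plan and table have inconsistent group sizes")
    test_rows_per_fold = plan.test_rows(labels)
    all_rows = np.arange(len(labels))
    ages = table.data["age"].to_numpy(dtype=np.float64)

    outcomes = []
    for i, te in enumerate(test_rows_per_fold):
        tr = np.setdiff1d(all_rows, te)
        x_tr, x_te = volumes[tr], volumes[te]
        y_tr, y_te = labels[tr], labels[te]
        if age_control:
            x_tr, x_te = _residualize_on_age(x_tr, x_te, ages[tr], ages[te])
        ranking = compute_fscore(x_tr, y_tr).ranking
        inner_plan = make_fold_plan(
            int(y_tr.sum()),
            int((1 - y_tr).sum()),
            plan.k,
            derive_seed(plan.seed, "inner", i),
        )
        state = sffs_select(
            x_tr, y_tr, ranking, config, inner_plan,
            floating=floating, fast=fast,
        )
        if state.features:
            clf = train_final_classifier(
                x_tr, y_tr, state.features, state.c, state.gamma,
                standardize=config.standardize,
            )
            scores = clf.decision_scores(x_te)
            preds = (scores > 0).astype(np.int64)
        else:  # nothing beat the majority baseline (null-like data)
            maj = 1 if y_tr.mean() > 0.5 else 0
            scores = np.zeros(len(te))
            preds = np.full(len(te), maj, dtype=np.int64)
        outcomes.append(
            FoldOutcome(
                fold_index=i,
                test_rows=te,
                ranking=ranking,
                selected_features=state.features,
                selected_names=[
                    table.region_names[j] for j in state.features
                ],
                c=state.c,
                gamma=state.gamma,
                train_accuracy=state.accuracy,
                test_accuracy=float(np.mean(preds == y_te)),
                decision_scores=scores,
                predictions=preds,
                trace=state.trace,
            )
        )

    freqs: dict[str, int] = {}
    for out in outcomes:
        for name in out.selected_names:
            freqs[name] = freqs.get(name, 0) + 1
    threshold = plan.k // 2 + 1
    consensus = sorted(
        [n for n, c in freqs.items() if c >= threshold],
        key=lambda n: (-freqs[n], n),
    )
    return SelectionResult(
        folds=outcomes,
        feature_names=list(table.region_names),
        mean_train_accuracy=float(
            np.mean([o.train_accuracy for o in outcomes])
        ),
        mean_test_accuracy=float(
            np.mean([o.test_accuracy for o in outcomes])
        ),
        selection_frequencies=dict(
            sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0]))
        ),
        consensus_features=consensus,
        seed=plan.seed,
    )


def pooled_scored_subjects(table: FeatureTable, result: SelectionResult):
    """Assemble out-of-fold ScoredSubjects for evaluation."""
    from .evaluation import ScoredSubjects

    ids, labs, preds, scores, folds = [], [], [], [], []
    labels = table.labels
    subject_ids = table.data["subject_id"].to_numpy()
    for out in result.folds:
        ids.append(subject_ids[out.test_rows])
        labs.append(labels[out.test_rows])
        preds.append(out.predictions)
        scores.append(out.decision_scores)
        folds.append(np.full(len(out.test_rows), out.fold_index))
    return ScoredSubjects(
        np.concatenate(ids),
        np.concatenate(labs),
        np.concatenate(preds),
        np.concatenate(scores),
        np.concatenate(folds),
    )
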