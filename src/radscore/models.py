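"""Final radiomic model construction on the robust feature set.

Six model families are supported: four linear scorers (ridge, lasso,
logistic regression, LDA) producing a Radiomics Score per sample, and two
probability classifiers (KNN with k tuned over 1..50, SVM with the kernel
chosen on a held-out validation part). Every family is assessed with the
same machinery as the selection loop: Youden cutoff fixed on the training
split, metric suites on train and test, an unpaired DeLong gate between
the two ROC curves, and permutation tests of the score between label
groups on each split. A family "succeeds" when both permutation tests
reject at 0.05; the best scorer is the successful family with the top
test-set AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression, RidgeCV
from sklearn.model_selection import KFold, StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .io import FeatureTable, StandardizationParams, standardize
from .selection import (
    FittedLinearScorer,
    SelectionConfig,
    fit_lasso_cv,
    split_cohort,
)
from .stats import (
    PerformanceReport,
    delong_compare,
    permutation_test_scores,
    report_at_cutoff,
    youden_cutoff,
)

log = logging.getLogger(__name__)

__all__ = [
    "ModelAssessment",
    "NoSuccessfulModelError",
    "LinearScorerModel",
    "ProbabilityModel",
    "final_split",
    "train_linear_scorer",
    "tune_knn",
    "tune_svm",
    "assess_scorer",
    "select_best_scorer",
]

LINEAR_FAMILIES = ("ridge", "lasso", "logistic", "lda")
DEFAULT_KERNELS = ("rbfdot", "polydot", "tanhdot", "vanilladot",
                   "laplacedot", "besseldot", "anovadot")


class NoSuccessfulModelError(RuntimeError):
    """No candidate family passed the dual permutation gate."""


@dataclass
class ModelAssessment:
    model_family: str
    train_report: PerformanceReport
    test_report: PerformanceReport
    delong_p: float
    train_perm_p: float
    test_perm_p: float
    success: bool
    cutoff: float
    model: object = None

    def to_row(self, which: str = "train") -> dict:
        rep = self.train_report if which == "train" else self.test_report
        return {"model": self.model_family, "set": which, **rep.as_dict()}


# ---------------------------------------------------------------------------
# scoring wrappers: everything exposes score_table(raw FeatureTable) -> scores


class LinearScorerModel:
    """Adapter placing raw tables on the training scale before computing RS."""

    def __init__(self, scorer: FittedLinearScorer):
        self.scorer = scorer
        self.model_family = scorer.model_family

    def score_table(self, table: FeatureTable) -> np.ndarray:
        std = self.scorer.standardization.transform(table.values[self.scorer.feature_names])
        return std.to_numpy(float) @ self.scorer.coefficients + self.scorer.intercept


class ProbabilityModel:
    """KNN/SVM adapter: scores are predicted probabilities of class 1."""

    def __init__(self, estimator, params: StandardizationParams, family: str,
                 predict_fn=None):
        self.estimator = estimator
        self.params = params
        self.model_family = family
        self._predict_fn = predict_fn

    def score_table(self, table: FeatureTable) -> np.ndarray:
        x = self.params.transform(table.values[list(self.params.mean.index)]).to_numpy(float)
        if self._predict_fn is not None:
            return self._predict_fn(x)
        proba = self.estimator.predict_proba(x)
        return proba[:, list(self.estimator.classes_).index(1)]


# ---------------------------------------------------------------------------
# splits & linear families


def final_split(table: FeatureTable, seed) -> tuple[FeatureTable, FeatureTable]:
    """The 65/35 stratified split used for final model training."""
    return split_cohort(table, 0.65, seed)


def _ridge_grid() -> np.ndarray:
    return np.logspace(-3, 3, 100)


def train_linear_scorer(
    train: FeatureTable, family: str, cv_folds: int = 10, seed: int = 0
) -> FittedLinearScorer:
    """Fit one linear family on the (raw) training table.

    Standardization parameters are computed here and stored on the returned
    scorer. Ridge and lasso tune their penalty by ``cv_folds``-fold CV at
    minimum mean squared error; logistic regression and LDA are fit
    unpenalized at default settings. The LDA scorer is the posterior
    log-odds direction so the Youden/permutation machinery applies
    uniformly across families.
    """
    if family not in LINEAR_FAMILIES:
        raise ValueError(f"unknown linear family {family!r}")
    (train_std,), params = standardize(train)
    x = train_std.matrix
    y = train.labels.astype(float)
    names = train.feature_names
    if family == "lasso":
        return fit_lasso_cv(train_std, cv_folds, seed, params=params)
    if family == "ridge":
        cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed % (2**31))
        model = RidgeCV(alphas=_ridge_grid(), scoring="neg_mean_squared_error", cv=cv)
        model.fit(x, y)
        return FittedLinearScorer(names, model.coef_, float(model.intercept_), params, "ridge")
    if family == "logistic":
        model = LogisticRegression(C=np.inf, max_iter=2000)
        model.fit(x, train.labels)
        return FittedLinearScorer(names, model.coef_[0], float(model.intercept_[0]), params, "logistic")
    # LDA: decision_function is the posterior log-odds under equal-covariance Gaussians
    model = LinearDiscriminantAnalysis()
    model.fit(x, train.labels)
    return FittedLinearScorer(names, model.coef_[0], float(model.intercept_[0]), params, "lda")


# ---------------------------------------------------------------------------
# KNN


def tune_knn(
    train: FeatureTable, k_range=range(1, 51), cv_folds: int = 10, seed: int = 0
) -> tuple[int, ProbabilityModel]:
    """Grid-search k by mean CV accuracy; ties resolve toward smaller k.

    Distances are Euclidean on standardized features; predicted
    probabilities are neighbour vote fractions. Grid points with k larger
    than the fold training size are skipped with a log message.
    """
    (train_std,), params = standardize(train)
    x = train_std.matrix
    y = train.labels
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed % (2**31))
    max_fit = min(len(tr) for tr, _ in cv.split(x, y))
    best_k, best_acc = None, -np.inf
    for k in k_range:
        if k > max_fit:
            log.warning("skipping k=%d: exceeds fold training size %d", k, max_fit)
            continue
        acc = cross_val_score(KNeighborsClassifier(n_neighbors=k), x, y, cv=cv,
                              scoring="accuracy").mean()
        if acc > best_acc + 1e-12:
            best_k, best_acc = k, acc
    model = KNeighborsClassifier(n_neighbors=best_k)
    model.fit(x, y)
    return best_k, ProbabilityModel(model, params, "knn")


# ---------------------------------------------------------------------------
# SVM


def _median_heuristic(x: np.ndarray) -> float:
    d = cdist(x, x)
    med = np.median(d[np.triu_indices_from(d, k=1)])
    return float(med) if med > 0 else 1.0


def _make_svm(kernel: str, x: np.ndarray):
    """Instantiate one kernel candidate; None when unimplemented."""
    if kernel == "rbfdot":
        return SVC(kernel="rbf", C=1.0, gamma="scale")
    if kernel == "polydot":
        return SVC(kernel="poly", C=1.0, degree=3, gamma="scale")
    if kernel == "tanhdot":
        return SVC(kernel="sigmoid", C=1.0, gamma="scale")
    if kernel == "vanilladot":
        return SVC(kernel="linear", C=1.0)
    if kernel == "laplacedot":
        sigma = 1.0 / _median_heuristic(x)

        def laplace(a, b, _s=sigma):
            return np.exp(-_s * cdist(a, b))

        return SVC(kernel=laplace, C=1.0)
    return None  # besseldot / anovadot have no counterpart here


def _platt(decision: np.ndarray, labels: np.ndarray):
    """Monotone (logistic) calibration of decision values to probabilities."""
    lr = LogisticRegression(max_iter=1000)
    lr.fit(decision.reshape(-1, 1), labels)
    return lr


def tune_svm(
    table: FeatureTable,
    kernel_set=DEFAULT_KERNELS,
    seed: int = 0,
    val_fraction: float = 0.35,
    test_of_val: float = 0.5,
) -> tuple[str, ProbabilityModel, FeatureTable, FeatureTable]:
    """Kernel selection on a disjoint three-way split (default 65/17.5/17.5).

    The training part fits one SVC per implementable kernel (cost 1,
    bandwidth by scale/median heuristic); the validation part picks the
    kernel with the top accuracy, ties broken by ``kernel_set`` order;
    probabilities come from a logistic calibration of decision values fit
    on the validation part. Returns (kernel, model, train_part, test_part);
    the test part is untouched by tuning. Unavailable kernels are logged
    and skipped, never silently substituted.
    """
    rng = np.random.default_rng(seed)
    train, rest = split_cohort(table, 1.0 - val_fraction, rng)
    val, test = split_cohort(rest, test_of_val, rng)
    (train_std, val_std), params = standardize(train, val)
    x_tr, y_tr = train_std.matrix, train.labels
    x_val, y_val = val_std.matrix, val.labels
    best = None
    for kernel in kernel_set:
        svc = _make_svm(kernel, x_tr)
        if svc is None:
            log.warning("kernel %s not implemented; skipped", kernel)
            continue
        svc.fit(x_tr, y_tr)
        acc = (svc.predict(x_val) == y_val).mean()
        if best is None or acc > best[0] + 1e-12:
            best = (acc, kernel, svc)
    if best is None:
        raise ValueError("no implementable kernel in kernel_set")
    _, kernel, svc = best
    platt = _platt(svc.decision_function(x_val), y_val)

    def predict(x: np.ndarray, _svc=svc, _pl=platt) -> np.ndarray:
        d = _svc.decision_function(x)
        return _pl.predict_proba(d.reshape(-1, 1))[:, list(_pl.classes_).index(1)]

    model = ProbabilityModel(svc, params, "svm", predict_fn=predict)
    return kernel, model, train, test


# ---------------------------------------------------------------------------
# assessment


def assess_scorer(
    model,
    train: FeatureTable,
    test: FeatureTable,
    config: SelectionConfig | None = None,
    rng=None,
) -> ModelAssessment:
    """Evaluate one fitted family on its train/test split.

    The Youden cutoff is a training-set artifact reapplied unchanged to the
    test split. Success requires the score (RS or predicted probability) to
    separate the label groups on *both* splits (permutation p < 0.05).
    """
    config = config or SelectionConfig()
    rng = np.random.default_rng(rng if rng is not None else 0)
    if isinstance(model, FittedLinearScorer):
        model = LinearScorerModel(model)
    s_train = np.asarray(model.score_table(train), float)
    s_test = np.asarray(model.score_table(test), float)
    family = getattr(model, "model_family", "unknown")
    if np.ptp(s_train) == 0 or np.ptp(s_test) == 0:
        nan = float("nan")
        return ModelAssessment(family, PerformanceReport(), PerformanceReport(),
                               nan, nan, nan, False, nan, model)
    op = youden_cutoff(s_train, train.labels)
    train_rep = report_at_cutoff(s_train, train.labels, op.cutoff)
    test_rep = report_at_cutoff(s_test, test.labels, op.cutoff)
    _, delong_p = delong_compare(s_train, train.labels, s_test, test.labels, paired=False)
    p_train = permutation_test_scores(s_train, train.labels, config.n_permutations, rng)
    p_test = permutation_test_scores(s_test, test.labels, config.n_permutations, rng)
    success = (p_train < config.rs_perm_alpha) and (p_test < config.rs_perm_alpha)
    return ModelAssessment(family, train_rep, test_rep, float(delong_p),
                           float(p_train), float(p_test), success, op.cutoff, model)


def select_best_scorer(assessments: list[ModelAssessment]) -> ModelAssessment:
    """Among successful families: max test AUC, then the smallest
    train-test AUC gap, then the higher train AUC."""
    if not assessments:
        raise ValueError("no assessments supplied")
    ok = [a for a in assessments if a.success]
    if not ok:
        raise NoSuccessfulModelError("no successful model")
    return max(ok, key=lambda a: (
        a.test_report.auc,
        -abs(a.train_report.auc - a.test_report.auc),
        a.train_report.auc,
    ))


def assessments_frame(assessments: list[ModelAssessment]) -> pd.DataFrame:
    rows = []
    for a in assessments:
        for which in ("train", "test"):
            row = a.to_row(which)
            row.update({"delong_p": a.delong_p, "train_perm_p": a.train_perm_p,
                        "test_perm_p": a.test_perm_p, "success": a.success})
            rows.append(row)
    return pd.DataFrame(rows)
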