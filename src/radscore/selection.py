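"""Iterative robust radiomic-feature selection.

The selection loop repeatedly re-splits the derivation cohort at seven
train fractions (8:2 down to 5:5), runs a per-split filtering cascade
(standardization -> zero-variance drop -> normality-adaptive redundancy
filter -> two-sample permutation screen) and fits a cross-validated Lasso
on what survives. A fitted candidate is *accepted* when the train and test
ROC curves do not differ (DeLong p above the gate) while the radiomics
score does separate the two label groups on the held-out split
(permutation p below the gate). Features appearing with nonzero penalized
coefficients in accepted candidates accrue selection counts across the
whole loop; features counted strictly more often than ``min_count`` form
the robust set handed to the final modeling stage.

At the default scale (1000 iterations x 7 ratios) the loop attempts
exactly 7000 Lasso candidates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import KFold

from .io import FeatureTable, StandardizationParams, standardize
from .stats import delong_compare, permutation_test_scores

__all__ = [
    "SelectionConfig",
    "FittedLinearScorer",
    "IterationRecord",
    "SelectionResult",
    "split_cohort",
    "drop_zero_variance",
    "redundancy_filter",
    "permutation_screen",
    "fit_lasso_cv",
    "compute_rs",
    "accept_candidate",
    "run_iterations",
    "select_robust_features",
]

DEFAULT_RATIOS = (0.8, 0.75, 0.7, 0.65, 0.6, 0.55, 0.5)


@dataclass
class SelectionConfig:
    split_ratios: tuple = DEFAULT_RATIOS
    n_iterations: int = 1000
    redundancy_r: float = 0.9
    redundancy_alpha: float = 0.05
    screen_alpha: float = 0.05
    n_permutations: int = 9999
    delong_alpha: float = 0.05  # the iteration gate; 0.50 is the stricter variant
    rs_perm_alpha: float = 0.05
    min_count: int = 100
    cv_folds: int = 10
    normality_alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not all(0 < r < 1 for r in self.split_ratios):
            raise ValueError("split ratios must be train fractions in (0, 1)")
        if self.n_iterations > 0 and self.min_count >= self.n_iterations * len(self.split_ratios):
            raise ValueError("min_count must be below the total number of candidates")


@dataclass
class FittedLinearScorer:
    """Linear radiomics scorer: RS = sum(feature * coefficient) + intercept.

    Feature values are understood on the training standardization scale;
    ``standardization`` carries the training means/sds needed to place new
    samples on that scale.
    """

    feature_names: list[str]
    coefficients: np.ndarray
    intercept: float
    standardization: StandardizationParams
    model_family: str = "lasso"

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.feature_names):
            raise ValueError("coefficients must align with feature_names")

    def to_dict(self) -> dict:
        return {
            "model_family": self.model_family,
            "feature_names": list(self.feature_names),
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "standardization": {
                "mean": self.standardization.mean.to_dict(),
                "sd": self.standardization.sd.to_dict(),
            },
        }


@dataclass
class IterationRecord:
    iteration: int
    ratio: float
    selected_feature_names: list[str]
    delong_p: float
    train_rs_perm_p: float
    test_rs_perm_p: float
    accepted: bool
    reason: str = ""


@dataclass
class SelectionResult:
    counts: dict[str, int]
    records: list[IterationRecord]
    total_candidates: int
    config: SelectionConfig = None  # type: ignore[assignment]

    @property
    def n_accepted(self) -> int:
        return sum(r.accepted for r in self.records)

    def counts_frame(self) -> pd.DataFrame:
        items = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(items, columns=["feature", "count"])

    def to_json(self, path) -> str:
        payload = {
            "total_candidates": self.total_candidates,
            "n_accepted": self.n_accepted,
            "counts": self.counts,
            "config": asdict(self.config) if self.config else None,
            "records": [asdict(r) for r in self.records],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return str(path)


# ---------------------------------------------------------------------------
# split & filters


def split_cohort(table: FeatureTable, train_fraction: float, rng) -> tuple[FeatureTable, FeatureTable]:
    """Label-stratified random partition into train/test.

    Per stratum the train share is round(fraction * stratum size); with the
    balanced 120-sample cohort this yields 96/24 at 0.8 and 78/42 at 0.65.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    labels = table.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("both labels must be present")
    train_idx, test_idx = [], []
    for lab in (0, 1):
        idx = np.flatnonzero(labels == lab)
        n_train = int(np.floor(train_fraction * len(idx) + 0.5))
        if n_train == 0 or n_train == len(idx):
            raise ValueError(f"label {lab} stratum would be empty in one partition")
        perm = rng.permutation(idx)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    return table.subset_samples(np.sort(train_idx)), table.subset_samples(np.sort(test_idx))


def drop_zero_variance(train: FeatureTable) -> list[str]:
    """Names of features with nonzero variance on the training split."""
    var = train.values.var(ddof=1)
    retained = [c for c in train.feature_names if var[c] > 0]
    if not retained:
        raise ValueError("all features have zero variance")
    return retained


def _corr_pvalue(r: float, n: int) -> float:
    if abs(r) >= 1:
        return 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return float(2 * sps.t.sf(abs(t), n - 2))


def redundancy_filter(
    train: FeatureTable,
    r_threshold: float = 0.9,
    alpha: float = 0.05,
    priority=None,
    normality_alpha: float = 0.05,
) -> tuple[list[str], list[dict]]:
    """Drop one member of every highly correlated feature pair.

    The correlation test adapts to normality: Pearson when both features
    pass Shapiro-Wilk, Spearman otherwise. A pair is redundant when
    |r| > ``r_threshold`` with correlation-test p < ``alpha``. Scanning is
    greedy in column order; within a flagged pair the member with the lower
    ``priority`` value survives (defaults to column order, remaining ties
    lexicographic).
    """
    names = train.feature_names
    if len(names) < 2:
        return list(names), []
    x = train.matrix
    n = x.shape[0]
    normal = np.array([
        sps.shapiro(x[:, j]).pvalue >= normality_alpha if len(np.unique(x[:, j])) >= 3 else False
        for j in range(x.shape[1])
    ])
    pearson = np.corrcoef(x, rowvar=False)
    spearman = np.corrcoef(sps.rankdata(x, axis=0), rowvar=False)

    def prio(name):
        return priority(name) if priority is not None else 0.0

    removed: set[int] = set()
    log: list[dict] = []
    for i in range(len(names)):
        if i in removed:
            continue
        for j in range(i + 1, len(names)):
            if i in removed:
                break
            if j in removed:
                continue
            use_pearson = normal[i] and normal[j]
            r = pearson[i, j] if use_pearson else spearman[i, j]
            if not np.isfinite(r) or abs(r) <= r_threshold:
                continue
            p = _corr_pvalue(r, n)
            if p >= alpha:
                continue
            pi, pj = prio(names[i]), prio(names[j])
            if pi < pj or (pi == pj and names[i] < names[j]):
                drop = j
            else:
                drop = i
            removed.add(drop)
            log.append({
                "kept": names[i if drop == j else j],
                "dropped": names[drop],
                "r": float(r),
                "p": p,
                "test": "pearson" if use_pearson else "spearman",
            })
            if drop == i:
                break
    retained = [nm for k, nm in enumerate(names) if k not in removed]
    return retained, log


def permutation_screen(
    train: FeatureTable, alpha: float, n_permutations: int, rng
) -> tuple[list[str], dict[str, float]]:
    """Per-feature two-sample permutation test of the group mean difference.

    Features whose Monte-Carlo p (add-one corrected) is >= ``alpha`` are
    removed. All features share one set of label permutations, which keeps
    the screen O(B * n * p) via a single matrix product.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = train.matrix
    y = train.labels
    n, p = x.shape
    n1 = int(y.sum())
    if n1 == 0 or n1 == n:
        raise ValueError("both labels must be present")
    col_sums = x.sum(axis=0)
    obs = np.abs(x[y == 1].mean(axis=0) - x[y == 0].mean(axis=0))
    member = np.zeros((n_permutations, n))
    order = np.argsort(rng.random((n_permutations, n)), axis=1)[:, :n1]
    rows = np.repeat(np.arange(n_permutations), n1)
    member[rows, order.ravel()] = 1.0
    sum1 = member @ x  # (B, p)
    stat = np.abs(sum1 / n1 - (col_sums[None, :] - sum1) / (n - n1))
    extreme = (stat >= obs[None, :] - 1e-12).sum(axis=0)
    pvals = (1 + extreme) / (n_permutations + 1)
    pmap = {name: float(pv) for name, pv in zip(train.feature_names, pvals)}
    retained = [name for name in train.feature_names if pmap[name] < alpha]
    return retained, pmap


# ---------------------------------------------------------------------------
# Lasso candidate fitting


def _lasso_alpha_grid(x: np.ndarray, y: np.ndarray, n_alphas: int = 100, decades: float = 4.0):
    resid = y - y.mean()
    alpha_max = np.max(np.abs(x.T @ resid)) / len(y)
    alpha_max = max(alpha_max, 1e-12)
    return np.logspace(np.log10(alpha_max), np.log10(alpha_max) - decades, n_alphas)


def fit_lasso_cv(
    train: FeatureTable,
    cv_folds: int = 10,
    seed: int = 0,
    params: StandardizationParams | None = None,
) -> FittedLinearScorer:
    """Lasso on the binary label with the penalty minimising CV mean squared
    error over a 4-decade descending log grid (100 points).

    ``train`` must already be standardized; ``params`` records the training
    standardization so the scorer can be applied to raw tables later.
    """
    if len(train.feature_names) < 2:
        raise ValueError("need at least 2 features")
    if train.n_samples < cv_folds:
        raise ValueError("fewer samples than CV folds")
    x = train.matrix
    y = train.labels.astype(float)
    alphas = _lasso_alpha_grid(x, y)
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed % (2**31))
    # warm-started coordinate-descent path per fold (one validation pass per
    # fold rather than per alpha keeps the 7000-candidate loop tractable);
    # check_input=False needs Fortran-ordered float64 inputs
    sq_err = np.zeros(len(alphas))
    for tr_idx, va_idx in cv.split(x):
        x_tr = x[tr_idx]
        y_tr = y[tr_idx]
        x_va, y_va = x[va_idx], y[va_idx]
        # lasso_path fits no intercept: centre within the fold, recover the
        # intercept per alpha from the fold means
        x_mean, y_mean = x_tr.mean(axis=0), y_tr.mean()
        xc = np.asfortranarray(x_tr - x_mean, dtype=np.float64)
        yc = np.ascontiguousarray(y_tr - y_mean, dtype=np.float64)
        _, coefs, _ = lasso_path(xc, yc, alphas=alphas, max_iter=5000,
                                 tol=1e-4, check_input=False)
        intercepts = y_mean - x_mean @ coefs
        pred = x_va @ coefs + intercepts[None, :]
        sq_err += ((y_va[:, None] - pred) ** 2).sum(axis=0)
    best_alpha = alphas[int(np.argmin(sq_err))]
    model = Lasso(alpha=best_alpha, max_iter=5000, tol=1e-4)
    model.fit(x, y)
    nz = np.flatnonzero(model.coef_)
    names = [train.feature_names[j] for j in nz]
    if params is None:
        params = StandardizationParams(
            pd.Series(0.0, index=train.feature_names), pd.Series(1.0, index=train.feature_names)
        )
    sub = StandardizationParams(params.mean[train.feature_names][names],
                                params.sd[train.feature_names][names])
    return FittedLinearScorer(names, model.coef_[nz], float(model.intercept_), sub, "lasso")


def compute_rs(scorer: FittedLinearScorer, table: FeatureTable) -> np.ndarray:
    """RS_i = sum_j value_ij * coef_j + intercept over the scorer's features.

    ``table`` is expected on the scorer's training standardization scale.
    """
    missing = [n for n in scorer.feature_names if n not in table.values.columns]
    if missing:
        raise KeyError(f"table lacks scorer features: {missing}")
    if not scorer.feature_names:
        return np.full(table.n_samples, scorer.intercept)
    x = table.values[scorer.feature_names].to_numpy(float)
    return x @ scorer.coefficients + scorer.intercept


def score_raw(scorer: FittedLinearScorer, table: FeatureTable) -> np.ndarray:
    """Standardize ``table`` with the scorer's stored training parameters,
    then compute RS."""
    std = scorer.standardization.transform(table.values[scorer.feature_names])
    return std.to_numpy(float) @ scorer.coefficients + scorer.intercept


# ---------------------------------------------------------------------------
# acceptance & the loop


def accept_candidate(
    scorer: FittedLinearScorer,
    train: FeatureTable,
    test: FeatureTable,
    config: SelectionConfig,
    rng,
    iteration: int = 0,
    ratio: float = float("nan"),
) -> IterationRecord:
    """Dual acceptance gate on a fitted candidate.

    Accepted iff the train/test ROC curves show no difference
    (unpaired DeLong p > ``delong_alpha``) *and* the test-set RS separates
    the label groups (permutation p < ``rs_perm_alpha``). Degenerate
    candidates (no selected features, constant RS) are auto-rejected.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    nan = float("nan")
    if not scorer.feature_names:
        return IterationRecord(iteration, ratio, [], nan, nan, nan, False, "no features selected")
    rs_train = compute_rs(scorer, train)
    rs_test = compute_rs(scorer, test)
    if np.ptp(rs_train) == 0 or np.ptp(rs_test) == 0:
        return IterationRecord(iteration, ratio, list(scorer.feature_names),
                               nan, nan, nan, False, "degenerate constant RS")
    _, delong_p = delong_compare(rs_train, train.labels, rs_test, test.labels, paired=False)
    train_p = permutation_test_scores(rs_train, train.labels, config.n_permutations, rng)
    test_p = permutation_test_scores(rs_test, test.labels, config.n_permutations, rng)
    accepted = (delong_p > config.delong_alpha) and (test_p < config.rs_perm_alpha)
    return IterationRecord(iteration, ratio, list(scorer.feature_names),
                           float(delong_p), float(train_p), float(test_p), accepted)


def _candidate(table, ratio, config, rng, iteration) -> IterationRecord:
    train, test = split_cohort(table, ratio, rng)
    nonzero = drop_zero_variance(train)
    train_nz = train.subset_features(nonzero)
    (train_std, test_std), params = standardize(train_nz, test.subset_features(nonzero))

    screen_cache: dict[str, float] = {}

    def priority(name: str) -> float:
        # on-demand permutation-screen p for redundancy tie-breaking
        if not screen_cache:
            _, pmap = permutation_screen(
                train_std, config.screen_alpha, min(config.n_permutations, 999), rng
            )
            screen_cache.update(pmap)
        return screen_cache.get(name, 1.0)

    retained, _ = redundancy_filter(
        train_std, config.redundancy_r, config.redundancy_alpha,
        priority=priority, normality_alpha=config.normality_alpha,
    )
    train_red = train_std.subset_features(retained)
    screened, _ = permutation_screen(train_red, config.screen_alpha, config.n_permutations, rng)
    if len(screened) < 2:
        return IterationRecord(iteration, ratio, [], float("nan"), float("nan"),
                               float("nan"), False, "fewer than 2 features after screening")
    sub_params = StandardizationParams(params.mean[screened], params.sd[screened])
    scorer = fit_lasso_cv(
        train_std.subset_features(screened), config.cv_folds,
        seed=int(rng.integers(2**31)), params=sub_params,
    )
    return accept_candidate(scorer, train_std, test_std, config, rng, iteration, ratio)


def run_iterations(table: FeatureTable, config: SelectionConfig) -> SelectionResult:
    """The full selection loop: every iteration visits every split ratio.

    Each (iteration, ratio) candidate runs on its own RNG substream derived
    from the master seed, so any single candidate is reproducible in
    isolation. Stage failures are logged as rejected candidates; the loop
    never aborts.
    """
    config.validate()
    counts: dict[str, int] = {name: 0 for name in table.feature_names}
    records: list[IterationRecord] = []
    for it in range(config.n_iterations):
        for ri, ratio in enumerate(config.split_ratios):
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, it, ri]))
            try:
                rec = _candidate(table, ratio, config, rng, it)
            except Exception as exc:  # noqa: BLE001 -- stage errors logged, loop continues
                rec = IterationRecord(it, ratio, [], float("nan"), float("nan"),
                                      float("nan"), False, f"stage error: {exc}")
            records.append(rec)
            if rec.accepted:
                for name in rec.selected_feature_names:
                    counts[name] = counts.get(name, 0) + 1
    return SelectionResult(counts, records, config.n_iterations * len(config.split_ratios), config)


def select_robust_features(result: SelectionResult, min_count: int = 100) -> list[str]:
    """Features counted *strictly more* than ``min_count`` times, ordered by
    descending count then name."""
    chosen = [(c, n) for n, c in result.counts.items() if c > min_count]
    chosen.sort(key=lambda t: (-t[0], t[1]))
    return [n for _, n in chosen]
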