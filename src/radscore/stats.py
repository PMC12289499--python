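"""Statistical evaluation primitives for score-based binary classifiers.

Implements the inference toolkit used throughout the pipeline: DeLong AUC
variance and AUC comparison, Monte-Carlo permutation tests on scores,
Youden-index operating points, confusion-matrix metric suites,
Hosmer-Lemeshow goodness of fit, calibration binning and decision-curve
net benefit.

Conventions
-----------
Labels are binary with 1 = positive class (lesional, CT-negative dominant
adrenal) and 0 = negative class. Higher scores indicate the positive class.
AUC uses the Mann-Whitney kernel with ties counted 1/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "ROCCurve",
    "OperatingPoint",
    "PerformanceReport",
    "DCACurve",
    "auc_delong",
    "delong_compare",
    "permutation_test_scores",
    "youden_cutoff",
    "confusion_metrics",
    "hosmer_lemeshow",
    "calibration_bins",
    "decision_curve",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class ROCCurve:
    """Empirical ROC curve with DeLong variance of the AUC."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_variance: float
    n_pos: int
    n_neg: int

    @property
    def ci95(self) -> tuple[float, float]:
        se = math.sqrt(max(self.auc_variance, 0.0))
        return (max(0.0, self.auc - 1.96 * se), min(1.0, self.auc + 1.96 * se))


@dataclass
class OperatingPoint:
    cutoff: float
    sensitivity: float
    specificity: float
    degenerate: bool = False

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


@dataclass
class PerformanceReport:
    """Classification metric suite at a stated cutoff.

    Rates with zero denominators are ``nan`` (reported as undefined,
    never silently coerced to 0).
    """

    auc: float = float("nan")
    auc_ci: tuple[float, float] = (float("nan"), float("nan"))
    cutoff: float = float("nan")
    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    accuracy: float = float("nan")
    error_rate: float = float("nan")
    recall: float = float("nan")
    f1: float = float("nan")
    kappa: float = float("nan")
    ppv: float = float("nan")
    npv: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci_low": self.auc_ci[0],
            "auc_ci_high": self.auc_ci[1],
            "cutoff": self.cutoff,
            "tp": self.tp,
            "fn": self.fn,
            "fp": self.fp,
            "tn": self.tn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "error_rate": self.error_rate,
            "recall": self.recall,
            "f1": self.f1,
            "kappa": self.kappa,
            "ppv": self.ppv,
            "npv": self.npv,
        }


@dataclass
class DCACurve:
    """Decision-curve analysis: net benefit across threshold probabilities."""

    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.treat_none is None:
            self.treat_none = np.zeros_like(np.asarray(self.thresholds, float))


# ---------------------------------------------------------------------------
# DeLong machinery


def _validate_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    uniq = set(np.unique(labels).tolist())
    if not uniq <= {0, 1}:
        raise ValueError(f"labels must be binary 0/1, got {sorted(uniq)}")
    if len(uniq) < 2:
        raise ValueError("both classes must be present")
    return scores, labels.astype(int)


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Structural components V10 (per positive) and V01 (per negative).

    AUC equals the mean of either component vector; the variance estimate
    is var(V10)/m + var(V01)/n with sample variances.
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return v10, v01


def auc_delong(scores, labels) -> tuple[float, float, tuple[float, float]]:
    """AUC via the Mann-Whitney statistic with DeLong variance and 95% CI.

    Ties between a positive and a negative score contribute 1/2. The CI is
    the normal approximation AUC +/- 1.96*SE truncated to [0, 1].
    """
    scores, labels = _validate_scores_labels(scores, labels)
    v10, v01 = _delong_components(scores, labels)
    auc = float(v10.mean())
    m, n = len(v10), len(v01)
    var = 0.0
    if m > 1:
        var += float(np.var(v10, ddof=1)) / m
    if n > 1:
        var += float(np.var(v01, ddof=1)) / n
    se = math.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))
    return auc, var, ci


def roc_curve_points(scores, labels) -> ROCCurve:
    """Full empirical ROC curve (thresholds are the unique scores, descending)."""
    scores, labels = _validate_scores_labels(scores, labels)
    thr = np.unique(scores)[::-1]
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    sens = np.array([(scores[pos] >= t).mean() for t in thr])
    spec = np.array([(scores[~pos] < t).mean() for t in thr])
    auc, var, _ = auc_delong(scores, labels)
    return ROCCurve(thr, sens, spec, auc, var, n_pos, n_neg)


def delong_compare(
    scores_a, labels_a, scores_b=None, labels_b=None, *, paired: bool = False
) -> tuple[float, float]:
    """Two-sided DeLong comparison of two AUCs, returning (Z, p).

    ``paired=True`` compares two score vectors over the *same* samples
    (labels must match element-wise); the covariance of the structural
    components enters the variance. ``paired=False`` treats the two
    (scores, labels) pairs as independent — the appropriate variant for
    comparing a training-set ROC with a disjoint test-set ROC.
    """
    scores_a, labels_a = _validate_scores_labels(scores_a, labels_a)
    scores_b, labels_b = _validate_scores_labels(scores_b, labels_b)
    if paired:
        if len(scores_a) != len(scores_b) or not np.array_equal(labels_a, labels_b):
            raise ValueError("paired comparison requires identical samples and labels")
        v10a, v01a = _delong_components(scores_a, labels_a)
        v10b, v01b = _delong_components(scores_b, labels_b)
        auc_a, auc_b = v10a.mean(), v10b.mean()
        m, n = len(v10a), len(v01a)
        s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
        s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
        s = s10 / m + s01 / n
        var = s[0, 0] + s[1, 1] - 2 * s[0, 1]
    else:
        auc_a, var_a, _ = auc_delong(scores_a, labels_a)
        auc_b, var_b, _ = auc_delong(scores_b, labels_b)
        var = var_a + var_b
    diff = float(auc_a - auc_b)
    if var <= 0:
        # degenerate curves (e.g. perfect separation on both sides)
        z = 0.0 if diff == 0 else math.copysign(float("inf"), diff)
        p = 1.0 if diff == 0 else 0.0
        return z, p
    z = diff / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


# ---------------------------------------------------------------------------
# permutation test


def permutation_test_scores(values, labels, n_permutations: int, rng) -> float:
    """Monte-Carlo two-sample permutation test on the absolute mean difference.

    Returns the add-one corrected p-value ``(1 + #extreme) / (B + 1)``;
    consequently p is in [1/(B+1), 1].
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    values, labels = _validate_scores_labels(values, labels)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = len(values)
    n1 = int(labels.sum())
    observed = abs(values[labels == 1].mean() - values[labels == 0].mean())
    total = values.sum()
    # vectorised: each permutation draws n1 indices without replacement
    perm = np.argsort(rng.random((n_permutations, n)), axis=1)[:, :n1]
    sum1 = values[perm].sum(axis=1)
    stat = np.abs(sum1 / n1 - (total - sum1) / (n - n1))
    extreme = int((stat >= observed - 1e-12).sum())
    return (1 + extreme) / (n_permutations + 1)


# ---------------------------------------------------------------------------
# operating points & confusion metrics


def youden_cutoff(scores, labels) -> OperatingPoint:
    """Cutoff maximising Youden's J = sensitivity + specificity - 1.

    Candidate cutoffs are the midpoints of adjacent sorted unique scores
    (plus outer sentinels); a sample is called positive when its score is
    >= the cutoff. Ties in J are broken toward the higher-specificity
    operating point (a deliberate bias toward fewer false positives).
    Constant scores yield a degenerate point with J = 0.
    """
    scores, labels = _validate_scores_labels(scores, labels)
    uniq = np.unique(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(uniq) == 1:
        return OperatingPoint(float(uniq[0]), 1.0, 0.0, degenerate=True)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cands = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    best = None
    for c in cands:
        sens = float((pos >= c).mean())
        spec = float((neg < c).mean())
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and spec > best[2]):
            best = (j, sens, spec, float(c))
    _, sens, spec, cut = best
    return OperatingPoint(cut, sens, spec)


def confusion_metrics(tp: int, fn: int, fp: int, tn: int) -> PerformanceReport:
    """Metric suite from confusion counts; zero-denominator rates are nan.

    kappa uses the marginal chance-agreement formula; for balanced true
    classes it reduces to 2*accuracy - 1.
    """
    for v in (tp, fn, fp, tn):
        if v < 0 or v != int(v):
            raise ValueError("confusion counts must be non-negative integers")
    n = tp + fn + fp + tn
    if n == 0:
        raise ValueError("empty confusion matrix")

    def _ratio(num, den):
        return num / den if den > 0 else float("nan")

    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    acc = (tp + tn) / n
    ppv = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    f1 = _ratio(2 * ppv * sens, ppv + sens) if not (math.isnan(ppv) or math.isnan(sens)) else float("nan")
    p_o = acc
    p_e = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / (n * n)
    kappa = _ratio(p_o - p_e, 1 - p_e) if p_e < 1 else float("nan")
    return PerformanceReport(
        tp=tp, fn=fn, fp=fp, tn=tn,
        sensitivity=sens, specificity=spec, accuracy=acc, error_rate=1 - acc,
        recall=sens, f1=f1, kappa=kappa, ppv=ppv, npv=npv,
    )


def report_at_cutoff(scores, labels, cutoff: float) -> PerformanceReport:
    """Full PerformanceReport (AUC + confusion suite) at a given cutoff."""
    scores, labels = _validate_scores_labels(scores, labels)
    pred = scores >= cutoff
    pos = labels == 1
    rep = confusion_metrics(
        int((pred & pos).sum()), int((~pred & pos).sum()),
        int((pred & ~pos).sum()), int((~pred & ~pos).sum()),
    )
    auc, _, ci = auc_delong(scores, labels)
    rep.auc = auc
    rep.auc_ci = ci
    rep.cutoff = float(cutoff)
    return rep


# ---------------------------------------------------------------------------
# goodness of fit, calibration, decision curves


def hosmer_lemeshow(probabilities, outcomes, g: int = 10) -> tuple[float, int, float]:
    """Hosmer-Lemeshow chi-square over g equal-frequency risk groups.

    Statistic = sum over groups of (O - E)^2 / (E (1 - E/n_g)), df = g - 2.
    Groups that tie on predicted probability are merged (with the reported
    ``g`` reduced accordingly).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.ndim != 1 or p.shape != y.shape:
        raise ValueError("probabilities and outcomes must be 1-D of equal length")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    if g < 3:
        raise ValueError("need at least 3 groups")
    n = len(p)
    if n < g:
        raise ValueError("fewer observations than groups")
    order = np.argsort(p, kind="mergesort")
    p, y = p[order], y[order]
    # equal-frequency bin edges; keep tied probabilities together
    edges = [int(round(i * n / g)) for i in range(g + 1)]
    groups = []
    start = 0
    for e in edges[1:]:
        e = max(e, start + 1) if start < n else e
        # extend to keep ties together
        while e < n and p[e - 1] == p[e]:
            e += 1
        if e > start:
            groups.append((start, min(e, n)))
            start = min(e, n)
        if start >= n:
            break
    groups = [(a, b) for a, b in groups if b > a]
    stat = 0.0
    for a, b in groups:
        ng = b - a
        obs = y[a:b].sum()
        exp = p[a:b].sum()
        denom = exp * (1 - exp / ng)
        if denom <= 0:
            continue
        stat += (obs - exp) ** 2 / denom
    df = len(groups) - 2
    if df < 1:
        return float(stat), df, float("nan")
    pval = float(sps.chi2.sf(stat, df))
    return float(stat), df, pval


def calibration_bins(probabilities, outcomes, n_bins: int = 10):
    """Per-bin (mean predicted, observed rate, count) over equal-frequency bins."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    n = len(p)
    if n < n_bins:
        raise ValueError("fewer observations than bins")
    order = np.argsort(p, kind="mergesort")
    p, y = p[order], y[order]
    edges = [int(round(i * n / n_bins)) for i in range(n_bins + 1)]
    out = []
    for a, b in zip(edges[:-1], edges[1:]):
        if b > a:
            out.append((float(p[a:b].mean()), float(y[a:b].mean()), b - a))
    return out


def decision_curve(probabilities, outcomes, thresholds=None) -> DCACurve:
    """Net benefit NB(t) = TP(t)/n - FP(t)/n * t/(1-t), prediction = p >= t.

    Includes treat-all (prevalence - (1-prevalence) t/(1-t)) and treat-none
    (identically zero) reference policies.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    t = np.asarray(thresholds, dtype=float)
    if np.any((t <= 0) | (t >= 1)):
        raise ValueError("thresholds must lie strictly in (0, 1)")
    n = len(p)
    prev = y.mean()
    nb = np.empty_like(t)
    for i, ti in enumerate(t):
        pred = p >= ti
        tp = (pred & (y == 1)).sum() / n
        fp = (pred & (y == 0)).sum() / n
        nb[i] = tp - fp * ti / (1 - ti)
    treat_all = prev - (1 - prev) * t / (1 - t)
    return DCACurve(t, nb, treat_all)
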