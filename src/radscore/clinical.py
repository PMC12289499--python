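"""Clinical covariate screening and the Clinical-Radiomic Score.

Covariates are first screened for group differences with a test matched to
their type and distribution (chi-square/Fisher for categorical, t-test for
continuous variables normal in both groups, Mann-Whitney otherwise).
Flagged covariates plus the Radiomics Score then enter a staged logistic
procedure: a univariate round drops candidates with p >= alpha, and
multivariate rounds iterate (fit, drop non-significant, refit) until every
remaining term is significant. The surviving terms and RS are fused in one
maximum-likelihood logistic model whose fitted probability is the
Clinical-Radiomic Score; the model exports a tabular nomogram.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.special import expit

from .io import ClinicalTable
from .stats import youden_cutoff

log = logging.getLogger(__name__)

__all__ = [
    "ScreeningReport",
    "ClinRadModel",
    "screen_clinical",
    "staged_logistic_selection",
    "fit_clin_rad",
    "export_nomogram",
]


@dataclass
class ScreeningReport:
    tests: dict[str, str]
    p_values: dict[str, float]
    flagged: dict[str, bool]
    notes: dict[str, str] = field(default_factory=dict)

    @property
    def flagged_variables(self) -> list[str]:
        return [v for v, f in self.flagged.items() if f]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variable": list(self.tests),
            "test": [self.tests[v] for v in self.tests],
            "p": [self.p_values[v] for v in self.tests],
            "flagged": [self.flagged[v] for v in self.tests],
        })


def screen_clinical(table: ClinicalTable, alpha: float = 0.05,
                    normality_alpha: float = 0.05) -> ScreeningReport:
    """Two-group screening of every clinical covariate.

    Categorical variables use chi-square, downgraded to Fisher's exact test
    (2x2 only) when any expected cell is below 5. Continuous variables use
    the two-sample t-test when Shapiro-Wilk accepts normality in both
    groups, Mann-Whitney U otherwise. Constant variables are reported
    unflagged with a note.
    """
    y = table.labels
    tests, pvals, flagged, notes = {}, {}, {}, {}
    for var in table.variables:
        col = table.data[var]
        if col.isna().any():
            raise ValueError(f"variable {var!r} has missing values; impute first")
        g1 = col[y == 1]
        g0 = col[y == 0]
        if col.nunique() < 2:
            tests[var], pvals[var], flagged[var] = "none", float("nan"), False
            notes[var] = "constant variable"
            continue
        if table.variable_types[var] == "categorical":
            ct = pd.crosstab(col, y)
            expected = sps.contingency.expected_freq(ct.to_numpy())
            if (expected < 5).any() and ct.shape == (2, 2):
                _, p = sps.fisher_exact(ct.to_numpy())
                tests[var] = "fisher"
                log.info("Fisher's exact used for %s (small expected cell)", var)
            else:
                _, p, _, _ = sps.chi2_contingency(ct.to_numpy())
                tests[var] = "chi-square"
        else:
            a1 = g1.to_numpy(float)
            a0 = g0.to_numpy(float)
            normal = (
                len(np.unique(a1)) >= 3 and len(np.unique(a0)) >= 3
                and sps.shapiro(a1).pvalue >= normality_alpha
                and sps.shapiro(a0).pvalue >= normality_alpha
            )
            if normal:
                _, p = sps.ttest_ind(a1, a0)
                tests[var] = "t"
            else:
                _, p = sps.mannwhitneyu(a1, a0, alternative="two-sided")
                tests[var] = "mann-whitney"
        pvals[var] = float(p)
        flagged[var] = bool(p < alpha)
    return ScreeningReport(tests, pvals, flagged, notes)


# ---------------------------------------------------------------------------
# logistic fitting (ML with a weak-ridge fallback for separation)


def _ridge_irls(xm: np.ndarray, y: np.ndarray, ridge: float = 1e-4) -> np.ndarray:
    """IRLS for logistic regression with a weak ridge penalty (separation-safe)."""
    beta = np.zeros(xm.shape[1])
    for _ in range(200):
        mu = expit(xm @ beta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        h = xm.T @ (xm * w[:, None]) + ridge * np.eye(xm.shape[1])
        grad = xm.T @ (y - mu) - ridge * beta
        step = np.linalg.solve(h, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    return beta


def _log_likelihood(xm: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = xm @ beta
    mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    return float((y * np.log(mu) + (1 - y) * np.log(1 - mu)).sum())


def _fit_ll(x: pd.DataFrame, y: np.ndarray):
    """Fit one logistic model: (params incl 'const', log-likelihood).

    Plain maximum likelihood via statsmodels where it is stable; on
    separation or non-convergence a weak-ridge IRLS fit stands in (logged),
    with the unpenalized likelihood evaluated at the penalized estimate.
    """
    design = sm.add_constant(x.astype(float), has_constant="add")
    xm = design.to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
            if res.mle_retvals.get("converged", False) and np.all(np.isfinite(res.params)) \
                    and np.max(np.abs(res.params)) < 50:
                return res.params, float(res.llf)
        except Exception:  # noqa: BLE001 -- fall through to the penalized fit
            pass
    log.warning("logistic ML fit unstable (separation?); using weak ridge fallback")
    beta = _ridge_irls(xm, y)
    return pd.Series(beta, index=design.columns), _log_likelihood(xm, y, beta)


def _logit_fit(x: pd.DataFrame, y: np.ndarray):
    """Fit a logistic model, returning (params, per-term p-values).

    P-values are likelihood-ratio tests (full vs the model without the
    term). Wald p-values lose power when a strong score induces
    quasi-separation (the Hauck-Donner effect); the LR test keeps ranking
    terms sensibly in that regime.
    """
    params, ll_full = _fit_ll(x, y)
    pvals = {}
    ybar = y.mean()
    for col in x.columns:
        rest = [c for c in x.columns if c != col]
        if rest:
            _, ll_red = _fit_ll(x[rest], y)
        else:
            n = len(y)
            ll_red = n * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar))
        stat = max(2.0 * (ll_full - ll_red), 0.0)
        pvals[col] = float(sps.chi2.sf(stat, 1))
    pvals["const"] = float("nan")
    return params, pd.Series(pvals)


def staged_logistic_selection(
    table: ClinicalTable,
    candidates: list[str],
    rs_values: np.ndarray,
    alpha: float = 0.05,
    max_rounds: int = 20,
) -> list[str]:
    """Univariate-then-multivariate pruning of candidate predictors.

    ``candidates`` are clinical variable names; the Radiomics Score enters
    the candidate pool under the name ``"RS"``. Round (a): univariate
    logistic per candidate, dropping p >= alpha. Rounds (b...): multivariate
    logistic on survivors, dropping every term with p >= alpha and
    refitting, until all terms are significant or nothing remains.
    """
    y = table.labels.astype(float)
    frame = table.data.copy()
    frame["RS"] = np.asarray(rs_values, float)
    pool = list(dict.fromkeys(list(candidates) + ["RS"]))
    # univariate round
    survivors = []
    for var in pool:
        _, pv = _logit_fit(frame[[var]], y)
        if pv[var] < alpha:
            survivors.append(var)
    # multivariate rounds
    for _ in range(max_rounds):
        if not survivors:
            return []
        _, pv = _logit_fit(frame[survivors], y)
        bad = [v for v in survivors if pv[v] >= alpha]
        if not bad:
            return survivors
        survivors = [v for v in survivors if v not in bad]
    return survivors


@dataclass
class ClinRadModel:
    """Fused logistic model over retained clinical covariates and RS.

    ``predict`` returns the Clinical-Radiomic Score (fitted probability).
    ``cutoff_youden`` is the derivation-set Youden operating point;
    ``cutoff_adjusted`` is an optional manually chosen operating point
    (e.g. trading sensitivity for specificity).
    """

    variable_names: list[str]  # includes "RS"
    coefficients: np.ndarray
    intercept: float
    variable_ranges: dict[str, tuple[float, float]]
    cutoff_youden: float
    cutoff_adjusted: float | None = None

    @property
    def cutoff(self) -> float:
        return self.cutoff_adjusted if self.cutoff_adjusted is not None else self.cutoff_youden

    def linear_predictor(self, frame: pd.DataFrame) -> np.ndarray:
        x = frame[self.variable_names].to_numpy(float)
        return x @ self.coefficients + self.intercept

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(frame))

    def to_dict(self) -> dict:
        return {
            "variable_names": list(self.variable_names),
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "variable_ranges": {k: list(v) for k, v in self.variable_ranges.items()},
            "cutoff_youden": self.cutoff_youden,
            "cutoff_adjusted": self.cutoff_adjusted,
        }


def fit_clin_rad(
    table: ClinicalTable,
    retained: list[str],
    rs_values: np.ndarray,
    cutoff_adjusted: float | None = None,
) -> ClinRadModel:
    """Maximum-likelihood logistic fit of the retained terms (RS included)."""
    if not retained or "RS" not in retained:
        raise ValueError("retained set must be nonempty and include 'RS'")
    frame = table.data.copy()
    frame["RS"] = np.asarray(rs_values, float)
    params, _ = _logit_fit(frame[retained], table.labels.astype(float))
    coefs = params[retained].to_numpy(float)
    intercept = float(params["const"])
    probs = expit(frame[retained].to_numpy(float) @ coefs + intercept)
    op = youden_cutoff(probs, table.labels)
    ranges = {v: (float(frame[v].min()), float(frame[v].max())) for v in retained}
    return ClinRadModel(list(retained), coefs, intercept, ranges,
                        float(op.cutoff), cutoff_adjusted)


def export_nomogram(model: ClinRadModel, n_grid: int = 21) -> dict:
    """Tabular nomogram for the fused model.

    Per-variable point axes are linear in the variable:
    ``points_v(x) = 100 * beta_v * (x - ref_v) / S`` with
    ``S = max_w |beta_w| * range_w`` and the reference ``ref_v`` at the end
    of the variable's derivation-data range where its risk contribution is
    lowest (the minimum for positive coefficients, the maximum for negative
    ones), so points are non-negative and the variable with the largest
    risk swing spans 0-100. Total points map back to probability by
    inverting the logistic link exactly.
    """
    betas = model.coefficients
    ranges = [model.variable_ranges[v] for v in model.variable_names]
    swings = [abs(b) * (hi - lo) for b, (lo, hi) in zip(betas, ranges)]
    s = max(swings)
    if s <= 0:
        raise ValueError("all variables have zero range; nomogram undefined")
    axes = {}
    base = model.intercept
    for v, b, (lo, hi) in zip(model.variable_names, betas, ranges):
        if hi == lo:
            raise ValueError(f"variable {v!r} has zero range")
        ref = lo if b >= 0 else hi
        grid = np.linspace(lo, hi, n_grid)
        pts = 100.0 * b * (grid - ref) / s
        axes[v] = pd.DataFrame({"value": grid, "points": pts})
        base += b * ref
    max_total = sum(100.0 * abs(b) * (hi - lo) / s for b, (lo, hi) in zip(betas, ranges))
    total = np.linspace(0.0, max_total, 200)
    prob = expit(base + total * s / 100.0)
    return {
        "axes": axes,
        "scale": s,
        "baseline_eta": base,
        "total_points_to_probability": pd.DataFrame({"total_points": total, "probability": prob}),
    }


def points_from_values(nomogram: dict, model: ClinRadModel, frame: pd.DataFrame) -> np.ndarray:
    """Total points for each sample under an exported nomogram."""
    s = nomogram["scale"]
    total = np.zeros(len(frame))
    for v, b in zip(model.variable_names, model.coefficients):
        lo, hi = model.variable_ranges[v]
        ref = lo if b >= 0 else hi
        total += 100.0 * b * (frame[v].to_numpy(float) - ref) / s
    return total


def probability_from_points(nomogram: dict, total_points: np.ndarray) -> np.ndarray:
    """Exact inversion of the nomogram's total-points axis."""
    return expit(nomogram["baseline_eta"] + np.asarray(total_points, float) * nomogram["scale"] / 100.0)
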