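"""Core table types, CSV readers/writers, reproducibility (ICC) filtering,
standardization and clinical imputation.

A :class:`FeatureTable` is the pipeline's central container: one row per
adrenal sample, one column per radiomic feature, plus a binary label
(1 = lesional CT-negative adrenal confirmed dominant by adrenal venous
sampling, 0 = CT-negative non-dominant side). Feature names carry a class
prefix (``shape_``, ``firstorder_``, ``glcm_``, ``glrlm_``, ``glszm_``,
``gldm_``, ``ngtdm_``) mimicking standard radiomics naming.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FEATURE_CLASSES",
    "CLINICAL_VARIABLES",
    "FeatureTable",
    "ClinicalTable",
    "ReproducibilityReport",
    "StandardizationParams",
    "FormatError",
    "load_feature_table",
    "save_feature_table",
    "load_clinical_table",
    "save_clinical_table",
    "icc_2_1",
    "icc_filter",
    "standardize",
    "impute_clinical",
]

#: the seven standard radiomic feature classes
FEATURE_CLASSES = ("shape", "firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm")

#: the 24 clinical covariates collected per patient (field abbreviations)
CLINICAL_VARIABLES = (
    "Age", "Gender", "Height", "Weight", "BMI", "SBP", "DBP", "HTN Duration",
    "Aldo-max", "Renin", "K+(Min.)", "Echo-IVSd", "Echo-LVEF", "RF-UA", "RF-Cr",
    "RF-EGFR", "U-MA/Cr", "U-K 24h", "U-K", "BL-TC", "BL-TG", "BL-LDL", "BL-HDL",
    "24h AE(Max.)",
)


class FormatError(ValueError):
    """Raised when a table file violates the declared schema."""


def _class_of(name: str) -> str:
    head = name.split("_", 1)[0]
    return head if head in FEATURE_CLASSES else "other"


@dataclass
class FeatureTable:
    """Samples x features matrix with binary labels and feature-class tags."""

    sample_ids: list[str]
    labels: np.ndarray
    values: pd.DataFrame  # index = sample_ids, columns = feature names
    feature_classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise FormatError("duplicate sample IDs")
        if len(self.values.columns) != len(set(self.values.columns)):
            raise FormatError("duplicate feature names")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise FormatError("labels must be 0/1")
        if self.values.shape[0] != len(self.sample_ids) or len(self.labels) != len(self.sample_ids):
            raise FormatError("inconsistent dimensions")
        if not self.feature_classes:
            self.feature_classes = {c: _class_of(c) for c in self.values.columns}
        self.values.index = pd.Index(self.sample_ids)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def subset_features(self, names) -> "FeatureTable":
        missing = [n for n in names if n not in self.values.columns]
        if missing:
            raise KeyError(f"features not in table: {missing}")
        return FeatureTable(
            list(self.sample_ids), self.labels.copy(), self.values[list(names)].copy(),
            {n: self.feature_classes[n] for n in names},
        )

    def subset_samples(self, idx) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(
            [self.sample_ids[i] for i in idx], self.labels[idx],
            self.values.iloc[idx].copy(), dict(self.feature_classes),
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(list(self.sample_ids), self.labels.copy(),
                            self.values.copy(), dict(self.feature_classes))


@dataclass
class ClinicalTable:
    """Per-patient clinical covariates with declared variable types."""

    sample_ids: list[str]
    labels: np.ndarray
    data: pd.DataFrame  # index = sample_ids, columns = variable names
    variable_types: dict[str, str] = field(default_factory=dict)  # continuous|categorical

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise FormatError("duplicate sample IDs")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise FormatError("labels must be 0/1")
        if not self.variable_types:
            self.variable_types = {
                c: ("categorical" if c == "Gender" else "continuous") for c in self.data.columns
            }
        for c in self.data.columns:
            if c not in self.variable_types:
                raise FormatError(f"variable {c!r} has no declared type")
        self.data.index = pd.Index(self.sample_ids)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def copy(self) -> "ClinicalTable":
        return ClinicalTable(list(self.sample_ids), self.labels.copy(),
                             self.data.copy(), dict(self.variable_types))


@dataclass
class ReproducibilityReport:
    """Per-feature ICC estimates and the retain/drop decision."""

    icc: dict[str, float]
    retained: dict[str, bool]
    icc_form: str
    threshold: float

    def to_frame(self, classes: dict[str, str] | None = None) -> pd.DataFrame:
        rows = []
        for name, v in self.icc.items():
            rows.append({
                "feature": name,
                "class": (classes or {}).get(name, _class_of(name)),
                "icc": v,
                "retained": self.retained[name],
            })
        return pd.DataFrame(rows)


@dataclass
class StandardizationParams:
    """Training-set means and sample standard deviations (n-1 denominator)."""

    mean: pd.Series
    sd: pd.Series

    def transform(self, values: pd.DataFrame) -> pd.DataFrame:
        return (values[self.mean.index] - self.mean) / self.sd

    def inverse(self, standardized: pd.DataFrame) -> pd.DataFrame:
        return standardized * self.sd + self.mean


# ---------------------------------------------------------------------------
# CSV I/O


def save_feature_table(table: FeatureTable, path) -> str:
    df = table.values.copy()
    df.insert(0, "label", table.labels)
    df.insert(0, "sample_id", table.sample_ids)
    df.to_csv(path, index=False, float_format="%.17g")
    return str(path)


def load_feature_table(path) -> FeatureTable:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("sample_id", "label"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    labels = df["label"]
    bad = labels[~labels.isin([0, 1])]
    if len(bad):
        raise FormatError(f"non-binary label {bad.iloc[0]!r} at row {bad.index[0]}")
    ids = df["sample_id"].astype(str).tolist()
    if len(ids) != len(set(ids)):
        dup = pd.Series(ids)[pd.Series(ids).duplicated()].iloc[0]
        raise FormatError(f"duplicate sample ID {dup!r}")
    vals = df.drop(columns=["sample_id", "label"])
    if vals.isna().any().any():
        col = vals.columns[vals.isna().any()][0]
        raise FormatError(f"missing value in feature column {col!r}")
    return FeatureTable(ids, labels.to_numpy(int), vals.astype(float))


def save_clinical_table(table: ClinicalTable, path) -> str:
    df = table.data.copy()
    df.insert(0, "label", table.labels)
    df.insert(0, "sample_id", table.sample_ids)
    df.to_csv(path, index=False, float_format="%.17g")
    return str(path)


def load_clinical_table(path, variable_types: dict[str, str] | None = None) -> ClinicalTable:
    df = pd.read_csv(path)
    for col in ("sample_id", "label"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    ids = df["sample_id"].astype(str).tolist()
    labels = df["label"].to_numpy(int)
    data = df.drop(columns=["sample_id", "label"])
    return ClinicalTable(ids, labels, data, variable_types or {})


# ---------------------------------------------------------------------------
# ICC filtering


def icc_2_1(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is subjects x raters. Closed form from the two-way ANOVA
    mean squares::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    x = np.asarray(ratings, dtype=float)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    sse = ((x - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 1.0 if msr == mse else 0.0
    return float((msr - mse) / denom)


def icc_filter(
    replicate_a: FeatureTable,
    replicate_b: FeatureTable,
    threshold: float = 0.75,
) -> tuple[list[str], ReproducibilityReport]:
    """Drop features whose two-delineation ICC(2,1) falls below ``threshold``.

    Features that are constant across subjects in both replicates carry no
    between-subject variance; their ICC is reported as 0 and they are
    dropped.
    """
    if replicate_a.sample_ids != replicate_b.sample_ids:
        raise ValueError("replicates must share sample IDs in the same order")
    if replicate_a.feature_names != replicate_b.feature_names:
        raise ValueError("replicates must share feature names")
    icc: dict[str, float] = {}
    retained: dict[str, bool] = {}
    for name in replicate_a.feature_names:
        a = replicate_a.values[name].to_numpy(float)
        b = replicate_b.values[name].to_numpy(float)
        if np.allclose(a, a[0]) and np.allclose(b, b[0]):
            val = 1.0 if np.allclose(a, b) else 0.0
        else:
            val = icc_2_1(np.column_stack([a, b]))
        icc[name] = val
        retained[name] = val >= threshold
    keep = [n for n in replicate_a.feature_names if retained[n]]
    return keep, ReproducibilityReport(icc, retained, "ICC(2,1)", threshold)


# ---------------------------------------------------------------------------
# standardization


def standardize(
    train: FeatureTable, *apply_to: FeatureTable
) -> tuple[list[FeatureTable], StandardizationParams]:
    """Z-score with training means/sds; the same parameters transform every
    ``apply_to`` table (never their own statistics)."""
    mean = train.values.mean()
    sd = train.values.std(ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(
            f"zero training-set variance in {list(zero.index)[:3]}; remove zero-variance features first"
        )
    params = StandardizationParams(mean, sd)
    out = []
    for t in (train, *apply_to):
        out.append(FeatureTable(list(t.sample_ids), t.labels.copy(),
                                params.transform(t.values), dict(t.feature_classes)))
    return out, params


# ---------------------------------------------------------------------------
# clinical imputation


def impute_clinical(table: ClinicalTable, *, alpha: float = 0.05,
                    max_missing: float = 0.5) -> ClinicalTable:
    """Fill missing clinical cells per the variable's distributional profile.

    Continuous variables whose observed values pass Shapiro-Wilk normality
    (p >= alpha) are mean-imputed; those that fail are median-imputed;
    categorical variables take the mode. Observed cells are never altered.
    """
    out = table.copy()
    for var in out.variables:
        col = out.data[var]
        n_missing = int(col.isna().sum())
        if n_missing == 0:
            continue
        if col.isna().all():
            raise ValueError(f"variable {var!r} entirely missing")
        if n_missing / len(col) >= max_missing:
            raise ValueError(f"variable {var!r} exceeds the missingness cap")
        observed = col.dropna()
        if out.variable_types[var] == "categorical":
            fill = observed.mode().iloc[0]
        else:
            vals = observed.to_numpy(float)
            if len(np.unique(vals)) < 3:
                normal = False
            else:
                normal = sps.shapiro(vals).pvalue >= alpha
            fill = float(vals.mean()) if normal else float(np.median(vals))
        out.data[var] = col.fillna(fill)
    return out
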