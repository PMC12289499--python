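"""Synthetic cohort generator.

Emulates the data the pipeline consumes without any patient download: a
derivation cohort of 120 adrenal samples (60 lesional / 60 non-dominant)
and a temporal validation cohort of 50 (25/25), each sample carrying 107
radiomic features in the seven standard classes, optional two-rater
replicate tables with controllable reliability, per-patient clinical
covariate tables with group differences planted in the seven variables the
screening stage is expected to flag, and small textured 3D phantoms for
the extraction front-end.

Feature values are drawn multivariate-normal within correlation blocks and
then passed through per-class monotone transforms so that some classes are
deliberately skewed (the selection stage branches on normality, and that
branch should be exercised). Informative features carry a location shift of
``d`` standard deviations between labels on the latent scale; because the
transforms are monotone, single-feature discrimination (AUC) is preserved.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CLINICAL_VARIABLES, ClinicalTable, FeatureTable

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "GroundTruth",
    "generate_feature_table",
    "generate_rater_replicates",
    "generate_clinical_table",
    "generate_phantom_volume",
    "inject_missingness",
]


class ConfigurationError(ValueError):
    """Inconsistent simulation configuration."""


DEFAULT_CLASS_COUNTS = {
    "shape": 14, "firstorder": 18, "glcm": 24, "glrlm": 16,
    "glszm": 16, "gldm": 14, "ngtdm": 5,
}

#: classes whose features are exponentiated to a log-normal (skewed) scale
SKEWED_CLASSES = frozenset({"glszm", "gldm", "ngtdm"})

#: signed standardized shifts (label 1 minus label 0) in the seven variables
#: the clinical screen should flag; signs follow the secretion physiology the
#: cohorts exhibit (non-dominant control side: higher aldosterone indices and
#: lower renin, potassium, triglycerides and uric acid).
DEFAULT_CLINICAL_EFFECTS = {
    "K+(Min.)": 0.8,
    "Echo-IVSd": -0.8,
    "RF-UA": 0.8,
    "24h AE(Max.)": -0.8,
    "Renin": 0.8,
    "Aldo-max": -0.8,
    "BL-TG": 0.8,
}


@dataclass
class SimulationConfig:
    n_derivation: int = 120
    n_validation: int = 50
    n_features: int = 107
    feature_class_counts: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    n_informative: int = 5
    effect_sizes: tuple = (1.2, 1.2, 1.2, 1.2, 1.2)
    informative_rho: float = 0.5
    n_redundant_pairs: int = 5
    redundant_rho: float = 0.95
    n_zero_variance: int = 2
    rater_noise_sd: float = 0.1
    clinical_effects: dict = field(default_factory=lambda: dict(DEFAULT_CLINICAL_EFFECTS))
    missing_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if sum(self.feature_class_counts.values()) != self.n_features:
            raise ConfigurationError("feature_class_counts must sum to n_features")
        if self.n_informative + 2 * self.n_redundant_pairs + self.n_zero_variance > self.n_features:
            raise ConfigurationError("planted feature roles exceed n_features")
        if len(self.effect_sizes) != self.n_informative:
            raise ConfigurationError("effect_sizes length must equal n_informative")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        unknown = set(self.clinical_effects) - set(CLINICAL_VARIABLES)
        if unknown:
            raise ConfigurationError(f"unknown clinical variables: {sorted(unknown)}")

    def cohort_size(self, cohort: str) -> int:
        if cohort == "derivation":
            return self.n_derivation
        if cohort == "validation":
            return self.n_validation
        raise ConfigurationError(f"unknown cohort {cohort!r}")


@dataclass
class GroundTruth:
    informative_feature_names: list[str]
    redundant_pair_names: list[tuple[str, str]]
    zero_variance_names: list[str]
    clinical_true_coefficients: dict[str, float]


def _feature_names(class_counts: dict) -> tuple[list[str], dict[str, str]]:
    names, classes = [], {}
    for cls, count in class_counts.items():
        for i in range(count):
            name = f"{cls}_feat{i + 1:02d}"
            names.append(name)
            classes[name] = cls
    return names, classes


def _cohort_rng(config: SimulationConfig, cohort: str, stream: str) -> np.random.Generator:
    # crc32 keyes the stream name deterministically across processes
    return np.random.default_rng(np.random.SeedSequence(
        [config.seed, zlib.crc32(stream.encode()) % (2**31), 0 if cohort == "derivation" else 1]
    ))


def generate_feature_table(
    config: SimulationConfig, cohort: str = "derivation"
) -> tuple[FeatureTable, GroundTruth]:
    """Draw one cohort's radiomic feature table plus its ground truth.

    Labels are balanced by construction. The latent draw is standard normal;
    informative columns receive their configured location shift for label-1
    samples, redundant pairs share a common factor at correlation
    ``redundant_rho``, zero-variance columns are constant, and skewed-class
    columns are exponentiated.
    """
    config.validate()
    n = config.cohort_size(cohort)
    rng = _cohort_rng(config, cohort, "features")
    names, classes = _feature_names(config.feature_class_counts)
    p = len(names)

    # role assignment is a deterministic function of the config seed only;
    # redundant pairs are drawn within one transform group (both members
    # skewed or both normal-scale) so the planted correlation survives the
    # per-class monotone transforms
    role_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    order = role_rng.permutation(p)
    k = 0
    zero_idx = order[k:k + config.n_zero_variance]; k += config.n_zero_variance
    rest = order[k:]
    normal_rest = np.array([j for j in rest if classes[names[j]] not in SKEWED_CLASSES], int)
    skewed_rest = np.array([j for j in rest if classes[names[j]] in SKEWED_CLASSES], int)
    pair_pool = normal_rest if len(normal_rest) >= 2 * config.n_redundant_pairs else skewed_rest
    pair_flat = pair_pool[: 2 * config.n_redundant_pairs]
    pair_idx = pair_flat.reshape(-1, 2)
    remaining = np.array([j for j in rest if j not in set(pair_flat.tolist())], int)
    info_idx = remaining[: config.n_informative]

    n1 = n // 2
    labels = np.array([1] * n1 + [0] * (n - n1))
    x = rng.standard_normal((n, p))

    rho = config.redundant_rho
    for a, b in pair_idx:
        x[:, b] = rho * x[:, a] + np.sqrt(1 - rho**2) * x[:, b]
    # informative features form an equicorrelated block (radiomic features
    # within a signal complex are strongly inter-correlated in practice);
    # unit marginal variance is preserved, so each feature's standalone
    # discrimination is still Phi(d / sqrt(2))
    r_info = config.informative_rho
    if len(info_idx) > 1 and r_info > 0:
        shared = rng.standard_normal(n)
        x[:, info_idx] = (np.sqrt(r_info) * shared[:, None]
                          + np.sqrt(1 - r_info) * x[:, info_idx])
    for j, d in zip(info_idx, config.effect_sizes):
        x[labels == 1, j] += d
    x[:, zero_idx] = 1.0

    for j, name in enumerate(names):
        if classes[name] in SKEWED_CLASSES and j not in set(zero_idx.tolist()):
            x[:, j] = np.exp(0.5 * x[:, j])

    prefix = "D" if cohort == "derivation" else "V"
    ids = [f"{prefix}{i + 1:04d}" for i in range(n)]
    table = FeatureTable(ids, labels, pd.DataFrame(x, columns=names), classes)
    truth = GroundTruth(
        informative_feature_names=[names[j] for j in info_idx],
        redundant_pair_names=[(names[a], names[b]) for a, b in pair_idx],
        zero_variance_names=[names[j] for j in zero_idx],
        clinical_true_coefficients=dict(config.clinical_effects),
    )
    return table, truth


def generate_rater_replicates(
    table: FeatureTable, rater_noise_sd, seed: int
) -> tuple[FeatureTable, FeatureTable]:
    """Two independent re-delineations of the same samples.

    Each replicate is the underlying table plus independent per-feature
    Gaussian noise, so a feature with between-subject variance s2 and noise
    variance e2 has expected ICC(2,1) of s2 / (s2 + e2). ``rater_noise_sd``
    is a scalar or a per-feature vector; zero noise makes the replicates
    identical (ICC = 1).
    """
    sd = np.broadcast_to(np.asarray(rater_noise_sd, float), (len(table.feature_names),)).copy()
    if np.any(sd < 0):
        raise ConfigurationError("rater noise sd must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(2):
        noise = rng.standard_normal(table.values.shape) * sd[None, :]
        out.append(FeatureTable(
            list(table.sample_ids), table.labels.copy(),
            table.values + noise, dict(table.feature_classes),
        ))
    return out[0], out[1]


# plausible synthetic marginals per clinical covariate:
# (distribution, location, scale) with "lognormal" parameters on the log scale.
CLINICAL_MARGINALS = {
    "Age": ("normal", 50.0, 11.0),
    "Gender": ("binary", 0.5, None),
    "Height": ("normal", 165.0, 8.0),
    "Weight": ("normal", 68.0, 12.0),
    "BMI": ("normal", 25.0, 3.5),
    "SBP": ("normal", 165.0, 20.0),
    "DBP": ("normal", 100.0, 13.0),
    "HTN Duration": ("lognormal", 4.0, 1.0),
    "Aldo-max": ("lognormal", 5.5, 0.5),
    "Renin": ("lognormal", 1.0, 0.9),
    "K+(Min.)": ("normal", 3.1, 0.45),
    "Echo-IVSd": ("normal", 10.5, 1.3),
    "Echo-LVEF": ("normal", 63.0, 5.0),
    "RF-UA": ("normal", 360.0, 80.0),
    "RF-Cr": ("normal", 70.0, 15.0),
    "RF-EGFR": ("normal", 95.0, 15.0),
    "U-MA/Cr": ("lognormal", 2.5, 1.0),
    "U-K 24h": ("normal", 45.0, 15.0),
    "U-K": ("normal", 30.0, 10.0),
    "BL-TC": ("normal", 4.6, 0.9),
    "BL-TG": ("lognormal", 0.3, 0.5),
    "BL-LDL": ("normal", 2.7, 0.8),
    "BL-HDL": ("normal", 1.2, 0.3),
    "24h AE(Max.)": ("lognormal", 2.8, 0.6),
}


def generate_clinical_table(config: SimulationConfig, cohort: str = "derivation") -> ClinicalTable:
    """Draw the 24-covariate clinical table for one cohort.

    Group differences appear only in ``config.clinical_effects``: a signed
    standardized shift applied on the latent (log for log-normal) scale to
    label-1 samples. All other covariates are exchangeable between groups.
    """
    config.validate()
    n = config.cohort_size(cohort)
    rng = _cohort_rng(config, cohort, "clinical")
    n1 = n // 2
    labels = np.array([1] * n1 + [0] * (n - n1))
    cols = {}
    for var in CLINICAL_VARIABLES:
        dist, loc, scale = CLINICAL_MARGINALS[var]
        shift = config.clinical_effects.get(var, 0.0)
        if dist == "binary":
            cols[var] = (rng.random(n) < loc).astype(int)
            continue
        z = rng.standard_normal(n) + shift * labels
        if dist == "normal":
            cols[var] = loc + scale * z
        else:  # lognormal
            cols[var] = np.exp(loc + scale * z)
    prefix = "D" if cohort == "derivation" else "V"
    ids = [f"{prefix}{i + 1:04d}" for i in range(n)]
    types = {v: ("categorical" if v == "Gender" else "continuous") for v in CLINICAL_VARIABLES}
    return ClinicalTable(ids, labels, pd.DataFrame(cols), types)


def generate_phantom_volume(
    shape: tuple[int, int, int] = (48, 48, 12),
    mask_spec: dict | None = None,
    spacing: tuple[float, float, float] = (1.0, 1.0, 5.0),
    seed: int = 0,
):
    """Textured 3D phantom image + ellipsoid mask as NIfTI-1 images.

    ``mask_spec`` holds ``center`` and ``semiaxes`` in millimetres (defaults
    centre the ellipsoid and fill ~60% of each axis). The foreground is a
    smoothed random texture on a gradient; the background is low-amplitude
    noise. Voxel spacing is recorded in the NIfTI header.
    """
    import nibabel as nib
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape)
    sp = np.asarray(spacing, float)
    extent = np.array(shape) * sp
    if mask_spec is None:
        mask_spec = {"center": tuple(extent / 2), "semiaxes": tuple(extent * 0.3)}
    center = np.asarray(mask_spec["center"], float)
    semi = np.asarray(mask_spec["semiaxes"], float)
    if np.any(center - semi < 0) or np.any(center + semi > extent):
        raise ValueError("mask ellipsoid does not fit inside the image")

    grid = np.indices(shape).astype(float)
    coords = (grid + 0.5) * sp.reshape(3, 1, 1, 1)  # voxel centres in mm
    dist2 = sum(((coords[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    mask = (dist2 <= 1.0).astype(np.uint8)
    if mask.sum() == 0:
        raise ValueError("empty mask")

    texture = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=1.5)
    gradient = coords[2] / extent[2]
    image = 40.0 + 5.0 * rng.standard_normal(shape)
    image[mask == 1] = 80.0 + 25.0 * texture[mask == 1] + 20.0 * gradient[mask == 1]

    affine = np.diag([sp[0], sp[1], sp[2], 1.0])
    img = nib.Nifti1Image(image.astype(np.float32), affine)
    msk = nib.Nifti1Image(mask, affine)
    img.header.set_zooms(tuple(sp))
    msk.header.set_zooms(tuple(sp))
    return img, msk


def inject_missingness(table: ClinicalTable, rate: float, seed: int) -> ClinicalTable:
    """Independently blank each covariate cell with probability ``rate``.

    Sample IDs and labels are never blanked.
    """
    if not 0 <= rate < 1:
        raise ConfigurationError("missing rate must lie in [0, 1)")
    out = table.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random(out.data.shape) < rate
    out.data = out.data.mask(mask)
    return out
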