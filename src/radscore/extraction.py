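"""Image + mask -> radiomic feature row.

A thin front-end over a pluggable feature engine. The engine contract is a
callable ``engine(image, mask, spacing, config) -> dict[str, float]``;
tests can inject a deterministic mock, and any external radiomics engine
can be adapted to the same contract. The built-in engine computes the
standard seven-class, 107-feature inventory directly: mesh-free shape
descriptors from the mask geometry, first-order statistics from the masked
intensities, and gray-level co-occurrence (GLCM), run-length (GLRLM),
size-zone (GLSZM), dependence (GLDM) and neighbourhood tone-difference
(NGTDM) statistics from a fixed-bin-width discretisation. The built-in
implementations follow the standard formula definitions in compact form
(GLCM offsets are the three axis-aligned directions, averaged) and are
deterministic; they are the package's own implementation, with feature
names matching the conventional inventory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import FEATURE_CLASSES, FeatureTable

__all__ = ["ExtractionConfig", "extract_features", "builtin_engine", "batch_extract",
           "FEATURE_INVENTORY"]

EPS = 1e-12

SHAPE_NAMES = [
    "Elongation", "Flatness", "LeastAxisLength", "MajorAxisLength",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "Maximum2DDiameterSlice",
    "Maximum3DDiameter", "MeshVolume", "MinorAxisLength", "Sphericity",
    "SurfaceArea", "SurfaceVolumeRatio", "VoxelVolume",
]
FIRSTORDER_NAMES = [
    "10Percentile", "90Percentile", "Energy", "Entropy", "InterquartileRange",
    "Kurtosis", "Maximum", "MeanAbsoluteDeviation", "Mean", "Median", "Minimum",
    "Range", "RobustMeanAbsoluteDeviation", "RootMeanSquared", "Skewness",
    "TotalEnergy", "Uniformity", "Variance",
]
GLCM_NAMES = [
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
]
GLRLM_NAMES = [
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized", "GrayLevelVariance",
    "HighGrayLevelRunEmphasis", "LongRunEmphasis", "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis", "LowGrayLevelRunEmphasis", "RunEntropy",
    "RunLengthNonUniformity", "RunLengthNonUniformityNormalized", "RunPercentage",
    "RunVariance", "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
]
GLSZM_NAMES = [
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized", "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis", "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis", "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis", "ZoneEntropy",
    "ZonePercentage", "ZoneVariance",
]
GLDM_NAMES = [
    "DependenceEntropy", "DependenceNonUniformity", "DependenceNonUniformityNormalized",
    "DependenceVariance", "GrayLevelNonUniformity", "GrayLevelVariance",
    "HighGrayLevelEmphasis", "LargeDependenceEmphasis",
    "LargeDependenceHighGrayLevelEmphasis", "LargeDependenceLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis", "SmallDependenceEmphasis",
    "SmallDependenceHighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
]
NGTDM_NAMES = ["Busyness", "Coarseness", "Complexity", "Contrast", "Strength"]

FEATURE_INVENTORY: dict[str, list[str]] = {
    "shape": SHAPE_NAMES, "firstorder": FIRSTORDER_NAMES, "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES, "glszm": GLSZM_NAMES, "gldm": GLDM_NAMES, "ngtdm": NGTDM_NAMES,
}


@dataclass
class ExtractionConfig:
    enabled_classes: tuple = FEATURE_CLASSES
    bin_width: float = 25.0
    mask_label: int = 1
    resampling: tuple | None = None  # recorded, not applied by the built-in engine

    def validate(self) -> None:
        unknown = set(self.enabled_classes) - set(FEATURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")


def _as_array(obj) -> tuple[np.ndarray, tuple[float, float, float] | None]:
    """Accept a nibabel image or a plain ndarray; return (data, spacing)."""
    if hasattr(obj, "get_fdata"):
        return np.asanyarray(obj.get_fdata()), tuple(float(z) for z in obj.header.get_zooms()[:3])
    return np.asarray(obj, dtype=float), None


# ---------------------------------------------------------------------------
# built-in engine


def _shape_features(mask: np.ndarray, spacing: np.ndarray) -> dict[str, float]:
    vox_vol = float(np.prod(spacing))
    n_vox = int(mask.sum())
    coords = np.argwhere(mask) * spacing[None, :]
    volume = n_vox * vox_vol
    # surface estimate: count exposed faces weighted by face area
    surface = 0.0
    for ax in range(3):
        face = float(np.prod(np.delete(spacing, ax)))
        padded = np.pad(mask, 1)
        diff = np.abs(np.diff(padded.astype(int), axis=ax))
        surface += diff.sum() * face
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / max(len(coords) - 1, 1)
    evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    evals = np.clip(evals, 0, None)
    major, minor, least = (4.0 * np.sqrt(evals)).tolist()

    def max_diam(pts: np.ndarray) -> float:
        if len(pts) < 2:
            return 0.0
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        # diameter of the bounding region is a tight, cheap upper surrogate;
        # refine over hull-extreme candidates along each axis
        cands = []
        for ax in range(pts.shape[1]):
            cands.append(pts[pts[:, ax].argmin()])
            cands.append(pts[pts[:, ax].argmax()])
        cands = np.unique(np.array(cands), axis=0)
        d = np.sqrt(((cands[:, None, :] - cands[None, :, :]) ** 2).sum(-1))
        return float(max(d.max(), np.linalg.norm(hi - lo) * 0 + d.max()))

    diam3d = max_diam(coords)
    d_slice = max(max_diam(coords[np.isclose(coords[:, 2], z)][:, :2])
                  for z in np.unique(coords[:, 2]))
    d_col = max(max_diam(coords[np.isclose(coords[:, 1], yv)][:, [0, 2]])
                for yv in np.unique(coords[:, 1]))
    d_row = max(max_diam(coords[np.isclose(coords[:, 0], xv)][:, 1:])
                for xv in np.unique(coords[:, 0]))
    sphericity = (np.pi ** (1 / 3)) * ((6 * volume) ** (2 / 3)) / max(surface, EPS)
    return {
        "Elongation": float(np.sqrt(evals[1] / max(evals[0], EPS))),
        "Flatness": float(np.sqrt(evals[2] / max(evals[0], EPS))),
        "LeastAxisLength": least,
        "MajorAxisLength": major,
        "Maximum2DDiameterColumn": d_col,
        "Maximum2DDiameterRow": d_row,
        "Maximum2DDiameterSlice": d_slice,
        "Maximum3DDiameter": diam3d,
        "MeshVolume": volume,
        "MinorAxisLength": minor,
        "Sphericity": float(sphericity),
        "SurfaceArea": float(surface),
        "SurfaceVolumeRatio": float(surface / max(volume, EPS)),
        "VoxelVolume": volume,
    }


def _firstorder_features(vals: np.ndarray, vox_vol: float, bin_width: float) -> dict[str, float]:
    p10, p25, p50, p75, p90 = np.percentile(vals, [10, 25, 50, 75, 90])
    hist, _ = np.histogram(vals, bins=max(int(np.ptp(vals) / bin_width) + 1, 1))
    p = hist / hist.sum()
    p = p[p > 0]
    robust = vals[(vals >= p10) & (vals <= p90)]
    mean = vals.mean()
    return {
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Energy": float((vals**2).sum()),
        "Entropy": float(-(p * np.log2(p)).sum()),
        "InterquartileRange": float(p75 - p25),
        "Kurtosis": float(((vals - mean) ** 4).mean() / max(vals.var() ** 2, EPS)),
        "Maximum": float(vals.max()),
        "MeanAbsoluteDeviation": float(np.abs(vals - mean).mean()),
        "Mean": float(mean),
        "Median": float(p50),
        "Minimum": float(vals.min()),
        "Range": float(np.ptp(vals)),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean()),
        "RootMeanSquared": float(np.sqrt((vals**2).mean())),
        "Skewness": float(((vals - mean) ** 3).mean() / max(vals.std() ** 3, EPS)),
        "TotalEnergy": float(vox_vol * (vals**2).sum()),
        "Uniformity": float((p**2).sum()),
        "Variance": float(vals.var()),
    }


def _discretize(image: np.ndarray, mask: np.ndarray, bin_width: float) -> np.ndarray:
    """Fixed-bin-width gray levels (1-based) inside the mask, 0 outside."""
    levels = np.zeros(image.shape, dtype=int)
    vals = image[mask]
    levels[mask] = np.floor((image[mask] - vals.min()) / bin_width).astype(int) + 1
    return levels


def _glcm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    ng = levels.max()
    pmat = np.zeros((ng, ng))
    for ax in range(3):
        a = np.take(levels, range(levels.shape[ax] - 1), axis=ax)
        b = np.take(levels, range(1, levels.shape[ax]), axis=ax)
        valid = (a > 0) & (b > 0)
        np.add.at(pmat, (a[valid] - 1, b[valid] - 1), 1.0)
    pmat = pmat + pmat.T
    total = pmat.sum()
    if total == 0:
        pmat = np.eye(ng)
        total = ng
    pmat /= total
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = pmat.sum(axis=1)
    mu = float((i * px).sum())
    sigma = float(np.sqrt(((i - mu) ** 2 * px).sum()))
    diff = np.abs(ii - jj)
    k_diff = np.arange(0, ng, dtype=float)
    p_diff = np.array([pmat[diff == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.array([pmat[(ii + jj) == k].sum() for k in k_sum])
    nz = pmat > 0
    hxy = float(-(pmat[nz] * np.log2(pmat[nz])).sum())
    pxpy = np.outer(px, px)
    nz2 = pxpy > 0
    hxy1 = float(-(pmat[nz2] * np.log2(pxpy[nz2])).sum())
    hxy2 = float(-(pxpy[nz2] * np.log2(pxpy[nz2])).sum())
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    da = float((k_diff * p_diff).sum())
    # MCC via the second-largest eigenvalue of Q
    with np.errstate(divide="ignore", invalid="ignore"):
        q = (pmat[:, None, :] * pmat[None, :, :] /
             np.maximum(px[:, None, None] * px[None, None, :], EPS)).sum(axis=2)
    eig = np.sort(np.real(np.linalg.eigvals(q)))[::-1]
    mcc = float(np.sqrt(np.clip(eig[1] if len(eig) > 1 else 0.0, 0.0, 1.0)))
    off = diff > 0
    corr = (float((ii * jj * pmat).sum()) - mu * mu) / max(sigma**2, EPS) if sigma > 0 else 1.0
    return {
        "Autocorrelation": float((ii * jj * pmat).sum()),
        "ClusterProminence": float((((ii + jj) - 2 * mu) ** 4 * pmat).sum()),
        "ClusterShade": float((((ii + jj) - 2 * mu) ** 3 * pmat).sum()),
        "ClusterTendency": float((((ii + jj) - 2 * mu) ** 2 * pmat).sum()),
        "Contrast": float(((ii - jj) ** 2 * pmat).sum()),
        "Correlation": float(corr),
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-(p_diff[p_diff > 0] * np.log2(p_diff[p_diff > 0])).sum()),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "Id": float((pmat / (1 + diff)).sum()),
        "Idm": float((pmat / (1 + diff**2)).sum()),
        "Idmn": float((pmat / (1 + (diff / ng) ** 2)).sum()),
        "Idn": float((pmat / (1 + diff / ng)).sum()),
        "Imc1": float((hxy - hxy1) / max(hx, EPS)),
        "Imc2": float(np.sqrt(np.clip(1 - np.exp(-2 * (hxy2 - hxy)), 0, 1))),
        "InverseVariance": float((pmat[off] / diff[off] ** 2).sum()),
        "JointAverage": mu,
        "JointEnergy": float((pmat**2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(pmat.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": float(-(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0])).sum()),
        "SumSquares": float(((ii - mu) ** 2 * pmat).sum()),
    }


def _runs_along_axis(levels: np.ndarray, ax: int):
    moved = np.moveaxis(levels, ax, -1)
    flat = moved.reshape(-1, moved.shape[-1])
    for line in flat:
        g_prev, length = 0, 0
        for g in line:
            if g == g_prev and g > 0:
                length += 1
            else:
                if g_prev > 0:
                    yield g_prev, length
                g_prev, length = g, 1 if g > 0 else 0
        if g_prev > 0 and length > 0:
            yield g_prev, length


def _weighted_matrix_stats(mat: np.ndarray, n_vox: int, prefix: dict[str, str]) -> dict[str, float]:
    """Shared emphasis/uniformity statistics over a (gray level x size) matrix.

    ``prefix`` maps the abstract statistic keys to class-specific names.
    """
    total = mat.sum()
    if total == 0:
        mat = np.ones_like(mat, dtype=float)
        total = mat.sum()
    p = mat / total
    g = np.arange(1, mat.shape[0] + 1, dtype=float)[:, None]
    s = np.arange(1, mat.shape[1] + 1, dtype=float)[None, :]
    pg = p.sum(axis=1)
    ps = p.sum(axis=0)
    mu_g = float((np.arange(1, mat.shape[0] + 1) * pg).sum())
    mu_s = float((np.arange(1, mat.shape[1] + 1) * ps).sum())
    nzp = p[p > 0]
    out = {
        "small": float((p / s**2).sum()),
        "large": float((p * s**2).sum()),
        "low": float((p / g**2).sum()),
        "high": float((p * g**2).sum()),
        "small_low": float((p / (g**2 * s**2)).sum()),
        "small_high": float((p * g**2 / s**2).sum()),
        "large_low": float((p * s**2 / g**2).sum()),
        "large_high": float((p * g**2 * s**2).sum()),
        "gln": float((mat.sum(axis=1) ** 2).sum() / total),
        "glnn": float(((mat.sum(axis=1) / total) ** 2).sum()),
        "sn": float((mat.sum(axis=0) ** 2).sum() / total),
        "snn": float(((mat.sum(axis=0) / total) ** 2).sum()),
        "glv": float((p * (g - mu_g) ** 2).sum()),
        "sv": float((p * (s - mu_s) ** 2).sum()),
        "entropy": float(-(nzp * np.log2(nzp)).sum()),
        "percentage": float(total / max(n_vox, 1)),
    }
    return {name: out[key] for key, name in prefix.items()}


def _glrlm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    ng = levels.max()
    runs: dict[tuple[int, int], float] = {}
    max_len = 1
    for ax in range(3):
        for g, ln in _runs_along_axis(levels, ax):
            runs[(g, ln)] = runs.get((g, ln), 0.0) + 1.0
            max_len = max(max_len, ln)
    mat = np.zeros((ng, max_len))
    for (g, ln), c in runs.items():
        mat[g - 1, ln - 1] = c
    n_vox = int(mask.sum()) * 3  # runs counted over three directions
    return _weighted_matrix_stats(mat, n_vox, {
        "gln": "GrayLevelNonUniformity", "glnn": "GrayLevelNonUniformityNormalized",
        "glv": "GrayLevelVariance", "high": "HighGrayLevelRunEmphasis",
        "large": "LongRunEmphasis", "large_high": "LongRunHighGrayLevelEmphasis",
        "large_low": "LongRunLowGrayLevelEmphasis", "low": "LowGrayLevelRunEmphasis",
        "entropy": "RunEntropy", "sn": "RunLengthNonUniformity",
        "snn": "RunLengthNonUniformityNormalized", "percentage": "RunPercentage",
        "sv": "RunVariance", "small": "ShortRunEmphasis",
        "small_high": "ShortRunHighGrayLevelEmphasis",
        "small_low": "ShortRunLowGrayLevelEmphasis",
    })


def _glszm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    ng = levels.max()
    structure = np.ones((3, 3, 3), dtype=int)  # 26-connectivity
    zones: dict[tuple[int, int], float] = {}
    max_size = 1
    for g in range(1, ng + 1):
        lab, n_lab = ndimage.label(levels == g, structure=structure)
        if n_lab == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for sz in sizes:
            zones[(g, int(sz))] = zones.get((g, int(sz)), 0.0) + 1.0
            max_size = max(max_size, int(sz))
    mat = np.zeros((ng, max_size))
    for (g, sz), c in zones.items():
        mat[g - 1, sz - 1] = c
    return _weighted_matrix_stats(mat, int(mask.sum()), {
        "gln": "GrayLevelNonUniformity", "glnn": "GrayLevelNonUniformityNormalized",
        "glv": "GrayLevelVariance", "high": "HighGrayLevelZoneEmphasis",
        "large": "LargeAreaEmphasis", "large_high": "LargeAreaHighGrayLevelEmphasis",
        "large_low": "LargeAreaLowGrayLevelEmphasis", "low": "LowGrayLevelZoneEmphasis",
        "sn": "SizeZoneNonUniformity", "snn": "SizeZoneNonUniformityNormalized",
        "small": "SmallAreaEmphasis", "small_high": "SmallAreaHighGrayLevelEmphasis",
        "small_low": "SmallAreaLowGrayLevelEmphasis", "entropy": "ZoneEntropy",
        "percentage": "ZonePercentage", "sv": "ZoneVariance",
    })


def _neighbor_stack(levels: np.ndarray):
    """Yield the 26-neighbourhood as aligned (neighbour, validity) arrays."""
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                shifted = np.zeros_like(levels)
                src = [slice(max(-d, 0), levels.shape[k] - max(d, 0)) for k, d in enumerate((dx, dy, dz))]
                dst = [slice(max(d, 0), levels.shape[k] - max(-d, 0)) for k, d in enumerate((dx, dy, dz))]
                shifted[tuple(dst)] = levels[tuple(src)]
                yield shifted


def _gldm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    ng = levels.max()
    dep = np.zeros(levels.shape, dtype=int)
    for nb in _neighbor_stack(levels):
        dep += ((nb == levels) & (nb > 0)).astype(int)
    g_vals = levels[mask]
    d_vals = dep[mask] + 1  # dependence includes the centre voxel
    mat = np.zeros((ng, int(d_vals.max())))
    np.add.at(mat, (g_vals - 1, d_vals - 1), 1.0)
    return _weighted_matrix_stats(mat, int(mask.sum()), {
        "entropy": "DependenceEntropy", "sn": "DependenceNonUniformity",
        "snn": "DependenceNonUniformityNormalized", "sv": "DependenceVariance",
        "gln": "GrayLevelNonUniformity", "glv": "GrayLevelVariance",
        "high": "HighGrayLevelEmphasis", "large": "LargeDependenceEmphasis",
        "large_high": "LargeDependenceHighGrayLevelEmphasis",
        "large_low": "LargeDependenceLowGrayLevelEmphasis",
        "low": "LowGrayLevelEmphasis", "small": "SmallDependenceEmphasis",
        "small_high": "SmallDependenceHighGrayLevelEmphasis",
        "small_low": "SmallDependenceLowGrayLevelEmphasis",
    })


def _ngtdm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    ng = levels.max()
    nb_sum = np.zeros(levels.shape, dtype=float)
    nb_cnt = np.zeros(levels.shape, dtype=float)
    for nb in _neighbor_stack(levels):
        valid = nb > 0
        nb_sum += np.where(valid, nb, 0.0)
        nb_cnt += valid
    with np.errstate(invalid="ignore", divide="ignore"):
        nb_mean = np.where(nb_cnt > 0, nb_sum / np.maximum(nb_cnt, 1), 0.0)
    gv = levels[mask]
    diff = np.abs(gv - nb_mean[mask])
    nv = len(gv)
    n_i = np.bincount(gv - 1, minlength=ng).astype(float)
    s_i = np.bincount(gv - 1, weights=diff, minlength=ng)
    p_i = n_i / nv
    act = p_i > 0
    idx = np.arange(1, ng + 1, dtype=float)
    ngp = int(act.sum())
    pi, pj = np.meshgrid(p_i[act], p_i[act], indexing="ij")
    vi, vj = np.meshgrid(idx[act], idx[act], indexing="ij")
    si, sj = np.meshgrid(s_i[act], s_i[act], indexing="ij")
    coarse = 1.0 / max(float((p_i * s_i).sum()), EPS)
    contrast = (float((pi * pj * (vi - vj) ** 2).sum()) / max(ngp * (ngp - 1), 1)) * (s_i.sum() / nv)
    busy_den = float(np.abs(vi * pi - vj * pj).sum())
    busyness = float((p_i * s_i).sum()) / max(busy_den, EPS)
    complexity = float((np.abs(vi - vj) * (pi * si + pj * sj) / (pi + pj)).sum()) / nv
    strength = float(((pi + pj) * (vi - vj) ** 2).sum()) / max(float(s_i.sum()), EPS)
    return {
        "Busyness": busyness, "Coarseness": min(coarse, 1e6), "Complexity": complexity,
        "Contrast": contrast, "Strength": strength,
    }


def builtin_engine(image: np.ndarray, mask: np.ndarray, spacing, config: ExtractionConfig) -> dict[str, float]:
    """The built-in feature engine. Returns ``{"<class>_<Name>": value}``."""
    spacing = np.asarray(spacing if spacing is not None else (1.0, 1.0, 1.0), float)
    vals = image[mask]
    levels = _discretize(image, mask, config.bin_width)
    out: dict[str, float] = {}
    per_class = {
        "shape": lambda: _shape_features(mask, spacing),
        "firstorder": lambda: _firstorder_features(vals, float(np.prod(spacing)), config.bin_width),
        "glcm": lambda: _glcm_features(levels, mask),
        "glrlm": lambda: _glrlm_features(levels, mask),
        "glszm": lambda: _glszm_features(levels, mask),
        "gldm": lambda: _gldm_features(levels, mask),
        "ngtdm": lambda: _ngtdm_features(levels, mask),
    }
    for cls in FEATURE_CLASSES:
        if cls not in config.enabled_classes:
            continue
        feats = per_class[cls]()
        expected = FEATURE_INVENTORY[cls]
        assert set(feats) == set(expected), f"engine returned wrong {cls} inventory"
        for name in expected:
            out[f"{cls}_{name}"] = float(feats[name])
    return out


def extract_features(image, mask, config: ExtractionConfig | None = None,
                     engine=builtin_engine, sample_id: str = "sample") -> pd.Series:
    """Extract one feature row from an image + mask pair.

    ``image`` and ``mask`` may be nibabel images (spacing taken from the
    header) or plain arrays. With the seven default classes enabled the row
    has exactly 107 class-prefixed features.
    """
    config = config or ExtractionConfig()
    config.validate()
    img, spacing_i = _as_array(image)
    msk, spacing_m = _as_array(mask)
    if img.shape != msk.shape:
        raise ValueError(f"image shape {img.shape} != mask shape {msk.shape}")
    if spacing_i is not None and spacing_m is not None and not np.allclose(spacing_i, spacing_m):
        raise ValueError("image and mask voxel spacing disagree")
    binary = msk == config.mask_label
    if not binary.any():
        raise ValueError(f"mask has no voxels with label {config.mask_label}")
    feats = engine(img, binary, spacing_i or spacing_m, config)
    return pd.Series(feats, name=sample_id, dtype=float)


def batch_extract(manifest: pd.DataFrame, config: ExtractionConfig | None = None,
                  engine=builtin_engine) -> FeatureTable:
    """Extract rows for a manifest with columns sample_id, image_path,
    mask_path and (binary) label."""
    import nibabel as nib

    rows, ids, labels = [], [], []
    for _, rec in manifest.iterrows():
        img = nib.load(rec["image_path"])
        msk = nib.load(rec["mask_path"])
        rows.append(extract_features(img, msk, config, engine, sample_id=str(rec["sample_id"])))
        ids.append(str(rec["sample_id"]))
        labels.append(int(rec.get("label", 0)))
    return FeatureTable(ids, np.array(labels), pd.DataFrame(rows))
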