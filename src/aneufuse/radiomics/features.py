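"""Texture-feature formulas per family (24 GLCM, 16 GLRLM, 16 GLSZM,
5 NGTDM, 14 GLDM), each implemented from its standard definition.

Degenerate-input rules (a constant ROI collapses most matrices to a single
cell) are fixed so no feature is ever NaN:

==================  =============================================
feature             degenerate value
==================  =============================================
glcm correlation    1 (zero marginal variance)
glcm imc1           0 (HX = HY = 0)
glcm imc2           0 (HXY2 <= HXY)
glcm mcc            1 (single gray level)
ngtdm coarseness    capped at 1e6 (zero denominator)
ngtdm contrast      0 (single gray level)
ngtdm busyness      0 (zero denominator)
ngtdm strength      0 (zero s-sum)
variances/entropies 0 wherever the distribution is a point mass
==================  =============================================

Logarithms are base 2 over strictly positive probabilities.
"""

from __future__ import annotations

import numpy as np

from .matrices import TextureMatrix

COARSENESS_CAP = 1e6

GLCM_NAMES = (
    "autocorrelation", "joint_average", "cluster_prominence", "cluster_shade",
    "cluster_tendency", "contrast", "correlation", "difference_average",
    "difference_entropy", "difference_variance", "joint_energy", "joint_entropy",
    "imc1", "imc2", "idm", "mcc", "idmn", "id", "idn", "inverse_variance",
    "maximum_probability", "sum_average", "sum_entropy", "sum_squares",
)
GLRLM_NAMES = (
    "short_run_emphasis", "long_run_emphasis", "gray_level_non_uniformity",
    "gray_level_non_uniformity_normalized", "run_length_non_uniformity",
    "run_length_non_uniformity_normalized", "run_percentage",
    "gray_level_variance", "run_variance", "run_entropy",
    "low_gray_level_run_emphasis", "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis", "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis", "long_run_high_gray_level_emphasis",
)
GLSZM_NAMES = (
    "small_area_emphasis", "large_area_emphasis", "gray_level_non_uniformity",
    "gray_level_non_uniformity_normalized", "size_zone_non_uniformity",
    "size_zone_non_uniformity_normalized", "zone_percentage",
    "gray_level_variance", "zone_variance", "zone_entropy",
    "low_gray_level_zone_emphasis", "high_gray_level_zone_emphasis",
    "small_area_low_gray_level_emphasis", "small_area_high_gray_level_emphasis",
    "large_area_low_gray_level_emphasis", "large_area_high_gray_level_emphasis",
)
NGTDM_NAMES = ("coarseness", "contrast", "busyness", "complexity", "strength")
GLDM_NAMES = (
    "small_dependence_emphasis", "large_dependence_emphasis",
    "gray_level_non_uniformity", "dependence_non_uniformity",
    "dependence_non_uniformity_normalized", "gray_level_variance",
    "dependence_variance", "dependence_entropy",
    "low_gray_level_emphasis", "high_gray_level_emphasis",
    "small_dependence_low_gray_level_emphasis",
    "small_dependence_high_gray_level_emphasis",
    "large_dependence_low_gray_level_emphasis",
    "large_dependence_high_gray_level_emphasis",
)


def _plog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    pos = p > 0
    out[pos] = p[pos] * np.log2(p[pos])
    return out


def glcm_features(tm: TextureMatrix) -> dict[str, float]:
    p = tm.matrix
    ng = tm.n_levels
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu_x = float(np.sum(i * px))
    sigma_x = float(np.sqrt(np.sum((i - mu_x) ** 2 * px)))

    # diagonal (difference) and cross-diagonal (sum) distributions
    k_diff = np.arange(0, ng)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])

    diff_avg = float(np.sum(k_diff * p_diff))
    hxy = float(-np.sum(_plog2(p)))
    pxpy = np.outer(px, px)
    with np.errstate(divide="ignore"):
        log_pxpy = np.where(pxpy > 0, np.log2(np.where(pxpy > 0, pxpy, 1.0)), 0.0)
    hxy1 = float(-np.sum(np.where(p > 0, p * log_pxpy, 0.0)))
    hxy2 = float(-np.sum(_plog2(pxpy)))
    hx = float(-np.sum(_plog2(px)))

    if sigma_x > 0:
        corr = float((np.sum(p * ii * jj) - mu_x * mu_x) / (sigma_x * sigma_x))
    else:
        corr = 1.0
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(1 - np.exp(-2.0 * (hxy2 - hxy)))) if hxy2 > hxy else 0.0

    present = px > 0
    if present.sum() <= 1:
        mcc = 1.0
    else:
        psub = p[np.ix_(present, present)]
        pxs = px[present]
        q = (psub / pxs[:, None]) @ (psub / pxs[None, :]).T
        ev = np.sort(np.real(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(ev[-2], 0.0))) if len(ev) >= 2 else 1.0

    inv_var = float(np.sum(p_diff[1:] / k_diff[1:] ** 2)) if ng > 1 else 0.0

    return {
        "autocorrelation": float(np.sum(p * ii * jj)),
        "joint_average": mu_x,
        "cluster_prominence": float(np.sum(p * (ii + jj - 2 * mu_x) ** 4)),
        "cluster_shade": float(np.sum(p * (ii + jj - 2 * mu_x) ** 3)),
        "cluster_tendency": float(np.sum(p * (ii + jj - 2 * mu_x) ** 2)),
        "contrast": float(np.sum(p * (ii - jj) ** 2)),
        "correlation": corr,
        "difference_average": diff_avg,
        "difference_entropy": float(-np.sum(_plog2(p_diff))),
        "difference_variance": float(np.sum((k_diff - diff_avg) ** 2 * p_diff)),
        "joint_energy": float(np.sum(p**2)),
        "joint_entropy": hxy,
        "imc1": float(imc1),
        "imc2": imc2,
        "idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "mcc": mcc,
        "idmn": float(np.sum(p / (1.0 + ((ii - jj) / ng) ** 2))),
        "id": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "idn": float(np.sum(p / (1.0 + np.abs(ii - jj) / ng))),
        "inverse_variance": inv_var,
        "maximum_probability": float(p.max()),
        "sum_average": float(np.sum(k_sum * p_sum)),
        "sum_entropy": float(-np.sum(_plog2(p_sum))),
        "sum_squares": float(np.sum(p * (ii - mu_x) ** 2)),
    }


def _run_zone_features(tm: TextureMatrix, names, percentage_denominator: float) -> dict[str, float]:
    """Shared formula set for GLRLM (runs) and GLSZM (zones)."""
    counts = tm.matrix
    n = counts.sum()
    if n == 0:
        return {k: 0.0 for k in names}
    p = counts / n
    ng, nl = counts.shape
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, nl + 1)[None, :]
    pg = p.sum(axis=1)
    pl = p.sum(axis=0)
    mu_i = float(np.sum(i[:, 0] * pg))
    mu_j = float(np.sum(j[0, :] * pl))
    return {
        names[0]: float(np.sum(p / j**2)),
        names[1]: float(np.sum(p * j**2)),
        names[2]: float(np.sum(counts.sum(axis=1) ** 2) / n),
        names[3]: float(np.sum(counts.sum(axis=1) ** 2) / n**2),
        names[4]: float(np.sum(counts.sum(axis=0) ** 2) / n),
        names[5]: float(np.sum(counts.sum(axis=0) ** 2) / n**2),
        names[6]: float(n / percentage_denominator) if percentage_denominator > 0 else 0.0,
        names[7]: float(np.sum(p * (i - mu_i) ** 2)),
        names[8]: float(np.sum(p * (j - mu_j) ** 2)),
        names[9]: float(-np.sum(_plog2(p))),
        names[10]: float(np.sum(p / i**2)),
        names[11]: float(np.sum(p * i**2)),
        names[12]: float(np.sum(p / (i**2 * j**2))),
        names[13]: float(np.sum(p * i**2 / j**2)),
        names[14]: float(np.sum(p * j**2 / i**2)),
        names[15]: float(np.sum(p * i**2 * j**2)),
    }


def glrlm_features(tm: TextureMatrix) -> dict[str, float]:
    # run percentage normalizes by (voxels x directions): each voxel can
    # start at most one run per direction
    return _run_zone_features(tm, GLRLM_NAMES, tm.n_voxels * tm.n_directions)


def glszm_features(tm: TextureMatrix) -> dict[str, float]:
    return _run_zone_features(tm, GLSZM_NAMES, tm.n_voxels)


def ngtdm_features(tm: TextureMatrix) -> dict[str, float]:
    n_i, p_i, s_i = tm.matrix[:, 0], tm.matrix[:, 1], tm.matrix[:, 2]
    nvp = n_i.sum()
    ng = tm.n_levels
    i = np.arange(1, ng + 1, dtype=float)
    present = p_i > 0
    ngp = int(present.sum())

    denom_coars = float(np.sum(p_i * s_i))
    coarseness = min(1.0 / denom_coars, COARSENESS_CAP) if denom_coars > 0 else COARSENESS_CAP

    if ngp > 1 and nvp > 0:
        pi_, pj_ = np.meshgrid(p_i, p_i, indexing="ij")
        ii, jj = np.meshgrid(i, i, indexing="ij")
        contrast = float(
            np.sum(pi_ * pj_ * (ii - jj) ** 2) / (ngp * (ngp - 1)) * (np.sum(s_i) / nvp)
        )
    else:
        contrast = 0.0

    busy_denom = 0.0
    complexity = 0.0
    strength_num = 0.0
    idx = np.nonzero(present)[0]
    for a in idx:
        for b in idx:
            busy_denom += abs(i[a] * p_i[a] - i[b] * p_i[b])
            if a != b:
                complexity += abs(i[a] - i[b]) * (p_i[a] * s_i[a] + p_i[b] * s_i[b]) / (p_i[a] + p_i[b])
                strength_num += (p_i[a] + p_i[b]) * (i[a] - i[b]) ** 2
    busyness = float(np.sum(p_i * s_i) / busy_denom) if busy_denom > 0 else 0.0
    complexity = complexity / nvp if nvp > 0 else 0.0
    s_sum = float(np.sum(s_i))
    strength = strength_num / s_sum if s_sum > 0 else 0.0

    return {
        "coarseness": float(coarseness),
        "contrast": contrast,
        "busyness": busyness,
        "complexity": float(complexity),
        "strength": float(strength),
    }


def gldm_features(tm: TextureMatrix) -> dict[str, float]:
    counts = tm.matrix
    n = counts.sum()
    if n == 0:
        return {k: 0.0 for k in GLDM_NAMES}
    p = counts / n
    ng, nd = counts.shape
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, nd + 1)[None, :]
    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    return {
        "small_dependence_emphasis": float(np.sum(p / j**2)),
        "large_dependence_emphasis": float(np.sum(p * j**2)),
        "gray_level_non_uniformity": float(np.sum(counts.sum(axis=1) ** 2) / n),
        "dependence_non_uniformity": float(np.sum(counts.sum(axis=0) ** 2) / n),
        "dependence_non_uniformity_normalized": float(np.sum(counts.sum(axis=0) ** 2) / n**2),
        "gray_level_variance": float(np.sum(p * (i - mu_i) ** 2)),
        "dependence_variance": float(np.sum(p * (j - mu_j) ** 2)),
        "dependence_entropy": float(-np.sum(_plog2(p))),
        "low_gray_level_emphasis": float(np.sum(p / i**2)),
        "high_gray_level_emphasis": float(np.sum(p * i**2)),
        "small_dependence_low_gray_level_emphasis": float(np.sum(p / (i**2 * j**2))),
        "small_dependence_high_gray_level_emphasis": float(np.sum(p * i**2 / j**2)),
        "large_dependence_low_gray_level_emphasis": float(np.sum(p * j**2 / i**2)),
        "large_dependence_high_gray_level_emphasis": float(np.sum(p * i**2 * j**2)),
    }


FAMILY_FEATURE_FUNCS = {
    "glcm": glcm_features,
    "glrlm": glrlm_features,
    "glszm": glszm_features,
    "ngtdm": ngtdm_features,
    "gldm": gldm_features,
}


def texture_features(tm: TextureMatrix) -> dict[str, float]:
    """Dispatch to the family's feature battery."""
    return FAMILY_FEATURE_FUNCS[tm.family](tm)
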