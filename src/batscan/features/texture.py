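"""Texture feature formulas over the gray-level matrices.

GLCM and GLRLM features are computed per direction and averaged over the
13 directions (vectorized across the direction axis).  Degenerate ROIs
(a single gray level, or a single voxel) return defined values rather
than NaN: correlation and the inverse-difference family fall back to
their perfect-dependence limits, spread measures to 0, and sums over
empty index sets to 0.
"""

from __future__ import annotations

import numpy as np

from .matrices import GrayLevelMatrix

_GLCM_SINGLE_VOXEL = {
    "Autocorrelation": 1.0, "JointAverage": 1.0, "ClusterProminence": 0.0,
    "ClusterShade": 0.0, "ClusterTendency": 0.0, "Contrast": 0.0,
    "Correlation": 1.0, "DifferenceAverage": 0.0, "DifferenceEntropy": 0.0,
    "DifferenceVariance": 0.0, "JointEnergy": 1.0, "JointEntropy": 0.0,
    "Imc1": 0.0, "Imc2": 0.0, "Id": 1.0, "Idm": 1.0, "Idmn": 1.0,
    "Idn": 1.0, "InverseVariance": 0.0, "MaximumProbability": 1.0,
    "SumEntropy": 0.0, "SumSquares": 0.0,
}


def _ent(p: np.ndarray) -> np.ndarray:
    """Shannon entropy (bits) along the last axis, 0·log0 = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -terms.sum(axis=-1)


def glcm_features(m: GrayLevelMatrix) -> dict[str, float]:
    """22 co-occurrence features, direction-averaged."""
    ng = m.n_levels
    totals = m.matrix.sum(axis=(1, 2))
    keep = totals > 0
    if not keep.any():  # single-voxel ROI: no co-occurring pairs at all
        return dict(_GLCM_SINGLE_VOXEL)
    P = m.matrix[keep] / totals[keep, None, None]
    D = len(P)
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = P.sum(axis=2)
    mu = (px * i).sum(axis=1)
    sigma2 = (((i - mu[:, None]) ** 2) * px).sum(axis=1)

    sum_idx = (ii + jj).astype(int).ravel() - 2
    diff_idx = np.abs(ii - jj).astype(int).ravel()
    p_sum = np.zeros((D, 2 * ng - 1))
    p_diff = np.zeros((D, ng))
    for d in range(D):
        flat = P[d].ravel()
        p_sum[d] = np.bincount(sum_idx, weights=flat, minlength=2 * ng - 1)
        p_diff[d] = np.bincount(diff_idx, weights=flat, minlength=ng)
    k_diff = np.arange(ng, dtype=float)
    da = (p_diff * k_diff).sum(axis=1)

    hx = _ent(px)
    hxy = _ent(P.reshape(D, -1))
    pxpy = px[:, :, None] * px[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        log_pxpy = np.log2(np.where(pxpy > 0, pxpy, 1.0))
    hxy1 = -(np.where(P > 0, P * log_pxpy, 0.0)).sum(axis=(1, 2))
    hxy2 = _ent(pxpy.reshape(D, -1))

    autoc = (P * (ii * jj)).sum(axis=(1, 2))
    corr = np.where(sigma2 > 0, (autoc - mu**2) / np.where(sigma2 > 0, sigma2, 1.0), 1.0)
    imc1 = np.where(hx > 0, (hxy - hxy1) / np.where(hx > 0, hx, 1.0), 0.0)
    imc2 = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0, None))

    absdiff = np.abs(ii - jj)
    diff2 = (ii - jj) ** 2
    offdiag = ii != jj
    inv_w = np.where(offdiag, 1.0 / np.where(offdiag, diff2, 1.0), 0.0)
    spread = ii + jj - 2.0 * mu[:, None, None]

    feats = {
        "Autocorrelation": autoc,
        "JointAverage": mu,
        "ClusterProminence": (spread**4 * P).sum(axis=(1, 2)),
        "ClusterShade": (spread**3 * P).sum(axis=(1, 2)),
        "ClusterTendency": (spread**2 * P).sum(axis=(1, 2)),
        "Contrast": (diff2 * P).sum(axis=(1, 2)),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": _ent(p_diff),
        "DifferenceVariance": ((k_diff - da[:, None]) ** 2 * p_diff).sum(axis=1),
        "JointEnergy": (P**2).sum(axis=(1, 2)),
        "JointEntropy": hxy,
        "Imc1": imc1,
        "Imc2": imc2,
        "Id": (P / (1.0 + absdiff)).sum(axis=(1, 2)),
        "Idm": (P / (1.0 + diff2)).sum(axis=(1, 2)),
        "Idmn": (P / (1.0 + diff2 / ng**2)).sum(axis=(1, 2)),
        "Idn": (P / (1.0 + absdiff / ng)).sum(axis=(1, 2)),
        "InverseVariance": (P * inv_w).sum(axis=(1, 2)),
        "MaximumProbability": P.max(axis=(1, 2)),
        "SumEntropy": _ent(p_sum),
        "SumSquares": (((ii - mu[:, None, None]) ** 2) * P).sum(axis=(1, 2)),
    }
    return {k: float(np.mean(v)) for k, v in feats.items()}


def _run_style_features(p: np.ndarray, n_voxels: int, prefix: dict[str, str]) -> dict[str, float]:
    """Shared formulas of the run-length / size-zone / dependence families.

    ``p`` holds raw count matrices indexed (gray level - 1, size - 1),
    either one matrix (2D) or a per-direction stack (3D); directional
    values are averaged.  ``prefix`` maps generic roles to the family's
    canonical feature names.
    """
    P = p[None] if p.ndim == 2 else p
    nr = P.sum(axis=(1, 2))
    keep = nr > 0
    if not keep.any():
        return {name: 0.0 for name in prefix.values()}
    P = P[keep]
    nr = nr[keep]
    i = np.arange(1, P.shape[1] + 1, dtype=float)
    j = np.arange(1, P.shape[2] + 1, dtype=float)
    pg = P.sum(axis=2)
    ps = P.sum(axis=1)
    pn = P / nr[:, None, None]
    mu_i = (i * pg).sum(axis=1) / nr
    mu_j = (j * ps).sum(axis=1) / nr

    vals = {
        "sre": (ps / j**2).sum(axis=1) / nr,
        "lre": (ps * j**2).sum(axis=1) / nr,
        "gln": (pg**2).sum(axis=1) / nr,
        "glnn": (pg**2).sum(axis=1) / nr**2,
        "rln": (ps**2).sum(axis=1) / nr,
        "rlnn": (ps**2).sum(axis=1) / nr**2,
        "rp": nr / n_voxels,
        "glv": (pn * (i[None, :, None] - mu_i[:, None, None]) ** 2).sum(axis=(1, 2)),
        "rv": (pn * (j[None, None, :] - mu_j[:, None, None]) ** 2).sum(axis=(1, 2)),
        "re": _ent(pn.reshape(len(pn), -1)),
        "lgle": (pg / i**2).sum(axis=1) / nr,
        "hgle": (pg * i**2).sum(axis=1) / nr,
        "srlgle": (P / (i[None, :, None] ** 2 * j[None, None, :] ** 2)).sum(axis=(1, 2)) / nr,
        "srhgle": (P * i[None, :, None] ** 2 / j[None, None, :] ** 2).sum(axis=(1, 2)) / nr,
        "lrlgle": (P * j[None, None, :] ** 2 / i[None, :, None] ** 2).sum(axis=(1, 2)) / nr,
        "lrhgle": (P * i[None, :, None] ** 2 * j[None, None, :] ** 2).sum(axis=(1, 2)) / nr,
    }
    return {name: float(np.mean(vals[role])) for role, name in prefix.items()}


_GLRLM_MAP = {
    "sre": "ShortRunEmphasis", "lre": "LongRunEmphasis",
    "gln": "GrayLevelNonUniformity", "glnn": "GrayLevelNonUniformityNormalized",
    "rln": "RunLengthNonUniformity", "rlnn": "RunLengthNonUniformityNormalized",
    "rp": "RunPercentage", "glv": "GrayLevelVariance", "rv": "RunVariance",
    "re": "RunEntropy", "lgle": "LowGrayLevelRunEmphasis",
    "hgle": "HighGrayLevelRunEmphasis", "srlgle": "ShortRunLowGrayLevelEmphasis",
    "srhgle": "ShortRunHighGrayLevelEmphasis", "lrlgle": "LongRunLowGrayLevelEmphasis",
    "lrhgle": "LongRunHighGrayLevelEmphasis",
}

_GLSZM_MAP = {
    "sre": "SmallAreaEmphasis", "lre": "LargeAreaEmphasis",
    "gln": "GrayLevelNonUniformity", "glnn": "GrayLevelNonUniformityNormalized",
    "rln": "SizeZoneNonUniformity", "rlnn": "SizeZoneNonUniformityNormalized",
    "rp": "ZonePercentage", "glv": "GrayLevelVariance", "rv": "ZoneVariance",
    "re": "ZoneEntropy", "lgle": "LowGrayLevelZoneEmphasis",
    "hgle": "HighGrayLevelZoneEmphasis", "srlgle": "SmallAreaLowGrayLevelEmphasis",
    "srhgle": "SmallAreaHighGrayLevelEmphasis", "lrlgle": "LargeAreaLowGrayLevelEmphasis",
    "lrhgle": "LargeAreaHighGrayLevelEmphasis",
}

_GLDM_MAP = {
    "sre": "SmallDependenceEmphasis", "lre": "LargeDependenceEmphasis",
    "gln": "GrayLevelNonUniformity", "rln": "DependenceNonUniformity",
    "rlnn": "DependenceNonUniformityNormalized", "glv": "GrayLevelVariance",
    "rv": "DependenceVariance", "re": "DependenceEntropy",
    "lgle": "LowGrayLevelEmphasis", "hgle": "HighGrayLevelEmphasis",
    "srlgle": "SmallDependenceLowGrayLevelEmphasis",
    "srhgle": "SmallDependenceHighGrayLevelEmphasis",
    "lrlgle": "LargeDependenceLowGrayLevelEmphasis",
    "lrhgle": "LargeDependenceHighGrayLevelEmphasis",
}


def glrlm_features(m: GrayLevelMatrix, n_voxels: int) -> dict[str, float]:
    """16 run-length features, direction-averaged."""
    return _run_style_features(m.matrix, n_voxels, _GLRLM_MAP)


def glszm_features(m: GrayLevelMatrix, n_voxels: int) -> dict[str, float]:
    """16 size-zone features."""
    return _run_style_features(m.matrix, n_voxels, _GLSZM_MAP)


def gldm_features(m: GrayLevelMatrix, n_voxels: int) -> dict[str, float]:
    """14 dependence features."""
    return _run_style_features(m.matrix, n_voxels, _GLDM_MAP)


def ngtdm_features(m: GrayLevelMatrix, n_voxels: int) -> dict[str, float]:
    """5 neighborhood gray-tone difference features."""
    n_i, p_i, s_i = m.matrix[:, 0], m.matrix[:, 1], m.matrix[:, 2]
    n = n_i.sum()
    if n == 0:
        return dict.fromkeys(("Coarseness", "Contrast", "Busyness", "Complexity", "Strength"), 0.0)
    i = np.arange(1, m.n_levels + 1, dtype=float)
    present = p_i > 0
    ngp = int(present.sum())
    ps = float((p_i * s_i).sum())

    coarseness = 1.0 / ps if ps > 0 else 1e6
    if ngp > 1:
        pi, pj = np.meshgrid(p_i[present], p_i[present], indexing="ij")
        iv, jv = np.meshgrid(i[present], i[present], indexing="ij")
        contrast = float((pi * pj * (iv - jv) ** 2).sum()) / (ngp * (ngp - 1)) * float(s_i.sum()) / n
        denom = float(np.abs(iv * pi - jv * pj).sum())
        busyness = ps / denom if denom > 0 else 0.0
        si, sj = np.meshgrid(s_i[present], s_i[present], indexing="ij")
        complexity = float((np.abs(iv - jv) * (pi * si + pj * sj) / (pi + pj)).sum()) / n
        s_total = float(s_i.sum())
        strength = float(((pi + pj) * (iv - jv) ** 2).sum()) / s_total if s_total > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }
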