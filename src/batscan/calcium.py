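"""Agatston calcium scoring on nonenhanced CT.

Lesion detection follows the printed rule: voxels strictly above 130 HU
inside a vascular territory, connected in-plane with 8-connectivity (the
Agatston score is a per-slice quantity, so 3D bridging is not used), and
components of fewer than 3 pixels are discarded.

Per lesion the slice score is area (mm^2) times the density weight from
the maximum HU: 1 for (130, 200), 2 for [200, 300), 3 for [300, 400) and
4 for >= 400.  The territory score sums slice scores; calcium volume is
total lesion voxels times voxel volume (no slice-thickness rescaling —
spacing is recorded with the result).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .grid import VolumeGrid, check_congruent

HU_THRESHOLD = 130.0
MIN_PIXELS = 3
_STRUCTURE_2D = np.ones((3, 3), dtype=bool)  # in-plane 8-connectivity


@dataclass
class Lesion:
    slice_index: int
    voxels: np.ndarray          # (n, 3) indices
    area_mm2: float
    max_hu: float
    weight: int
    slice_score: float


@dataclass
class CalciumResult:
    territory: str
    lesions: list[Lesion]
    agatston_score: float
    calcium_volume: float       # mm^3
    spacing: tuple[float, float, float]

    @property
    def positive(self) -> bool:
        return self.agatston_score > 0


def density_weight(max_hu: float) -> int:
    if max_hu >= 400:
        return 4
    if max_hu >= 300:
        return 3
    if max_hu >= 200:
        return 2
    return 1


def detect_lesions(ct: VolumeGrid, territory_mask: np.ndarray) -> list[Lesion]:
    """Per-slice connected bright components inside the territory."""
    territory_mask = np.asarray(territory_mask, dtype=bool)
    if not territory_mask.any():
        raise ValueError("empty territory mask")
    check_congruent(ct, territory_mask)
    pixel_area = ct.spacing[1] * ct.spacing[2]
    bright = (ct.values > HU_THRESHOLD) & territory_mask
    lesions: list[Lesion] = []
    for z in range(ct.shape[0]):
        lab, n = ndimage.label(bright[z], structure=_STRUCTURE_2D)
        for comp in range(1, n + 1):
            rc = np.argwhere(lab == comp)
            if len(rc) < MIN_PIXELS:
                continue
            voxels = np.column_stack([np.full(len(rc), z), rc])
            max_hu = float(ct.values[z][lab == comp].max())
            w = density_weight(max_hu)
            area = len(rc) * pixel_area
            lesions.append(Lesion(z, voxels, area, max_hu, w, area * w))
    return lesions


def agatston(lesions: list[Lesion], spacing, territory: str = "CAC") -> CalciumResult:
    """Total Agatston score and calcium volume for one territory."""
    spacing = tuple(float(s) for s in spacing)
    score = float(sum(l.slice_score for l in lesions))
    n_vox = int(sum(len(l.voxels) for l in lesions))
    volume = n_vox * float(np.prod(spacing))
    return CalciumResult(territory, lesions, score, volume, spacing)


def score_territory(ct: VolumeGrid, territory_mask: np.ndarray, territory: str = "CAC") -> CalciumResult:
    return agatston(detect_lesions(ct, territory_mask), ct.spacing, territory)


def territory_compare(results_by_group: dict[str, list[CalciumResult]]) -> pd.DataFrame:
    """Group summary: incidence, and mean +/- SD over calcium-positive
    patients only (all patients enter the incidence test)."""
    rows = []
    for group, results in results_by_group.items():
        if not results:
            raise ValueError(f"group {group!r} is empty")
        scores = np.array([r.agatston_score for r in results])
        volumes = np.array([r.calcium_volume for r in results])
        pos = scores > 0
        row = {
            "group": group,
            "n": len(results),
            "n_positive": int(pos.sum()),
            "incidence": float(pos.mean()),
            "score_mean_pos": float(scores[pos].mean()) if pos.any() else np.nan,
            "score_sd_pos": float(scores[pos].std(ddof=1)) if pos.sum() > 1 else np.nan,
            "volume_mean_pos": float(volumes[pos].mean()) if pos.any() else np.nan,
            "volume_sd_pos": float(volumes[pos].std(ddof=1)) if pos.sum() > 1 else np.nan,
        }
        rows.append(row)
    return pd.DataFrame(rows)
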