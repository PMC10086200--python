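"""Depot-level feature extraction: the full 1,743-entry census.

For each depot the CT is cropped to a padded bounding box, the 19-type
filter bank is applied, and for every image type the 18 first-order and
73 texture features are computed on the fixed-bin-width discretized ROI.
The 14 shape features are computed once, on the original geometry.
Everything is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ..grid import VolumeGrid, DepotROI, check_congruent
from ..preprocess import PreprocessConfig, apply_filter_bank, discretize, effective_bin_width
from . import matrices as gm
from .firstorder import first_order
from .registry import TEXTURE_CLASSES, census_keys, column_name
from .shape import shape_3d
from .texture import (
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

#: padding around the depot bounding box before filtering, voxels per axis;
#: covers the largest LoG kernel support in-plane at 1 mm pixels.
_PAD = (2, 6, 6)


@dataclass
class FeatureVector:
    """Named feature map for one depot."""

    entries: dict[tuple[str, str, str], float]
    depot_id: str = ""
    patient_id: str = ""

    def __len__(self) -> int:
        return len(self.entries)

    def to_series(self) -> pd.Series:
        return pd.Series({column_name(k): v for k, v in self.entries.items()})


def _crop(values: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    bb = ndimage.find_objects(mask.astype(np.int8))[0]
    padded = tuple(
        slice(max(0, s.start - p), min(n, s.stop + p))
        for s, p, n in zip(bb, _PAD, mask.shape)
    )
    return values[padded], mask[padded]


def texture_features(values: np.ndarray, mask: np.ndarray, bin_width: float,
                     max_levels: int | None = 64) -> dict[str, dict[str, float]]:
    """All five texture families for one image type on one ROI."""
    bw = effective_bin_width(values[mask], bin_width, max_levels)
    levels, ng = discretize(values, mask, bw)
    n_vox = int(mask.sum())
    return {
        "glcm": glcm_features(gm.glcm(levels, ng)),
        "glrlm": glrlm_features(gm.glrlm(levels, ng), n_vox),
        "glszm": glszm_features(gm.glszm(levels, ng), n_vox),
        "gldm": gldm_features(gm.gldm(levels, ng), n_vox),
        "ngtdm": ngtdm_features(gm.ngtdm(levels, ng), n_vox),
    }


def extract_all(ct: VolumeGrid, roi: DepotROI, config: PreprocessConfig | None = None) -> FeatureVector:
    """The full census for one depot (CT image types only)."""
    config = config or PreprocessConfig()
    config.validate()
    check_congruent(ct, roi.mask)
    try:
        sub_values, sub_mask = _crop(ct.values, roi.mask)
        sub = VolumeGrid(sub_values, ct.spacing, ct.origin)
        filtered = apply_filter_bank(sub, config)

        entries: dict[tuple[str, str, str], float] = {}
        for name, value in shape_3d(roi.mask, ct.spacing).items():
            entries[("original", "shape", name)] = value
        for image_type, grid in filtered.items():
            fo = first_order(grid.values, sub_mask, grid.voxel_volume,
                             config.bin_width, config.max_levels)
            for name, value in fo.items():
                entries[(image_type, "firstorder", name)] = value
            tex = texture_features(grid.values, sub_mask, config.bin_width, config.max_levels)
            for cls, feats in tex.items():
                for name, value in feats.items():
                    entries[(image_type, cls, name)] = value
    except Exception as exc:
        raise RuntimeError(
            f"feature extraction failed for depot {roi.depot_id} "
            f"(patient {roi.patient_id}): {exc}"
        ) from exc

    ordered = {k: entries[k] for k in census_keys(config.filter_bank)}
    bad = [k for k, v in ordered.items() if not np.isfinite(v)]
    if bad:
        raise RuntimeError(f"non-finite features for depot {roi.depot_id}: {bad[:5]}")
    return FeatureVector(ordered, roi.depot_id, roi.patient_id)


def extract_table(ct_by_patient: dict[str, VolumeGrid], rois: list[DepotROI],
                  config: PreprocessConfig | None = None) -> pd.DataFrame:
    """Feature table: one row per depot, canonical columns plus metadata."""
    rows = []
    for roi in rois:
        fv = extract_all(ct_by_patient[roi.patient_id], roi, config)
        row = {"patient_id": roi.patient_id, "depot_id": roi.depot_id,
               "region": roi.region, "laterality": roi.laterality}
        row.update({column_name(k): v for k, v in fv.entries.items()})
        rows.append(row)
    return pd.DataFrame(rows)


META_COLUMNS = ("patient_id", "depot_id", "region", "laterality")


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS and c != "bat_flag"]
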