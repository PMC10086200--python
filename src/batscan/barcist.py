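"""Reference-standard BAT labeling from paired PET-CT (BARCIST 1.0 rule).

A depot voxel is adipose when its CT value lies in the closed window
[-190, -10] HU; an adipose voxel is BAT when its SUV is >= 1.5.  A depot
is BAT when it holds at least ``min_bat_voxels`` BAT voxels (default 1),
and a patient is BAT-positive when at least one depot is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import VolumeGrid, DepotROI, check_congruent

HU_WINDOW = (-190.0, -10.0)
SUV_THRESHOLD = 1.5


@dataclass
class DepotLabel:
    depot_id: str
    patient_id: str
    adipose_voxel_count: int
    bat_voxel_count: int
    bat_flag: bool
    max_suv: float
    mean_suv: float
    warning: str | None = None


def label_depot(ct: VolumeGrid, pet: VolumeGrid, roi: DepotROI, min_bat_voxels: int = 1) -> DepotLabel:
    check_congruent(ct, pet, roi.mask)
    hu = ct.values[roi.mask]
    suv = pet.values[roi.mask]
    adipose = (hu >= HU_WINDOW[0]) & (hu <= HU_WINDOW[1])
    n_adipose = int(adipose.sum())
    if n_adipose == 0:
        return DepotLabel(roi.depot_id, roi.patient_id, 0, 0, False, float(suv.max()),
                          float(suv.mean()), warning="no adipose voxels in ROI")
    bat = adipose & (suv >= SUV_THRESHOLD)
    n_bat = int(bat.sum())
    suv_ad = suv[adipose]
    return DepotLabel(roi.depot_id, roi.patient_id, n_adipose, n_bat,
                      n_bat >= min_bat_voxels, float(suv_ad.max()), float(suv_ad.mean()))


def label_patient(labels: list[DepotLabel]) -> bool:
    """Patient BAT-positive iff at least one depot is BAT."""
    if not labels:
        raise ValueError("patient has no depots")
    return any(l.bat_flag for l in labels)


def label_table(ct_by_patient, pet_by_patient, rois: list[DepotROI],
                min_bat_voxels: int = 1) -> pd.DataFrame:
    """Per-depot labels joined to the cohort truth-table schema."""
    rows = []
    for roi in rois:
        lab = label_depot(ct_by_patient[roi.patient_id], pet_by_patient[roi.patient_id],
                          roi, min_bat_voxels)
        rows.append({
            "patient_id": roi.patient_id, "depot_id": roi.depot_id,
            "region": roi.region, "laterality": roi.laterality,
            "adipose_voxel_count": lab.adipose_voxel_count,
            "bat_voxel_count": lab.bat_voxel_count,
            "bat_flag": lab.bat_flag, "max_suv": lab.max_suv,
            "mean_suv": lab.mean_suv, "warning": lab.warning or "",
        })
    return pd.DataFrame(rows)
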