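"""Seeded synthetic PET-CT phantom cohorts.

Emulates the study population the analysis assumes: each patient carries
6-13 adipose depots (bilateral cervical / supraclavicular / axillary pairs
plus midline mediastinal depots) segmented on CT, with paired PET SUV
uptake, plus coronary and thoracic-aorta territory masks into which bright
calcified lesions can be injected.

BAT depots differ from WAT depots in three ways, mirroring the biology
(small lipid droplets, high mitochondrial content → denser, finer-grained
tissue with FDG uptake):

* mean HU shifted upward by ``bat_mean_hu_shift``;
* a rougher Gaussian-random-field texture (higher variance, shorter
  correlation length);
* SUV drawn from ``bat_suv_range`` (entirely >= 1.5) instead of
  ``wat_suv_range`` (entirely < 1.5).

All depot HU are clipped to the adipose window [-190, -10] so the BARCIST
CT criterion holds by construction.  A single integer seed drives a
hierarchical per-patient stream: the same spec and seed reproduce the
cohort bit for bit, and extending ``n_patients`` leaves earlier patients
unchanged.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import VolumeGrid, DepotROI, save_volume, save_mask

FAT_WINDOW = (-190.0, -10.0)
SUV_BAT_MIN = 1.5
CALCIUM_HU = 130.0

_VOLUME_SHAPE = (14, 60, 60)  # (slice, row, col); spacing default 5x1x1 mm

# Depot site templates: (region, centre slice, centre row, column offset
# from the midline).  Bilateral sites are mirrored about the mid-column.
_BILATERAL_SITES = (
    ("cervical", 11, 18, 10),
    ("supraclavicular", 8, 22, 16),
    ("axillary", 5, 28, 21),
)
# Up to seven midline mediastinal slots, mutually disjoint.
_MEDIASTINAL_SLOTS = ((1, 34), (4, 34), (7, 34), (1, 42), (4, 42), (7, 42), (10, 38))

# Vascular territories, clear of every depot site.
_TERRITORY_BOXES = {
    "CAC": (slice(0, 4), slice(46, 53), slice(18, 29)),
    "TAC": (slice(0, 6), slice(46, 53), slice(34, 43)),
}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic cohort.

    Defaults emulate the development cohort: 86 patients at 50% BAT
    prevalence (43 vs 43), 6-13 depots each, adipose HU inside the fat
    window, BAT SUV >= 1.5, and calcification more frequent in non-BAT
    patients.
    """

    n_patients: int = 86
    bat_prevalence: float = 0.5
    depots_per_patient_range: tuple[int, int] = (6, 13)
    bat_mean_hu_shift: float = 20.0
    bat_texture_sd: float = 12.0
    wat_mean_hu: float = -110.0
    wat_texture_sd: float = 5.0
    bat_corr_mm: float = 1.2
    wat_corr_mm: float = 3.0
    bat_suv_range: tuple[float, float] = (1.8, 4.0)
    wat_suv_range: tuple[float, float] = (0.4, 1.2)
    calcium_rate_bat: float = 0.10
    calcium_rate_nonbat: float = 0.35
    lesion_intensity_range: tuple[float, float] = (150.0, 450.0)
    voxel_spacing: tuple[float, float, float] = (5.0, 1.0, 1.0)
    rng_seed: int = 0

    def validate(self) -> None:
        lo, hi = self.depots_per_patient_range
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.bat_prevalence <= 1.0:
            raise ValueError("bat_prevalence must be a probability")
        if not (6 <= lo <= hi <= 13):
            raise ValueError("depots_per_patient_range must lie within [6, 13]")
        for m in (self.wat_mean_hu, self.wat_mean_hu + self.bat_mean_hu_shift):
            if not FAT_WINDOW[0] <= m <= FAT_WINDOW[1]:
                raise ValueError(f"depot mean HU {m} outside the fat window {FAT_WINDOW}")
        if self.bat_suv_range[0] < SUV_BAT_MIN or self.bat_suv_range[0] > self.bat_suv_range[1]:
            raise ValueError("bat_suv_range must lie entirely >= 1.5")
        if self.wat_suv_range[1] >= SUV_BAT_MIN or self.wat_suv_range[0] > self.wat_suv_range[1]:
            raise ValueError("wat_suv_range must lie entirely < 1.5")
        for r in (self.calcium_rate_bat, self.calcium_rate_nonbat):
            if not 0.0 <= r <= 1.0:
                raise ValueError("calcium rates must be probabilities")
        if self.lesion_intensity_range[0] <= CALCIUM_HU:
            raise ValueError("lesion intensities must exceed 130 HU")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "PhantomSpec":
        with open(path) as fh:
            d = json.load(fh)
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)


@dataclass
class PhantomTruth:
    """Ground truth for parameter-recovery tests."""

    depot_bat: dict[str, bool]
    patient_bat: bool
    lesions: dict[str, list[np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.depot_bat and self.patient_bat != any(self.depot_bat.values()):
            raise ValueError("patient BAT flag must be the OR of depot flags")


@dataclass
class PhantomPatient:
    patient_id: str
    ct: VolumeGrid
    pet: VolumeGrid
    depots: list[DepotROI]
    territories: dict[str, np.ndarray]
    truth: PhantomTruth
    covariates: dict[str, float] = field(default_factory=dict)


def _random_field(shape, sd, corr_mm, spacing, rng) -> np.ndarray:
    """Zero-mean Gaussian random field with ~unit-variance, scaled by sd."""
    noise = rng.standard_normal(shape)
    sigma_vox = [max(corr_mm / s, 1e-6) for s in spacing]
    smooth = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="reflect")
    std = smooth.std()
    if std < 1e-12:
        return np.zeros(shape)
    return sd * smooth / std


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return d <= 1.0


def _assign_bat(pair_regions, n_medial, rng) -> tuple[list[bool], list[bool]]:
    """BAT flags for bilateral pairs (joint) and mediastinal depots."""
    pair_flags = [bool(rng.random() < 0.6) for _ in pair_regions]
    med_flags = [bool(rng.random() < 0.3) for _ in range(n_medial)]
    if not (any(pair_flags) or any(med_flags)):
        pair_flags[int(rng.integers(len(pair_flags)))] = True
    return pair_flags, med_flags


def generate_patient(spec: PhantomSpec, patient_id: str, rng: np.random.Generator) -> PhantomPatient:
    shape = _VOLUME_SHAPE
    spacing = spec.voxel_spacing

    # soft-tissue background
    ct = 40.0 + 8.0 * rng.standard_normal(shape)
    np.clip(ct, -50.0, 110.0, out=ct)
    pet = np.clip(0.7 + 0.1 * rng.standard_normal(shape), 0.05, 1.4)

    is_bat_patient = bool(rng.random() < spec.bat_prevalence)

    lo, hi = spec.depots_per_patient_range
    n_depots = int(rng.integers(lo, hi + 1))
    n_medial = n_depots - 6
    med_slots = [_MEDIASTINAL_SLOTS[i] for i in rng.choice(len(_MEDIASTINAL_SLOTS), n_medial, replace=False)]

    if is_bat_patient:
        pair_flags, med_flags = _assign_bat(_BILATERAL_SITES, n_medial, rng)
    else:
        pair_flags = [False] * len(_BILATERAL_SITES)
        med_flags = [False] * n_medial

    depots: list[DepotROI] = []
    depot_bat: dict[str, bool] = {}
    mid_col = shape[2] // 2
    k = 0

    def paint_depot(mask: np.ndarray, bat: bool, drng: np.random.Generator) -> None:
        bb = ndimage.find_objects(mask.astype(np.int8))[0]
        sub = mask[bb]
        mean = spec.wat_mean_hu + (spec.bat_mean_hu_shift if bat else 0.0)
        sd = spec.bat_texture_sd if bat else spec.wat_texture_sd
        corr = spec.bat_corr_mm if bat else spec.wat_corr_mm
        tex = _random_field(sub.shape, sd, corr, spacing, drng)
        ct[bb][sub] = np.clip(mean + tex[sub], *FAT_WINDOW)
        suv_lo, suv_hi = spec.bat_suv_range if bat else spec.wat_suv_range
        base = drng.uniform(suv_lo, suv_hi)
        pet[bb][sub] = np.clip(base + 0.05 * drng.standard_normal(sub.shape)[sub], suv_lo, suv_hi)

    for (region, cs, cr, off), bat in zip(_BILATERAL_SITES, pair_flags):
        jit = rng.integers(-1, 2, size=3)
        radii = (float(rng.integers(1, 3)), float(rng.integers(3, 6)), float(rng.integers(3, 6)))
        for lat, sign in (("left", -1), ("right", 1)):
            center = (cs + jit[0], cr + jit[1], mid_col + sign * (off + jit[2]))
            mask = _ellipsoid(shape, center, radii)
            depot_id = f"{patient_id}_d{k:02d}"
            k += 1
            depots.append(DepotROI(mask, region, lat, patient_id, depot_id))
            depot_bat[depot_id] = bat
            paint_depot(mask, bat, rng)

    for (cs, cr), bat in zip(med_slots, med_flags):
        jit = rng.integers(-1, 2, size=2)
        radii = (float(rng.integers(1, 3)), float(rng.integers(2, 4)), float(rng.integers(2, 4)))
        center = (cs, cr + jit[0], mid_col + jit[1])
        mask = _ellipsoid(shape, center, radii)
        depot_id = f"{patient_id}_d{k:02d}"
        k += 1
        depots.append(DepotROI(mask, "mediastinal", "midline", patient_id, depot_id))
        depot_bat[depot_id] = bat
        paint_depot(mask, bat, rng)

    territories = {}
    for name, box in _TERRITORY_BOXES.items():
        m = np.zeros(shape, dtype=bool)
        m[box] = True
        territories[name] = m

    ct_grid = VolumeGrid(ct, spacing)
    lesions: dict[str, list[np.ndarray]] = {name: [] for name in territories}
    rate = spec.calcium_rate_bat if is_bat_patient else spec.calcium_rate_nonbat
    for name, tmask in territories.items():
        if rng.random() < rate:
            n_lesions = int(rng.integers(1, 4))
            intensity = float(rng.uniform(*spec.lesion_intensity_range))
            size = int(rng.integers(4, 13))
            ct_grid, les = inject_calcium(ct_grid, tmask, n_lesions, intensity, size, rng=rng)
            lesions[name] = les

    covariates = {
        "age": float(np.clip(rng.normal(43, 12), 18, 85)),
        "sex": float(rng.integers(0, 2)),
        "weight": float(np.clip(rng.normal(70, 12), 40, 120)),
        "temperature": float(rng.normal(8, 6)),
    }

    truth = PhantomTruth(depot_bat, is_bat_patient, lesions)
    return PhantomPatient(patient_id, ct_grid, VolumeGrid(pet, spacing), depots, territories, truth, covariates)


def generate_cohort(spec: PhantomSpec) -> list[PhantomPatient]:
    """Generate a full seeded cohort; identical spec+seed is bit-identical."""
    spec.validate()
    root = np.random.SeedSequence(spec.rng_seed)
    patients = []
    for i, child in enumerate(root.spawn(spec.n_patients)):
        rng = np.random.default_rng(child)
        patients.append(generate_patient(spec, f"P{i:03d}", rng))
    return patients


def inject_calcium(
    ct: VolumeGrid,
    territory_mask: np.ndarray,
    n_lesions: int,
    intensity: float,
    lesion_size: int,
    rng: np.random.Generator | None = None,
) -> tuple[VolumeGrid, list[np.ndarray]]:
    """Place bright single-slice lesions inside a vascular territory.

    Each lesion is a connected in-plane (8-connected) blob of
    ``lesion_size`` voxels at ``intensity`` HU; lesions are pairwise
    separated by more than one voxel so they stay distinct components.
    Returns the modified CT and, per lesion, the (n,3) voxel index array.
    """
    territory_mask = np.asarray(territory_mask, dtype=bool)
    if not territory_mask.any():
        raise ValueError("territory mask is empty")
    if intensity <= CALCIUM_HU:
        raise ValueError(f"lesion intensity must exceed {CALCIUM_HU} HU")
    if n_lesions == 0:
        return ct, []
    rng = np.random.default_rng(0) if rng is None else rng

    values = ct.values.copy()
    occupied = np.zeros(ct.shape, dtype=bool)
    lesions: list[np.ndarray] = []
    for _ in range(n_lesions):
        placed = False
        for _attempt in range(200):
            candidates = np.argwhere(territory_mask & ~ndimage.binary_dilation(occupied, iterations=2))
            if len(candidates) == 0:
                break
            seed = candidates[rng.integers(len(candidates))]
            blob = _grow_blob(seed, lesion_size, territory_mask, occupied, rng)
            if blob is not None:
                lesions.append(blob)
                occupied[tuple(blob.T)] = True
                values[tuple(blob.T)] = intensity
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not fit {n_lesions} lesions of {lesion_size} voxels in the territory"
            )
    return ct.like(values), lesions


def _grow_blob(seed, size, territory, occupied, rng) -> np.ndarray | None:
    """Grow an in-plane 8-connected blob from a seed voxel; None if stuck."""
    forbidden = ndimage.binary_dilation(occupied, iterations=2)
    blob = {tuple(seed)}
    frontier = [tuple(seed)]
    while len(blob) < size and frontier:
        base = frontier[int(rng.integers(len(frontier)))]
        neigh = [
            (base[0], base[1] + dr, base[2] + dc)
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dr, dc) != (0, 0)
        ]
        added = False
        for v in (neigh[i] for i in rng.permutation(len(neigh))):
            if (
                v not in blob
                and all(0 <= v[i] < territory.shape[i] for i in range(3))
                and territory[v]
                and not forbidden[v]
            ):
                blob.add(v)
                frontier.append(v)
                added = True
                break
        if not added:
            frontier.remove(base)
    if len(blob) < size:
        return None
    return np.array(sorted(blob))


def perturb_mask(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A second 'rater': seeded boundary perturbation of a depot mask.

    Flips a fraction of the in-plane boundary voxels (outward additions
    and inward removals, ~15% each), emulating interobserver segmentation
    variability without displacing the depot.  Never returns an empty
    mask.
    """
    mask = np.asarray(mask, dtype=bool)
    struct = np.zeros((1, 3, 3), dtype=bool)
    struct[0] = [[0, 1, 0], [1, 1, 1], [0, 1, 0]]
    out = mask.copy()
    boundary_out = ndimage.binary_dilation(mask, structure=struct) & ~mask
    boundary_in = mask & ~ndimage.binary_erosion(mask, structure=struct)
    for coords, flip_to in ((np.argwhere(boundary_out), True), (np.argwhere(boundary_in), False)):
        if len(coords):
            pick = rng.random(len(coords)) < 0.15
            sel = coords[pick]
            out[tuple(sel.T)] = flip_to
    if not out.any():
        return mask.copy()
    return out


def truth_table(patients: list[PhantomPatient]) -> pd.DataFrame:
    """Per-depot truth as a tidy table (the cohort's label CSV schema)."""
    rows = []
    for p in patients:
        for d in p.depots:
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "depot_id": d.depot_id,
                    "region": d.region,
                    "laterality": d.laterality,
                    "bat_flag": bool(p.truth.depot_bat[d.depot_id]),
                }
            )
    return pd.DataFrame(rows)


def write_cohort(patients: list[PhantomPatient], outdir: str, spec: PhantomSpec | None = None) -> None:
    """Export a cohort as NIfTI volumes/masks plus CSV truth tables."""
    os.makedirs(outdir, exist_ok=True)
    if spec is not None:
        spec.to_json(os.path.join(outdir, "phantom_spec.json"))
    truth_table(patients).to_csv(os.path.join(outdir, "truth.csv"), index=False)
    for p in patients:
        pdir = os.path.join(outdir, p.patient_id)
        os.makedirs(pdir, exist_ok=True)
        save_volume(p.ct, os.path.join(pdir, "ct.nii.gz"))
        save_volume(p.pet, os.path.join(pdir, "pet.nii.gz"))
        for d in p.depots:
            save_mask(d.mask, p.ct.spacing, os.path.join(pdir, f"{d.depot_id}_{d.region}_{d.laterality}.nii.gz"))
        for name, m in p.territories.items():
            save_mask(m, p.ct.spacing, os.path.join(pdir, f"territory_{name}.nii.gz"))
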