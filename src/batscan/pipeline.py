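"""End-to-end study analogue.

simulate -> BARCIST label -> extract (two segmentations) -> select ->
7:3 depot split -> train SVM -> Youden cutoff -> depot & patient calls ->
Agatston calcium by radiomics group -> diagnostic summaries, all from one
seeded config.  The manifest collects every summary plus the seeds and
sizes needed to reproduce the run.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import calcium as ca
from .barcist import label_table
from .evaluation import diagnostics, group_compare
from .features import extract_table, feature_columns
from .grid import DepotROI
from .phantom import PhantomSpec, generate_cohort, perturb_mask, truth_table
from .preprocess import PreprocessConfig
from .scoring import DepotScoreModel, call_cohort
from .selection import SelectionReport, select_features


@dataclass
class RunConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    icc_threshold: float = 0.80
    r_threshold: float = 0.90
    train_fraction: float = 0.7
    cv_folds: int = 5
    criterion: int = 2
    seed: int = 0
    n_external_patients: int = 0          # per external site; 0 disables
    external_hu_shift: float = 5.0        # site effect on WAT mean HU
    outdir: str | None = None

    def validate(self) -> None:
        self.phantom.validate()
        self.preprocess.validate()
        for t in (self.icc_threshold, self.r_threshold, self.train_fraction):
            if not 0.0 < t < 1.0:
                raise ValueError("thresholds and split fraction must lie in (0,1)")
        if self.criterion not in (1, 2):
            raise ValueError("criterion must be 1 or 2")


def split_cohorts(depot_ids, labels, train_fraction: float = 0.7, seed: int = 0):
    """Stratified depot-level train / internal-validation split."""
    depot_ids = np.asarray(depot_ids)
    labels = np.asarray(labels).astype(int)
    if min((labels == 1).sum(), (labels == 0).sum()) < 2:
        raise ValueError("too few depots per class to split")
    train_ids, val_ids = train_test_split(
        depot_ids, train_size=train_fraction, stratify=labels, random_state=seed
    )
    return set(train_ids.tolist()), set(val_ids.tolist())


def _cohort_tables(patients, config: RunConfig, rater2: bool, rng: np.random.Generator):
    """Labels plus rater-1 (and optionally rater-2) feature tables."""
    ct = {p.patient_id: p.ct for p in patients}
    pet = {p.patient_id: p.pet for p in patients}
    rois = [d for p in patients for d in p.depots]
    labels = label_table(ct, pet, rois)
    feats1 = extract_table(ct, rois, config.preprocess)
    feats2 = None
    if rater2:
        rois2 = [
            DepotROI(perturb_mask(d.mask, rng), d.region, d.laterality, d.patient_id, d.depot_id)
            for d in rois
        ]
        feats2 = extract_table(ct, rois2, config.preprocess)
    return labels, feats1, feats2


def _depot_calls(model: DepotScoreModel, feats: pd.DataFrame, names) -> pd.DataFrame:
    out = feats[["patient_id", "depot_id", "region", "laterality"]].copy()
    rs = model.radiomics_score(feats[list(names)].to_numpy(float))
    out["radiomics_score"] = rs
    out["positive"] = rs > model.cutoff_
    return out


def _patient_truth(labels: pd.DataFrame) -> pd.Series:
    return labels.groupby("patient_id")["bat_flag"].any()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the manifest dictionary."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    manifest: dict = {"seed": config.seed, "stages": []}

    def stage(name):
        manifest["stages"].append(name)

    # ---- simulate + reference-standard labels + features -----------------
    stage("simulate")
    dev_patients = generate_cohort(config.phantom)
    stage("label+extract")
    labels, feats1, feats2 = _cohort_tables(dev_patients, config, rater2=True, rng=rng)
    y = labels["bat_flag"].to_numpy(bool)
    names_all = feature_columns(feats1)
    manifest["n_patients"] = len(dev_patients)
    manifest["n_depots"] = len(labels)
    manifest["n_bat_depots"] = int(y.sum())
    manifest["n_features"] = len(names_all)

    # ---- 7:3 depot split -------------------------------------------------
    stage("split")
    train_ids, val_ids = split_cohorts(labels["depot_id"], y, config.train_fraction, config.seed)
    in_train = labels["depot_id"].isin(train_ids).to_numpy()

    # ---- selection cascade on the training depots ------------------------
    stage("select")
    report = select_features(
        feats1[in_train], feats2[in_train], y[in_train], names_all,
        config.icc_threshold, config.r_threshold, config.cv_folds, config.seed,
    )
    manifest["selection"] = {
        "post_icc": report.n_post_icc, "post_prune": report.n_post_prune,
        "final": report.n_final, "lasso_alpha": report.lasso_alpha,
        "final_features": report.final_features,
    }

    # ---- train + cutoff --------------------------------------------------
    stage("train")
    model = DepotScoreModel(random_state=config.seed, feature_names=report.final_features)
    model.fit(feats1.loc[in_train, report.final_features].to_numpy(float), y[in_train].astype(int))
    manifest["cutoff"] = float(model.cutoff_)
    manifest["youden_j"] = float(model.youden_j_)

    # ---- depot-level diagnostics ----------------------------------------
    stage("score")
    calls = _depot_calls(model, feats1, report.final_features)
    summaries = {}
    for cohort, mask in (("training", in_train), ("internal_validation", ~in_train)):
        s = diagnostics(calls.loc[mask, "positive"].to_numpy(int), y[mask].astype(int),
                        calls.loc[mask, "radiomics_score"].to_numpy(), "depot", cohort)
        summaries[f"depot/{cohort}"] = s

    # ---- patient-level criteria on the development cohort ----------------
    stage("diagnose")
    pt_truth = _patient_truth(labels)
    pt_calls = call_cohort(calls).set_index("patient_id")
    pt_truth = pt_truth.loc[pt_calls.index]
    for crit in (1, 2):
        s = diagnostics(pt_calls[f"criterion{crit}_positive"].to_numpy(int),
                        pt_truth.to_numpy(int), None, "patient", f"development/criterion{crit}")
        summaries[f"patient/criterion{crit}"] = s

    # ---- external validation cohorts ------------------------------------
    if config.n_external_patients > 0:
        stage("external")
        for site in (1, 2):
            spec = PhantomSpec(**{**asdict(config.phantom),
                                  "n_patients": config.n_external_patients,
                                  "wat_mean_hu": config.phantom.wat_mean_hu + config.external_hu_shift,
                                  "rng_seed": config.phantom.rng_seed + 1000 * site})
            ext = generate_cohort(spec)
            ext_labels, ext_feats, _ = _cohort_tables(ext, config, rater2=False, rng=rng)
            ey = ext_labels["bat_flag"].to_numpy(bool)
            ecalls = _depot_calls(model, ext_feats, report.final_features)
            summaries[f"depot/external{site}"] = diagnostics(
                ecalls["positive"].to_numpy(int), ey.astype(int),
                ecalls["radiomics_score"].to_numpy(), "depot", f"external{site}")
            ept_truth = _patient_truth(ext_labels)
            ept_calls = call_cohort(ecalls).set_index("patient_id")
            summaries[f"patient/external{site}/criterion{config.criterion}"] = diagnostics(
                ept_calls[f"criterion{config.criterion}_positive"].to_numpy(int),
                ept_truth.loc[ept_calls.index].to_numpy(int), None,
                "patient", f"external{site}/criterion{config.criterion}")

    # ---- calcium by radiomics group --------------------------------------
    stage("calcium")
    rs_group = pt_calls[f"criterion{config.criterion}_positive"]
    calcium_results = {"BAT-RS": {"CAC": [], "TAC": []}, "non-BAT-RS": {"CAC": [], "TAC": []}}
    for p in dev_patients:
        group = "BAT-RS" if bool(rs_group.get(p.patient_id, False)) else "non-BAT-RS"
        for terr, mask in p.territories.items():
            calcium_results[group][terr].append(ca.score_territory(p.ct, mask, terr))
    calcium_summary = {}
    for terr in ("CAC", "TAC"):
        by_group = {g: calcium_results[g][terr] for g in calcium_results if calcium_results[g][terr]}
        if len(by_group) == 2:
            table = ca.territory_compare(by_group)
            pos = {g: np.array([r.positive for r in res], dtype=int)
                   for g, res in by_group.items()}
            test = group_compare(pos["BAT-RS"], pos["non-BAT-RS"], kind="categorical")
            calcium_summary[terr] = {
                "incidence": {g: float(v) for g, v in zip(table["group"], table["incidence"])},
                "test": test.test, "p_value": test.p_value,
            }
    manifest["calcium"] = calcium_summary

    # ---- manifest --------------------------------------------------------
    manifest["diagnostics"] = {
        key: {m: list(map(float, v)) for m, v in s.metrics.items()} for key, s in summaries.items()
    }
    manifest["summaries"] = summaries
    manifest["selection_report"] = report
    manifest["model"] = model
    manifest["depot_calls"] = calls
    manifest["patient_calls"] = pt_calls.reset_index()
    manifest["features"] = feats1
    manifest["labels"] = labels

    if config.outdir:
        _write_artifacts(manifest, config)
    return manifest


def _write_artifacts(manifest: dict, config: RunConfig) -> None:
    out = config.outdir
    os.makedirs(out, exist_ok=True)
    manifest["features"].to_csv(os.path.join(out, "features.csv"), index=False)
    manifest["labels"].to_csv(os.path.join(out, "labels.csv"), index=False)
    manifest["depot_calls"].to_csv(os.path.join(out, "depot_calls.csv"), index=False)
    manifest["patient_calls"].to_csv(os.path.join(out, "patient_calls.csv"), index=False)
    manifest["selection_report"].to_frame().to_csv(os.path.join(out, "selection.csv"), index=False)
    manifest["selection_report"].to_json(os.path.join(out, "selection.json"))
    manifest["model"].to_json(os.path.join(out, "model.json"))
    pd.concat([s.to_frame() for s in manifest["summaries"].values()]).to_csv(
        os.path.join(out, "diagnostics.csv"), index=False)
    lean = {k: v for k, v in manifest.items()
            if k in ("seed", "stages", "n_patients", "n_depots", "n_bat_depots",
                     "n_features", "selection", "cutoff", "youden_j", "calcium",
                     "diagnostics")}
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(lean, fh, indent=2)
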