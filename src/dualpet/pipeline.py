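"""Pipeline orchestration: simulate -> extract -> analyze -> model.

Each stage reads and writes plain CSV/JSON/NIfTI files in a working
directory and records a manifest (config hash, package version, seed,
output checksums, warnings) so that silent changes in intermediate tables
are detectable and reruns with the same config and inputs are
byte-reproducible.  The thin ``dualpet`` command-line interface in
:mod:`dualpet.cli` wraps these functions; they are equally usable from
Python.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .concordance import (
    adjudicate_concordance,
    classify_site,
    flag_spleen,
    label_components,
    overlap_matrix,
    threshold_segment,
)
from .errors import ConfigurationError, GridMismatchError
from .features import (
    CLINICAL_COLUMNS,
    aggregate_patient,
    imaging_feature_columns,
    lesion_metrics,
    sdmax,
    spleen_reference,
)
from .models import CVConfig, cross_validated_attribution, survival_to_binary
from .stats import (
    contingency_test,
    dichotomize_median,
    event_rate_hr,
    km_fit,
    logrank,
    welch_test,
)
from .synthetic import SynthConfig, generate_cohort
from .volume import read_volume, write_volume

log = logging.getLogger("dualpet")

COHORT_COLUMNS = [
    "patient_id", "age", "sex", "height_cm", "weight_kg", "bmi",
    "highrisk_cytogenetics", "b2m_mg_l", "disease_duration_months",
    "response", "os_days", "os_event",
]
BINARY_FEATURES = ("sex", "highrisk_cytogenetics")


@dataclass
class PipelineConfig:
    """All method-level adjudication choices in one auditable place."""

    concordance_threshold: float = 0.10
    concordance_strict: bool = True  # concordant iff overlap fraction strictly > threshold
    overlap_denominator: str = "min"
    bone_threshold: float = 0.10
    bone_strict: bool = False  # medullary iff bone overlap >= threshold
    connectivity: int = 26
    segment_suv_threshold: float = 2.5
    use_provided_masks: bool = True
    bsa_formula: str = "dubois"
    hr_method: str = "person_time"
    horizon_days: float = 183.0
    analysis_unit: str = "cycle"
    seed: int = 0
    cv: CVConfig = field(default_factory=CVConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)

    def __post_init__(self) -> None:
        for name in ("concordance_threshold", "bone_threshold"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ConfigurationError(f"{name} must lie in (0, 1), got {v}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "cv" in kwargs:
            kwargs["cv"] = CVConfig(**kwargs["cv"])
        if "synth" in kwargs:
            kwargs["synth"] = SynthConfig(**kwargs["synth"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("grid_shape", "voxel_spacing_mm", "lesions_per_patient_range",
                    "lesion_radius_mm_range"):
            d["synth"][key] = list(d["synth"][key])
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(stage: str, out_dir: Path, config: PipelineConfig,
                   files: list[Path], warnings: list[str]) -> Path:
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config.to_yaml().encode()).hexdigest(),
        "outputs": {f.name: _sha256(f) for f in files},
        "warnings": warnings,
    }
    path = Path(out_dir) / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

_TRACER_FILE = {"FDG": "fdg", "CXCR4": "cxcr4"}


def run_simulate(config: PipelineConfig, out_dir) -> Path:
    """Generate a synthetic cohort and write volumes + tables to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    synth = dataclasses.replace(config.synth, seed=config.seed)
    patients = generate_cohort(synth, render=True)
    cohort_rows, truth_feat_rows, truth_lesion_frames = [], [], []
    files: list[Path] = []
    for p in patients:
        for tracer, tag in _TRACER_FILE.items():
            f1 = out / f"{p.patient_id}_{tag}_pet.nii.gz"
            f2 = out / f"{p.patient_id}_{tag}_mask.nii.gz"
            write_volume(p.volumes[tracer], f1)
            write_volume(p.lesion_masks[tracer], f2)
            files += [f1, f2]
        for name, vol in (("bone", p.bone_mask), ("spleen", p.spleen_mask), ("body", p.body_mask)):
            f = out / f"{p.patient_id}_{name}.nii.gz"
            write_volume(vol, f)
            files.append(f)
        cohort_rows.append({"patient_id": p.patient_id, **p.clinical,
                            **{k: p.outcome[k] for k in ("response", "os_days", "os_event")}})
        truth_feat_rows.append({"patient_id": p.patient_id, **p.truth_features,
                                "lp_response": p.outcome["lp_response"],
                                "lp_survival": p.outcome["lp_survival"]})
        tl = p.truth_lesions.copy()
        tl.insert(0, "patient_id", p.patient_id)
        truth_lesion_frames.append(tl)
    cohort = pd.DataFrame(cohort_rows)[COHORT_COLUMNS]
    cohort.to_csv(out / "cohort.csv", index=False)
    pd.DataFrame(truth_feat_rows).to_csv(out / "truth_features.csv", index=False)
    pd.concat(truth_lesion_frames, ignore_index=True).to_csv(out / "truth_lesions.csv", index=False)
    files += [out / "cohort.csv", out / "truth_features.csv", out / "truth_lesions.csv"]
    log.info("simulate: wrote %d units to %s", len(patients), out)
    return write_manifest("simulate", out, config, files, [])


# ---------------------------------------------------------------------------
# extract
# ---------------------------------------------------------------------------


def _unit_paths(data_dir: Path, unit: str) -> dict:
    paths = {
        "fdg_pet": data_dir / f"{unit}_fdg_pet.nii.gz",
        "cxcr4_pet": data_dir / f"{unit}_cxcr4_pet.nii.gz",
        "fdg_mask": data_dir / f"{unit}_fdg_mask.nii.gz",
        "cxcr4_mask": data_dir / f"{unit}_cxcr4_mask.nii.gz",
        "bone": data_dir / f"{unit}_bone.nii.gz",
        "spleen": data_dir / f"{unit}_spleen.nii.gz",
        "body": data_dir / f"{unit}_body.nii.gz",
    }
    missing = [p.name for p in paths.values() if not p.exists()]
    if missing:
        raise FileNotFoundError(f"unit {unit}: missing input files {missing}")
    return paths


def extract_unit(config: PipelineConfig, volumes: dict) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Lesion table, pair table and patient feature dict for one unit.

    ``volumes`` maps the keys of :func:`_unit_paths` to ScalarVolumes.
    Lesions are quantified per tracer on that tracer's PET grid; overlap is
    adjudicated on the FDG grid after propagating the CXCR4 mask.
    """
    lesion_sets, rows = {}, []
    for tracer, pet_key, mask_key in (("FDG", "fdg_pet", "fdg_mask"),
                                      ("CXCR4", "cxcr4_pet", "cxcr4_mask")):
        pet = volumes[pet_key]
        if config.use_provided_masks:
            mask = volumes[mask_key]
        else:
            mask = threshold_segment(pet, config.segment_suv_threshold, volumes["body"])
        lesion_sets[tracer] = label_components(mask, pet, tracer, config.connectivity)

    fdg, cx = lesion_sets["FDG"], lesion_sets["CXCR4"]
    if not cx.labels.same_grid(fdg.labels):
        raise GridMismatchError(
            "CXCR4 and FDG volumes are on different grids; propagate the masks onto "
            "a common grid first (see dualpet.volume.resample_mask)"
        )
    pairs = overlap_matrix(fdg, cx)
    table = adjudicate_concordance(
        pairs, fdg, cx,
        threshold=config.concordance_threshold,
        denominator=config.overlap_denominator,
        strict=config.concordance_strict,
    )
    for tracer, lset, pet_key in (("FDG", fdg, "fdg_pet"), ("CXCR4", cx, "cxcr4_pet")):
        bone = volumes["bone"]
        spleen = volumes["spleen"]
        pet = volumes[pet_key]
        for les in lset.lesions:
            m = lesion_metrics(les, pet)
            rows.append({
                "tracer": tracer,
                "lesion_id": les.label,
                "n_voxels": les.n_voxels,
                "volume_ml": les.volume_ml,
                "centroid_x_mm": les.centroid_mm[0],
                "centroid_y_mm": les.centroid_mm[1],
                "centroid_z_mm": les.centroid_mm[2],
                "category": table.category[(tracer, les.label)],
                "site": classify_site(les, bone, threshold=config.bone_threshold,
                                      strict=config.bone_strict),
                "in_spleen": flag_spleen(les, spleen),
                "suv_mean": m.suv_mean,
                "suv_max": m.suv_max,
                "mtv_ml": m.mtv_ml,
            })
    lesion_table = pd.DataFrame(rows, columns=[
        "tracer", "lesion_id", "n_voxels", "volume_ml", "centroid_x_mm", "centroid_y_mm",
        "centroid_z_mm", "category", "site", "in_spleen", "suv_mean", "suv_max", "mtv_ml",
    ])
    feats = aggregate_patient(lesion_table)
    counts = table.counts()
    feats["spleen_SUVmean"] = spleen_reference(
        volumes["fdg_pet"], volumes["spleen"],
        [dataclasses.replace(ls.labels, units="binary",
                             values=(ls.labels.values > 0).astype(np.uint8))
         for ls in lesion_sets.values()],
    )
    return lesion_table, table.pairs, {"features": feats, "counts": counts}


def run_extract(config: PipelineConfig, data_dir, out_dir) -> Path:
    """Extract lesion/pair tables and the patient feature matrix for a cohort."""
    data_dir, out = Path(data_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = pd.read_csv(data_dir / "cohort.csv")
    lesion_frames, pair_frames, feat_rows, warnings = [], [], [], []
    for _, unit_row in cohort.iterrows():
        unit = unit_row["patient_id"]
        paths = _unit_paths(data_dir, unit)
        volumes = {k: read_volume(p) for k, p in paths.items()}
        lesions, pairs, res = extract_unit(config, volumes)
        feats = res["features"]
        for df, acc in ((lesions, lesion_frames), (pairs, pair_frames)):
            df = df.copy()
            df.insert(0, "patient_id", unit)
            acc.append(df)
        n_lesions = len(lesions)
        if n_lesions == 0:
            warnings.append(f"{unit}: zero lesions; intensity features missing")
        log.info("extract %s: %d lesions, categories %s", unit, n_lesions, res["counts"])
        for tracer in ("FDG", "CXCR4"):
            sub = lesions[lesions["tracer"] == tracer]
            cents = sub[["centroid_x_mm", "centroid_y_mm", "centroid_z_mm"]].to_numpy()
            feats[f"sDmax_{tracer}"] = sdmax(
                cents, unit_row["height_cm"], unit_row["weight_kg"], config.bsa_formula
            )
        row = {"patient_id": unit, **feats}
        row.update({k: unit_row[k] for k in CLINICAL_COLUMNS})
        row.update({k: unit_row[k] for k in ("response", "os_days", "os_event")})
        feat_rows.append(row)
    cols = ["patient_id"] + imaging_feature_columns() + list(CLINICAL_COLUMNS) + [
        "response", "os_days", "os_event"]
    features = pd.DataFrame(feat_rows)[cols]
    lesion_table = pd.concat(lesion_frames, ignore_index=True) if lesion_frames else pd.DataFrame()
    pair_table = pd.concat(pair_frames, ignore_index=True) if pair_frames else pd.DataFrame()
    lesion_table.to_csv(out / "lesion_table.csv", index=False)
    pair_table.to_csv(out / "pair_table.csv", index=False)
    features.to_csv(out / "features.csv", index=False)
    files = [out / "lesion_table.csv", out / "pair_table.csv", out / "features.csv"]
    return write_manifest("extract", out, config, files, warnings)


# ---------------------------------------------------------------------------
# analyze
# ---------------------------------------------------------------------------


def analysis_feature_columns(features: pd.DataFrame) -> list[str]:
    cols = imaging_feature_columns() + list(CLINICAL_COLUMNS)
    return [c for c in cols if c in features.columns]


def run_analyze(config: PipelineConfig, features_csv, out_dir) -> Path:
    """Univariate program: Welch/contingency vs response, KM/log-rank vs OS."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(features_csv)
    warnings: list[str] = []
    resp_rows, surv_rows, km_rows = [], [], []
    responders = df["response"] == 1
    for col in analysis_feature_columns(df):
        x = df.loc[responders, col].to_numpy(dtype=float)
        y = df.loc[~responders, col].to_numpy(dtype=float)
        if col in BINARY_FEATURES:
            tab = np.array([
                [np.nansum(x == 1), np.nansum(x == 0)],
                [np.nansum(y == 1), np.nansum(y == 0)],
            ])
            try:
                r = contingency_test(tab)
                resp_rows.append({"feature": col, "kind": "binary", "estimate": r.odds_ratio,
                                  "ci_low": r.or_ci95[0], "ci_high": r.or_ci95[1],
                                  "p": r.p, "method": r.method,
                                  "n_responder": int(np.isfinite(x).sum()),
                                  "n_nonresponder": int(np.isfinite(y).sum())})
            except Exception as exc:
                warnings.append(f"{col}: contingency skipped ({exc})")
            continue
        vals = df[col].to_numpy(dtype=float)
        if np.nanstd(vals) == 0 or np.isfinite(vals).sum() < 4:
            warnings.append(f"{col}: constant or insufficient data; skipped")
            continue
        try:
            r = welch_test(x, y)
        except Exception as exc:
            warnings.append(f"{col}: welch skipped ({exc})")
            continue
        resp_rows.append({"feature": col, "kind": "continuous", "estimate": r.mean_diff,
                          "ci_low": r.ci95[0], "ci_high": r.ci95[1], "p": r.p_two_sided,
                          "method": "welch", "hedges_g": r.hedges_g,
                          "g_ci_low": r.g_ci95[0], "g_ci_high": r.g_ci95[1],
                          "n_responder": r.n_x, "n_nonresponder": r.n_y})
        # survival by median split of the same feature
        if df["os_event"].sum() == 0:
            continue
        groups = dichotomize_median(df[col])
        hi_mask, lo_mask = (groups == "high").to_numpy(), (groups == "low").to_numpy()
        if hi_mask.sum() == 0 or lo_mask.sum() == 0:
            warnings.append(f"{col}: degenerate median split; survival skipped")
            continue
        t_hi, e_hi = df.loc[hi_mask, "os_days"], df.loc[hi_mask, "os_event"]
        t_lo, e_lo = df.loc[lo_mask, "os_days"], df.loc[lo_mask, "os_event"]
        chi2, p = logrank(t_hi, e_hi, t_lo, e_lo)
        hr, (hr_lo, hr_hi) = event_rate_hr(t_hi, e_hi, t_lo, e_lo, config.hr_method)
        surv_rows.append({"feature": col, "hr": hr, "hr_ci_low": hr_lo, "hr_ci_high": hr_hi,
                          "logrank_chi2": chi2, "logrank_p": p,
                          "n_high": int(hi_mask.sum()), "n_low": int(lo_mask.sum())})
        for gname, t, e in (("high", t_hi, e_hi), ("low", t_lo, e_lo)):
            if e.sum() == 0:
                continue
            kf = km_fit(t, e).to_frame()
            kf.insert(0, "group", gname)
            kf.insert(0, "feature", col)
            km_rows.append(kf)
    if df["os_event"].sum() == 0:
        warnings.append("no events in cohort; survival stage abstained")
    resp_cols = ["feature", "kind", "estimate", "ci_low", "ci_high", "p", "method",
                 "hedges_g", "g_ci_low", "g_ci_high", "n_responder", "n_nonresponder"]
    surv_cols = ["feature", "hr", "hr_ci_low", "hr_ci_high", "logrank_chi2",
                 "logrank_p", "n_high", "n_low"]
    km_cols = ["feature", "group", "time", "survival", "ci_low", "ci_high",
               "n_at_risk", "n_events"]
    pd.DataFrame(resp_rows, columns=resp_cols if not resp_rows else None).to_csv(
        out / "univariate_response.csv", index=False)
    pd.DataFrame(surv_rows, columns=surv_cols if not surv_rows else None).to_csv(
        out / "univariate_survival.csv", index=False)
    km = pd.concat(km_rows, ignore_index=True) if km_rows else pd.DataFrame(columns=km_cols)
    km.to_csv(out / "km_curves.csv", index=False)
    files = [out / "univariate_response.csv", out / "univariate_survival.csv", out / "km_curves.csv"]
    return write_manifest("analyze", out, config, files, warnings)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


def _report_json(report, excluded: int) -> dict:
    table = report.table.reset_index()
    return {
        "n_explained": report.n_explained,
        "excluded_units": excluded,
        "fold_metrics": {
            "mean_auroc": float(np.nanmean(report.fold_metrics["auroc"])),
            "mean_balanced_accuracy": float(report.fold_metrics["balanced_accuracy"].mean()),
        },
        "features": [
            {
                "feature": row["feature"],
                "mean_abs_shap": float(row["mean_abs_shap"]),
                "rank": int(row["rank"]),
                "direction": float(row["direction"]),
                "sign_agreement": None if pd.isna(row["sign_agreement"])
                else float(row["sign_agreement"]),
                "stable": bool(row["stable"]) if pd.notna(row["sign_agreement"]) else False,
            }
            for _, row in table.iterrows()
        ],
    }


def run_model(config: PipelineConfig, features_csv, out_dir) -> Path:
    """Decision-tree + SHAP reports for response and 6-month survival."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(features_csv)
    X = df[analysis_feature_columns(df)]
    cv = dataclasses.replace(config.cv, seed=config.seed)
    warnings: list[str] = []
    files: list[Path] = []

    y_resp = df["response"].to_numpy(dtype=int)
    rep = cross_validated_attribution(X, y_resp, cv)
    (out / "report_response.json").write_text(
        json.dumps(_report_json(rep, 0), indent=2))
    files.append(out / "report_response.json")

    labels, n_excl = survival_to_binary(df["os_days"], df["os_event"], config.horizon_days)
    keep = labels.notna()
    if n_excl:
        warnings.append(f"survival model: {n_excl} units censored before horizon excluded")
    y_surv = labels[keep].to_numpy(dtype=int)
    rep_s = cross_validated_attribution(X[keep.to_numpy()], y_surv, cv)
    (out / "report_survival6m.json").write_text(
        json.dumps(_report_json(rep_s, n_excl), indent=2))
    files.append(out / "report_survival6m.json")
    return write_manifest("model", out, config, files, warnings)


def run_report(out_dir) -> Path:
    """Collect stage outputs into one summary JSON."""
    out = Path(out_dir)
    summary: dict = {"package_version": __version__}
    for stage in ("simulate", "extract", "analyze", "model"):
        m = out / f"manifest_{stage}.json"
        if m.exists():
            summary[stage] = json.loads(m.read_text())
    path = out / "summary.json"
    path.write_text(json.dumps(summary, indent=2))
    return path
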