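"""Synthetic paired-tracer PET cohorts with known planted ground truth.

Every downstream stage of the pipeline is testable without patient data:
this module generates, per analysis unit, co-registered FDG and CXCR4
phantom volumes with spherical lesions, binary lesion masks per tracer,
anatomical masks (bone, spleen, body), clinical covariates, and outcomes
drawn from explicit response/survival models applied to the *planted*
feature values.  The planted truth (per-lesion category, site, size and
uptake; per-unit bracket features and linear predictors) is returned
alongside the images, so recovery tests never need to re-derive it.

Study-condition defaults are calibrated to the clinical cohort the
pipeline was designed around: 20-109 lesions per unit, ~40% concordant
lesions, ~40% extramedullary lesions, ~80% of discordant lesions visible
only on the CXCR4 tracer, and a baseline hazard giving a median overall
survival near 198 days.  Anatomy is a minimal body phantom - an
ellipsoidal body containing a spinal column, a pelvic slab, two femur
cylinders (the bone compartment) and a splenic ellipsoid - which is
sufficient to exercise site classification and the spleen reference, not
an attempt at realistic anatomy.

Concordant lesions are planted at a shared center with independently
jittered radii per tracer, so cross-tracer overlap fractions vary around
the adjudication threshold; discordant lesions exist in exactly one
tracer's mask and leave only background in the other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigurationError, PlacementError
from .features import (
    CLINICAL_COLUMNS,
    aggregate_patient,
    imaging_feature_columns,
    sdmax,
)
from .volume import ScalarVolume

__all__ = [
    "ResponseModel",
    "SurvivalModel",
    "SynthConfig",
    "SynthPatient",
    "generate_cohort",
    "cohort_feature_table",
    "plant_lesion",
    "sphere_support",
    "assign_outcomes",
    "simulate_group_difference",
    "simulate_survival_groups",
    "plant_response_effect",
]

#: median overall survival (days) of the calibration cohort
MEDIAN_OS_DAYS = 198.0


@dataclass
class ResponseModel:
    """Logistic response model on standardized planted features."""

    intercept: float = 0.0
    coefficients: dict[str, float] = field(
        default_factory=lambda: {
            "SUVmean[FDG medullary concordant]": -0.9,
            "SUVmean[FDG extramedullary concordant]": -0.9,
            "SUVmax[CXCR4 extramedullary discordant]": 0.5,
            "TLC[CXCR4 extramedullary discordant]": 0.4,
            "highrisk_cytogenetics": 0.4,
        }
    )


@dataclass
class SurvivalModel:
    """Exponential survival: hazard = baseline * exp(linear predictor).

    The default baseline is calibrated so that, under the default
    coefficient frailty (which shortens the marginal median relative to
    the baseline-exponential median), the cohort median overall survival
    lands at ~198 days.
    """

    baseline_hazard_per_day: float = math.log(2.0) / 210.0
    coefficients: dict[str, float] = field(
        default_factory=lambda: {
            "TLG[FDG medullary concordant]": 0.75,
            "sDmax_FDG": 0.5,
            "MTV[CXCR4 medullary concordant]": 0.5,
            "bmi": -0.3,
        }
    )

    def __post_init__(self) -> None:
        if self.baseline_hazard_per_day <= 0:
            raise ConfigurationError("survival_model.baseline_hazard_per_day must be > 0")


# per-tracer, per-category lognormal (mu, sigma) of lesion peak SUV
_DEFAULT_SUV_PARAMS = {
    "FDG": {"concordant": (1.5, 0.40), "FDG_only": (1.4, 0.40)},
    "CXCR4": {"concordant": (1.8, 0.45), "CXCR4_only": (1.7, 0.45)},
}


@dataclass
class SynthConfig:
    """Study conditions of the synthetic cohort.

    Fractions are per-unit means; per-unit values are drawn from a clipped
    normal with the corresponding ``*_scale`` spread (scale 0 pins every
    unit at the mean).
    """

    n_patients: int = 22
    grid_shape: tuple[int, int, int] = (64, 64, 96)
    voxel_spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    lesions_per_patient_range: tuple[int, int] = (20, 109)
    concordant_fraction_mean: float = 0.40
    concordant_fraction_scale: float = 0.18
    extramedullary_fraction_mean: float = 0.40
    extramedullary_fraction_scale: float = 0.15
    cxcr4_only_fraction: float = 0.795  # share of discordant lesions seen on CXCR4 only
    suv_params: dict = field(default_factory=lambda: {
        t: dict(c) for t, c in _DEFAULT_SUV_PARAMS.items()
    })
    background_suv: float = 1.0
    spleen_suv: dict = field(default_factory=lambda: {"FDG": 1.8, "CXCR4": 2.5})
    lesion_radius_mm_range: tuple[float, float] = (4.0, 9.0)
    radius_jitter: float = 0.15  # relative radius jitter between tracers (concordant)
    gaussian_taper: bool = False
    response_model: ResponseModel = field(default_factory=ResponseModel)
    survival_model: SurvivalModel = field(default_factory=SurvivalModel)
    censoring_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if len(self.grid_shape) != 3 or any(int(s) < 8 for s in self.grid_shape):
            raise ConfigurationError("grid_shape must be 3 ints, each >= 8")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ConfigurationError("voxel_spacing_mm must be positive")
        lo, hi = self.lesions_per_patient_range
        if lo < 0 or hi < lo:
            raise ConfigurationError("lesions_per_patient_range must be 0 <= lo <= hi")
        for name in ("concordant_fraction_mean", "extramedullary_fraction_mean",
                     "cxcr4_only_fraction", "censoring_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        rlo, rhi = self.lesion_radius_mm_range
        if rlo <= 0 or rhi < rlo:
            raise ConfigurationError("lesion_radius_mm_range must be 0 < lo <= hi")
        if min(self.lesion_radius_mm_range) < min(self.voxel_spacing_mm) / 2.0:
            # radii below half a voxel degenerate to single-voxel lesions; allowed
            pass
        if self.background_suv < 0:
            raise ConfigurationError("background_suv must be >= 0")

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape) * np.asarray(self.voxel_spacing_mm)


# ---------------------------------------------------------------------------
# analytic body phantom geometry
# ---------------------------------------------------------------------------


class _Phantom:
    """Analytic in/out predicates for the body phantom, in physical mm."""

    def __init__(self, config: SynthConfig):
        ext = config.extent_mm
        self.center = ext / 2.0
        self.body_semi = np.array([0.39 * ext[0], 0.39 * ext[1], 0.458 * ext[2]])
        self.spine_half = np.array([0.0625 * ext[0], 0.0625 * ext[1]])
        self.spine_z = (0.156 * ext[2], 0.859 * ext[2])
        self.pelvis_half = np.array([0.219 * ext[0], 0.094 * ext[1]])
        self.pelvis_z = (0.104 * ext[2], 0.208 * ext[2])
        self.femur_x = (self.center[0] - 0.156 * ext[0], self.center[0] + 0.156 * ext[0])
        self.femur_r = 0.055 * ext[0]
        self.femur_z = (0.042 * ext[2], 0.182 * ext[2])
        self.spleen_center = self.center + np.array([0.215 * ext[0], -0.098 * ext[1], 0.151 * ext[2]])
        self.spleen_semi = np.array([0.086 * ext[0], 0.070 * ext[1], 0.073 * ext[2]])

    def in_body(self, p: np.ndarray) -> np.ndarray:
        q = (p - self.center) / self.body_semi
        return (q**2).sum(axis=-1) <= 1.0

    def _in_spine(self, p):
        return (
            (np.abs(p[..., 0] - self.center[0]) <= self.spine_half[0])
            & (np.abs(p[..., 1] - self.center[1]) <= self.spine_half[1])
            & (p[..., 2] >= self.spine_z[0])
            & (p[..., 2] <= self.spine_z[1])
        )

    def _in_pelvis(self, p):
        return (
            (np.abs(p[..., 0] - self.center[0]) <= self.pelvis_half[0])
            & (np.abs(p[..., 1] - self.center[1]) <= self.pelvis_half[1])
            & (p[..., 2] >= self.pelvis_z[0])
            & (p[..., 2] <= self.pelvis_z[1])
        )

    def _in_femur(self, p):
        hit = np.zeros(p.shape[:-1], dtype=bool)
        for fx in self.femur_x:
            r2 = (p[..., 0] - fx) ** 2 + (p[..., 1] - self.center[1]) ** 2
            hit |= (r2 <= self.femur_r**2) & (p[..., 2] >= self.femur_z[0]) & (
                p[..., 2] <= self.femur_z[1]
            )
        return hit

    def in_bone(self, p: np.ndarray) -> np.ndarray:
        return self._in_spine(p) | self._in_pelvis(p) | self._in_femur(p)

    def in_spleen(self, p: np.ndarray) -> np.ndarray:
        q = (p - self.spleen_center) / self.spleen_semi
        return (q**2).sum(axis=-1) <= 1.0

    # -- samplers ---------------------------------------------------------
    def sample_bone_point(self, rng: np.random.Generator) -> np.ndarray:
        spine_vol = 4 * self.spine_half.prod() * (self.spine_z[1] - self.spine_z[0])
        pelvis_vol = 4 * self.pelvis_half.prod() * (self.pelvis_z[1] - self.pelvis_z[0])
        femur_vol = 2 * math.pi * self.femur_r**2 * (self.femur_z[1] - self.femur_z[0])
        total = spine_vol + pelvis_vol + femur_vol
        u = rng.random() * total
        if u < spine_vol:
            return np.array([
                self.center[0] + rng.uniform(-1, 1) * self.spine_half[0],
                self.center[1] + rng.uniform(-1, 1) * self.spine_half[1],
                rng.uniform(*self.spine_z),
            ])
        if u < spine_vol + pelvis_vol:
            return np.array([
                self.center[0] + rng.uniform(-1, 1) * self.pelvis_half[0],
                self.center[1] + rng.uniform(-1, 1) * self.pelvis_half[1],
                rng.uniform(*self.pelvis_z),
            ])
        fx = self.femur_x[int(rng.integers(2))]
        while True:
            dx, dy = rng.uniform(-1, 1, 2) * self.femur_r
            if dx**2 + dy**2 <= self.femur_r**2:
                return np.array([fx + dx, self.center[1] + dy, rng.uniform(*self.femur_z)])

    def sample_soft_tissue_point(
        self, rng: np.random.Generator, margin_mm: float, max_tries: int = 2000
    ) -> np.ndarray:
        """Uniform point inside the body, outside bone, with a body margin."""
        semi = np.maximum(self.body_semi - margin_mm, 1.0)
        for _ in range(max_tries):
            p = self.center + rng.uniform(-1, 1, 3) * semi
            q = (p - self.center) / semi
            if (q**2).sum() > 1.0:
                continue
            # keep the planted sphere clear of bone so the site truth is clean
            probes = p + margin_mm * np.array(
                [[0, 0, 0], [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
            )
            if not self.in_bone(probes).any():
                return p
        return p  # fall back to the last candidate

    def render_masks(self, config: SynthConfig) -> dict[str, ScalarVolume]:
        idx = np.indices(config.grid_shape).reshape(3, -1).T
        pts = idx * np.asarray(config.voxel_spacing_mm)
        shape = tuple(config.grid_shape)
        out = {}
        for name, pred in (
            ("body", self.in_body),
            ("bone", self.in_bone),
            ("spleen", self.in_spleen),
        ):
            vals = pred(pts).reshape(shape).astype(np.uint8)
            out[name] = ScalarVolume(vals, config.voxel_spacing_mm, (0, 0, 0), "binary")
        # anatomy is defined inside the body
        out["bone"].values &= out["body"].values
        out["spleen"].values &= out["body"].values
        return out


# ---------------------------------------------------------------------------
# lesion rendering
# ---------------------------------------------------------------------------


def sphere_support(volume: ScalarVolume, center_mm, radius_mm: float) -> np.ndarray:
    """(n, 3) indices of voxel centers within ``radius_mm`` of the center.

    A radius smaller than half the smallest voxel pitch degenerates to the
    single voxel containing the center.
    """
    center = np.asarray(center_mm, dtype=float)
    spacing = np.asarray(volume.spacing_mm)
    origin = np.asarray(volume.origin_mm)
    nearest = np.round((center - origin) / spacing).astype(int)
    if np.any(nearest < 0) or np.any(nearest >= np.asarray(volume.shape)):
        raise PlacementError(f"lesion center {center} falls outside the voxel grid")
    lo = np.maximum(np.floor((center - radius_mm - origin) / spacing).astype(int), 0)
    hi = np.minimum(
        np.ceil((center + radius_mm - origin) / spacing).astype(int) + 1,
        np.asarray(volume.shape),
    )
    grids = np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1)
    d2 = ((idx * spacing + origin - center) ** 2).sum(axis=1)
    idx = idx[d2 <= radius_mm**2]
    if len(idx) == 0:
        idx = nearest[None, :]
    return idx


def plant_lesion(
    volume: ScalarVolume,
    center_mm,
    radius_mm: float,
    peak_suv: float,
    gaussian_taper: bool = False,
) -> ScalarVolume:
    """Add a spherical-support uptake blob to a PET volume.

    Uniform blobs take ``peak_suv`` on the whole support; Gaussian-tapered
    blobs decay with sigma = radius/2 inside the support.  Voxel values
    never drop below their previous value (lesions add uptake).
    """
    out = volume.copy()
    idx = sphere_support(volume, center_mm, radius_mm)
    if gaussian_taper:
        d2 = (
            (idx * np.asarray(volume.spacing_mm) + np.asarray(volume.origin_mm)
             - np.asarray(center_mm, dtype=float)) ** 2
        ).sum(axis=1)
        sigma = max(radius_mm / 2.0, 1e-6)
        blob = peak_suv * np.exp(-d2 / (2.0 * sigma**2))
    else:
        blob = np.full(len(idx), peak_suv)
    sel = tuple(idx.T)
    out.values = out.values.astype(float)
    out.values[sel] = np.maximum(out.values[sel], blob)
    return out


def _taper_mean(peak: float, radius: float) -> float:
    """Mean value of a Gaussian-tapered blob over its spherical support."""
    r = np.linspace(0, radius, 256)
    sigma = radius / 2.0
    w = r**2
    return float(peak * np.trapezoid(np.exp(-(r**2) / (2 * sigma**2)) * w, r)
                 / np.trapezoid(w, r))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass
class SynthPatient:
    """One synthetic analysis unit: images, masks, clinical data and truth."""

    patient_id: str
    clinical: dict
    outcome: dict
    truth_lesions: pd.DataFrame
    truth_features: dict
    volumes: dict | None = None  # tracer -> ScalarVolume (SUV)
    lesion_masks: dict | None = None  # tracer -> ScalarVolume (binary)
    bone_mask: ScalarVolume | None = None
    spleen_mask: ScalarVolume | None = None
    body_mask: ScalarVolume | None = None


def _clipped_normal(rng, mean, scale, lo=0.0, hi=1.0):
    if scale == 0:
        return float(mean)
    return float(np.clip(rng.normal(mean, scale), lo, hi))


def _draw_clinical(rng: np.random.Generator) -> dict:
    sex = int(rng.random() < 0.455)  # 1 = female
    height = float(rng.normal(165.0 if sex else 178.0, 7.0))
    bmi = float(np.clip(rng.normal(26.0, 4.0), 17.0, 45.0))
    weight = bmi * (height / 100.0) ** 2
    return {
        "age": float(np.clip(np.round(rng.normal(56.0, 8.0)), 30, 82)),
        "sex": sex,
        "height_cm": round(height, 1),
        "weight_kg": round(weight, 1),
        "bmi": round(bmi, 1),
        "highrisk_cytogenetics": int(rng.random() < 0.583),
        "b2m_mg_l": round(float(rng.lognormal(math.log(2.95), 0.6)), 2),
        "disease_duration_months": round(float(np.clip(rng.lognormal(math.log(49.5), 0.7), 1, 240)), 1),
    }


def _draw_lesions(rng: np.random.Generator, config: SynthConfig, phantom: _Phantom) -> pd.DataFrame:
    """Sample the planted per-lesion truth for one unit."""
    lo, hi = config.lesions_per_patient_range
    n = int(rng.integers(lo, hi + 1))
    cf = _clipped_normal(rng, config.concordant_fraction_mean, config.concordant_fraction_scale)
    ef = _clipped_normal(rng, config.extramedullary_fraction_mean, config.extramedullary_fraction_scale)
    rlo, rhi = config.lesion_radius_mm_range
    max_r = rhi * (1 + config.radius_jitter)
    # pad > sqrt(3) voxel pitch so rendered spheres can't touch even diagonally
    sep_pad = 2.0 * max(config.voxel_spacing_mm)
    rows = []
    placed: list[tuple[np.ndarray, float]] = []  # (center, radius) of accepted lesions
    for i in range(n):
        concordant = rng.random() < cf
        if concordant:
            category = "concordant"
        else:
            category = "CXCR4_only" if rng.random() < config.cxcr4_only_fraction else "FDG_only"
        site = "extramedullary" if rng.random() < ef else "medullary"
        base_r = float(rng.uniform(rlo, rhi))
        if concordant and config.radius_jitter > 0:
            r_fdg = base_r * (1 + rng.uniform(-config.radius_jitter, config.radius_jitter))
            r_cx = base_r * (1 + rng.uniform(-config.radius_jitter, config.radius_jitter))
        else:
            r_fdg = r_cx = base_r
        r_max = max(r_fdg if category != "CXCR4_only" else 0,
                    r_cx if category != "FDG_only" else 0)
        center = None
        for _ in range(120):
            cand = (
                phantom.sample_bone_point(rng)
                if site == "medullary"
                else phantom.sample_soft_tissue_point(rng, margin_mm=max_r + sep_pad)
            )
            ok = all(
                np.linalg.norm(cand - c0) > r_max + r0 + sep_pad for c0, r0 in placed
            )
            if ok:
                center = cand
                break
        overlapping = center is None
        if overlapping:
            center = cand  # accept the last candidate; flagged in truth
        placed.append((center, r_max))
        suv = {}
        for tracer, radius, present in (
            ("FDG", r_fdg, category != "CXCR4_only"),
            ("CXCR4", r_cx, category != "FDG_only"),
        ):
            if not present:
                suv[tracer] = (np.nan, np.nan)
                continue
            key = "concordant" if category == "concordant" else category
            mu, sigma = config.suv_params[tracer][key]
            peak = max(float(rng.lognormal(mu, sigma)), 1.5 * config.background_suv)
            mean = _taper_mean(peak, radius) if config.gaussian_taper else peak
            suv[tracer] = (peak, mean)
        rows.append(
            {
                "lesion_uid": i + 1,
                "category": category,
                "site": site,
                "center_x_mm": center[0],
                "center_y_mm": center[1],
                "center_z_mm": center[2],
                "radius_fdg_mm": r_fdg if category != "CXCR4_only" else np.nan,
                "radius_cxcr4_mm": r_cx if category != "FDG_only" else np.nan,
                "peak_suv_fdg": suv["FDG"][0],
                "suv_mean_fdg": suv["FDG"][1],
                "peak_suv_cxcr4": suv["CXCR4"][0],
                "suv_mean_cxcr4": suv["CXCR4"][1],
                "overlapping_placement": overlapping,
            }
        )
    cols = [
        "lesion_uid", "category", "site", "center_x_mm", "center_y_mm", "center_z_mm",
        "radius_fdg_mm", "radius_cxcr4_mm", "peak_suv_fdg", "suv_mean_fdg",
        "peak_suv_cxcr4", "suv_mean_cxcr4", "overlapping_placement",
    ]
    return pd.DataFrame(rows, columns=cols)


def _truth_lesion_records(truth: pd.DataFrame, voxel_ml: float) -> pd.DataFrame:
    """Flatten planted lesions into per-(tracer, lesion) metric rows."""
    recs = []
    for _, row in truth.iterrows():
        for tracer, rcol, pcol, mcol in (
            ("FDG", "radius_fdg_mm", "peak_suv_fdg", "suv_mean_fdg"),
            ("CXCR4", "radius_cxcr4_mm", "peak_suv_cxcr4", "suv_mean_cxcr4"),
        ):
            r = row[rcol]
            if np.isnan(r):
                continue
            mtv = 4.0 / 3.0 * math.pi * r**3 / 1000.0
            recs.append(
                {
                    "tracer": tracer,
                    "site": row["site"],
                    "category": row["category"],
                    "n_voxels": mtv / voxel_ml,  # analytic volume in voxel-equivalents
                    "suv_mean": row[mcol],
                    "suv_max": row[pcol],
                    "mtv_ml": mtv,
                    "center": np.array([row["center_x_mm"], row["center_y_mm"], row["center_z_mm"]]),
                }
            )
    return pd.DataFrame(
        recs, columns=["tracer", "site", "category", "n_voxels", "suv_mean", "suv_max", "mtv_ml", "center"]
    )


def _truth_features(
    truth: pd.DataFrame, clinical: dict, config: SynthConfig
) -> dict:
    voxel_ml = float(np.prod(config.voxel_spacing_mm)) / 1000.0
    recs = _truth_lesion_records(truth, voxel_ml)
    feats = aggregate_patient(recs)
    for tracer in ("FDG", "CXCR4"):
        sub = recs[recs["tracer"] == tracer] if len(recs) else recs
        cents = np.stack(sub["center"].to_list()) if len(sub) >= 2 else np.empty((0, 3))
        feats[f"sDmax_{tracer}"] = sdmax(cents, clinical["height_cm"], clinical["weight_kg"])
    feats["spleen_SUVmean"] = config.spleen_suv["FDG"]
    feats.update({k: clinical[k] for k in CLINICAL_COLUMNS})
    return feats


def _render_patient(
    config: SynthConfig, phantom: _Phantom, anat: dict, truth: pd.DataFrame
) -> tuple[dict, dict]:
    spacing = config.voxel_spacing_mm
    volumes, masks = {}, {}
    for tracer, rcol, pcol in (
        ("FDG", "radius_fdg_mm", "peak_suv_fdg"),
        ("CXCR4", "radius_cxcr4_mm", "peak_suv_cxcr4"),
    ):
        vals = np.where(anat["body"].values > 0, config.background_suv, 0.0).astype(float)
        vals[anat["spleen"].values > 0] = config.spleen_suv[tracer]
        pet = ScalarVolume(vals, spacing, (0, 0, 0), "SUV")
        mask = np.zeros(config.grid_shape, dtype=np.uint8)
        for _, row in truth.iterrows():
            r = row[rcol]
            if np.isnan(r):
                continue
            center = (row["center_x_mm"], row["center_y_mm"], row["center_z_mm"])
            pet = plant_lesion(pet, center, r, row[pcol], config.gaussian_taper)
            mask[tuple(sphere_support(pet, center, r).T)] = 1
        volumes[tracer] = pet
        masks[tracer] = ScalarVolume(mask, spacing, (0, 0, 0), "binary")
    return volumes, masks


def assign_outcomes(
    truth_features: pd.DataFrame,
    response_model: ResponseModel,
    survival_model: SurvivalModel,
    censoring_rate: float,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Draw response and survival outcomes from the planted feature values.

    Features named by the model coefficients are standardized across the
    cohort (zero-variance or missing values contribute 0), the response is
    Bernoulli(logistic(linear predictor)) and survival is exponential with
    hazard = baseline * exp(linear predictor).  Censoring is independent:
    with probability ``censoring_rate`` a unit is censored uniformly before
    its event time.  The linear predictors are returned for truth-keeping.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(truth_features)

    def linpred(coefs: dict[str, float], intercept: float = 0.0) -> np.ndarray:
        lp = np.full(n, intercept, dtype=float)
        for name, beta in coefs.items():
            if name not in truth_features.columns:
                raise ConfigurationError(f"outcome model references unknown feature {name!r}")
            v = truth_features[name].to_numpy(dtype=float)
            if not np.isfinite(v).any():
                continue
            mu, sd = np.nanmean(v), np.nanstd(v)
            z = (v - mu) / sd if sd > 0 else np.zeros(n)
            z[~np.isfinite(z)] = 0.0
            lp += beta * z
        return lp

    lp_resp = linpred(response_model.coefficients, response_model.intercept)
    response = (rng.random(n) < expit(lp_resp)).astype(int)
    lp_surv = linpred(survival_model.coefficients)
    hazard = survival_model.baseline_hazard_per_day * np.exp(lp_surv)
    event_time = rng.exponential(1.0 / hazard)
    censored = rng.random(n) < censoring_rate
    os_days = np.where(censored, rng.uniform(0, 1, n) * event_time, event_time)
    return pd.DataFrame(
        {
            "response": response,
            "os_days": np.round(os_days, 1),
            "os_event": (~censored).astype(int),
            "lp_response": lp_resp,
            "lp_survival": lp_surv,
        },
        index=truth_features.index,
    )


def generate_cohort(config: SynthConfig, render: bool = True) -> list[SynthPatient]:
    """Generate a full synthetic cohort, deterministically from the seed.

    With ``render=False`` only the planted truth (lesion tables, features,
    clinical covariates, outcomes) is produced - the random stream is
    identical either way, so a rendered and an unrendered cohort from the
    same config share the same truth.
    """
    phantom = _Phantom(config)
    ss = np.random.SeedSequence(config.seed)
    unit_seeds = ss.spawn(config.n_patients + 1)
    anat = phantom.render_masks(config) if render else None
    patients: list[SynthPatient] = []
    feats_rows = []
    for i in range(config.n_patients):
        rng = np.random.default_rng(unit_seeds[i])
        clinical = _draw_clinical(rng)
        truth = _draw_lesions(rng, config, phantom)
        feats = _truth_features(truth, clinical, config)
        feats_rows.append(feats)
        patients.append(
            SynthPatient(
                patient_id=f"unit{i + 1:03d}",
                clinical=clinical,
                outcome={},
                truth_lesions=truth,
                truth_features=feats,
            )
        )
    feature_df = pd.DataFrame(feats_rows, index=[p.patient_id for p in patients])
    outcomes = assign_outcomes(
        feature_df,
        config.response_model,
        config.survival_model,
        config.censoring_rate,
        np.random.default_rng(unit_seeds[-1]),
    )
    for p, (_, out) in zip(patients, outcomes.iterrows()):
        p.outcome = out.to_dict()
    if render:
        for p in patients:
            volumes, masks = _render_patient(config, phantom, anat, p.truth_lesions)
            p.volumes, p.lesion_masks = volumes, masks
            p.bone_mask, p.spleen_mask, p.body_mask = (
                anat["bone"], anat["spleen"], anat["body"],
            )
    return patients


def cohort_feature_table(patients: list[SynthPatient]) -> pd.DataFrame:
    """Planted-truth feature matrix (canonical columns) with outcomes."""
    rows = []
    for p in patients:
        row = {"patient_id": p.patient_id}
        row.update(p.truth_features)
        row.update({k: p.outcome[k] for k in ("response", "os_days", "os_event")})
        rows.append(row)
    cols = ["patient_id"] + imaging_feature_columns() + list(CLINICAL_COLUMNS) + [
        "response", "os_days", "os_event",
    ]
    return pd.DataFrame(rows)[cols]


# ---------------------------------------------------------------------------
# feature-level study-condition simulators (no images)
# ---------------------------------------------------------------------------


def simulate_group_difference(
    n: int, g: float = -1.0, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Two balanced groups with a planted standardized mean difference.

    Group labels are Bernoulli(0.5); the marker is N(g, 1) for group 1
    (responders) and N(0, 1) for group 0, so the population standardized
    difference group1 - group0 equals ``g``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = (rng.random(n) < 0.5).astype(int)
    values = rng.normal(0.0, 1.0, n) + g * labels
    return values, labels


def simulate_survival_groups(
    n: int,
    rate_ratio: float = 2.6,
    baseline_hazard: float = math.log(2.0) / MEDIAN_OS_DAYS,
    censoring_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Exponential survival with a planted hazard ratio across a median split.

    A lognormal burden marker is drawn; units above the cohort median have
    hazard ``baseline * rate_ratio``, the rest ``baseline``.  Returns the
    marker, observed times and event flags (independent uniform censoring).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    marker = rng.lognormal(3.0, 0.8, n)
    high = marker > np.median(marker)
    hazard = baseline_hazard * np.where(high, rate_ratio, 1.0)
    t = rng.exponential(1.0 / hazard)
    censored = rng.random(n) < censoring_rate
    times = np.where(censored, rng.uniform(0, 1, n) * t, t)
    return pd.DataFrame(
        {"marker": marker, "high": high, "os_days": times, "os_event": (~censored).astype(int)}
    )


def plant_response_effect(
    features: pd.DataFrame,
    feature: str,
    g: float = -1.0,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Re-plant a response effect of size ``g`` on one feature column.

    Draws balanced Bernoulli labels and shifts the named feature by
    ``g * sd`` for responders, leaving every other column untouched; used
    to test that attribution ranks the causal feature first.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = (rng.random(len(features)) < 0.5).astype(int)
    out = features.copy()
    col = out[feature].to_numpy(dtype=float)
    sd = np.nanstd(col)
    if sd == 0 or np.isnan(sd):
        sd = 1.0
    out[feature] = col + g * sd * labels
    return out, labels
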