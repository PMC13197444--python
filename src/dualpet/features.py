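"""Per-lesion uptake/burden metrics and patient-level bracket aggregates.

Lesion metrics
    * SUVmean / SUVmax over the lesion's voxels,
    * MTV (molecular tumor volume) = voxel count x voxel volume, in ml,
    * TLG = MTV x SUVmean on the FDG scan (total lesion glycolysis),
    * TLC = MTV x SUVmean on the CXCR4 scan (total lesion CXCR4-expression).

Patient aggregates use bracket notation ``metric[tracer site class]``,
e.g. ``SUVmean[FDG medullary concordant]``: for each tracer x site
(medullary / extramedullary) x concordance class (concordant / discordant)
subset, SUVmean is the voxel-pooled (volume-weighted) mean, SUVmax the
subset maximum, and MTV / TLG / TLC are sums over member lesions.  Empty
subsets yield *missing* intensity metrics but *zero* burden metrics: a
patient without, say, extramedullary discordant lesions has no SUV there
but genuinely zero tumor volume.

sDmax is the maximum pairwise distance between lesion centroids (cm)
standardized by body surface area (DuBois by default), a disease
dissemination metric; the spleen reference is the mean SUV over spleen
voxels excluding any lesion voxels of either tracer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .concordance import Lesion
from .errors import DomainError
from .volume import ScalarVolume

__all__ = [
    "LesionMetrics",
    "lesion_metrics",
    "aggregate_patient",
    "sdmax",
    "body_surface_area",
    "spleen_reference",
    "imaging_feature_columns",
    "CLINICAL_COLUMNS",
    "ClinicalRecord",
]

SITES = ("medullary", "extramedullary")
CLASSES = ("concordant", "discordant")
#: burden metric carrying the tracer-specific intensity-volume product
_PRODUCT_METRIC = {"FDG": "TLG", "CXCR4": "TLC"}

CLINICAL_COLUMNS = (
    "age",
    "sex",
    "height_cm",
    "weight_kg",
    "bmi",
    "highrisk_cytogenetics",
    "b2m_mg_l",
    "disease_duration_months",
)


@dataclass
class ClinicalRecord:
    """Clinical covariates of one analysis unit.

    ``sex`` is coded 1 = female, 0 = male; ``highrisk_cytogenetics`` is a
    0/1 flag; beta-2 microglobulin in mg/l.  BMI must agree with
    height/weight to within 0.1 kg/m^2 when all three are present.
    """

    age: float
    sex: int
    height_cm: float
    weight_kg: float
    bmi: float
    highrisk_cytogenetics: int
    b2m_mg_l: float
    disease_duration_months: float

    def __post_init__(self) -> None:
        if self.height_cm > 0 and self.weight_kg > 0 and not np.isnan(self.bmi):
            implied = self.weight_kg / (self.height_cm / 100.0) ** 2
            if abs(implied - self.bmi) > 0.1:
                raise DomainError(
                    f"bmi {self.bmi:.2f} inconsistent with height/weight ({implied:.2f})"
                )

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in CLINICAL_COLUMNS}


@dataclass
class LesionMetrics:
    suv_mean: float
    suv_max: float
    mtv_ml: float
    product: float  # TLG for FDG, TLC for CXCR4

    @property
    def tlg(self) -> float:
        return self.product

    @property
    def tlc(self) -> float:
        return self.product


def lesion_metrics(lesion: Lesion, pet: ScalarVolume) -> LesionMetrics:
    """SUVmean/SUVmax/MTV and the intensity-volume product for one lesion."""
    if lesion.n_voxels == 0:
        raise DomainError("cannot compute metrics of an empty lesion")
    vals = pet.values[tuple(lesion.indices.T)].astype(float)
    mtv = lesion.n_voxels * pet.voxel_volume_ml
    mean = float(vals.mean())
    return LesionMetrics(mean, float(vals.max()), mtv, mtv * mean)


def bracket(metric: str, tracer: str, site: str, cls: str) -> str:
    """Canonical feature name, e.g. ``MTV[CXCR4 medullary concordant]``."""
    return f"{metric}[{tracer} {site} {cls}]"


def imaging_feature_columns() -> list[str]:
    """The canonical patient-level imaging feature names, in fixed order."""
    cols = []
    for tracer in ("FDG", "CXCR4"):
        for site in SITES:
            for cls in CLASSES:
                for metric in ("SUVmean", "SUVmax", "MTV", _PRODUCT_METRIC[tracer]):
                    cols.append(bracket(metric, tracer, site, cls))
    cols += ["sDmax_FDG", "sDmax_CXCR4", "spleen_SUVmean"]
    return cols


def aggregate_patient(lesion_table: pd.DataFrame) -> dict[str, float]:
    """Aggregate a per-lesion table to bracket-notation patient features.

    ``lesion_table`` needs columns ``tracer, site, category, n_voxels,
    suv_mean, suv_max, mtv_ml`` where ``category`` is ``concordant`` or a
    tracer-only label (mapped to the ``discordant`` class).  SUVmean is
    pooled over voxels (volume-weighted mean of lesion means, which equals
    the mean over the union region for uniform voxel grids).
    """
    out: dict[str, float] = {}
    if len(lesion_table):
        cls_of = lesion_table["category"].map(
            lambda c: "concordant" if c == "concordant" else "discordant"
        )
    for tracer in ("FDG", "CXCR4"):
        for site in SITES:
            for cls in CLASSES:
                if len(lesion_table):
                    sub = lesion_table[
                        (lesion_table["tracer"] == tracer)
                        & (lesion_table["site"] == site)
                        & (cls_of == cls)
                    ]
                else:
                    sub = lesion_table
                prod = _PRODUCT_METRIC[tracer]
                if len(sub) == 0:
                    out[bracket("SUVmean", tracer, site, cls)] = np.nan
                    out[bracket("SUVmax", tracer, site, cls)] = np.nan
                    out[bracket("MTV", tracer, site, cls)] = 0.0
                    out[bracket(prod, tracer, site, cls)] = 0.0
                    continue
                nvox = sub["n_voxels"].to_numpy(dtype=float)
                means = sub["suv_mean"].to_numpy(dtype=float)
                mtv = sub["mtv_ml"].to_numpy(dtype=float)
                out[bracket("SUVmean", tracer, site, cls)] = float(
                    (means * nvox).sum() / nvox.sum()
                )
                out[bracket("SUVmax", tracer, site, cls)] = float(sub["suv_max"].max())
                out[bracket("MTV", tracer, site, cls)] = float(mtv.sum())
                out[bracket(prod, tracer, site, cls)] = float((mtv * means).sum())
    return out


def body_surface_area(height_cm: float, weight_kg: float, formula: str = "dubois") -> float:
    """Body surface area in m^2 (DuBois-DuBois default, Mosteller optional)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise DomainError("height and weight must be positive")
    if formula == "dubois":
        return 0.007184 * height_cm**0.725 * weight_kg**0.425
    if formula == "mosteller":
        return float(np.sqrt(height_cm * weight_kg / 3600.0))
    raise DomainError(f"unknown BSA formula {formula!r}")


def sdmax(
    centroids_mm: np.ndarray,
    height_cm: float,
    weight_kg: float,
    formula: str = "dubois",
) -> float:
    """Body-surface-standardized maximum inter-lesion distance (cm/m^2).

    Dmax is the largest pairwise Euclidean distance between lesion
    centroids; fewer than two lesions yield a missing value.
    """
    centroids_mm = np.atleast_2d(np.asarray(centroids_mm, dtype=float))
    if len(centroids_mm) < 2:
        return float("nan")
    dmax_cm = float(pdist(centroids_mm).max()) / 10.0
    return dmax_cm / body_surface_area(height_cm, weight_kg, formula)


def spleen_reference(
    pet: ScalarVolume,
    spleen_mask: ScalarVolume,
    lesion_masks: list[ScalarVolume],
) -> float:
    """Mean SUV over spleen voxels outside every tracer's lesion mask.

    Returns a missing value when lesions cover the entire spleen.
    """
    pet.require_same_grid(spleen_mask, "PET and spleen mask")
    region = spleen_mask.values > 0
    for m in lesion_masks:
        pet.require_same_grid(m, "PET and lesion mask")
        region &= ~(m.values > 0)
    if not region.any():
        return float("nan")
    return float(pet.values[region].mean())
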