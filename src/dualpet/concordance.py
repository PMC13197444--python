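"""Lesion extraction, cross-tracer matching and concordance adjudication.

Lesions are connected components of a binary segmentation mask
(26-neighborhood by default, the usual choice for blob-like PET uptake).
Lesions from the two tracers are matched by voxel-wise overlap on a common
grid; a lesion is *concordant* when it shares more than a threshold
fraction of volume (default strictly >10%, intersection over the smaller
of the two lesion volumes) with at least one lesion of the other tracer,
otherwise it is tracer-only (*discordant*).  Site is *medullary* when at
least 10% (inclusive) of the lesion's voxels fall inside the bone mask,
else *extramedullary*; splenic membership is flagged on any voxel overlap
with the spleen mask.

For cohort totals, a group of mutually qualifying concordant lesions (a
connected component of the qualifying-pair graph across the two tracers)
counts as one concordant lesion, so that

    n_concordant_groups + n_FDG_only + n_CXCR4_only

partitions the total distinct-lesion count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .errors import DomainError, GridMismatchError
from .volume import ScalarVolume

__all__ = [
    "Lesion",
    "LesionSet",
    "ConcordanceTable",
    "label_components",
    "threshold_segment",
    "overlap_matrix",
    "adjudicate_concordance",
    "classify_site",
    "flag_spleen",
]

TRACERS = ("FDG", "CXCR4")
OVERLAP_DENOMINATORS = ("min", "a", "b", "union")


@dataclass
class Lesion:
    """One connected component of a tracer's lesion mask."""

    label: int
    indices: np.ndarray  # (n_voxels, 3) integer voxel indices
    n_voxels: int
    volume_ml: float
    centroid_mm: np.ndarray


@dataclass
class LesionSet:
    """All lesions of one tracer on one voxel grid."""

    tracer: str
    labels: ScalarVolume  # integer label volume, 0 = background
    lesions: list[Lesion] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.lesions)

    def lesion(self, label: int) -> Lesion:
        return self.lesions[label - 1]


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise DomainError(f"connectivity must be 6 or 26, got {connectivity}")


def label_components(
    mask: ScalarVolume,
    pet: ScalarVolume | None = None,
    tracer: str = "FDG",
    connectivity: int = 26,
) -> LesionSet:
    """Label connected components of a binary mask as lesions.

    Per lesion: voxel index list, voxel count, volume in ml (count x voxel
    volume) and the intensity-unweighted centroid of voxel centers in mm.
    ``pet`` is only used to enforce grid consistency with the mask.
    """
    if mask.units != "binary":
        raise DomainError("label_components requires a binary mask")
    if pet is not None:
        mask.require_same_grid(pet, "mask and PET")
    lab, n = ndimage.label(mask.values, structure=_structure(connectivity))
    lesions: list[Lesion] = []
    if n:
        idx = np.argwhere(lab > 0)
        lab_at = lab[tuple(idx.T)]
        order = np.argsort(lab_at, kind="stable")
        idx, lab_at = idx[order], lab_at[order]
        starts = np.searchsorted(lab_at, np.arange(1, n + 2))
        vox_ml = mask.voxel_volume_ml
        for lbl in range(1, n + 1):
            vox = idx[starts[lbl - 1] : starts[lbl]]
            centroid = mask.index_to_mm(vox.mean(axis=0))
            lesions.append(
                Lesion(lbl, vox, len(vox), len(vox) * vox_ml, centroid)
            )
    return LesionSet(
        tracer,
        ScalarVolume(lab.astype(np.int32), mask.spacing_mm, mask.origin_mm, "label"),
        lesions,
    )


def threshold_segment(
    pet: ScalarVolume, suv_threshold: float, body_mask: ScalarVolume
) -> ScalarVolume:
    """Simple SUV-threshold segmentation inside the body mask.

    Stand-in lesion detector: voxels with SUV >= threshold within the body.
    """
    pet.require_same_grid(body_mask, "PET and body mask")
    out = (pet.values >= suv_threshold) & (body_mask.values > 0)
    return ScalarVolume(out.astype(np.uint8), pet.spacing_mm, pet.origin_mm, "binary")


def overlap_matrix(a: LesionSet, b: LesionSet) -> pd.DataFrame:
    """All cross-tracer lesion pairs with a nonzero voxel intersection.

    Returns a frame with columns ``label_a, label_b, intersection_voxels``
    (exact counts), empty when the label volumes are disjoint.
    """
    a.labels.require_same_grid(b.labels, "lesion label volumes")
    la, lb = a.labels.values, b.labels.values
    both = (la > 0) & (lb > 0)
    if not both.any():
        return pd.DataFrame(columns=["label_a", "label_b", "intersection_voxels"]).astype(int)
    pairs, counts = np.unique(
        np.stack([la[both], lb[both]]), axis=1, return_counts=True
    )
    return pd.DataFrame(
        {
            "label_a": pairs[0].astype(int),
            "label_b": pairs[1].astype(int),
            "intersection_voxels": counts.astype(int),
        }
    )


@dataclass
class ConcordanceTable:
    """Cross-tracer pairing with per-lesion category/site assignments."""

    pairs: pd.DataFrame  # label_a, label_b, intersection_voxels, overlap_fraction, qualifies
    category: dict[tuple[str, int], str]  # (tracer, label) -> concordant / FDG_only / CXCR4_only
    site: dict[tuple[str, int], str] = field(default_factory=dict)
    in_spleen: dict[tuple[str, int], bool] = field(default_factory=dict)
    n_concordant_groups: int = 0

    def counts(self) -> dict[str, int]:
        """Cohort-style partition: concordant pair-groups count once."""
        vals = list(self.category.values())
        return {
            "concordant": self.n_concordant_groups,
            "FDG_only": vals.count("FDG_only"),
            "CXCR4_only": vals.count("CXCR4_only"),
        }

    @property
    def n_distinct_lesions(self) -> int:
        c = self.counts()
        return c["concordant"] + c["FDG_only"] + c["CXCR4_only"]


def _overlap_fraction(inter, va, vb, denominator):
    if denominator == "min":
        return inter / np.minimum(va, vb)
    if denominator == "a":
        return inter / va
    if denominator == "b":
        return inter / vb
    if denominator == "union":
        return inter / (va + vb - inter)
    raise DomainError(
        f"overlap denominator must be one of {OVERLAP_DENOMINATORS}, got {denominator!r}"
    )


def adjudicate_concordance(
    pairs: pd.DataFrame,
    a: LesionSet,
    b: LesionSet,
    threshold: float = 0.10,
    denominator: str = "min",
    strict: bool = True,
) -> ConcordanceTable:
    """Assign concordant / tracer-only categories from overlap fractions.

    A lesion is concordant iff it participates in at least one pair whose
    overlap fraction exceeds ``threshold`` (strictly, by default).  Category
    is a per-lesion property: one lesion may anchor several qualifying
    pairs but holds a single category.  Concordant lesions are grouped into
    pair-graph connected components for cohort counting.
    """
    if not (0 < threshold < 1):
        raise DomainError(f"concordance threshold must lie in (0, 1), got {threshold}")
    pairs = pairs.copy()
    if len(pairs):
        va = np.array([a.lesion(l).n_voxels for l in pairs["label_a"]], dtype=float)
        vb = np.array([b.lesion(l).n_voxels for l in pairs["label_b"]], dtype=float)
        inter = pairs["intersection_voxels"].to_numpy(dtype=float)
        frac = _overlap_fraction(inter, va, vb, denominator)
        pairs["overlap_fraction"] = frac
        pairs["qualifies"] = frac > threshold if strict else frac >= threshold
    else:
        pairs["overlap_fraction"] = pd.Series(dtype=float)
        pairs["qualifies"] = pd.Series(dtype=bool)

    only = {"FDG": "FDG_only", "CXCR4": "CXCR4_only"}
    category: dict[tuple[str, int], str] = {}
    conc_a = set(pairs.loc[pairs["qualifies"], "label_a"])
    conc_b = set(pairs.loc[pairs["qualifies"], "label_b"])
    for les in a.lesions:
        category[(a.tracer, les.label)] = (
            "concordant" if les.label in conc_a else only.get(a.tracer, f"{a.tracer}_only")
        )
    for les in b.lesions:
        category[(b.tracer, les.label)] = (
            "concordant" if les.label in conc_b else only.get(b.tracer, f"{b.tracer}_only")
        )

    # pair-group count: connected components of the qualifying bipartite graph
    n_groups = 0
    q = pairs[pairs["qualifies"]]
    if len(q):
        na = len(a.lesions)
        rows = q["label_a"].to_numpy() - 1
        cols = q["label_b"].to_numpy() - 1 + na
        n_nodes = na + len(b.lesions)
        adj = coo_matrix(
            (np.ones(len(q)), (rows, cols)), shape=(n_nodes, n_nodes)
        )
        n_comp, comp = connected_components(adj, directed=False)
        used = np.zeros(n_nodes, dtype=bool)
        used[rows] = True
        used[cols] = True
        n_groups = len(np.unique(comp[used]))
    return ConcordanceTable(pairs, category, n_concordant_groups=n_groups)


def classify_site(
    lesion: Lesion,
    bone_mask: ScalarVolume,
    labels: ScalarVolume | None = None,
    threshold: float = 0.10,
    strict: bool = False,
) -> str:
    """Medullary vs. extramedullary by fractional overlap with bone.

    Medullary iff (lesion voxels inside bone) / (lesion voxels) >= threshold
    (inclusive by default).
    """
    if labels is not None:
        labels.require_same_grid(bone_mask, "lesion grid and bone mask")
    if bone_mask.units != "binary":
        raise DomainError("bone mask must be binary")
    inside = bone_mask.values[tuple(lesion.indices.T)].sum()
    frac = inside / lesion.n_voxels
    medullary = frac > threshold if strict else frac >= threshold
    return "medullary" if medullary else "extramedullary"


def flag_spleen(lesion: Lesion, spleen_mask: ScalarVolume) -> bool:
    """True iff the lesion shares at least one voxel with the spleen mask."""
    if spleen_mask.units != "binary":
        raise DomainError("spleen mask must be binary")
    return bool(spleen_mask.values[tuple(lesion.indices.T)].any())
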