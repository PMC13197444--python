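"""Scalar voxel volumes, NIfTI I/O, SUV conversion and mask resampling.

A :class:`ScalarVolume` is a 3-D array of voxel values together with the
physical geometry of its grid.  Voxel index ``(i, j, k)`` (0-based) maps to
the physical point ``origin_mm + index * spacing_mm``; all distances in the
package are computed in physical millimetres under this convention.  The
default pipeline only accepts axis-aligned geometries (the affine is a
positive scaling plus a translation); oblique or flipped affines are
rejected with a :class:`~dualpet.errors.FormatError` rather than silently
reinterpreted.

PET values are body-weight standardized uptake values (SUV).  Decay,
scatter and attenuation correction are assumed to have been applied by the
scanner; :func:`to_suv` only performs the dose/weight normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import DomainError, FormatError, GridMismatchError

__all__ = [
    "ScalarVolume",
    "RigidTransform",
    "read_volume",
    "write_volume",
    "to_suv",
    "resample_mask",
]

#: Recognised value-unit tags for a ScalarVolume.
UNITS = ("SUV", "Bq_per_ml", "binary", "label")


@dataclass
class ScalarVolume:
    """A 3-D voxel grid with physical spacing.

    Parameters
    ----------
    values
        3-D array of voxel values (SUV, activity concentration, or {0,1}).
    spacing_mm
        Positive voxel pitch along each axis, in mm.
    origin_mm
        Physical coordinate of voxel (0, 0, 0), in mm.
    units
        One of ``"SUV"``, ``"Bq_per_ml"``, ``"binary"``.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    units: str = "SUV"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise FormatError(
                f"expected a 3-D volume, got shape {self.values.shape}"
            )
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise DomainError(f"spacing_mm must be 3 positive reals, got {self.spacing_mm}")
        if self.units not in UNITS:
            raise DomainError(f"units must be one of {UNITS}, got {self.units!r}")
        if self.units == "binary":
            vals = np.unique(self.values)
            if not np.all(np.isin(vals, (0, 1))):
                raise DomainError("binary volume contains values other than {0, 1}")

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 ml = 1000 mm^3)."""
        return float(np.prod(self.spacing_mm)) / 1000.0

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def index_to_mm(self, index: np.ndarray) -> np.ndarray:
        """Physical coordinates (mm) of voxel indices (..., 3)."""
        return np.asarray(self.origin_mm) + np.asarray(index) * np.asarray(self.spacing_mm)

    def same_grid(self, other: "ScalarVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=atol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=atol)
        )

    def require_same_grid(self, other: "ScalarVolume", what: str = "volumes") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"{what} must share the voxel grid: "
                f"{self.shape}/{self.spacing_mm} vs {other.shape}/{other.spacing_mm}"
            )

    def copy(self) -> "ScalarVolume":
        return replace(self, values=self.values.copy())


@dataclass
class RigidTransform:
    """Rigid (rotation + translation) map from moving to fixed physical space."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation_mm = np.asarray(self.translation_mm, dtype=float)
        if self.rotation.shape != (3, 3):
            raise DomainError("rotation must be a 3x3 matrix")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise DomainError("rotation must be orthonormal")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise DomainError("rotation determinant must be +1 (proper rotation)")

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        return points_mm @ self.rotation.T + self.translation_mm

    def inverse_apply(self, points_mm: np.ndarray) -> np.ndarray:
        return (points_mm - self.translation_mm) @ self.rotation


def read_volume(path) -> ScalarVolume:
    """Read a NIfTI volume, extracting spacing and origin from the affine.

    Only axis-aligned affines (positive diagonal scaling + translation) are
    accepted; non-3-D images raise :class:`FormatError`.  The unit tag is
    recovered from the NIfTI ``descrip`` field when it matches a known unit,
    otherwise volumes whose values are a subset of {0, 1} are tagged
    ``binary`` and everything else ``SUV``.
    """
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt file
        raise FormatError(f"could not read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D image, got {data.ndim}-D")
    aff = img.affine
    lin = aff[:3, :3]
    if not np.allclose(lin, np.diag(np.diag(lin)), atol=1e-6) or np.any(np.diag(lin) <= 0):
        raise FormatError(
            f"{path}: affine is not an axis-aligned positive scaling; "
            "oblique or flipped volumes are not supported by the default pipeline"
        )
    spacing = tuple(np.diag(lin))
    origin = tuple(aff[:3, 3])
    descrip = ""
    try:
        descrip = img.header["descrip"].item().decode(errors="ignore")
    except Exception:
        pass
    if descrip in UNITS:
        units = descrip
    else:
        vals = np.unique(data)
        units = "binary" if np.all(np.isin(vals, (0, 1))) else "SUV"
    return ScalarVolume(np.asarray(data, dtype=np.uint8 if units == "binary" else np.float32),
                        spacing, origin, units)


def write_volume(vol: ScalarVolume, path) -> None:
    """Write a volume as NIfTI-1 with the spacing/origin encoded in the affine."""
    dtype = {"binary": np.uint8, "label": np.int32}.get(vol.units, np.float32)
    img = nib.Nifti1Image(vol.values.astype(dtype), vol.affine)
    img.header["descrip"] = vol.units.encode()
    img.header.set_zooms(vol.spacing_mm)
    nib.save(img, str(path))


def to_suv(activity: ScalarVolume, weight_kg: float, injected_dose_MBq: float) -> ScalarVolume:
    """Convert an activity-concentration volume (Bq/ml) to body-weight SUV.

    SUV = concentration [kBq/ml] x body weight [g] / injected dose [kBq],
    i.e. ``value_Bq_per_ml * weight_kg / (dose_MBq * 1000)``.
    """
    if weight_kg <= 0:
        raise DomainError(f"weight_kg must be positive, got {weight_kg}")
    if injected_dose_MBq <= 0:
        raise DomainError(f"injected_dose_MBq must be positive, got {injected_dose_MBq}")
    if activity.units != "Bq_per_ml":
        raise DomainError(f"expected a Bq_per_ml volume, got units {activity.units!r}")
    suv = activity.values * (weight_kg / (injected_dose_MBq * 1000.0))
    return ScalarVolume(suv, activity.spacing_mm, activity.origin_mm, "SUV")


def resample_mask(
    mask: ScalarVolume,
    target: ScalarVolume,
    transform: RigidTransform | None = None,
) -> ScalarVolume:
    """Resample a binary mask onto ``target``'s grid with nearest-neighbor.

    ``transform`` maps points from the mask's (moving) physical space into
    the target's (fixed) physical space; each target voxel center is pulled
    back through the inverse map and sampled from the nearest mask voxel.
    Identity transform on an identical grid returns the mask unchanged.
    """
    if mask.units != "binary":
        raise DomainError("resample_mask requires a binary mask")
    if transform is None and mask.same_grid(target):
        out = mask.copy()
        out.spacing_mm, out.origin_mm = target.spacing_mm, target.origin_mm
        return out
    idx = np.indices(target.shape, dtype=float)  # (3, X, Y, Z)
    pts = idx.reshape(3, -1).T * np.asarray(target.spacing_mm) + np.asarray(target.origin_mm)
    if transform is not None:
        pts = transform.inverse_apply(pts)
    src = (pts - np.asarray(mask.origin_mm)) / np.asarray(mask.spacing_mm)
    sampled = ndimage.map_coordinates(
        mask.values.astype(np.uint8), src.T, order=0, mode="constant", cval=0
    )
    return ScalarVolume(
        sampled.reshape(target.shape).astype(np.uint8),
        target.spacing_mm,
        target.origin_mm,
        "binary",
    )
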