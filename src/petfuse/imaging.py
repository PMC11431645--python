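"""3D volumes, lesion masks and the preprocessing transforms.

Conventions
-----------
* Arrays are indexed ``(x, y, z)`` with 0-based voxel indices; spacing and
  origin are in millimetres, so the physical position of voxel ``(i, j, k)``
  is ``origin + (i, j, k) * spacing``.
* Bounding boxes are half-open ``[min, max)`` per axis.
* CT intensities are Hounsfield units; PET intensities are SUV (body-weight
  normalised uptake). Fused volumes carry the ``FUSED`` modality tag.
* All transforms are pure: inputs are never modified in place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import SimpleITK as sitk
from skimage import exposure

from .errors import (
    AlignmentError,
    BoundsError,
    DegenerateInputError,
    FormatError,
    ParameterError,
    ValidationError,
)

MODALITIES = ("CT", "PET", "FUSED")
MASK_LABELS = ("GTVp", "GTVn", "COMBINED")

#: Display windows used by the challenge figures: HU for CT, SUV for PET.
DEFAULT_CT_WINDOW = (-140.0, 260.0)
DEFAULT_PET_WINDOW = (0.0, 12.0)

#: Body weight (kg) assumed when the clinical record lacks one, for SUV scaling.
DEFAULT_BODY_WEIGHT_KG = 75.0


def _as_tuple3(x, name: str) -> tuple[float, float, float]:
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise ParameterError(f"{name} must have exactly 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass(frozen=True)
class Volume3D:
    """A 3D scalar image with physical spacing, origin and a modality tag."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "CT"

    def __post_init__(self):
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3 or min(data.shape) < 1:
            raise FormatError(f"volume data must be 3D with all axes >= 1, got shape {data.shape}")
        spacing = _as_tuple3(self.spacing, "spacing")
        if any(s <= 0 for s in spacing):
            raise FormatError(f"spacing must be strictly positive, got {spacing}")
        if self.modality not in MODALITIES:
            raise ParameterError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", _as_tuple3(self.origin, "origin"))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray, modality: Optional[str] = None) -> "Volume3D":
        return Volume3D(data, self.spacing, self.origin, modality or self.modality)

    def same_grid(self, other: "Volume3D | LesionMask", atol: float = 1e-6) -> bool:
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass(frozen=True)
class LesionMask:
    """Binary lesion mask on the grid of an annotated volume."""

    data: np.ndarray
    label: str = "GTVp"
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise FormatError(f"mask must be 3D, got shape {data.shape}")
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise FormatError(f"mask values must be exactly 0 or 1, got {uniq}")
        if self.label not in MASK_LABELS:
            raise ParameterError(f"mask label must be one of {MASK_LABELS}, got {self.label!r}")
        object.__setattr__(self, "data", data.astype(bool))
        object.__setattr__(self, "spacing", _as_tuple3(self.spacing, "spacing"))
        object.__setattr__(self, "origin", _as_tuple3(self.origin, "origin"))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def union(self, other: "LesionMask", label: str = "COMBINED") -> "LesionMask":
        if self.data.shape != other.data.shape:
            raise FormatError("cannot union masks on different grids")
        return LesionMask(self.data | other.data, label, self.spacing, self.origin)


@dataclass(frozen=True)
class BoundingBox:
    """Half-open per-axis voxel index ranges ``[min, max)``."""

    mins: tuple[int, int, int]
    maxs: tuple[int, int, int]

    def __post_init__(self):
        mins = tuple(int(v) for v in self.mins)
        maxs = tuple(int(v) for v in self.maxs)
        if any(lo >= hi for lo, hi in zip(mins, maxs)):
            raise BoundsError(f"bounding box must satisfy min < max per axis, got {mins}..{maxs}")
        if any(lo < 0 for lo in mins):
            raise BoundsError(f"bounding box min indices must be >= 0, got {mins}")
        object.__setattr__(self, "mins", mins)
        object.__setattr__(self, "maxs", maxs)

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in zip(self.mins, self.maxs))  # type: ignore[return-value]

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(hi - lo for lo, hi in zip(self.mins, self.maxs))  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# NIfTI I/O (SimpleITK handles the header; arrays are transposed to (x, y, z))
# ---------------------------------------------------------------------------

def read_volume(path: str | Path, modality: str = "CT") -> Volume3D:
    """Read a 3D NIfTI image into a :class:`Volume3D`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise FormatError(f"{path} is {img.GetDimension()}D; a 3D image is required")
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # (z,y,x) -> (x,y,z)
    return Volume3D(data, img.GetSpacing(), img.GetOrigin(), modality)


def write_volume(v: Volume3D | LesionMask, path: str | Path) -> Path:
    """Write a volume or mask as NIfTI (.nii / .nii.gz)."""
    data = v.data.astype(np.uint8) if isinstance(v, LesionMask) else v.data
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
    img.SetSpacing(v.spacing)
    img.SetOrigin(v.origin)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path))
    return path


def read_mask(path: str | Path, label: str = "GTVp") -> LesionMask:
    v = read_volume(path, modality="CT")
    return LesionMask((v.data > 0.5), label, v.spacing, v.origin)


# ---------------------------------------------------------------------------
# Preprocessing transforms
# ---------------------------------------------------------------------------

def zscore_normalize(v: Volume3D, region: Optional[LesionMask] = None) -> Volume3D:
    """Z-score voxel intensities: ``I' = (I - mu) / sigma``.

    ``mu`` and ``sigma`` (population sd) are taken over the whole volume, or
    over ``region`` when given.
    """
    if region is not None:
        if region.data.shape != v.data.shape:
            raise AlignmentError(
                f"region shape {region.data.shape} does not match volume shape {v.data.shape}"
            )
        values = v.data[region.data]
        if values.size == 0:
            raise DegenerateInputError("normalization region is empty")
    else:
        values = v.data
    mu = float(values.mean())
    sigma = float(values.std())  # population sd, ddof=0
    if sigma <= 0 or not math.isfinite(sigma):
        raise DegenerateInputError("cannot z-score a constant volume (sigma = 0)")
    return v.with_data((v.data - mu) / sigma)


CONTRAST_METHODS = ("none", "log", "histogram_equalization")


def enhance_contrast(
    v: Volume3D,
    method: str = "none",
    window: Optional[tuple[float, float]] = None,
) -> Volume3D:
    """Monotone contrast enhancement ``I' = f(I)``.

    ``method`` selects ``f`` from a small registry; ``window=(lo, hi)`` clips
    intensities to a display window first (e.g. HU [-140, 260] for CT, SUV
    [0, 12] for PET). The pipeline default is the identity: which ``f`` best
    serves feature extraction is an open modelling choice, not a given.
    """
    if method not in CONTRAST_METHODS:
        raise ParameterError(f"unknown contrast method {method!r}; choose from {CONTRAST_METHODS}")
    data = v.data
    if window is not None:
        lo, hi = float(window[0]), float(window[1])
        if not lo < hi:
            raise ParameterError(f"window must satisfy lo < hi, got ({lo}, {hi})")
        data = np.clip(data, lo, hi)
    if method == "log":
        # shift so the minimum maps to 0, then log1p: monotone, order-preserving
        data = np.log1p(data - data.min())
    elif method == "histogram_equalization":
        flat = exposure.equalize_hist(data)
        data = flat.reshape(v.data.shape)
    else:
        data = data.copy()
    return v.with_data(data)


def crop_roi(v: Volume3D, box: BoundingBox) -> Volume3D:
    """Crop to a bounding box; spacing is kept, origin shifts to the box corner."""
    for lo, hi, n in zip(box.mins, box.maxs, v.data.shape):
        if hi > n:
            raise BoundsError(f"box {box.mins}..{box.maxs} exceeds grid shape {v.data.shape}")
    origin = tuple(o + lo * s for o, lo, s in zip(v.origin, box.mins, v.spacing))
    return Volume3D(v.data[box.slices].copy(), v.spacing, origin, v.modality)


def crop_mask(mask: LesionMask, box: BoundingBox) -> LesionMask:
    for lo, hi, n in zip(box.mins, box.maxs, mask.data.shape):
        if hi > n:
            raise BoundsError(f"box {box.mins}..{box.maxs} exceeds grid shape {mask.data.shape}")
    origin = tuple(o + lo * s for o, lo, s in zip(mask.origin, box.mins, mask.spacing))
    return LesionMask(mask.data[box.slices].copy(), mask.label, mask.spacing, origin)


def bounding_box_of(mask: LesionMask, margin_mm: float = 0.0) -> BoundingBox:
    """Tightest half-open box around the mask, expanded by ``margin_mm`` and clipped."""
    coords = np.argwhere(mask.data)
    if coords.size == 0:
        raise DegenerateInputError("cannot take the bounding box of an empty mask")
    mins = coords.min(axis=0)
    maxs = coords.max(axis=0) + 1
    if margin_mm < 0:
        raise ParameterError("margin_mm must be >= 0")
    margin_vox = [math.ceil(margin_mm / s) for s in mask.spacing]
    mins = np.maximum(mins - margin_vox, 0)
    maxs = np.minimum(maxs + margin_vox, mask.data.shape)
    return BoundingBox(tuple(mins), tuple(maxs))


def resample(
    v: Volume3D,
    target_spacing: Sequence[float],
    interpolation: str = "linear",
) -> Volume3D:
    """Resample onto a uniform grid with the requested voxel spacing.

    The output grid covers the same physical extent:
    ``new_shape = round(old_shape * old_spacing / new_spacing)``. Intensity
    images default to linear interpolation; masks must use nearest.
    """
    target = _as_tuple3(target_spacing, "target_spacing")
    if any(s <= 0 for s in target):
        raise ParameterError(f"target spacing must be positive, got {target}")
    if interpolation not in ("linear", "nearest"):
        raise ParameterError(f"interpolation must be 'linear' or 'nearest', got {interpolation!r}")
    if np.allclose(target, v.spacing):
        return v.with_data(v.data.copy())
    new_shape = tuple(
        max(1, int(round(n * s / t))) for n, s, t in zip(v.data.shape, v.spacing, target)
    )
    img = sitk.GetImageFromArray(np.ascontiguousarray(v.data.transpose(2, 1, 0)))
    img.SetSpacing(v.spacing)
    img.SetOrigin(v.origin)
    interp = sitk.sitkLinear if interpolation == "linear" else sitk.sitkNearestNeighbor
    out = sitk.Resample(
        img,
        new_shape,
        sitk.Transform(),
        interp,
        v.origin,
        target,
        img.GetDirection(),
        0.0,
        sitk.sitkFloat64,
    )
    data = sitk.GetArrayFromImage(out).transpose(2, 1, 0)
    return Volume3D(data, target, v.origin, v.modality)


def resample_mask(mask: LesionMask, target_spacing: Sequence[float]) -> LesionMask:
    """Nearest-neighbour resampling for binary masks."""
    v = Volume3D(mask.data.astype(np.float64), mask.spacing, mask.origin, "CT")
    out = resample(v, target_spacing, interpolation="nearest")
    return LesionMask(out.data > 0.5, mask.label, out.spacing, out.origin)


def resample_to_grid(v: Volume3D, reference: Volume3D, interpolation: str = "linear") -> Volume3D:
    """Resample ``v`` onto the exact grid (shape/spacing/origin) of ``reference``.

    Used to bring PET onto the finer CT grid before image-level fusion.
    """
    if interpolation not in ("linear", "nearest"):
        raise ParameterError(f"interpolation must be 'linear' or 'nearest', got {interpolation!r}")
    img = sitk.GetImageFromArray(np.ascontiguousarray(v.data.transpose(2, 1, 0)))
    img.SetSpacing(v.spacing)
    img.SetOrigin(v.origin)
    interp = sitk.sitkLinear if interpolation == "linear" else sitk.sitkNearestNeighbor
    out = sitk.Resample(
        img,
        reference.data.shape,
        sitk.Transform(),
        interp,
        reference.origin,
        reference.spacing,
        img.GetDirection(),
        0.0,
        sitk.sitkFloat64,
    )
    data = sitk.GetArrayFromImage(out).transpose(2, 1, 0)
    return Volume3D(data, reference.spacing, reference.origin, v.modality)


def suv_weight_fallback(weight_kg: Optional[float]) -> float:
    """Body weight used for SUV scaling; missing weights fall back to 75 kg."""
    if weight_kg is None or (isinstance(weight_kg, float) and math.isnan(weight_kg)):
        return DEFAULT_BODY_WEIGHT_KG
    weight_kg = float(weight_kg)
    if weight_kg <= 0:
        raise ValidationError(f"recorded body weight must be positive, got {weight_kg}")
    return weight_kg
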