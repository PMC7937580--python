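"""Medical-image volume I/O, geometry checks, and CT-based lung masking.

NIfTI is the canonical on-disk format; DICOM series directories are accepted
read-only. Geometry (shape, voxel spacing, orientation) is enforced strictly:
a volume/mask pair that does not match is an error, never silently resampled,
because the uptake histogram the normalization step depends on is only
meaningful on the native grid.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import nibabel as nib
import numpy as np
from scipy import ndimage

Modality = Literal["ventilation", "perfusion", "ct"]

_UPTAKE_MODALITIES = ("ventilation", "perfusion")
_MODALITIES = ("ventilation", "perfusion", "ct")

#: absolute tolerance (mm) when comparing voxel spacings
SPACING_ATOL_MM = 1e-3


class GeometryError(ValueError):
    """Raised when a volume and mask do not share shape/spacing/orientation."""


class NoLungFoundError(ValueError):
    """Raised when CT lung masking finds no qualifying low-attenuation component."""


class FormatError(ValueError):
    """Raised for malformed or internally inconsistent image inputs."""


def _affine_spacing(affine: np.ndarray) -> tuple[float, float, float]:
    return tuple(float(s) for s in nib.affines.voxel_sizes(affine))


@dataclass
class UptakeVolume:
    """A 3D scalar grid (PET uptake in arbitrary activity units, or CT in HU)
    with its placement metadata.

    ``values`` is indexed [i, j, k]; ``affine`` is the 4x4 voxel-to-world
    matrix (mm). Uptake modalities must be finite and non-negative; CT may be
    negative (air is about -1000 HU).
    """

    values: np.ndarray
    affine: np.ndarray
    modality: Modality

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError(
                f"expected a 3D grid with >=1 voxel per axis, got shape {self.values.shape}"
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if self.modality not in _MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite (NaN/inf) voxel values")
        if self.modality in _UPTAKE_MODALITIES and np.any(self.values < 0):
            raise ValueError(f"{self.modality} uptake must be non-negative")
        if not all(s > 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be strictly positive, got {self.spacing}")

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Per-axis voxel size in mm, derived from the affine."""
        return _affine_spacing(self.affine)

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 mL = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class LungMask:
    """Binary lung mask on the same grid as its paired :class:`UptakeVolume`."""

    values: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("lung mask must be binary (0/1)")
        self.values = arr.astype(bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("lung mask must be a 3D grid")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if not self.values.any():
            raise ValueError("lung mask is empty (no voxel set)")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return _affine_spacing(self.affine)

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())


def check_geometry(volume: UptakeVolume, mask: LungMask | UptakeVolume) -> None:
    """Verify that ``volume`` and ``mask`` live on the same grid.

    Shape must match exactly; spacing within ``SPACING_ATOL_MM``; the
    direction-cosine part of the affine within 1e-3. Raises
    :class:`GeometryError` listing every differing attribute.
    """
    problems: list[str] = []
    if volume.shape != mask.shape:
        problems.append(f"shape: {volume.shape} vs {mask.shape}")
    if not np.allclose(volume.spacing, mask.spacing, atol=SPACING_ATOL_MM):
        problems.append(f"spacing: {volume.spacing} vs {mask.spacing}")
    # orientation: compare normalised direction columns
    va = volume.affine[:3, :3] / np.asarray(volume.spacing)
    ma = mask.affine[:3, :3] / np.asarray(mask.spacing)
    if not np.allclose(va, ma, atol=1e-3):
        problems.append("orientation: direction cosines differ")
    if problems:
        raise GeometryError("geometry mismatch: " + "; ".join(problems))


def read_volume(path: str | os.PathLike, modality: Modality) -> UptakeVolume:
    """Read a NIfTI file or a DICOM series directory into an :class:`UptakeVolume`.

    DICOM slices are assembled in slice-position order by SimpleITK's series
    reader; a series with inconsistent spacing or orientation raises
    :class:`FormatError`.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such file or directory: {p}")
    if p.is_dir():
        values, affine = _read_dicom_series(p)
    else:
        img = nib.load(str(p))
        values = np.asarray(img.get_fdata(), dtype=np.float64)
        affine = np.asarray(img.affine, dtype=np.float64)
        if values.ndim == 4 and values.shape[3] == 1:
            values = values[..., 0]
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{p}: volume contains non-finite voxel values")
    return UptakeVolume(values=values, affine=affine, modality=modality)


def _read_dicom_series(directory: Path) -> tuple[np.ndarray, np.ndarray]:
    import SimpleITK as sitk

    reader = sitk.ImageSeriesReader()
    file_names = reader.GetGDCMSeriesFileNames(str(directory))
    if not file_names:
        raise FormatError(f"{directory}: no DICOM series found")
    reader.SetFileNames(file_names)
    try:
        image = reader.Execute()
    except RuntimeError as exc:  # mixed spacing/orientation etc.
        raise FormatError(f"{directory}: inconsistent DICOM series ({exc})") from exc
    # sanity-check slice spacing uniformity, which SimpleITK tolerates silently
    positions = []
    for fn in file_names:
        import pydicom

        ds = pydicom.dcmread(fn, stop_before_pixels=True)
        positions.append([float(v) for v in ds.ImagePositionPatient])
    if len(positions) > 2:
        steps = np.diff(np.asarray(positions), axis=0)
        step_norms = np.linalg.norm(steps, axis=1)
        if not np.allclose(step_norms, step_norms[0], atol=1e-3):
            raise FormatError(
                f"{directory}: inconsistent DICOM series (non-uniform ImagePositionPatient spacing)"
            )
    # SimpleITK index order is (x,y,z); transpose to (i,j,k)=(x,y,z) array order
    arr = sitk.GetArrayFromImage(image)  # (z,y,x)
    values = np.ascontiguousarray(arr.transpose(2, 1, 0)).astype(np.float64)
    spacing = np.asarray(image.GetSpacing())
    direction = np.asarray(image.GetDirection()).reshape(3, 3)
    origin = np.asarray(image.GetOrigin())
    affine = np.eye(4)
    # LPS (DICOM) -> RAS (NIfTI) flips the first two axes
    lps_to_ras = np.diag([-1.0, -1.0, 1.0])
    affine[:3, :3] = lps_to_ras @ direction @ np.diag(spacing)
    affine[:3, 3] = lps_to_ras @ origin
    return values, affine


def write_volume(volume: UptakeVolume | LungMask, path: str | os.PathLike) -> None:
    """Write a volume or mask to NIfTI.

    Masks are stored as uint8 so the round-trip is bit-exact; uptake is stored
    as float64.
    """
    p = Path(path)
    if not p.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {p.parent}")
    if isinstance(volume, LungMask):
        data = volume.values.astype(np.uint8)
    else:
        data = volume.values.astype(np.float64)
    img = nib.Nifti1Image(data, volume.affine)
    try:
        nib.save(img, str(p))
    except PermissionError as exc:
        raise OSError(f"cannot write {p}: {exc}") from exc


def derive_lung_mask_from_ct(
    ct: UptakeVolume,
    air_threshold: float = -400.0,
    min_component_volume: float = 200.0,
) -> LungMask:
    """Derive a simple lung mask from a CT volume by attenuation thresholding.

    Voxels below ``air_threshold`` (HU) are candidate air; connected components
    reachable from the grid's exterior faces (outside-body air) are discarded,
    as are components smaller than ``min_component_volume`` (mL). This is a
    convenience stand-in for a clinical lung contour: when a curated mask is
    available it should be supplied directly and is treated as authoritative.
    """
    if ct.modality != "ct":
        raise ValueError(f"lung masking requires a CT volume, got modality {ct.modality!r}")
    air = ct.values < air_threshold
    labels, n = ndimage.label(air)
    if n == 0:
        raise NoLungFoundError("no lung found: no voxels below the air threshold")
    # labels present on any exterior face are connected to outside air
    border_labels: set[int] = set()
    for axis in range(3):
        for face in (0, -1):
            sl: list[slice | int] = [slice(None)] * 3
            sl[axis] = face
            border_labels.update(np.unique(labels[tuple(sl)]))
    border_labels.discard(0)
    min_voxels = min_component_volume / ct.voxel_volume_ml
    counts = np.bincount(labels.ravel())
    keep = [
        lab
        for lab in range(1, n + 1)
        if lab not in border_labels and counts[lab] >= min_voxels
    ]
    if not keep:
        raise NoLungFoundError(
            "no lung found: no interior low-attenuation component of at least "
            f"{min_component_volume:g} mL"
        )
    mask = np.isin(labels, keep)
    return LungMask(values=mask, affine=ct.affine)
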