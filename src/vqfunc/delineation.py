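"""Threshold-based functional-volume delineation and matched V/Q volumes.

A functional volume at threshold t is the set of lung voxels whose normalized
uptake is at least t times the converged peak intensity. The comparison is
inclusive (>=) so that hotspot voxels clipped exactly to the peak are part of
every functional volume, as the normalization contract requires. The default
sweep covers 5-70% of peak in 5% steps (14 thresholds). Matched volumes are
the voxelwise intersection of the ventilation and perfusion functional
volumes at the same threshold, each modality normalized independently.

No morphological cleanup is applied: the method is pure thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_volumes import GeometryError, LungMask
from .normalization import NormalizationResult

#: 5% to 70% of peak intensity in 5% increments
DEFAULT_THRESHOLDS: tuple[float, ...] = tuple(round(0.05 * k, 2) for k in range(1, 15))


@dataclass
class FunctionalVolume:
    """Binary functional-lung mask at one threshold fraction of the peak."""

    threshold_fraction: float
    mask: np.ndarray
    lung_voxel_count: int
    voxel_volume_ml: float
    modality: str  # ventilation | perfusion | matched

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def fractional_volume(self) -> float:
        """Functional voxel count over total lung voxel count."""
        return self.voxel_count / self.lung_voxel_count

    @property
    def absolute_volume_ml(self) -> float:
        return self.voxel_count * self.voxel_volume_ml


@dataclass
class ThresholdSweep:
    thresholds: tuple[float, ...]
    volumes: list[FunctionalVolume]

    def __iter__(self):
        return iter(self.volumes)

    def __len__(self) -> int:
        return len(self.volumes)

    def fractional_volumes(self) -> dict[float, float]:
        return {v.threshold_fraction: v.fractional_volume for v in self.volumes}


def delineate(
    normalized: NormalizationResult,
    mask: LungMask,
    threshold_fraction: float,
    modality: str = "ventilation",
    exclude_clipped: bool = False,
) -> FunctionalVolume:
    """Delineate the functional volume at one fraction of the converged peak.

    ``exclude_clipped=True`` removes the voxels the normalization clipped from
    the functional mask — a sensitivity analysis, off by default (clipped
    voxels sit exactly at the peak and are otherwise always included).
    """
    if not (0.0 < threshold_fraction <= 1.0):
        raise ValueError(f"threshold_fraction must lie in (0, 1], got {threshold_fraction}")
    if normalized.normalized_values.shape != mask.shape:
        raise GeometryError(
            f"shape mismatch: {normalized.normalized_values.shape} vs {mask.shape}"
        )
    cutoff = threshold_fraction * normalized.peak_intensity
    functional = mask.values & (normalized.normalized_values >= cutoff)
    if exclude_clipped:
        functional = functional & ~normalized.clipped_mask
    return FunctionalVolume(
        threshold_fraction=float(threshold_fraction),
        mask=functional,
        lung_voxel_count=mask.voxel_count,
        voxel_volume_ml=mask.voxel_volume_ml,
        modality=modality,
    )


def sweep(
    normalized: NormalizationResult,
    mask: LungMask,
    thresholds=DEFAULT_THRESHOLDS,
    modality: str = "ventilation",
    exclude_clipped: bool = False,
) -> ThresholdSweep:
    """Delineate a functional volume at each threshold (default 5-70% by 5%)."""
    thresholds = tuple(float(t) for t in thresholds)
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    volumes = [
        delineate(normalized, mask, t, modality=modality, exclude_clipped=exclude_clipped)
        for t in thresholds
    ]
    return ThresholdSweep(thresholds=thresholds, volumes=volumes)


def matched_volume(
    ventilation: FunctionalVolume, perfusion: FunctionalVolume
) -> FunctionalVolume:
    """Voxelwise intersection of V and Q functional volumes at one threshold."""
    if {ventilation.modality, perfusion.modality} != {"ventilation", "perfusion"}:
        raise ValueError(
            "matched_volume needs one ventilation and one perfusion volume, got "
            f"{ventilation.modality!r} and {perfusion.modality!r}"
        )
    if ventilation.threshold_fraction != perfusion.threshold_fraction:
        raise ValueError(
            f"threshold mismatch: {ventilation.threshold_fraction} vs "
            f"{perfusion.threshold_fraction}"
        )
    if ventilation.mask.shape != perfusion.mask.shape:
        raise GeometryError(
            f"shape mismatch: {ventilation.mask.shape} vs {perfusion.mask.shape}"
        )
    if ventilation.lung_voxel_count != perfusion.lung_voxel_count:
        raise GeometryError("ventilation and perfusion lung masks differ in size")
    vol = ventilation if ventilation.modality == "ventilation" else perfusion
    perf = perfusion if vol is ventilation else ventilation
    return FunctionalVolume(
        threshold_fraction=vol.threshold_fraction,
        mask=vol.mask & perf.mask,
        lung_voxel_count=vol.lung_voxel_count,
        voxel_volume_ml=vol.voxel_volume_ml,
        modality="matched",
    )


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom
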