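"""Iterative histogram-convergence normalization of lung uptake.

Tracer clumping in the proximal airways produces focal voxels tens of times
brighter than functional lung tissue. Thresholding at a fraction of the raw
in-lung maximum is then anchored to an artifact, not to physiology. The
remedy implemented here iteratively replaces the maximum with a representative
*peak intensity*:

1. compute the mean x and standard deviation s of uptake over all lung
   voxels; the candidate peak is x + 4s;
2. if the first candidate is at or above the original maximum, or within 1%
   of it, the maximum is already representative and no reduction is applied;
3. otherwise, voxels strictly above the current candidate are ignored and
   the statistics recomputed; the convergence ratio z_i = c_i / c_{i-1}
   compares successive candidates, and iteration stops once z > 0.99;
4. every supra-peak voxel is reintroduced into the normalized volume clipped
   to the converged peak, so it participates in all downstream functional
   volumes.

Statistics use the population standard deviation (divide by n) over raw
stored voxel values; no histogram binning is performed. Candidates are
non-increasing across iterations (removing values above x + 4s can only
lower both the mean and the spread), so the loop always terminates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_volumes import LungMask, UptakeVolume, check_geometry

#: multiplier k in the candidate peak x + k*s
DEFAULT_SIGMA_MULTIPLIER = 4.0
#: stop once candidate_i / candidate_{i-1} exceeds this ratio
DEFAULT_CONVERGENCE_CUTOFF = 0.99
#: defensive bound; convergence is mathematically guaranteed well before this
MAX_ITERATIONS = 100


class ConvergenceError(RuntimeError):
    """Raised if the iteration cap is hit (pathological input)."""


@dataclass(frozen=True)
class IterationRecord:
    """Statistics of one normalization iteration.

    ``candidate_peak`` is mean + sigma_multiplier * sd over the voxels
    retained at this iteration; ``z`` is the ratio to the previous candidate
    (undefined, ``None``, at the first iteration).
    """

    index: int
    mean: float
    sd: float
    candidate_peak: float
    z: float | None
    retained_count: int


@dataclass
class NormalizationResult:
    """Outcome of :func:`converge_peak` on one volume/mask pair."""

    peak_intensity: float
    reduction_applied: bool
    iterations: list[IterationRecord]
    normalized_values: np.ndarray
    clipped_mask: np.ndarray  # True at voxels reduced to the peak
    normalized_voxel_count: int
    normalized_volume_fraction: float
    original_max: float

    def to_report(self) -> dict:
        """JSON-serialisable summary (for CLI reports and provenance)."""
        return {
            "peak_intensity": self.peak_intensity,
            "original_max": self.original_max,
            "reduction_applied": self.reduction_applied,
            "normalized_voxel_count": self.normalized_voxel_count,
            "normalized_volume_fraction": self.normalized_volume_fraction,
            "iterations": [
                {
                    "index": r.index,
                    "mean": r.mean,
                    "sd": r.sd,
                    "candidate_peak": r.candidate_peak,
                    "z": r.z,
                    "retained_count": r.retained_count,
                }
                for r in self.iterations
            ],
        }


def candidate_sequence(
    values,
    sigma_multiplier: float = DEFAULT_SIGMA_MULTIPLIER,
    convergence_cutoff: float = DEFAULT_CONVERGENCE_CUTOFF,
    max_iterations: int = MAX_ITERATIONS,
) -> tuple[list[IterationRecord], bool, float]:
    """Run the convergence loop on a flat list of in-lung uptake values.

    This is the pure core of :func:`converge_peak`: no geometry, just the
    value list. Returns ``(records, reduction_applied, peak_intensity)``.

    Parameters
    ----------
    values
        Flat array of at least two finite uptake values.
    sigma_multiplier
        k in the candidate peak mean + k*sd (default 4).
    convergence_cutoff
        Iteration stops once candidate_i/candidate_{i-1} exceeds this (default
        0.99, i.e. successive candidates within 1%). The same cutoff governs
        the first-iteration guard against the original maximum.
    """
    vals = np.asarray(values, dtype=np.float64).ravel()
    if vals.size < 2:
        raise ValueError(f"need at least 2 values, got {vals.size}")
    if not np.all(np.isfinite(vals)):
        raise ValueError("values contain non-finite entries")
    if not (0.0 < convergence_cutoff < 1.0):
        raise ValueError("convergence_cutoff must lie in (0, 1)")
    if sigma_multiplier <= 0:
        raise ValueError("sigma_multiplier must be positive")

    original_max = float(vals.max())
    retained = vals
    records: list[IterationRecord] = []

    mean = float(retained.mean())
    sd = float(retained.std())  # population sd (ddof=0)
    candidate = mean + sigma_multiplier * sd
    records.append(
        IterationRecord(
            index=1, mean=mean, sd=sd, candidate_peak=candidate, z=None,
            retained_count=retained.size,
        )
    )
    # First-iteration guard: maximum already representative.
    if candidate >= original_max or candidate >= convergence_cutoff * original_max:
        return records, False, original_max

    prev = candidate
    for i in range(2, max_iterations + 1):
        retained = retained[retained <= prev]  # strictly-above voxels ignored
        if retained.size == 0:
            raise ConvergenceError("all voxels excluded during iteration")
        mean = float(retained.mean())
        sd = float(retained.std())
        candidate = mean + sigma_multiplier * sd
        z = candidate / prev
        records.append(
            IterationRecord(
                index=i, mean=mean, sd=sd, candidate_peak=candidate, z=z,
                retained_count=retained.size,
            )
        )
        if z > convergence_cutoff:
            return records, True, candidate
        prev = candidate
    raise ConvergenceError(f"no convergence within {max_iterations} iterations")


def converge_peak(
    volume: UptakeVolume,
    mask: LungMask,
    sigma_multiplier: float = DEFAULT_SIGMA_MULTIPLIER,
    convergence_cutoff: float = DEFAULT_CONVERGENCE_CUTOFF,
) -> NormalizationResult:
    """Converge the peak intensity over a lung mask and clip supra-peak voxels.

    The returned ``normalized_values`` equal the input everywhere except at
    in-lung voxels strictly above the converged peak, which are set exactly to
    the peak; outside-lung voxels are untouched. Re-running on the output is a
    no-op (the guard fires), and multiplying the uptake by any c > 0 scales
    the peak by c without changing the clipped voxel set or the z trajectory.
    """
    check_geometry(volume, mask)
    in_lung = mask.values
    lung_vals = volume.values[in_lung]
    if lung_vals.size < 2:
        raise ValueError("lung mask must contain at least 2 voxels")

    records, reduction_applied, peak = candidate_sequence(
        lung_vals,
        sigma_multiplier=sigma_multiplier,
        convergence_cutoff=convergence_cutoff,
    )
    normalized = volume.values.copy()
    clipped = np.zeros(volume.shape, dtype=bool)
    if reduction_applied:
        clipped = in_lung & (volume.values > peak)
        normalized[clipped] = peak
    count = int(clipped.sum())
    return NormalizationResult(
        peak_intensity=float(peak),
        reduction_applied=reduction_applied,
        iterations=records,
        normalized_values=normalized,
        clipped_mask=clipped,
        normalized_voxel_count=count,
        normalized_volume_fraction=count / mask.voxel_count,
        original_max=float(lung_vals.max()),
    )
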