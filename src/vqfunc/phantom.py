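"""Synthetic V/Q PET/CT phantoms and cohorts with known ground truth.

The phantom emulates the artifacts the delineation pipeline must survive,
without attempting physical PET simulation (no scanner PSF, attenuation,
scatter, or reconstruction noise):

* two ellipsoidal lungs inside a soft-tissue body on a CT grid (lungs at
  -800 HU, body at 40 HU, exterior air at -1000 HU);
* heterogeneous background uptake drawn from a right-skewed positive
  distribution (lognormal by default, gamma as an option), split into a
  designed high-function region and a low-uptake remainder;
* an optional linear gravity gradient multiplying uptake along one axis;
* focal airway-clumping hotspots: spheres of controllable radius placed
  inside the lung at a stated multiple of the background mean — these are
  the intensity outliers the normalization step must clip;
* perfusion shine-through: a stated fraction of each ventilation hotspot's
  intensity is copied into the paired perfusion image at the same location.

Everything is deterministic given the spec's seed. ``generate_cohort``
produces patient records whose fractional volumes and PFT scores share a
designed Pearson correlation, for parameter-recovery testing of the
correlogram machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cohort_analysis import PFT_METRICS, PatientRecord
from .delineation import DEFAULT_THRESHOLDS
from .io_volumes import LungMask, UptakeVolume

_LUNG_HU = -800.0
_BODY_HU = 40.0
_AIR_HU = -1000.0


@dataclass(frozen=True)
class Hotspot:
    """A spherical clumping artifact: center (voxel coords), radius in mm,
    and intensity as a multiple of the background (high-function) mean."""

    center: tuple[float, float, float]
    radius_mm: float
    intensity_multiple: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("hotspot radius must be positive")
        if self.intensity_multiple <= 1:
            raise ValueError("hotspot intensity_multiple must exceed 1")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic patient's V/Q PET/CT study.

    Defaults give a 64x64x64 grid at 4 mm isotropic (~2.6e5 voxels, ~1e4 lung
    voxels): large enough for realistic in-lung statistics, small enough that
    the whole pipeline runs in seconds.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    # ellipsoids as (center voxel, semi-axes in voxels)
    lung_centers: tuple[tuple[float, float, float], ...] = ((20.0, 32.0, 32.0), (44.0, 32.0, 32.0))
    lung_semiaxes: tuple[tuple[float, float, float], ...] = ((9.0, 12.0, 20.0), (9.0, 12.0, 20.0))
    background_family: str = "lognormal"  # or "gamma"
    background_mean: float = 1.0
    background_cv: float = 0.15  # coefficient of variation of background uptake
    functional_fraction: float = 0.6  # designed high-function share of the lung
    low_uptake_ratio: float = 0.15  # low-function mean as a fraction of background_mean
    gradient_magnitude: float = 0.0  # linear multiplier 1 +/- g along gradient_axis
    gradient_axis: int = 2
    hotspots: tuple[Hotspot, ...] = ()
    shine_through_fraction: float = 0.0
    noise_sd_fraction: float = 0.0  # extra Gaussian noise, sd as fraction of local mean
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.shine_through_fraction <= 1.0):
            raise ValueError("shine_through_fraction must lie in [0, 1]")
        if self.background_family not in ("lognormal", "gamma"):
            raise ValueError(f"unknown background family {self.background_family!r}")
        if not (0.0 < self.functional_fraction <= 1.0):
            raise ValueError("functional_fraction must lie in (0, 1]")


@dataclass
class PhantomTruth:
    """Ground truth carried alongside a generated phantom."""

    lung_mask: LungMask
    hotspot_mask: np.ndarray
    functional_region_mask: np.ndarray
    true_functional_fraction: float
    hotspot_fraction: float  # hotspot voxels / lung voxels


def _ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, center, semiaxes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _sphere_mask(shape, spacing, center, radius_mm) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, sp in zip(grids, center, spacing):
        acc = acc + ((g - c) * sp) ** 2
    return acc <= radius_mm**2


def _background_draw(rng, family, mean, cv, size) -> np.ndarray:
    """Positive right-skewed draw with the requested mean and CV."""
    if cv <= 0:
        return np.full(size, mean)
    if family == "lognormal":
        sigma2 = np.log1p(cv**2)
        mu = np.log(mean) - sigma2 / 2.0
        return rng.lognormal(mu, np.sqrt(sigma2), size)
    # gamma: shape k = 1/cv^2, scale = mean/k
    k = 1.0 / cv**2
    return rng.gamma(k, mean / k, size)


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[UptakeVolume, UptakeVolume, UptakeVolume, PhantomTruth]:
    """Generate a (ventilation, perfusion, CT, truth) tuple from a spec.

    Ventilation and perfusion share the lung geometry and the designed
    functional region but draw independent background noise; hotspots live in
    the ventilation image at full intensity and in the perfusion image scaled
    by ``shine_through_fraction``.
    """
    shape = spec.grid_shape
    rng = np.random.default_rng(spec.seed)
    affine = np.diag([*spec.spacing_mm, 1.0])

    lung = np.zeros(shape, dtype=bool)
    for center, axes in zip(spec.lung_centers, spec.lung_semiaxes):
        lung |= _ellipsoid_mask(shape, center, axes)
    if not lung.any():
        raise ValueError("phantom lung geometry produced an empty mask")

    # body: envelope ellipsoid around both lungs
    body_center = np.mean(np.asarray(spec.lung_centers), axis=0)
    body_axes = np.max(np.asarray(spec.lung_semiaxes), axis=0) * 1.6 + np.max(
        np.abs(np.asarray(spec.lung_centers) - body_center), axis=0
    )
    body = _ellipsoid_mask(shape, body_center, body_axes) | lung
    ct_values = np.full(shape, _AIR_HU)
    ct_values[body] = _BODY_HU
    ct_values[lung] = _LUNG_HU
    ct = UptakeVolume(values=ct_values, affine=affine, modality="ct")

    # designed high-function region: axial fraction of each lung (dependent
    # region), deterministic from the geometry
    functional = np.zeros(shape, dtype=bool)
    lung_idx = np.argwhere(lung)
    axis = spec.gradient_axis
    coords = lung_idx[:, axis]
    cut = np.quantile(coords, 1.0 - spec.functional_fraction, method="nearest")
    sel = coords >= cut
    functional[tuple(lung_idx[sel].T)] = True
    # quantile ties can over/undershoot; accept the realised fraction as truth
    true_frac = functional.sum() / lung.sum()

    hotspot = np.zeros(shape, dtype=bool)
    for h in spec.hotspots:
        s = _sphere_mask(shape, spec.spacing_mm, h.center, h.radius_mm)
        if not (s & lung).sum() or (s & ~lung).any():
            raise ValueError(f"hotspot at {h.center} is not fully inside the lung")
        hotspot |= s

    def one_modality(sub_rng) -> np.ndarray:
        vals = np.zeros(shape)
        n_lung = int(lung.sum())
        bg = _background_draw(
            sub_rng, spec.background_family, spec.background_mean, spec.background_cv, n_lung
        )
        vals[lung] = bg
        low = ~functional & lung
        vals[low] *= spec.low_uptake_ratio
        if spec.gradient_magnitude:
            pos = np.linspace(-1.0, 1.0, shape[axis])
            sl = [None, None, None]
            sl[axis] = slice(None)
            vals *= 1.0 + spec.gradient_magnitude * pos[tuple(sl)]
        if spec.noise_sd_fraction:
            noise = sub_rng.normal(0.0, spec.noise_sd_fraction, n_lung)
            vals[lung] *= np.clip(1.0 + noise, 0.0, None)
        return vals

    vent_vals = one_modality(np.random.default_rng(rng.integers(2**31)))
    perf_vals = one_modality(np.random.default_rng(rng.integers(2**31)))

    hot_levels = np.zeros(shape)
    for h in spec.hotspots:
        s = _sphere_mask(shape, spec.spacing_mm, h.center, h.radius_mm)
        hot_levels[s] = np.maximum(hot_levels[s], h.intensity_multiple * spec.background_mean)
    vent_vals = np.where(hotspot, hot_levels, vent_vals)
    if spec.shine_through_fraction > 0:
        perf_vals = np.where(
            hotspot,
            np.maximum(perf_vals, spec.shine_through_fraction * hot_levels),
            perf_vals,
        )

    truth = PhantomTruth(
        lung_mask=LungMask(values=lung, affine=affine),
        hotspot_mask=hotspot,
        functional_region_mask=functional,
        true_functional_fraction=float(true_frac),
        hotspot_fraction=float(hotspot.sum() / lung.sum()),
    )
    vent = UptakeVolume(values=vent_vals, affine=affine, modality="ventilation")
    perf = UptakeVolume(values=perf_vals, affine=affine, modality="perfusion")
    return vent, perf, ct, truth


def hotspot_validation_specs(n_phantoms: int, seed: int) -> list[PhantomSpec]:
    """Seeded battery of phantoms for end-to-end hotspot-recovery checks.

    Each phantom carries 1-3 spherical hotspots with radii drawn from
    6.6-9.6 mm and intensities 10-50x the background mean, so the total
    hotspot load spans roughly 0.1-1% of the lung volume — the scale of
    clinically reported clumping artifacts. Centers are sampled well inside
    the lung ellipsoids so every sphere fits entirely within the lung.
    """
    rng = np.random.default_rng(seed)
    base = PhantomSpec()
    centers = np.asarray(base.lung_centers)
    semiaxes = np.asarray(base.lung_semiaxes)
    specs = []
    for _ in range(n_phantoms):
        hotspots = []
        for _ in range(int(rng.integers(1, 4))):
            lung_i = int(rng.integers(0, len(centers)))
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            radial = 0.55 * rng.uniform() ** (1.0 / 3.0)
            center = centers[lung_i] + radial * direction * semiaxes[lung_i]
            hotspots.append(
                Hotspot(
                    center=tuple(center),
                    radius_mm=float(rng.uniform(6.6, 9.6)),
                    intensity_multiple=float(rng.uniform(10.0, 50.0)),
                )
            )
        specs.append(
            replace(base, hotspots=tuple(hotspots), shine_through_fraction=0.15,
                    seed=int(rng.integers(2**31)))
        )
    return specs


def generate_cohort(
    n: int,
    correlation_design: dict[str, float],
    seed: int,
    perfusion_only_fraction: float = 14 / 66,
    thresholds=DEFAULT_THRESHOLDS,
    fv_scale: float = 0.08,
    max_clipped_fraction: float = 0.05,
) -> list[tuple[PhantomSpec, PatientRecord]]:
    """Simulate a cohort with designed imaging-PFT correlations.

    Each patient has a latent lung-function score z ~ N(0,1). Fractional
    functional volumes are affine in z (so sweeps nest and the designed
    correlation is exact), and each PFT metric m with designed correlation
    rho_m is rho_m * z + sqrt(1-rho_m^2) * independent noise, mapped to a
    plausible clinical scale. A ``perfusion_only_fraction`` share of patients
    (mirroring cohorts where some patients receive only the perfusion study)
    lack ventilation and matched entries. Clipped-volume fractions are drawn
    from a lognormal with sub-percent median (ventilation 0.23%, perfusion
    0.06%, capped at ``max_clipped_fraction``), with ventilation reduced more
    often than perfusion, matching clinically reported clumping scales. Returns one (PhantomSpec,
    PatientRecord) pair per patient; the spec is a ready-to-run imaging
    phantom whose seed derives from the cohort seed.
    """
    if n < 3:
        raise ValueError(f"cohort size must be at least 3, got {n}")
    for m, rho in correlation_design.items():
        if m not in PFT_METRICS:
            raise ValueError(f"unknown PFT metric {m!r}")
        if not (-1.0 < rho < 1.0):
            raise ValueError(f"designed correlation must lie in (-1, 1), got {m}={rho}")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    n_perf_only = int(round(perfusion_only_fraction * n))
    perf_only = np.zeros(n, dtype=bool)
    perf_only[rng.choice(n, size=n_perf_only, replace=False)] = True

    # affine maps to clinical scales; Pearson r is affine-invariant
    pft_loc = {"fvc_pct_pred": 85.0, "fev_pct_pred": 75.0, "fev_fvc": 0.65, "dlco_pct_pred": 70.0}
    pft_scale = {"fvc_pct_pred": 15.0, "fev_pct_pred": 18.0, "fev_fvc": 0.10, "dlco_pct_pred": 16.0}

    thresholds = tuple(float(t) for t in thresholds)
    t_hi = max(thresholds)
    # per-threshold fractional-volume centres, decreasing in threshold
    centres = {t: 0.85 - 0.75 * (t / t_hi) * 0.8 for t in thresholds}

    out: list[tuple[PhantomSpec, PatientRecord]] = []
    for i in range(n):
        pft = {}
        for m, rho in correlation_design.items():
            eps = rng.standard_normal()
            score = rho * z[i] + np.sqrt(1.0 - rho**2) * eps
            pft[m] = float(max(pft_loc[m] + pft_scale[m] * score, 1e-3))
        fracs: dict[tuple[str, float], float] = {}
        mods = ("perfusion",) if perf_only[i] else ("ventilation", "perfusion")
        offsets = {"ventilation": 0.0, "perfusion": -0.02}
        for mod in mods:
            for t in thresholds:
                f = centres[t] + offsets[mod] + fv_scale * z[i]
                fracs[(mod, t)] = float(np.clip(f, 1e-4, 1.0))
        if not perf_only[i]:
            for t in thresholds:
                fracs[("matched", t)] = min(
                    fracs[("ventilation", t)], fracs[("perfusion", t)]
                )
        # clipped-volume fractions: right-skewed, sub-percent typical scale,
        # ventilation clipped more often and more heavily than perfusion
        reduction_prob = {"ventilation": 48 / 52, "perfusion": 21 / 66}
        clip_median = {"ventilation": 0.0023, "perfusion": 0.0006}
        clip_frac = {}
        for mod in mods:
            if rng.uniform() < reduction_prob[mod]:
                f = clip_median[mod] * float(np.exp(1.3 * rng.standard_normal()))
                clip_frac[mod] = min(f, max_clipped_fraction)
            else:
                clip_frac[mod] = 0.0
        record = PatientRecord(
            patient_id=f"synth{i:03d}",
            pft=pft,
            fractional_volumes=fracs,
            normalized_volume_fraction=clip_frac,
            reduction_applied={mod: f > 0 for mod, f in clip_frac.items()},
        )
        hotspot = Hotspot(center=(20.0, 32.0, 40.0), radius_mm=8.0,
                          intensity_multiple=float(rng.uniform(10.0, 50.0)))
        spec = PhantomSpec(seed=int(rng.integers(2**31)), hotspots=(hotspot,),
                           shine_through_fraction=0.15)
        out.append((spec, record))
    return out
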