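# Methods

## Model and assumptions

The package treats functional lung as the set of lung voxels whose tracer
uptake is at least a stated fraction of a *representative* peak intensity.
Two assumptions underlie this:

* **Uptake ranks function.** Within the lung contour, higher ventilation or
  perfusion tracer uptake indicates better-functioning tissue, up to a
  saturation level; absolute calibration (SUV) is unnecessary because every
  quantity used downstream is a ratio (threshold fraction of peak, voxel
  fraction of lung).
* **Supra-physiological voxels are artifacts.** Focal uptake far above the
  bulk in-lung distribution reflects airway clumping of inhaled tracer (or
  its shine-through into perfusion), not function. The method does not try to
  localise clumping anatomically; it detects and clips intensity outliers
  only. A voxel can be clipped without any clumping being present, and
  clumping inside an otherwise bright region can escape clipping.

## Peak convergence

Let x̄ and σ be the mean and standard deviation of uptake over the currently
retained lung voxels, and c = x̄ + kσ the candidate peak (k = 4 by default).
The first iteration acts as a guard: if c₁ ≥ max or c₁ ≥ 0.99·max, the raw
maximum is kept and nothing is clipped. Otherwise voxels strictly above the
current candidate are excluded, statistics recomputed, and iteration stops
once z = cᵢ/cᵢ₋₁ > 0.99. All voxels above the converged peak are set exactly
to it in the normalized volume, so they belong to every functional volume.

Removing values above x̄ + 4σ can only lower both the mean and the spread of
the retained set, so candidates are non-increasing and z ≤ 1; the loop
terminates because each pass either removes a voxel or satisfies the z
cutoff. A defensive cap of 100 iterations exists but is unreachable in
practice (≤ 7 iterations observed across all validation inputs). The
procedure is scale-equivariant (uptake × c scales the peak by c, leaving the
clipped set and z trajectory unchanged) and idempotent (re-running on its own
output fires the guard).

Numerical conventions, fixed and documented because the choice is otherwise
open:

* σ is the **population** standard deviation (divide by n). At the ~10⁴–10⁵
  voxel counts of a lung this differs from the sample convention by < 10⁻⁴
  relative, but oracle tests require one fixed convention.
* Exclusion during iteration is **strict** (value > candidate is excluded);
  thresholding downstream is **inclusive** (value ≥ t × peak), which
  guarantees clipped voxels, sitting exactly at the peak, are reintroduced.
* The guard compares the first candidate to the **original maximum**
  (c₁ ≥ 0.99·max), matching the convergence cutoff's "within 1%" reading; z
  is undefined at i = 1 and reported as null.
* Zero-uptake voxels inside the lung participate in x̄ and σ; no histogram
  binning is performed — statistics are computed on the raw stored values.
* In-lung statistics require ≥ 2 voxels; non-finite uptake is rejected at
  I/O time.

The constants k = 4, cutoff 0.99, and the 5–70%-by-5% threshold grid are the
method's operating point and are the defaults everywhere; they are exposed in
`RunConfig` only to enable sensitivity analyses.

## Delineation and matched volumes

Functional volumes are pure thresholdings — no connectivity filtering or
morphological cleanup — so masks nest exactly with increasing threshold and
the fractional volume (functional voxels / lung voxels) is non-increasing.
Matched volumes intersect the ventilation and perfusion masks at the same
threshold, with each image normalized to its **own** converged peak (the two
modalities have unrelated activity scales). An off-by-default flag excludes
the clipped voxels from functional volumes to support the sensitivity
analysis described below.

## Geometry and I/O

NIfTI is canonical on disk; DICOM series are read-only input, assembled in
slice-position order and rejected if spacing or orientation varies within the
series. A volume/mask pair with mismatched shape, spacing (> 10⁻³ mm), or
direction cosines is an error — never silently resampled, because resampling
redistributes intensities and corrupts the uptake histogram the convergence
step operates on. The CT lung mask (air below −400 HU, interior connected
components ≥ 200 mL, exterior air excluded) is a convenience for phantoms and
quick looks; any supplied clinical contour is treated as authoritative,
including whatever tumour-exclusion policy it embodies.

## Cohort analysis

Correlogram cells are Pearson correlations over pairwise-complete patients:
perfusion-only patients contribute to perfusion cells only, and matched cells
use only dual-scan patients. Cells with fewer than 3 patients or a constant
input are reported as undefined with a reason, never as r = 0. 95% intervals
use the Fisher z-transform with standard error 1/√(n−3); they are descriptive
only. No multiple-testing correction is applied across the grid — the
correlogram reports effect sizes, not tests. The FEV/FVC column of a cohort
CSV is taken at face value as the measured ratio.

## Synthetic phantoms: what they emulate and what they do not

The imaging phantom provides: two ellipsoidal lungs on a 64³ grid at 4 mm
isotropic (~1.8 × 10⁴ lung voxels, chosen so the full pipeline runs in
seconds at realistic in-lung voxel counts); lognormal background uptake
(default CV 0.15 — positive and right-skewed like tracer uptake; gamma
optional) split into a designed high-function region (default 60% of lung at
full uptake, remainder at 0.15×, a dependent-region pattern); an optional
linear gravity-gradient multiplier (a proxy, not a physiological model);
spherical hotspots at 10–50× background mean; and perfusion shine-through as
a stated fraction of ventilation hotspot intensity. The two-level background
makes the guard meaningful: without hotspots, x̄ + 4σ of the bimodal lung
distribution exceeds the sample maximum and no reduction occurs.

Not emulated: scanner point-spread, attenuation, scatter, reconstruction
noise, partial-volume blur at hotspot edges, and respiratory motion. Passing
phantom tests therefore demonstrates the *algorithmic* contract — outlier
clipping recovers the designed peak and functional region when artifacts are
compact and intense — not performance on reconstructed clinical PET, where
hotspot borders are blurred and lung uptake is textured at many scales.

The cohort simulator draws a latent function score z ~ N(0,1) per patient;
fractional volumes are affine in z (sweeps nest per patient; the designed
imaging–PFT Pearson correlation is exact in population) and each PFT metric
with designed correlation ρ is ρz + √(1−ρ²)ε on a plausible clinical scale.
Because all metrics share one latent factor, the implied PFT–PFT correlation
matrix is positive-definite by construction; designed |ρ| ≥ 1 is rejected.
By default 14/66 of patients are perfusion-only. Clipped-volume fractions are
lognormal with sub-percent medians (ventilation 0.23%, perfusion 0.06%,
σ_ln = 1.3, capped at 5%), applied at reduction rates of 48/52 and 21/66
respectively — the scale and V-over-Q asymmetry reported for clinical
clumping.

## Validation protocol and problem sizes

The acceptance script and end-to-end tests use: 200 flat uptake samples
(n ≤ 10⁴, lognormal backgrounds with 0–5% outliers at 5–100×) checked for
*exact* agreement against an independent from-scratch reference loop; 50
phantoms with 0.1–1% hotspot load (clipped fraction within 0.3 percentage
points of truth; 30%-threshold Dice ≥ 0.95 versus raw-maximum anchoring);
and 500 replicate 66-patient cohorts per designed ρ ∈ {0, 0.3, 0.6, 0.9},
aggregating the four PFT cells of the ventilation modality (n = 52 per cell)
for mean-r bias and Fisher-CI coverage. The clipped-voxel sensitivity check
compares correlograms with clipped voxels included versus excluded on five
simulated cohorts at ρ = 0.6 over thresholds {15%, 30%, 55%}.

## Known limitations

* The clipping statistic is global per image: diffuse (non-focal) artifacts
  that merge with the uptake distribution are not detected.
* The CT lung mask is attenuation-only and will include trachea/main bronchi
  if they are interior air at the chosen threshold; clinical use should
  supply a curated contour.
* Matched volumes assume the V and Q images are already co-registered on an
  identical grid; no registration is performed.
* Printed clinical correlation values from patient cohorts are not
  reproducible here — they depend on private data; cohort-level claims in
  this package are validated on simulation only.
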