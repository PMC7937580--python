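"""End-to-end per-patient pipeline: normalize -> delineate -> match.

``run_pipeline`` ties the stages into one reproducible run directory with
normalized volumes, per-threshold functional masks, matched masks, a tidy
CSV of fractional volumes, and a JSON provenance record (config, package
version, input checksums). Identical inputs and config produce identical
outputs. A missing modality (a perfusion-only study) is handled by running
the available image alone and skipping matched volumes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .delineation import FunctionalVolume, matched_volume, sweep
from .io_volumes import LungMask, UptakeVolume, check_geometry, read_volume, write_volume
from .normalization import NormalizationResult, converge_peak

log = logging.getLogger("vqfunc")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    """An error in a named pipeline stage, carrying the offending file."""

    def __init__(self, stage: str, path, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {path}: {cause}")
        self.stage = stage
        self.path = path


def _normalize_one(
    modality: str,
    pet_path: Path,
    mask: LungMask,
    config: RunConfig,
    out_dir: Path,
) -> tuple[NormalizationResult, dict]:
    try:
        volume = read_volume(pet_path, modality)
        check_geometry(volume, mask)
        result = converge_peak(
            volume,
            mask,
            sigma_multiplier=config.sigma_multiplier,
            convergence_cutoff=config.convergence_cutoff,
        )
    except Exception as exc:
        raise StageError("normalize", pet_path, exc) from exc
    out_nii = out_dir / f"{modality}_normalized.nii.gz"
    write_volume(
        UptakeVolume(values=result.normalized_values, affine=mask.affine, modality=modality),
        out_nii,
    )
    report_path = out_dir / f"{modality}_normalization.json"
    report_path.write_text(json.dumps(result.to_report(), indent=2, sort_keys=True))
    log.info(
        "%s: peak=%.6g (max %.6g), reduction=%s, clipped %.3f%% of lung",
        modality, result.peak_intensity, result.original_max,
        result.reduction_applied, 100 * result.normalized_volume_fraction,
    )
    return result, {"normalized": str(out_nii), "report": str(report_path)}


def _write_sweep(volumes: list[FunctionalVolume], mask: LungMask, out_dir: Path, modality: str):
    rows = []
    for fv in volumes:
        pct = round(fv.threshold_fraction * 100)
        if fv.mask.any():  # empty functional volume: record the row, no mask file
            path = out_dir / f"{modality}_functional_{pct:02d}pct.nii.gz"
            write_volume(LungMask(values=fv.mask, affine=mask.affine), path)
        rows.append(
            {
                "modality": modality,
                "threshold": fv.threshold_fraction,
                "voxels": fv.voxel_count,
                "fractional_volume": fv.fractional_volume,
                "absolute_volume_mL": fv.absolute_volume_ml,
            }
        )
    return rows


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    mask_path: str | Path,
    ventilation_path: str | Path | None = None,
    perfusion_path: str | Path | None = None,
    patient_id: str = "patient",
) -> Path:
    """Run normalize -> delineate (-> match) and write a run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if ventilation_path is None and perfusion_path is None:
        raise ValueError("at least one of ventilation/perfusion is required")

    mask_img = read_volume(mask_path, "ct")  # geometry carrier; values checked below
    mask = LungMask(values=mask_img.values > 0.5, affine=mask_img.affine)

    inputs = {"mask": str(mask_path)}
    results: dict[str, NormalizationResult] = {}
    sweeps: dict[str, list[FunctionalVolume]] = {}
    rows: list[dict] = []
    for modality, path in (("ventilation", ventilation_path), ("perfusion", perfusion_path)):
        if path is None:
            continue
        inputs[modality] = str(path)
        result, _ = _normalize_one(modality, Path(path), mask, config, out)
        results[modality] = result
        try:
            sw = sweep(
                result, mask, thresholds=config.thresholds, modality=modality,
                exclude_clipped=not config.include_clipped_in_volume,
            )
        except Exception as exc:
            raise StageError("delineate", path, exc) from exc
        sweeps[modality] = sw.volumes
        rows.extend(_write_sweep(sw.volumes, mask, out, modality))

    if "ventilation" in sweeps and "perfusion" in sweeps:
        try:
            matched = [
                matched_volume(v, q)
                for v, q in zip(sweeps["ventilation"], sweeps["perfusion"])
            ]
        except Exception as exc:
            raise StageError("match", out, exc) from exc
        rows.extend(_write_sweep(matched, mask, out, "matched"))

    df = pd.DataFrame(rows)
    df.insert(0, "patient_id", patient_id)
    df.to_csv(out / "fractional_volumes.csv", index=False)

    provenance = {
        "package": "vqfunc",
        "version": __version__,
        "patient_id": patient_id,
        "config": config.to_dict(),
        "inputs": {k: {"path": v, "sha256": _sha256(Path(v))} for k, v in inputs.items()},
        "normalization": {m: r.to_report() for m, r in results.items()},
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    return out
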