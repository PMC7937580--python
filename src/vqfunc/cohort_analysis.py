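"""Cohort-level correlograms of fractional functional volume vs PFTs.

Each cohort member carries pulmonary function test (PFT) scores — FVC and FEV
as % of predicted, the FEV/FVC ratio, and DLCO % predicted — plus the
fractional functional volume at every (modality, threshold). The correlogram
is the grid of Pearson correlation coefficients over (PFT metric x modality x
threshold), computed on pairwise-complete patients: a patient missing a scan
(a perfusion-only study, for example) contributes only to the cells of the
modalities they have, and matched-volume cells use only patients with both
scans. 95% confidence intervals come from the Fisher z-transform,
r = tanh(atanh(r) +/- 1.96 / sqrt(n-3)); they quantify uncertainty and do not
gate anything. No multiple-testing correction is applied across the grid —
the correlogram reports effect sizes, not hypothesis tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

PFT_METRICS = ("fvc_pct_pred", "fev_pct_pred", "fev_fvc", "dlco_pct_pred")
MODALITIES = ("ventilation", "perfusion", "matched")

#: minimum pairwise-complete patients for a defined correlation cell
MIN_N = 3


@dataclass
class PatientRecord:
    """One patient's PFT scores and per-(modality, threshold) fractional volumes.

    ``fractional_volumes`` maps ``(modality, threshold_fraction)`` to the
    fraction of total lung delineated; ``normalized_volume_fraction`` maps
    modality to the fraction of lung clipped during normalization (None for a
    modality where no reduction was applied is expressed as 0.0; a missing
    modality is simply absent from both maps).
    """

    patient_id: str
    pft: dict[str, float]
    fractional_volumes: dict[tuple[str, float], float] = field(default_factory=dict)
    normalized_volume_fraction: dict[str, float] = field(default_factory=dict)
    reduction_applied: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, v in self.pft.items():
            if key not in PFT_METRICS:
                raise ValueError(f"unknown PFT metric {key!r}")
            if not (v > 0):
                raise ValueError(f"PFT value must be positive, got {key}={v}")
        for (mod, t), f in self.fractional_volumes.items():
            if mod not in MODALITIES:
                raise ValueError(f"unknown modality {mod!r}")
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"fractional volume out of [0,1]: {mod}@{t} = {f}")

    def modalities(self) -> set[str]:
        return {mod for mod, _ in self.fractional_volumes}


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher z-transform confidence interval for a Pearson correlation."""
    if n <= 3 or abs(r) >= 1.0:
        return (float("nan"), float("nan"))
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    crit = stats.norm.ppf(0.5 + level / 2.0)
    return (math.tanh(z - crit * se), math.tanh(z + crit * se))


@dataclass
class CorrelogramTable:
    """Tidy table of correlation cells.

    ``data`` columns: pft_metric, modality, threshold, r, n, ci_low, ci_high,
    defined, reason. Undefined cells (too few patients, or a constant input)
    keep r = NaN with the reason recorded, never a fabricated 0.
    """

    data: pd.DataFrame

    def cell(self, pft_metric: str, modality: str, threshold: float) -> pd.Series:
        sel = self.data[
            (self.data.pft_metric == pft_metric)
            & (self.data.modality == modality)
            & (np.isclose(self.data.threshold, threshold))
        ]
        if sel.empty:
            raise KeyError((pft_metric, modality, threshold))
        return sel.iloc[0]

    def r(self, pft_metric: str, modality: str, threshold: float) -> float:
        return float(self.cell(pft_metric, modality, threshold).r)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @property
    def defined_fraction(self) -> float:
        return float(self.data.defined.mean())


def build_correlogram(
    cohort: list[PatientRecord],
    pft_metrics=PFT_METRICS,
    ci_level: float = 0.95,
) -> CorrelogramTable:
    """Compute Pearson r per (PFT metric, modality, threshold) cell.

    Thresholds and modalities are discovered from the cohort's fractional
    volume keys. Cells are computed on pairwise-complete patients (both the
    PFT value and that modality's fractional volume present).
    """
    if not cohort:
        raise ValueError("cohort is empty")
    keys = sorted({k for p in cohort for k in p.fractional_volumes})
    rows = []
    for mod, t in keys:
        for metric in pft_metrics:
            xs, ys = [], []
            for p in cohort:
                if metric in p.pft and (mod, t) in p.fractional_volumes:
                    xs.append(p.pft[metric])
                    ys.append(p.fractional_volumes[(mod, t)])
            n = len(xs)
            row = {
                "pft_metric": metric,
                "modality": mod,
                "threshold": t,
                "n": n,
                "r": float("nan"),
                "ci_low": float("nan"),
                "ci_high": float("nan"),
                "defined": False,
                "reason": "",
            }
            if n < MIN_N:
                row["reason"] = f"fewer than {MIN_N} pairwise-complete patients"
            elif np.ptp(xs) == 0 or np.ptp(ys) == 0:
                row["reason"] = "constant input"
            else:
                r = float(stats.pearsonr(xs, ys).statistic)
                lo, hi = fisher_ci(r, n, level=ci_level)
                row.update(r=r, ci_low=lo, ci_high=hi, defined=True)
            rows.append(row)
    return CorrelogramTable(data=pd.DataFrame(rows))


def summarize_normalized_volumes(cohort: list[PatientRecord]) -> pd.DataFrame:
    """Per-modality median/mean/max clipped-volume fraction, as % of total lung.

    Statistics are computed over patients for whom a reduction was actually
    applied; ``n_reduced``/``n_total`` records how many of the patients with
    that modality needed one. Modalities with no scanned patient are omitted.
    """
    rows = []
    for mod in ("ventilation", "perfusion"):
        scanned = [p for p in cohort if mod in p.normalized_volume_fraction]
        if not scanned:
            continue
        reduced = [
            p.normalized_volume_fraction[mod]
            for p in scanned
            if p.reduction_applied.get(mod, p.normalized_volume_fraction[mod] > 0)
        ]
        row = {
            "modality": mod,
            "n_reduced": len(reduced),
            "n_total": len(scanned),
            "median_pct": float("nan"),
            "mean_pct": float("nan"),
            "max_pct": float("nan"),
        }
        if reduced:
            arr = 100.0 * np.asarray(reduced)
            row.update(
                median_pct=float(np.median(arr)),
                mean_pct=float(arr.mean()),
                max_pct=float(arr.max()),
            )
        rows.append(row)
    if not rows:
        raise ValueError("no modality with at least one scanned patient")
    return pd.DataFrame(rows)


def plot_correlogram(table: CorrelogramTable, out: str | Path) -> None:
    """Render the correlogram as one heatmap panel per modality.

    Thresholds run along the x-axis, PFT metrics along the y-axis, cell color
    is Pearson r on a symmetric [-1, 1] diverging scale; undefined cells are
    hatched. Output is deterministic for a given table.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = table.data
    if df.empty or not df.defined.any():
        raise ValueError("correlogram has no defined cells to plot")
    modalities = [m for m in MODALITIES if (df.modality == m).any()]
    metrics = list(dict.fromkeys(df.pft_metric))
    fig, axes = plt.subplots(
        1, len(modalities), figsize=(5.2 * len(modalities), 3.2), squeeze=False
    )
    for ax, mod in zip(axes[0], modalities):
        sub = df[df.modality == mod]
        thresholds = sorted(sub.threshold.unique())
        grid = np.full((len(metrics), len(thresholds)), np.nan)
        for _, row in sub.iterrows():
            i = metrics.index(row.pft_metric)
            j = thresholds.index(row.threshold)
            grid[i, j] = row.r
        masked = np.ma.masked_invalid(grid)
        im = ax.imshow(masked, vmin=-1, vmax=1, cmap="RdBu_r", aspect="auto")
        # hatch undefined cells
        for (i, j), bad in np.ndenumerate(masked.mask):
            if bad:
                ax.add_patch(
                    plt.Rectangle((j - 0.5, i - 0.5), 1, 1, fill=False, hatch="///")
                )
        ax.set_xticks(range(len(thresholds)))
        ax.set_xticklabels([f"{t:.0%}" for t in thresholds], rotation=90, fontsize=7)
        ax.set_yticks(range(len(metrics)))
        ax.set_yticklabels(metrics, fontsize=7)
        ax.set_title(mod)
        ax.set_xlabel("threshold (% of peak)")
    fig.colorbar(im, ax=axes[0].tolist(), label="Pearson r", shrink=0.85)
    fig.savefig(out, dpi=150, metadata={"Software": None} if str(out).endswith(".png") else None)
    plt.close(fig)


def cohort_to_frame(cohort: list[PatientRecord]) -> pd.DataFrame:
    """Flatten a cohort to the tool's CSV schema.

    Columns: patient_id, the four PFT metrics, then ``<modality>_<pct>``
    fractional-volume columns (e.g. ``ventilation_30``) and
    ``<modality>_normalized_fraction``.
    """
    rows = []
    for p in cohort:
        row: dict[str, object] = {"patient_id": p.patient_id}
        for m in PFT_METRICS:
            row[m] = p.pft.get(m, float("nan"))
        for (mod, t), f in sorted(p.fractional_volumes.items()):
            row[f"{mod}_{round(t * 100):d}"] = f
        for mod, f in p.normalized_volume_fraction.items():
            row[f"{mod}_normalized_fraction"] = f
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_from_frame(df: pd.DataFrame) -> list[PatientRecord]:
    """Inverse of :func:`cohort_to_frame` (NaN cells mean missing data)."""
    cohort = []
    for _, row in df.iterrows():
        pft = {
            m: float(row[m])
            for m in PFT_METRICS
            if m in row and pd.notna(row[m])
        }
        fracs: dict[tuple[str, float], float] = {}
        normfrac: dict[str, float] = {}
        for col in df.columns:
            if pd.isna(row[col]):
                continue
            for mod in MODALITIES:
                if col == f"{mod}_normalized_fraction":
                    normfrac[mod] = float(row[col])
                elif col.startswith(f"{mod}_"):
                    suffix = col[len(mod) + 1 :]
                    if suffix.isdigit():
                        fracs[(mod, int(suffix) / 100.0)] = float(row[col])
        cohort.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                pft=pft,
                fractional_volumes=fracs,
                normalized_volume_fraction=normfrac,
            )
        )
    return cohort
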