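"""Voxel-wise apparent diffusion coefficient (ADC) mapping from DW-MRI.

The signal of a mono-exponentially diffusing voxel follows
S(b) = S0 * exp(-b * ADC), so an ordinary least-squares fit of ln S against
the diffusion weighting b yields the ADC as minus the slope; the intercept
absorbs the S0 normalization.  Voxels with a non-positive signal at any
b-value are outside the domain of the log transform and are flagged
invalid.  Tumor voxels with ADC above a threshold (default
0.0011 mm^2/s) are classified as necrotic — high diffusivity reflects low
cellularity — and the per-tumor summary statistic is the median ADC over
valid ROI voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

NECROSIS_ADC_THRESHOLD = 0.0011  # mm^2/s


@dataclass
class DWISeries:
    """Stack of diffusion-weighted images, one frame per b-value."""

    signals: np.ndarray  # (n_b, *spatial)
    b_values: np.ndarray  # s/mm^2
    roi: np.ndarray | None = None
    voxel_size_mm: float = 1.0

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, float)
        self.b_values = np.asarray(self.b_values, float)
        if self.b_values.ndim != 1 or np.unique(self.b_values).size < 2:
            raise ValueError("need at least 2 distinct b-values")
        if self.signals.shape[0] != self.b_values.size:
            raise ValueError("one signal frame per b-value required")
        if self.roi is None:
            self.roi = np.ones(self.signals.shape[1:], bool)
        self.roi = np.asarray(self.roi, bool)
        if self.roi.shape != self.signals.shape[1:]:
            raise ValueError("ROI shape must match the image frames")


@dataclass
class ADCMap:
    adc: np.ndarray  # mm^2/s; NaN where invalid
    intercept: np.ndarray
    valid: np.ndarray
    roi: np.ndarray
    voxel_size_mm: float = 1.0
    invalid_reason: str = field(default="non-positive signal at some b-value")


def fit_adc(series: DWISeries) -> ADCMap:
    """Per-voxel OLS fit of ln S on b; ADC = -slope, intercept returned too."""
    if not series.roi.any():
        raise ValueError("empty ROI")
    b = series.b_values
    sig = series.signals.reshape(b.size, -1)
    valid = (sig > 0).all(axis=0) & series.roi.ravel()
    if not valid.any():
        raise ValueError("all ROI voxels have non-positive signals")
    design = np.column_stack([b, np.ones_like(b)])
    adc = np.full(sig.shape[1], np.nan)
    intercept = np.full(sig.shape[1], np.nan)
    logs = np.log(sig[:, valid])
    coef, *_ = np.linalg.lstsq(design, logs, rcond=None)
    adc[valid] = -coef[0]
    intercept[valid] = coef[1]
    shape = series.signals.shape[1:]
    return ADCMap(
        adc=adc.reshape(shape),
        intercept=intercept.reshape(shape),
        valid=valid.reshape(shape),
        roi=series.roi,
        voxel_size_mm=series.voxel_size_mm,
    )


def classify_necrosis(
    adc_map: ADCMap, threshold: float = NECROSIS_ADC_THRESHOLD
) -> tuple[np.ndarray, float]:
    """Necrosis mask (ADC strictly above threshold) and necrotic fraction of the ROI."""
    valid = adc_map.valid & adc_map.roi
    if not valid.any():
        raise ValueError("no valid voxels")
    mask = np.zeros_like(valid)
    mask[valid] = adc_map.adc[valid] > threshold
    fraction = float(mask.sum() / valid.sum())
    return mask, fraction


def median_adc(adc_map: ADCMap) -> float:
    """Median ADC over valid ROI voxels (necrotic voxels included)."""
    valid = adc_map.valid & adc_map.roi
    if not valid.any():
        raise ValueError("no valid voxels")
    return float(np.median(adc_map.adc[valid]))


def relative_adc(
    median_by_day: dict[str, dict[float, float]], groups: dict[str, str] | None = None
) -> dict:
    """Per-tumor ADC ratios to day 0 with one-sample and group t-tests.

    ``median_by_day`` maps tumor id -> {day: median ADC}; day 0 must be
    present and positive.  Returns per-tumor ratio series, per-day group
    mean +/- SEM, one-sample t-tests of the ratios against 1 per day, and
    (when two groups each have >= 2 tumors) two-sample t-tests between
    groups per day.
    """
    ratios: dict[str, dict[float, float]] = {}
    for tumor, series in median_by_day.items():
        if 0 not in series and 0.0 not in series:
            raise ValueError(f"tumor {tumor!r} is missing the day-0 baseline")
        base = series.get(0, series.get(0.0))
        if base <= 0:
            raise ValueError(f"tumor {tumor!r} has non-positive baseline ADC")
        ratios[tumor] = {day: v / base for day, v in series.items()}
    days = sorted({d for s in ratios.values() for d in s})
    groups = groups or {t: "all" for t in ratios}
    out = {"ratios": ratios, "per_day": {}}
    for day in days:
        by_group: dict[str, list[float]] = {}
        for tumor, series in ratios.items():
            if day in series:
                by_group.setdefault(groups.get(tumor, "all"), []).append(series[day])
        entry: dict[str, object] = {}
        for gname, vals in by_group.items():
            v = np.asarray(vals, float)
            sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else np.nan
            if v.size <= 1:
                one_p = np.nan
            elif v.std(ddof=1) == 0:  # degenerate: all ratios identical
                one_p = 1.0 if v[0] == 1.0 else 0.0
            else:
                one_p = float(stats.ttest_1samp(v, 1.0).pvalue)
            entry[gname] = {"mean": float(v.mean()), "sem": sem, "n": int(v.size),
                            "p_vs_baseline": one_p}
        gnames = sorted(by_group)
        if len(gnames) == 2:
            a, bvals = by_group[gnames[0]], by_group[gnames[1]]
            if min(len(a), len(bvals)) < 2:
                raise ValueError("two-sample comparison needs >= 2 tumors per group")
            entry["p_between_groups"] = float(stats.ttest_ind(a, bvals).pvalue)
        out["per_day"][day] = entry
    return out
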