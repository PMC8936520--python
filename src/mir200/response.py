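"""Radiation-response metrics in vitro and in vivo.

Clonogenic survival fractions, gammaH2Ax double-strand-break signal
normalized to a spiked-in REH reference population, exponential tumor
growth kinetics (doubling time Td), the time-to-1.5x-baseline endpoint
(T1.5x), tumor growth delay (TGD) and the radiosensitization enhancement
factor (EF = TGD ratio between a miRNA-overexpressing line and its
control).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GrowthCurve:
    """Volume measurements of a single tumor over time.

    Days must be strictly increasing and volumes positive; day 0 is the
    baseline (irradiation day for treated tumors).
    """

    tumor_id: str
    group: str
    days: np.ndarray
    volumes_mm3: np.ndarray
    irradiation_day: float | None = None

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, float)
        self.volumes_mm3 = np.asarray(self.volumes_mm3, float)
        if not np.all(np.diff(self.days) > 0):
            raise ValueError("measurement days must be strictly increasing")
        if np.any(self.volumes_mm3 <= 0):
            raise ValueError("volumes must be positive")


def plating_efficiency(colonies: int, seeded: int) -> float:
    """Fraction of unirradiated cells that form a >50-cell colony."""
    if seeded <= 0:
        raise ValueError("seeded cell count must be positive")
    if colonies > seeded or colonies < 0:
        raise ValueError("colony count must lie in [0, seeded]")
    return colonies / seeded


def survival_fraction(colonies: int, seeded: int, pe: float) -> float:
    """Clonogenic survival fraction at a dose, corrected by plating efficiency."""
    if not (0 < pe <= 1):
        raise ValueError("plating efficiency must lie in (0, 1]")
    return plating_efficiency(colonies, seeded) / pe


def relative_gamma_h2ax(
    sample_median: float, reh_median: float, baseline_ratio: float
) -> float:
    """gammaH2Ax signal normalized to the REH spike-in, relative to unirradiated.

    (sample/REH) divided by the unirradiated sample's (sample/REH) ratio.
    """
    if reh_median <= 0:
        raise ValueError("REH median intensity must be positive")
    if baseline_ratio <= 0:
        raise ValueError("baseline ratio must be positive")
    return (sample_median / reh_median) / baseline_ratio


def doubling_time(curve: GrowthCurve, window: tuple[float, float] | None = None) -> float:
    """Exponential-phase doubling time Td = ln2 / slope of ln V vs t (days).

    ``window`` restricts the fit to a day range (the manually identified
    exponential phase).  A non-positive slope returns inf (non-growing).
    """
    days, vols = curve.days, curve.volumes_mm3
    if window is not None:
        keep = (days >= window[0]) & (days <= window[1])
        days, vols = days[keep], vols[keep]
    if days.size < 3:
        raise ValueError("need at least 3 measurements in the fit window")
    slope, _ = np.polyfit(days, np.log(vols), 1)
    if slope <= 1e-12:  # flat or shrinking: non-growing
        return float("inf")
    return float(np.log(2.0) / slope)


def time_to_factor(curve: GrowthCurve, factor: float = 1.5) -> tuple[float, bool]:
    """First time the volume reaches factor x baseline, linearly interpolated.

    Returns (T days, censored); a tumor that never crosses is censored at
    its last measurement day.  Day 0 must be present.
    """
    if curve.days[0] != 0:
        raise ValueError("day-0 baseline measurement required")
    target = factor * curve.volumes_mm3[0]
    v = curve.volumes_mm3
    above = np.where(v >= target)[0]
    if above.size == 0:
        return float(curve.days[-1]), True
    i = int(above[0])
    if v[i] == target or i == 0:
        return float(curve.days[i]), False
    t0, t1 = curve.days[i - 1], curve.days[i]
    v0, v1 = v[i - 1], v[i]
    return float(t0 + (t1 - t0) * (target - v0) / (v1 - v0)), False


def growth_delay(
    curves: list[GrowthCurve],
    mir_line: str = "mir200",
    control_line: str = "control",
    factor: float = 1.5,
    censor_warn_fraction: float = 0.2,
) -> dict:
    """Tumor growth delay and enhancement factor from T1.5x endpoints.

    Groups are named ``"<line>_irradiated"`` / ``"<line>_unirradiated"``.
    TGD(line) = mean T1.5x(irradiated) - mean T1.5x(unirradiated) over
    uncensored tumors; EF = TGD(miR line) / TGD(control line), undefined
    (NaN, flagged) when the control TGD is <= 0.  Also reports the
    two-sample t-test between the irradiated groups and a per-group
    censoring flag when more than ``censor_warn_fraction`` of tumors never
    reach the endpoint.
    """
    records = []
    for c in curves:
        t, cens = time_to_factor(c, factor)
        records.append({"tumor_id": c.tumor_id, "group": c.group, "t": t, "censored": cens})
    df = pd.DataFrame(records)
    out: dict = {"per_tumor": df}
    means, flags = {}, {}
    for g, sub in df.groupby("group"):
        unc = sub.loc[~sub["censored"], "t"]
        means[g] = float(unc.mean()) if len(unc) else np.nan
        flags[g] = bool(sub["censored"].mean() > censor_warn_fraction)
    out["group_mean_t"] = means
    out["high_censoring"] = flags
    tgd = {}
    for line in (mir_line, control_line):
        irr, unirr = f"{line}_irradiated", f"{line}_unirradiated"
        if irr in means and unirr in means:
            tgd[line] = means[irr] - means[unirr]
    out["tgd"] = tgd
    ef = np.nan
    ef_defined = False
    if mir_line in tgd and control_line in tgd:
        if tgd[control_line] > 0:
            ef = tgd[mir_line] / tgd[control_line]
            ef_defined = True
    out["ef"] = float(ef)
    out["ef_defined"] = ef_defined
    a = df.loc[(df["group"] == f"{mir_line}_irradiated") & ~df["censored"], "t"]
    b = df.loc[(df["group"] == f"{control_line}_irradiated") & ~df["censored"], "t"]
    if len(a) >= 2 and len(b) >= 2:
        if a.std() == 0 and b.std() == 0:  # degenerate noiseless groups
            out["p_irradiated_groups"] = 1.0 if a.mean() == b.mean() else 0.0
        else:
            out["p_irradiated_groups"] = float(stats.ttest_ind(a, b).pvalue)
    return out
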