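"""miRNA expression normalization and the miR-200a/b/-429 score.

The score summarizes the coordinated expression of the five chromosome-1
miR-200 family members (miR-200a-5p/-3p, miR-200b-5p/-3p, miR-429) in a
tumor: each member's log2 expression is median-centered across the cohort
and the per-patient score is the arithmetic mean of the centered values.
A three-member variant (miR-200a-3p, miR-200b-3p, miR-429) supports
RT-qPCR cohorts where the 5p strands were not assayed.

Expression matrices are pandas DataFrames with features (mature miRNA
names) as the index and samples as columns.  A ``scale`` entry in
``DataFrame.attrs`` records how values were derived (``log2_rpm``,
``neg_delta_ct`` or ``log2_intensity``); all scales are log2-like, so
higher always means more abundant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

FIVE_MEMBER_SCORE = (
    "hsa-miR-200a-5p",
    "hsa-miR-200a-3p",
    "hsa-miR-200b-5p",
    "hsa-miR-200b-3p",
    "hsa-miR-429",
)
THREE_MEMBER_SCORE = ("hsa-miR-200a-3p", "hsa-miR-200b-3p", "hsa-miR-429")

SCALE_TAGS = ("log2_rpm", "neg_delta_ct", "log2_intensity")


@dataclass
class ScoreVector:
    """Per-sample miR-200a/b/-429 score with the member list that produced it."""

    values: pd.Series
    members: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValueError("score must record a non-empty member list")
        if not np.all(np.isfinite(self.values.to_numpy(float))):
            raise ValueError("scores must be finite")


def normalize_rpm(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2 reads-per-million normalization of a raw miRNA count matrix.

    value = log2(count / sample_total * 1e6 + pseudocount).  The pseudocount
    keeps zero counts finite on the log scale.
    """
    arr = counts.to_numpy(float)
    if (arr < 0).any():
        raise ValueError("count matrix contains negative entries")
    totals = arr.sum(axis=0)
    bad = np.where(totals <= 0)[0]
    if bad.size:
        names = ", ".join(str(counts.columns[i]) for i in bad)
        raise ValueError(f"zero total count in sample(s): {names}")
    rpm = arr / totals * 1e6
    out = pd.DataFrame(np.log2(rpm + pseudocount), index=counts.index, columns=counts.columns)
    out.attrs["scale"] = "log2_rpm"
    return out


def median_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each feature's median across samples, so every row has median 0."""
    if matrix.shape[1] < 1:
        raise ValueError("at least one sample required")
    if matrix.isna().all(axis=1).any():
        missing = matrix.index[matrix.isna().all(axis=1)].tolist()
        raise ValueError(f"feature(s) with no observed values: {missing}")
    centered = matrix.sub(matrix.median(axis=1), axis=0)
    centered.attrs = dict(matrix.attrs)
    return centered


def compute_score(
    matrix: pd.DataFrame,
    members: tuple[str, ...] = FIVE_MEMBER_SCORE,
    allow_subset: bool = False,
    center: bool = True,
) -> ScoreVector:
    """Per-sample mean of the median-centered log2 expression of the members.

    Parameters
    ----------
    matrix
        Features x samples log2-scale expression.
    members
        miRNA ids averaged into the score.
    allow_subset
        If True, members absent from the matrix are dropped (the used subset
        is recorded); otherwise a missing member raises.
    center
        Median-center the member rows first (the standard definition).  Set
        False only if the matrix is already centered.
    """
    present = [m for m in members if m in matrix.index]
    missing = [m for m in members if m not in matrix.index]
    if missing and not allow_subset:
        raise KeyError(f"score member(s) not in matrix: {missing}")
    if not present:
        raise KeyError("no score members present in matrix")
    sub = matrix.loc[present]
    if center:
        sub = median_center(sub)
    return ScoreVector(values=sub.mean(axis=0), members=tuple(present))


def expression_from_ct(
    ct: pd.DataFrame, references: tuple[str, ...]
) -> pd.DataFrame:
    """Convert an RT-qPCR Ct table to a log2-like expression matrix.

    Each feature's Ct is normalized to the mean Ct of the reference RNAs in
    the same sample and negated (-dCt), so that higher values mean higher
    abundance, matching the sequencing-based log2 scale.  Reference rows
    are dropped from the output.
    """
    if len(references) == 0:
        raise ValueError("at least one reference feature required")
    missing_ref = [r for r in references if r not in ct.index]
    if missing_ref:
        raise KeyError(f"reference feature(s) not in Ct table: {missing_ref}")
    arr = ct.to_numpy(float)
    if np.nanmin(arr) <= 0 or np.nanmax(arr) > 40:
        raise ValueError("Ct values must lie in (0, 40]")
    ref = ct.loc[list(references)]
    if ref.isna().any().any():
        bad = ref.columns[ref.isna().any(axis=0)].tolist()
        raise ValueError(f"missing reference Ct in sample(s): {bad}")
    neg_dct = -(ct.sub(ref.mean(axis=0), axis=1))
    out = neg_dct.drop(index=list(references))
    out.attrs["scale"] = "neg_delta_ct"
    return out


def white_heteroscedasticity_test(
    fitted: np.ndarray, residuals: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """White test for heteroscedasticity of residuals against fitted values.

    Regresses squared residuals on the fitted value and its square; the LM
    statistic n*R^2 is chi-square with 2 df under homoscedasticity.  Returns
    (statistic, p, points) where points is the (fitted, residual) array for
    the diagnostic residual-versus-predicted plot.
    """
    fitted = np.asarray(fitted, float)
    residuals = np.asarray(residuals, float)
    if fitted.size != residuals.size:
        raise ValueError("fitted and residuals must have equal length")
    if fitted.size < 5:
        raise ValueError("need at least 5 observations")
    if np.ptp(fitted) == 0:
        raise ValueError("fitted values have zero variance")
    from scipy import stats

    n = fitted.size
    sq = residuals**2
    if np.ptp(sq) == 0:  # constant squared residuals carry no signal
        stat, p = 0.0, 1.0
    else:
        exog = sm.add_constant(np.column_stack([fitted, fitted**2]))
        aux = sm.OLS(sq, exog).fit()
        stat = n * aux.rsquared
        p = float(stats.chi2.sf(stat, df=2))
    points = np.column_stack([fitted, residuals])
    return float(stat), p, points
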