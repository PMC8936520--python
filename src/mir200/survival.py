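"""Site-specific survival analysis for biomarker evaluation.

Builds per-site endpoints (central pelvic control, lateral pelvic control,
distal control, progression-free survival) from clinical follow-up tables,
estimates Kaplan-Meier curves, runs log-rank tests and Cox proportional
hazards models (uni- and multivariate with forward/backward stepwise
selection), and performs an exhaustive optimal-cutoff scan of a continuous
biomarker with permutation-based multiplicity correction.

Clinical tables are pandas DataFrames with one row per patient and columns
``patient_id``, ``followup_months``, ``recurrence_site`` (one of
``central``/``lateral``/``distant``, empty or NaN if none; multi-site
recurrences as ``;``-separated labels), ``recurrence_months``, plus any
covariates.  Endpoint tables carry ``time`` (months) and ``event`` (0/1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

SITES = ("central", "lateral", "distant")
ENDPOINTS = ("central_control", "lateral_control", "distal_control", "pfs")
_SITE_OF_ENDPOINT = {
    "central_control": "central",
    "lateral_control": "lateral",
    "distal_control": "distant",
}


@dataclass
class CoxResult:
    covariate: str
    coef: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    converged: bool = True

    def __post_init__(self) -> None:
        if self.converged and not (self.ci_low <= self.hr <= self.ci_high):
            raise ValueError("HR must lie inside its confidence interval")


@dataclass
class KMCurve:
    """Product-limit curve for one group: survival at each event time."""

    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray


@dataclass
class CutoffResult:
    cutoff: float
    n_low: int
    n_high: int
    chi2: float
    p_uncorrected: float
    p_corrected: float
    fraction_low: float
    scan: pd.DataFrame = field(repr=False, default=None)


def build_endpoint(
    clinical: pd.DataFrame, endpoint: str, horizon_months: float = 60.0
) -> pd.DataFrame:
    """Construct a (time, event) table for a named endpoint.

    For a site-specific endpoint the event is the first recurrence at that
    site; a recurrence at another site only censors the patient at that
    recurrence time.  Patients without recurrence are censored at
    min(follow-up, horizon).  PFS counts the first recurrence at any site
    as an event.  All times are administratively truncated at the horizon.
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}; expected one of {ENDPOINTS}")
    rows = []
    for _, r in clinical.iterrows():
        raw = r.get("recurrence_site")
        sites = []
        if isinstance(raw, str) and raw.strip():
            sites = [s.strip() for s in raw.split(";")]
            for s in sites:
                if s not in SITES:
                    raise ValueError(f"unknown recurrence site label {s!r}")
        if sites:
            rec_t = float(r["recurrence_months"])
            if endpoint == "pfs":
                t, ev = rec_t, 1
            else:
                target = _SITE_OF_ENDPOINT[endpoint]
                t, ev = rec_t, int(target in sites)
        else:
            t, ev = float(r["followup_months"]), 0
        if t > horizon_months:
            t, ev = horizon_months, 0
        rows.append((r["patient_id"], t, ev))
    out = pd.DataFrame(rows, columns=["patient_id", "time", "event"])
    out.attrs["endpoint"] = endpoint
    return out


def km_estimate(endpoint: pd.DataFrame, groups: pd.Series | None = None) -> dict[str, KMCurve]:
    """Kaplan-Meier product-limit estimate per group (one group if None)."""
    if groups is None:
        groups = pd.Series("all", index=endpoint.index)
    curves: dict[str, KMCurve] = {}
    for name, idx in groups.groupby(groups).groups.items():
        sub = endpoint.loc[idx]
        if len(sub) == 0:
            raise ValueError(f"empty group {name!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        event_table = kmf.event_table
        curves[str(name)] = KMCurve(
            group=str(name),
            times=event_table.index.to_numpy(float),
            survival=kmf.survival_function_["KM_estimate"].to_numpy(float),
            at_risk=event_table["at_risk"].to_numpy(float),
            censor_times=sub.loc[(sub["event"] == 0), "time"].to_numpy(float),
        )
    return curves


def logrank_test(endpoint: pd.DataFrame, groups: pd.Series) -> tuple[float, float]:
    """Unweighted log-rank chi-square (k-1 df) comparing the group curves."""
    if groups.nunique() < 2:
        raise ValueError("need at least two groups")
    if endpoint["event"].sum() < 1:
        raise ValueError("no events observed")
    res = multivariate_logrank_test(endpoint["time"], groups, endpoint["event"])
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    endpoint: pd.DataFrame, covariates: pd.DataFrame, alpha: float = 0.05
) -> list[CoxResult]:
    """Cox proportional-hazards fit (Efron tie handling) of all covariates jointly.

    Returns one CoxResult per covariate with Wald p and 95% CI.  Raises on
    constant covariates; non-convergence is returned as a flagged result.
    """
    for c in covariates.columns:
        if covariates[c].nunique() <= 1:
            raise ValueError(f"covariate {c!r} has zero variance")
    if endpoint["event"].sum() < 1:
        raise ValueError("no events observed")
    df = pd.concat(
        [endpoint[["time", "event"]].reset_index(drop=True), covariates.reset_index(drop=True)],
        axis=1,
    )
    cph = CoxPHFitter(alpha=alpha)
    try:
        cph.fit(df, duration_col="time", event_col="event", fit_options={"precision": 1e-11})
    except Exception:
        return [
            CoxResult(c, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, converged=False)
            for c in covariates.columns
        ]
    s = cph.summary
    lo, hi = f"coef lower {100*(1-alpha):g}%", f"coef upper {100*(1-alpha):g}%"
    return [
        CoxResult(
            covariate=str(c),
            coef=float(s.loc[c, "coef"]),
            se=float(s.loc[c, "se(coef)"]),
            hr=float(np.exp(s.loc[c, "coef"])),
            ci_low=float(np.exp(s.loc[c, lo])),
            ci_high=float(np.exp(s.loc[c, hi])),
            p=float(s.loc[c, "p"]),
        )
        for c in covariates.columns
    ]


def _log_partial_likelihood(endpoint: pd.DataFrame, covariates: pd.DataFrame) -> float:
    df = pd.concat(
        [endpoint[["time", "event"]].reset_index(drop=True), covariates.reset_index(drop=True)],
        axis=1,
    )
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event", fit_options={"precision": 1e-11})
    return float(cph.log_likelihood_)


def _null_log_likelihood(endpoint: pd.DataFrame) -> float:
    # Efron log partial likelihood at beta = 0 depends only on the risk sets
    t = endpoint["time"].to_numpy(float)
    e = endpoint["event"].to_numpy(int)
    ll = 0.0
    for tau in np.unique(t[e == 1]):
        d = int(((t == tau) & (e == 1)).sum())
        n_risk = int((t >= tau).sum())
        # Efron denominator at beta=0 for the j-th of d tied deaths: n_risk - j
        ll -= sum(np.log(n_risk - j) for j in range(d))
    return ll


def stepwise_cox(
    endpoint: pd.DataFrame,
    candidates: pd.DataFrame,
    direction: str = "both",
    screen_p: float = 0.1,
    enter_p: float = 0.05,
    remove_p: float = 0.10,
) -> dict:
    """Stepwise Cox model selection after a univariate screen.

    Candidates with univariate Wald p <= ``screen_p`` enter the pool.
    Forward selection adds the covariate with the smallest likelihood-ratio
    p if <= ``enter_p``; backward elimination starts from the full screened
    model and drops the covariate with the largest LR p while >= ``remove_p``.
    ``direction='both'`` runs both and reports whether they agree.
    """
    if direction not in ("forward", "backward", "both"):
        raise ValueError("direction must be forward, backward or both")
    if candidates.shape[1] < 1:
        raise ValueError("need at least one candidate covariate")
    uni = {c: cox_fit(endpoint, candidates[[c]])[0] for c in candidates.columns}
    pool = [c for c, r in uni.items() if r.converged and r.p <= screen_p]
    result = {"univariate": uni, "screened": pool}
    if not pool:
        result.update(selected=[], model=[], forward=[], backward=[], agree=True,
                      note="no candidate passed the univariate screen")
        return result

    def lr_p(base: list[str], full: list[str]) -> float:
        ll_full = _log_partial_likelihood(endpoint, candidates[full])
        ll_base = (
            _log_partial_likelihood(endpoint, candidates[base])
            if base
            else _null_log_likelihood(endpoint)
        )
        lr = 2.0 * (ll_full - ll_base)
        return float(stats.chi2.sf(max(lr, 0.0), df=len(full) - len(base)))

    def forward() -> list[str]:
        model: list[str] = []
        remaining = list(pool)
        while remaining:
            pvals = {c: lr_p(model, model + [c]) for c in remaining}
            best = min(pvals, key=pvals.get)
            if pvals[best] <= enter_p:
                model.append(best)
                remaining.remove(best)
            else:
                break
        return model

    def backward() -> list[str]:
        model = list(pool)
        while len(model) > 0:
            pvals = {c: lr_p([m for m in model if m != c], model) for c in model}
            worst = max(pvals, key=pvals.get)
            if pvals[worst] >= remove_p:
                model.remove(worst)
            else:
                break
        return model

    fwd = forward() if direction in ("forward", "both") else None
    bwd = backward() if direction in ("backward", "both") else None
    selected = fwd if fwd is not None else bwd
    agree = (set(fwd) == set(bwd)) if (fwd is not None and bwd is not None) else None
    model_fit = cox_fit(endpoint, candidates[selected]) if selected else []
    result.update(selected=selected, model=model_fit, forward=fwd, backward=bwd, agree=agree)
    return result


def _logrank_scan(
    time: np.ndarray, event: np.ndarray, low_matrix: np.ndarray
) -> np.ndarray:
    """Two-group log-rank chi-square for many splits at once.

    ``low_matrix`` is (n_subjects, n_cutoffs) boolean, True for the low group,
    with subjects ordered by ascending time.  Returns chi2 per cutoff.
    """
    n = time.shape[0]
    uniq, first = np.unique(time, return_index=True)
    # at-risk counts just before each distinct time
    n_risk = n - first  # subjects with time >= uniq[k]
    # reverse cumulative membership: low-group at risk at each distinct time
    rev = np.cumsum(low_matrix[::-1], axis=0)[::-1]
    n1_risk = rev[first]  # (n_times, n_cutoffs)
    ev_w = event[:, None] * low_matrix
    d1 = np.add.reduceat(ev_w, first, axis=0)
    d = np.add.reduceat(event.astype(float), first)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = n1_risk / n_risk[:, None]
        o_minus_e = (d1 - d[:, None] * frac).sum(axis=0)
        denom = np.where(n_risk > 1, n_risk - 1.0, np.nan)
        var = (d * (n_risk - d) / denom)[:, None] * frac * (1.0 - frac)
        v = np.nansum(var, axis=0)
        chi2 = np.where(v > 0, o_minus_e**2 / v, 0.0)
    return chi2


def optimal_cutoff_scan(
    score: pd.Series,
    endpoint: pd.DataFrame,
    min_group_fraction: float = 0.10,
    correction: str = "permutation",
    n_permutations: int = 1000,
    seed: int | None = None,
) -> CutoffResult:
    """Exhaustive scan for the biomarker cutoff maximizing the log-rank statistic.

    Every distinct score value whose low/high split leaves at least
    ``min_group_fraction`` of the patients in each group is evaluated.  The
    uncorrected p is the chi-square tail of the best statistic; because the
    cutoff is chosen to maximize the statistic, a corrected p is also
    reported: ``permutation`` re-runs the full scan on label-permuted data,
    ``min_p`` applies the analytic Sidak bound over the number of candidate
    cutoffs, ``none`` repeats the uncorrected value.
    """
    n = len(score)
    if n < 20:
        raise ValueError("need at least 20 subjects for a cutoff scan")
    if endpoint["event"].sum() < 1:
        raise ValueError("no events observed")
    if correction not in ("none", "permutation", "min_p"):
        raise ValueError(f"unknown correction {correction!r}")
    s = score.to_numpy(float)
    order = np.argsort(endpoint["time"].to_numpy(float), kind="stable")
    t = endpoint["time"].to_numpy(float)[order]
    e = endpoint["event"].to_numpy(int)[order]
    s_sorted = s[order]
    min_count = int(np.ceil(min_group_fraction * n))
    values = np.unique(s)
    n_low = (s[:, None] <= values[None, :]).sum(axis=0)
    ok = (n_low >= min_count) & ((n - n_low) >= min_count)
    if not ok.any():
        raise ValueError("no cutoff satisfies the minimum group fraction")
    cuts = values[ok]
    low = s_sorted[:, None] <= cuts[None, :]
    chi2 = _logrank_scan(t, e, low)
    best = int(np.argmax(chi2))
    best_chi2 = float(chi2[best])
    p_unc = float(stats.chi2.sf(best_chi2, df=1))
    if correction == "none":
        p_corr = p_unc
    elif correction == "min_p":
        p_corr = float(1.0 - (1.0 - p_unc) ** len(cuts))
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            chi2_p = _logrank_scan(t, e, s[perm][order][:, None] <= cuts[None, :])
            if chi2_p.max() >= best_chi2:
                hits += 1
        p_corr = (hits + 1.0) / (n_permutations + 1.0)
    p_corr = max(p_corr, p_unc)
    scan = pd.DataFrame({"cutoff": cuts, "chi2": chi2, "n_low": (s[:, None] <= cuts[None, :]).sum(axis=0)})
    nl = int(scan.loc[best, "n_low"])
    return CutoffResult(
        cutoff=float(cuts[best]),
        n_low=nl,
        n_high=n - nl,
        chi2=best_chi2,
        p_uncorrected=p_unc,
        p_corrected=float(p_corr),
        fraction_low=nl / n,
        scan=scan,
    )


def log_minus_log(curve: KMCurve) -> tuple[np.ndarray, list[str]]:
    """(log t, log(-log S(t))) points for graphical proportional-hazards checks.

    Points with S(t) at 0 or 1 (or t = 0) are skipped; the notes list says
    how many were dropped.
    """
    notes: list[str] = []
    t = curve.times
    s = curve.survival
    keep = (s > 0) & (s < 1) & (t > 0)
    if (~keep).any():
        notes.append(f"skipped {int((~keep).sum())} point(s) with S(t) in {{0,1}} or t=0")
    pts = np.column_stack([np.log(t[keep]), np.log(-np.log(s[keep]))])
    return pts, notes


def holm_sidak_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Step-down Holm-Sidak adjusted p-values (monotone, elementwise >= raw p)."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm-sidak")[1]


def dichotomize_hypoxia(scores: np.ndarray | list[float], cutoff: float = 0.0) -> np.ndarray:
    """Classify tumors as more/less hypoxic at a predefined signature cutoff.

    Scores strictly above the cutoff are "more hypoxic"; the boundary value
    is assigned to "less hypoxic".
    """
    scores = np.asarray(scores, float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("hypoxia scores must be finite")
    return np.where(scores > cutoff, "more", "less")
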