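"""Dual-cohort miRNA-target anticorrelation filtering and network construction.

Candidate miRNA->gene relations (e.g. a miRGate-style download of validated
plus predicted targets) are tested for inverse expression correlation in two
independent patient cohorts.  A gene is kept as a potential target of a
miRNA when the Spearman correlation is negative with nominal p < 0.05 in
BOTH cohorts and the Benjamini-Hochberg q-value is < 0.1 in at least one.
Retained pairs form a bipartite regulatory network (miRNA and gene nodes)
whose per-miRNA degrees and multi-miRNA target fractions summarize the
overlap in targeting.

The BH adjustment family is, by default, the candidate gene list of one
miRNA within one cohort; pass ``family='global'`` to adjust across all
pairs of a cohort at once.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

P_BOTH_COHORTS = 0.05
Q_ONE_COHORT = 0.1


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i} p_(j)*m/j, capped at 1."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _rank_rows(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=1)


def correlate(
    mirna: pd.DataFrame,
    genes: pd.DataFrame,
    candidates: dict[str, set[str]],
    cohort: str,
    family: str = "per_mirna",
) -> pd.DataFrame:
    """Spearman anticorrelation screen of candidate targets in one cohort.

    Returns a tidy table with one row per (miRNA, candidate gene) pair:
    ``mirna, gene, cohort, rho, p, q``.  Ties receive average ranks and the
    two-sided p-value uses the t approximation.  Pairs where either vector
    is constant have undefined rho and are excluded from the BH family
    (reported with NaN rho/p/q).  Candidate gene ids absent from the gene
    matrix are reported in ``result.attrs['unmatched']``.
    """
    if family not in ("per_mirna", "global"):
        raise ValueError("family must be 'per_mirna' or 'global'")
    if list(mirna.columns) != list(genes.columns):
        raise ValueError("miRNA and gene matrices must share identical sample ids")
    n = mirna.shape[1]
    if n < 10:
        raise ValueError("need at least 10 samples per cohort")
    unmatched = sorted(
        {g for gs in candidates.values() for g in gs} - set(genes.index)
    )
    gene_rank = pd.DataFrame(
        _rank_rows(genes.to_numpy(float)), index=genes.index, columns=genes.columns
    )
    rows = []
    for mir, cand in candidates.items():
        if mir not in mirna.index:
            raise KeyError(f"candidate map references unknown miRNA {mir!r}")
        present = sorted(set(cand) & set(genes.index))
        mvals = mirna.loc[mir].to_numpy(float)
        m_const = np.ptp(mvals) == 0
        mrank = stats.rankdata(mvals)
        mr = mrank - mrank.mean()
        sub = gene_rank.loc[present].to_numpy(float)
        gr = sub - sub.mean(axis=1, keepdims=True)
        denom = np.sqrt((gr**2).sum(axis=1) * (mr**2).sum())
        g_const = denom == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = (gr @ mr) / denom
        rho = np.where(m_const | g_const, np.nan, rho)
        with np.errstate(invalid="ignore", divide="ignore"):
            tstat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
        p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
        p = np.where(np.isnan(rho), np.nan, np.clip(p, 0.0, 1.0))
        for g, r_, p_ in zip(present, rho, p):
            rows.append((mir, g, cohort, r_, p_))
    out = pd.DataFrame(rows, columns=["mirna", "gene", "cohort", "rho", "p"])
    out["q"] = np.nan
    if family == "per_mirna":
        for mir in out["mirna"].unique():
            mask = (out["mirna"] == mir) & out["p"].notna()
            if mask.any():
                out.loc[mask, "q"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    else:
        mask = out["p"].notna()
        if mask.any():
            out.loc[mask, "q"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    out.attrs["unmatched"] = unmatched
    return out


def collapse_probes(genes: pd.DataFrame, probe_to_gene: pd.Series) -> pd.DataFrame:
    """Collapse multiple probes per gene to the probe with largest IQR."""
    iqr = genes.quantile(0.75, axis=1) - genes.quantile(0.25, axis=1)
    best = (
        pd.DataFrame({"gene": probe_to_gene.reindex(genes.index), "iqr": iqr})
        .dropna(subset=["gene"])
        .sort_values("iqr", kind="stable")
        .groupby("gene")
        .tail(1)
    )
    out = genes.loc[best.index]
    out.index = best["gene"].to_numpy()
    return out


def filter_targets(
    c1: pd.DataFrame,
    c2: pd.DataFrame,
    p_threshold: float = P_BOTH_COHORTS,
    q_threshold: float = Q_ONE_COHORT,
) -> dict:
    """Apply the dual-cohort potential-target rule.

    A (miRNA, gene) pair is retained when rho < 0 in both cohorts, nominal
    p < ``p_threshold`` in both, and q < ``q_threshold`` in at least one.
    Returns ``{'pairs': per-pair table, 'genes': per-gene potential-target
    ids, 'dropped_single_cohort': pairs present in only one cohort}``.
    """
    key = ["mirna", "gene"]
    merged = c1.merge(c2, on=key, suffixes=("_1", "_2"), how="outer", indicator=True)
    single = merged.loc[merged["_merge"] != "both", key]
    both = merged[merged["_merge"] == "both"].drop(columns="_merge")
    keep = (
        (both["rho_1"] < 0)
        & (both["rho_2"] < 0)
        & (both["p_1"] < p_threshold)
        & (both["p_2"] < p_threshold)
        & ((both["q_1"] < q_threshold) | (both["q_2"] < q_threshold))
    )
    pairs = both[keep.fillna(False)].reset_index(drop=True)
    return {
        "pairs": pairs,
        "genes": sorted(pairs["gene"].unique()),
        "dropped_single_cohort": single.reset_index(drop=True),
    }


def build_network(
    filtered_pairs: pd.DataFrame, q_threshold: float = Q_ONE_COHORT, q_rule: str = "any"
) -> nx.Graph:
    """Bipartite miRNA-target network from the filtered pair table.

    An edge is included iff the pair passed the dual-cohort filter and its
    q-value is below ``q_threshold`` in at least one cohort (``q_rule='any'``)
    or in both (``q_rule='both'``).  Nodes are the endpoints of included
    edges; an empty table yields an empty graph.
    """
    if q_rule not in ("any", "both"):
        raise ValueError("q_rule must be 'any' or 'both'")
    g = nx.Graph()
    for _, r in filtered_pairs.iterrows():
        qs = [r["q_1"], r["q_2"]]
        hit = [q < q_threshold for q in qs if not np.isnan(q)]
        ok = any(hit) if q_rule == "any" else (len(hit) == 2 and all(hit))
        if ok:
            g.add_node(r["mirna"], bipartite="mirna")
            g.add_node(r["gene"], bipartite="gene")
            g.add_edge(
                r["mirna"], r["gene"],
                rho_1=r["rho_1"], rho_2=r["rho_2"],
                q_1=r["q_1"], q_2=r["q_2"],
            )
    return g


def network_stats(net: nx.Graph) -> dict:
    """Per-miRNA target counts and the multi-miRNA target gene fraction."""
    mirnas = [n for n, d in net.nodes(data=True) if d.get("bipartite") == "mirna"]
    genes = [n for n, d in net.nodes(data=True) if d.get("bipartite") == "gene"]
    degree = dict(net.degree())
    per_mirna = {m: degree[m] for m in mirnas}
    multi = [g for g in genes if degree[g] > 1]
    return {
        "per_mirna_targets": per_mirna,
        "n_genes": len(genes),
        "n_multi_mirna_genes": len(multi),
        "multi_mirna_fraction": len(multi) / len(genes) if genes else 0.0,
    }
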