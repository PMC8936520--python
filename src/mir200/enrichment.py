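"""Over-representation analysis of a gene list against GMT gene-set collections.

One-sided hypergeometric tests (optionally with the conservative EASE
overlap-minus-one variant) with Benjamini-Hochberg adjustment per category.
Two background modes mirror the usual choices when interpreting a filtered
target list: the global gene universe, or the unfiltered candidate list the
targets were drawn from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import bh_adjust


@dataclass
class GeneSetCollection:
    """Named gene sets with a category label (process/component/function/pathway)."""

    sets: dict[str, set[str]]
    category: str = "pathway"

    def __post_init__(self) -> None:
        empty = [k for k, v in self.sets.items() if not v]
        if empty:
            raise ValueError(f"empty gene set(s): {empty}")


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            genes = sorted(collection.sets[name])
            fh.write("\t".join([name, collection.category] + genes) + "\n")


def ora_test(
    gene_list: set[str],
    gene_set: set[str],
    background: set[str],
    ease: bool = False,
) -> dict:
    """One-sided hypergeometric over-representation test for a single set.

    All counts are taken within the background: p = P(overlap >= observed)
    drawing |list| genes from the background.  With ``ease=True`` the
    observed overlap is reduced by one before testing (never below zero),
    the conservative convention popularized by DAVID's EASE score.  Fold
    enrichment = (overlap/list)/(set/background).
    """
    if not background:
        raise ValueError("background is empty")
    glist = set(gene_list) & background
    if not glist:
        raise ValueError("gene list is empty within the background")
    gset = set(gene_set) & background
    if not gset:
        raise ValueError("gene set does not intersect the background")
    n_bg, n_set, n_list = len(background), len(gset), len(glist)
    overlap = len(glist & gset)
    k = max(overlap - 1, 0) if ease else overlap
    # P(X >= k) for X ~ Hypergeom(N=n_bg, K=n_set, n=n_list)
    p = float(stats.hypergeom.sf(k - 1, n_bg, n_set, n_list))
    fold = (overlap / n_list) / (n_set / n_bg)
    return {
        "overlap": overlap,
        "set_size": n_set,
        "list_size": n_list,
        "background_size": n_bg,
        "p": min(p, 1.0),
        "fold_enrichment": fold,
    }


def enrich_all(
    gene_list: set[str],
    collection: GeneSetCollection,
    background: set[str],
    q_sig: float = 0.01,
    ease: bool = False,
) -> pd.DataFrame:
    """Run ora_test over every set in a collection and BH-adjust within it.

    Genes absent from the background are dropped (count reported in
    ``result.attrs['n_dropped']``).  Sets disjoint from the background are
    skipped.  Returns a table sorted by p with a ``significant`` flag at
    q < ``q_sig``; the BH family is the collection (one category).
    """
    glist = set(gene_list) & background
    dropped = len(set(gene_list)) - len(glist)
    rows = []
    for name, gset in collection.sets.items():
        if not (set(gset) & background):
            continue
        r = ora_test(glist, gset, background, ease=ease)
        r["set"] = name
        r["category"] = collection.category
        rows.append(r)
    out = pd.DataFrame(rows)
    out.attrs["n_dropped"] = dropped
    if out.empty:
        out.attrs["note"] = "gene list disjoint from all sets"
        return out
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < q_sig
    out = out.sort_values("p", kind="stable").reset_index(drop=True)
    cols = ["set", "category", "overlap", "set_size", "list_size",
            "background_size", "fold_enrichment", "p", "q", "significant"]
    attrs = out.attrs
    out = out[cols]
    out.attrs = attrs
    return out
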