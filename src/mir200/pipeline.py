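"""End-to-end orchestration of the analysis on synthetic or file inputs.

``run_synthetic_pipeline`` generates two patient cohorts plus the imaging
and xenograft fixtures, then runs every downstream stage: miR-200a/b/-429
scoring, site-specific survival analysis with the optimal-cutoff scan,
dual-cohort target-network inference, enrichment with both backgrounds,
ADC mapping with necrosis classification, histology quantification, and
the growth-delay / enhancement-factor summary.  ``export_tables`` writes
the result bundle as tidy CSV/JSON.  All randomness flows from the
configuration seed, so two runs with equal configs produce byte-identical
output files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import adc as adc_mod
from . import histology as histo_mod
from . import io as io_mod
from . import network as net_mod
from . import response as resp_mod
from . import score as score_mod
from . import survival as surv_mod
from .enrichment import enrich_all
from .synthetic import (
    SimulationConfig,
    gen_candidate_map,
    gen_cohort,
    gen_dwi,
    gen_gene_expression,
    gen_gene_sets,
    gen_growth,
    gen_histology,
)

STAGES = ("score", "survival", "network", "enrichment", "adc", "histology", "response")


def merge_cohort_scores(matrices: list[pd.DataFrame]) -> pd.Series:
    """Score each cohort separately (median centering is per cohort) and pool."""
    parts = [score_mod.compute_score(m, members=tuple(m.index)).values for m in matrices]
    return pd.concat(parts)


def run_synthetic_pipeline(
    config: SimulationConfig | None = None,
    stages: tuple[str, ...] = STAGES,
    n_permutations: int = 200,
) -> dict:
    """Run the full pipeline on generated data; returns a results dict."""
    config = config or SimulationConfig()
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    results: dict = {"config": config}

    mats, clins, truths = [], [], []
    for i in range(len(config.n_patients)):
        m, c, t = gen_cohort(config, cohort_index=i, seed=config.seed + 10 * i)
        mats.append(m)
        clins.append(c)
        truths.append(t)
    clinical = pd.concat(clins, ignore_index=True)
    results["cohorts"] = {"matrices": mats, "clinical": clinical, "truths": truths}

    if "score" in stages:
        score = merge_cohort_scores(mats)
        results["score"] = score
    else:
        score = merge_cohort_scores(mats)

    if "survival" in stages:
        surv: dict = {}
        score_by_patient = score.reindex(clinical["patient_id"]).to_numpy()
        for endpoint in surv_mod.ENDPOINTS:
            table = surv_mod.build_endpoint(clinical, endpoint, config.censor_months)
            cov = pd.DataFrame({"score": score_by_patient})
            surv[endpoint] = {
                "endpoint_table": table,
                "cox_continuous": surv_mod.cox_fit(table, cov)[0],
            }
        pfs = surv["pfs"]["endpoint_table"]
        surv["cutoff_scan"] = surv_mod.optimal_cutoff_scan(
            pd.Series(score_by_patient, index=pfs.index),
            pfs,
            correction="permutation",
            n_permutations=n_permutations,
            seed=config.seed + 100,
        )
        results["survival"] = surv

    genes_by_cohort, gene_truths = [], []
    need_net = "network" in stages or "enrichment" in stages
    if need_net:
        for i, m in enumerate(mats):
            g, gt = gen_gene_expression(config, m, seed=config.seed + 20 + i)
            genes_by_cohort.append(g)
            gene_truths.append(gt)
        candidates = gen_candidate_map(mats[0], genes_by_cohort[0])
        c1 = net_mod.correlate(mats[0], genes_by_cohort[0], candidates, "cohort1")
        c2 = net_mod.correlate(mats[1], genes_by_cohort[1], candidates, "cohort2")
        filtered = net_mod.filter_targets(c1, c2)
        graph = net_mod.build_network(filtered["pairs"])
        stats_ = net_mod.network_stats(graph)
        truth_targets = gene_truths[0].true_target_gene_ids
        declared = set(filtered["genes"])
        recall = (
            len(declared & truth_targets) / len(truth_targets) if truth_targets else np.nan
        )
        fdr = len(declared - truth_targets) / len(declared) if declared else 0.0
        results["network"] = {
            "correlations": (c1, c2),
            "filtered": filtered,
            "graph": graph,
            "stats": stats_,
            "recall": recall,
            "false_discovery_fraction": fdr,
            "truth_targets": truth_targets,
        }

    if "enrichment" in stages:
        gene_ids = list(genes_by_cohort[0].index)
        collection, planted = gen_gene_sets(
            gene_ids, n_sets=50, planted_set_fraction=0.8,
            seed=config.seed + 30, true_targets=results["network"]["truth_targets"],
        )
        declared = set(results["network"]["filtered"]["genes"]) or set(
            results["network"]["truth_targets"]
        )
        global_bg = set(gene_ids)
        cand_bg = set().union(*gen_candidate_map(mats[0], genes_by_cohort[0]).values())
        results["enrichment"] = {
            "collection": collection,
            "planted_set": planted,
            "global_background": enrich_all(declared, collection, global_bg),
            "candidate_background": enrich_all(declared, collection, cand_bg),
        }

    if "adc" in stages:
        series, truth = gen_dwi(config, seed=config.seed + 40)
        adc_map = adc_mod.fit_adc(series)
        mask, frac = adc_mod.classify_necrosis(adc_map)
        results["adc"] = {
            "series": series,
            "truth": truth,
            "map": adc_map,
            "necrosis_mask": mask,
            "necrotic_fraction": frac,
            "median_adc": adc_mod.median_adc(adc_map),
        }

    if "histology" in stages:
        h = gen_histology(config, seed=config.seed + 50)
        conc = histo_mod.color_deconvolve(h["ki67_rgb"])
        dab = conc[..., 1]
        labels, count = histo_mod.segment_nuclei(
            dab, threshold=0.5, necrosis=h["necrosis"], parenchyma=h["parenchyma"]
        )
        hyp_dab = histo_mod.color_deconvolve(h["hypoxia_rgb"])[..., 1]
        hyp_mask = histo_mod.segment_by_threshold(hyp_dab, 0.5, roi=h["roi"])
        gfp_dab = histo_mod.color_deconvolve(h["gfp_rgb"])[..., 1]
        gfp_mask = histo_mod.segment_by_threshold(gfp_dab, 0.5, roi=h["roi"])
        metrics = histo_mod.HistoMetrics(
            necrotic_fraction=histo_mod.necrotic_fraction(h["necrosis"], h["roi"]),
            hypoxic_fraction=histo_mod.hypoxic_fraction(hyp_mask, h["roi"], h["necrosis"]),
            gfp_area_fraction=histo_mod.gfp_area_fraction(gfp_mask, h["roi"], h["necrosis"]),
            nucleus_count=count,
            cell_density_per_mm2=histo_mod.cell_density(count, gfp_mask),
        )
        results["histology"] = {"inputs": h, "labels": labels, "metrics": metrics}

    if "response" in stages:
        curves, truth = gen_growth(config, seed=config.seed + 60)
        td = {
            line: float(
                np.mean(
                    [
                        resp_mod.doubling_time(c)
                        for c in curves
                        if c.group == f"{line}_unirradiated"
                    ]
                )
            )
            for line in config.td_days
        }
        delay = resp_mod.growth_delay(curves)
        results["response"] = {"curves": curves, "truth": truth, "td": td, "delay": delay}

    return results


def export_tables(results: dict, outdir) -> list[Path]:
    """Write the result bundle as CSV/JSON files; returns the written paths."""
    out = io_mod.ensure_dir(outdir)
    written: list[Path] = []

    def save_df(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, index=False, float_format="%.10g")
        written.append(p)

    if "score" in results:
        save_df(
            results["score"].rename("score").rename_axis("patient_id").reset_index(),
            "scores.csv",
        )
    if "survival" in results:
        rows = []
        for endpoint in surv_mod.ENDPOINTS:
            r = results["survival"][endpoint]["cox_continuous"]
            rows.append(
                {
                    "endpoint": endpoint,
                    "covariate": r.covariate,
                    "P": r.p,
                    "HR": r.hr,
                    "CI_low": r.ci_low,
                    "CI_high": r.ci_high,
                }
            )
        save_df(pd.DataFrame(rows), "cox_continuous_score.csv")
        scan = results["survival"]["cutoff_scan"]
        p = out / "cutoff_scan.json"
        p.write_text(
            json.dumps(
                {
                    "cutoff": scan.cutoff,
                    "n_low": scan.n_low,
                    "n_high": scan.n_high,
                    "chi2": scan.chi2,
                    "p_uncorrected": scan.p_uncorrected,
                    "p_corrected": scan.p_corrected,
                    "fraction_low": scan.fraction_low,
                },
                indent=2,
            )
        )
        written.append(p)
    if "network" in results:
        c1, c2 = results["network"]["correlations"]
        save_df(pd.concat([c1, c2], ignore_index=True), "correlations.csv")
        save_df(results["network"]["filtered"]["pairs"], "potential_target_pairs.csv")
        sif = out / "network.sif"
        io_mod.write_network_sif(results["network"]["graph"], sif)
        written.append(sif)
        stats_ = dict(results["network"]["stats"])
        p = out / "network_stats.json"
        p.write_text(json.dumps(stats_, indent=2, default=float))
        written.append(p)
    if "enrichment" in results:
        save_df(results["enrichment"]["global_background"], "enrichment_global_bg.csv")
        save_df(results["enrichment"]["candidate_background"], "enrichment_candidate_bg.csv")
    if "adc" in results:
        p = out / "adc_summary.json"
        p.write_text(
            json.dumps(
                {
                    "median_adc_mm2_per_s": results["adc"]["median_adc"],
                    "necrotic_fraction": results["adc"]["necrotic_fraction"],
                },
                indent=2,
            )
        )
        written.append(p)
    if "histology" in results:
        m = results["histology"]["metrics"]
        p = out / "histology_metrics.json"
        p.write_text(json.dumps(m.__dict__, indent=2))
        written.append(p)
    if "response" in results:
        d = results["response"]["delay"]
        p = out / "response_summary.json"
        p.write_text(
            json.dumps(
                {
                    "mean_td_days": results["response"]["td"],
                    "group_mean_t15x_days": d["group_mean_t"],
                    "tgd_days": d["tgd"],
                    "ef": d["ef"],
                    "ef_defined": d["ef_defined"],
                },
                indent=2,
            )
        )
        written.append(p)
    return written
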