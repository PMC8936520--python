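# mir200

A tested Python pipeline for evaluating the **miR-200a/b/-429 cluster as a
biomarker of radioresistance** in locally advanced cervical cancer, and for
the quantitative imaging and xenograft analyses that accompany such a
study.  It is aimed at translational researchers who want to score the
miR-200 cluster in their own cohorts, stratify patients by site-specific
outcome, infer miRNA-target networks from dual-cohort expression data, or
quantify DW-MRI and immunohistochemistry read-outs reproducibly.

## What it computes

- **miR-200a/b/-429 score** — per-patient mean of the median-centered log2
  expression of miR-200a-5p/-3p, miR-200b-5p/-3p and miR-429 (RPM-based
  sequencing variant, −ΔCt qPCR variant, and a three-member subset).
- **Site-specific survival analysis** — endpoints for central pelvic,
  lateral pelvic and distal control and progression-free survival;
  Kaplan-Meier/log-rank, Cox PH models (uni-/multivariate with
  forward-backward stepwise selection), log-minus-log PH checks,
  Holm-Šidák adjustment, and an x-tile-style optimal-cutoff scan with
  permutation correction.
- **Target network** — Spearman anticorrelation screen of candidate
  miRNA→gene relations in two cohorts (rho < 0, p < 0.05 in both, BH
  q < 0.1 in at least one), bipartite network construction and degree
  statistics.
- **Enrichment** — hypergeometric over-representation of the target list
  against GMT collections, with global-universe or candidate-list
  backgrounds and optional EASE correction.
- **ADC maps** — voxel-wise log-linear fits of DW-MRI series, necrosis
  classification at ADC > 0.0011 mm²/s, per-tumor median ADC, and
  longitudinal ADC-ratio statistics.
- **Histology** — H-DAB color deconvolution, threshold segmentation,
  watershed splitting of nucleus clusters (> 200 px) on the distance
  transform, and necrotic/hypoxic/GFP fractions plus Ki-67 cell density.
- **Radiation response** — clonogenic survival fractions, normalized
  γH2Ax, doubling times, T₁.₅ₓ endpoints, tumor growth delay and the
  enhancement factor EF = TGD(miR line)/TGD(control line).
- **Synthetic data** — a first-class generator producing every input above
  with known ground truth (cohorts with planted hazard ratio and planted
  anticorrelated targets, DWI and histology phantoms, growth curves with
  planted delays), used by the test suite to close the
  generate-analyze-recover loop.

## Worked example

Run the full pipeline on the default synthetic study conditions (two
cohorts of 90 and 110 patients, true hazard ratio 0.40 per unit score,
50 planted targets among 2000 candidates):

```bash
mir200 run --seed 1 --outdir demo
```

Selected numbers from the emitted tables (`demo/cox_continuous_score.csv`,
`demo/network_stats.json`, `demo/response_summary.json`):

```
endpoint  covariate  P            HR      CI_low  CI_high
pfs       score      1.58e-10    0.426    0.328    0.553
```

The Cox fit on the pooled 200 synthetic patients recovers the planted
hazard ratio of 0.40 per unit score (HR 0.43, 95% CI 0.33–0.55).  The
target filter declares 51 potential target genes, recovering all 50
planted ones plus one false positive, and the growth-delay analysis
returns TGD 19.9 d for the miRNA-overexpressing line versus 4.0 d for the
control line, i.e. an enhancement factor of 5.0 against a planted value
of 5 (the planted delays are 20 and 4 days; the small deviations are
linear-interpolation error at 3-day measurement spacing).

The same stages are available individually (`mir200 simulate`, `score`,
`survive`, `targets`, `enrich`, `adc`, `histo`, `response`) for running on
your own TSV/CSV/TIFF inputs; see `mir200 <command> --help`.

As a library:

```python
from mir200.score import compute_score
from mir200.survival import build_endpoint, cox_fit, optimal_cutoff_scan

score = compute_score(expr_matrix)           # features x samples DataFrame
pfs = build_endpoint(clinical, "pfs")        # 60-month horizon by default
result = cox_fit(pfs, covariates)[0]         # HR, 95% CI, Wald p
```

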