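# Methods

This package implements, as a tested and reusable pipeline, the analysis
workflow used to evaluate the miR-200a/b/-429 cluster as a biomarker of
radioresistance in locally advanced cervical cancer, together with the
quantitative imaging and xenograft analyses that support the biological
interpretation.  Every stage can be exercised end to end on synthetic data
with known ground truth, so the statistical behaviour of the whole chain is
testable without access to patient data.

## The miR-200a/b/-429 score

Small-RNA-seq counts are normalized to reads per million annotated mature
miRNAs and log2-transformed; we add a pseudocount of 1 inside the log so
zero counts stay finite (configurable).  Each of the five chromosome-1
cluster members (miR-200a-5p/-3p, miR-200b-5p/-3p, miR-429) is
median-centered across the cohort, and the per-patient score is the
arithmetic mean of the centered values.  Median centering is strictly
per cohort: scores are relative quantities and are not comparable across
cohorts, so pooled analyses re-center within each cohort before merging.

For RT-qPCR cohorts the expression value is −ΔCt, i.e. the negative of the
feature Ct minus the mean Ct of the reference RNAs in the same sample.
The sign convention makes low score mean low expression on all platforms.
A three-member variant (miR-200a-3p, miR-200b-3p, miR-429) covers arrays
that do not report the 5p strands.

Heteroscedasticity of expression values over their fitted range is checked
with the White test: the LM statistic n·R² from regressing squared
residuals on the fitted value and its square, referred to chi-square with
2 df.

## Survival analysis

Four endpoints are constructed from the clinical table: central pelvic
control, lateral pelvic control, distal control, and progression-free
survival.  For a site endpoint the event is the first recurrence at that
site; a recurrence at another site censors the patient at that time, and
patients without recurrence are censored at the administrative horizon
(default 60 months, configurable).  The censoring convention for
other-site recurrences is a design choice of this package; competing-risks
models are out of scope.

Kaplan-Meier estimation, the unweighted log-rank test and Cox proportional
hazards regression (Efron tie handling, Wald confidence intervals) are
delegated to lifelines.  The Newton-Raphson precision is tightened to
1e-11 so that maximum partial-likelihood estimates agree with a
brute-force maximizer to better than 1e-6 even on nearly flat likelihoods.
Stepwise model selection restricts candidates to univariate p ≤ 0.1, then
adds covariates at likelihood-ratio p ≤ 0.05 (forward) or removes them at
p ≥ 0.10 (backward); both directions are run and their agreement reported.
Proportional hazards are assessed graphically via log(−log S(t)) against
log t.

The optimal-cutoff scan dichotomizes a continuous biomarker at every
distinct value whose split leaves at least a minimum fraction (default
10%) of patients in each group, and picks the cutoff maximizing the
two-group log-rank statistic.  Because the maximum is selected, the
nominal chi-square p is optimistic; the scan therefore also reports a
corrected p, either by re-running the full scan on label-permuted data
(default 1000 permutations) or by the analytic Šidák bound over the number
of candidate cutoffs.  Both uncorrected and corrected values are emitted.
The scan is vectorized over cutoffs, which makes the permutation loop
cheap (a 200-patient scan with 1000 permutations runs in about a second).

A predefined-zero cutoff dichotomizes the hypoxia gene signature into
more/less hypoxic; the boundary value 0 is assigned to "less hypoxic".

## Target network inference

Candidate miRNA→gene relations (validated plus predicted, miRGate-style)
are screened by Spearman correlation between miRNA and gene expression in
two independent cohorts.  A pair is retained as a potential target when
rho < 0 with nominal two-sided p < 0.05 in both cohorts and
Benjamini-Hochberg q < 0.1 in at least one.  The BH family is, by default,
one miRNA's candidate list within one cohort (a global family is
available); the q-rule for network edges ("at least one cohort", default)
is likewise configurable to "both".  Pairs with a constant expression
vector have undefined correlation and are excluded from the FDR family
rather than assigned p = 1.  When several probes map to one gene, the
probe with the largest interquartile range is used.

Retained pairs form a bipartite graph (networkx) from which per-miRNA
target counts and the fraction of genes targeted by more than one miRNA
are computed.

## Enrichment

Over-representation of a gene list in GMT gene-set collections uses the
one-sided hypergeometric tail, with all counts taken within the chosen
background.  Two backgrounds reproduce the two published analysis modes:
the global gene universe, and the unfiltered candidate-target list.  An
optional EASE-style variant subtracts one from the observed overlap before
testing.  BH adjustment is applied within each category; significance is
flagged at q < 0.01 by default.

## ADC mapping

Mono-exponential diffusion, S(b) = S0·exp(−b·ADC), is fitted voxel-wise by
ordinary least squares of ln S on b; the S0 normalization is absorbed by
the intercept, so regressing ln S directly is algebraically identical to
fitting ln(S/S0).  Voxels with a non-positive signal at any b-value are
flagged invalid and excluded.  Necrosis is classified by the strict rule
ADC > 0.0011 mm²/s, and the per-tumor summary is the median ADC over all
valid ROI voxels, necrosis included (exclusion is not part of the
published rule).  b-values always come from input metadata, never from
code, so both acquisition protocols (200–1000 and 200–800 s/mm²) are
handled transparently.

A note on noise: with four b-values spanning 800 s/mm² and additive
Gaussian noise at SNR 20, the per-voxel ADC estimate has a relative
standard error of roughly 15%; no fitting method can make single voxels
much better under these conditions.  The per-tumor median over ~10⁴
voxels, which is the quantity the downstream analysis uses, recovers the
true ADC to well under 2%, and that is the recovery contract the tests
enforce.

## Histology quantification

Stain separation uses Ruifrok-Johnston color deconvolution: optical
density OD = −log10((pixel+ε)/255) unmixed by the inverse of a stain
matrix (default: the standard hematoxylin-DAB vector set; configurable).
Negative unmixed concentrations are clipped to zero.  The synthetic
renderer uses the same matrix as a forward model, so deconvolution is an
exact inverse in the noiseless case.

Nuclei are segmented by thresholding the DAB channel; 8-connected
components larger than 200 px are treated as cell clusters and split by
watershed on the Euclidean distance transform, seeded at h-maxima of the
distance map (h = 1 px, to suppress single-pixel ripple maxima).  Nuclei
whose centroid falls in the necrosis mask are removed, and only nuclei
with centroid inside the parenchyma (GFP-positive) mask are counted.
Centroid membership is this package's resolution of "cells in necrotic
areas"; the original rule is not specified at pixel level.

Per-section metrics: necrotic fraction = necrotic area / ROI; hypoxic
fraction and GFP area fraction are relative to the ROI after exclusion of
necrosis; cell density = nuclei per mm² of GFP-positive area (pixel size
default 0.46 μm).  Manual steps of the original workflow — ROI and
necrosis outlines, intensity thresholds — are explicit inputs and never
auto-chosen.

## Radiation response

Clonogenic survival: PE = colonies/seeded at 0 Gy; SF = (colonies/seeded)/PE.
γH2Ax signal is normalized to the spiked-in REH reference population and
expressed relative to the unirradiated condition.  Tumor doubling time is
ln 2 over the slope of ln V against time within a caller-supplied
exponential-phase window; non-positive slopes flag a non-growing tumor.
T₁.₅ₓ is the first crossing of 1.5× the day-0 volume, linearly
interpolated between bracketing measurements, censored at the last
observation when never reached.  Tumor growth delay is the difference of
mean uncensored T₁.₅ₓ between irradiated and unirradiated groups of a
line, and the enhancement factor is the TGD ratio of the
miRNA-overexpressing line to its control — the standard radiobiology
definition, adopted because the source does not print the formula.
Censored T₁.₅ₓ values are excluded from the means and a flag is raised
when more than 20% of a group is censored.

## Synthetic study conditions

The generator defaults encode the conditions of the study the pipeline was
built for, and are not tuned per experiment:

| parameter | default | rationale |
|---|---|---|
| cohort sizes | 90 and 110 | the two sequencing cohorts |
| inter-miRNA Pearson r | 0.85 | middle of the observed 0.74–0.93 range |
| hazard ratio per unit score | 0.40 | the reported prognostic effect |
| baseline hazard | −ln(0.7)/60 per month | ~30% recurrence by 60 months |
| recurrence-site mix | 21/20/59% central/lateral/distant | reported site distribution |
| candidate genes / planted targets | 2000 / 50 | desk-scale screen with known truth |
| planted target Spearman rho | −0.5 | clearly detectable at n≈100 yet noisy |
| b-values | 200, 400, 700, 1000 s/mm² | characterization protocol |
| viable / necrotic ADC | 0.8e-3 / 1.4e-3 mm²/s | straddles the 1.1e-3 threshold |
| necrotic fraction | 0.25 | typical xenograft section |
| doubling times | 4.5 d (control), 5.0 d (miR line) | SiHa xenograft scale |
| growth delays | 4 d (control), 20 d (miR line) | planted EF = 5 |

miRNA values are multivariate Gaussian with equicorrelation on the log2
scale; event times are exponential proportional hazards on the true score;
the recurrence site is a single independent multinomial draw (multi-site
recurrence is a config option, off by default).  Planted target genes mix
a standardized miRNA with Gaussian noise at the Pearson weight
2·sin(π·ρ_s/6) that yields the requested Spearman ρ_s for bivariate normal
data.  DWI noise is additive Gaussian on the signal (the simplest model
consistent with the log-linear fit; Rician noise is not modelled).
Histology phantoms render disc nuclei through the forward stain matrix,
with necrosis and hypoxia as area bands of exactly known fraction.  Growth
curves are V0·2^(t/Td) with irradiated tumors stalled at V0 for the
planted delay.

What the generator does **not** emulate: sequencing read-level noise and
batch effects, non-proportional hazards, informative censoring, spatially
correlated MRI noise, stain variability and uneven illumination, and
irregular nuclear morphology.  Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery under the stated
models, not robustness to every artefact of real data.

## Numerical choices and degenerate inputs

- All randomness flows through `numpy.random.default_rng` seeds carried in
  the configuration; equal config and seed give byte-identical output
  files.
- Spearman p-values use the t approximation with average ranks for ties;
  |rho| = 1 maps to p = 0.
- The cutoff-scan permutation p is (hits+1)/(permutations+1) and is never
  allowed below the uncorrected p.
- Zero-variance covariates, empty ROIs, all-invalid voxel sets, missing
  baselines and singular stain matrices raise immediately with named
  errors; non-convergent Cox fits return a flagged result instead of
  raising.
- Constant squared residuals short-circuit the White test to (0, 1); flat
  growth curves return infinite doubling time rather than a negative one.
- Test and demonstration problem sizes (e.g. 200 null replicates for FDR
  calibration, 25 replicates for cutoff recovery, 10⁴ voxels for noisy ADC
  recovery) were chosen as the smallest sizes at which the Monte-Carlo
  error is clearly below the tolerance being checked.

## Known limitations

- Site-specific endpoints use censoring, not competing-risks modelling;
  cumulative-incidence estimates would differ when recurrence rates are
  high.
- The stepwise selection p-values are conditional on selection and should
  be read descriptively, as in the original analysis.
- The enrichment module reproduces the hypergeometric statistics of a
  DAVID-style analysis but not its term curation or redundancy handling.
- The watershed splitter assumes roughly convex nuclei; heavily elongated
  or overlapping-by-more-than-touching nuclei may not split correctly.
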