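"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure of a two-cohort cervical
cancer biomarker study and its supporting xenograft experiments:

* two patient cohorts (n = 90 and 110) with five highly co-expressed
  miRNAs (pairwise Pearson r around 0.85, within the observed 0.74-0.93
  range), exponential proportional-hazards recurrence with per-unit-score
  hazard ratio 0.4, a ~30% five-year event rate, and a
  21% / 20% / 59% central / lateral / distant recurrence-site mix;
* gene expression with planted negative-Spearman targets of the miRNAs
  among independent null genes;
* mono-exponential DW-MRI decay with a high-ADC necrotic region;
* H-DAB histology rendered through the forward stain matrix, with
  disc nuclei, necrosis and hypoxia regions of known area;
* exponential tumor growth with treatment-induced growth delay.

Everything is driven by :class:`SimulationConfig` plus a seed; identical
configuration and seed reproduce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection
from .histology import stain_to_rgb
from .response import GrowthCurve
from .score import FIVE_MEMBER_SCORE, compute_score
from .adc import DWISeries

#: ~30% of patients recur within 60 months under the baseline hazard
BASELINE_HAZARD_PER_MONTH = -np.log(0.7) / 60.0


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohorts and xenograft experiments."""

    seed: int = 0
    n_patients: tuple[int, int] = (90, 110)
    n_mirnas: int = 5
    inter_mirna_rho: float = 0.85
    log_hr_score: float = float(np.log(0.4))
    site_mix: tuple[float, float, float] = (0.21, 0.20, 0.59)  # central, lateral, distant
    n_genes: int = 2000
    n_true_targets: int = 50
    target_rho: float = -0.5
    censor_months: float = 60.0
    # DW-MRI
    dwi_shape: tuple[int, int] = (32, 32)
    b_values: tuple[float, ...] = (200.0, 400.0, 700.0, 1000.0)
    noise_sd: float = 0.0
    adc_viable: float = 0.0008
    adc_necrotic: float = 0.0014
    necrosis_fraction: float = 0.25
    # histology
    image_shape: tuple[int, int] = (256, 256)
    n_nuclei: int = 40
    nucleus_radius_px: int = 5
    n_touching_pairs: int = 0
    hypoxia_fraction: float = 0.2
    # growth
    n_tumors_per_group: int = 9
    td_days: dict = field(default_factory=lambda: {"mir200": 5.0, "control": 4.5})
    delay_days: dict = field(default_factory=lambda: {"mir200": 20.0, "control": 4.0})
    baseline_volume_mm3: float = 220.0
    growth_noise_sd: float = 0.0
    followup_days: float = 60.0
    measurement_interval_days: float = 3.0

    def __post_init__(self) -> None:
        if abs(sum(self.site_mix) - 1.0) > 1e-12:
            raise ValueError("site_mix must sum to 1")
        if not 0 < self.inter_mirna_rho < 1:
            raise ValueError("inter_mirna_rho must lie in (0, 1)")
        if not -1 < self.target_rho < 0:
            raise ValueError("target_rho must lie in (-1, 0)")
        if self.noise_sd < 0 or self.growth_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        for name in ("n_mirnas", "n_genes", "n_true_targets", "n_nuclei"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_true_targets > self.n_genes:
            raise ValueError("n_true_targets cannot exceed n_genes")


@dataclass
class GroundTruth:
    """What the generator planted, for closing the parameter-recovery loop."""

    true_hr: float | None = None
    scores: pd.Series | None = None
    true_target_gene_ids: set = field(default_factory=set)
    target_of: dict = field(default_factory=dict)  # gene -> miRNA
    true_adc_map: np.ndarray | None = None
    true_necrosis_mask: np.ndarray | None = None
    true_necrotic_fraction: float | None = None
    true_hypoxic_fraction: float | None = None
    true_gfp_fraction: float | None = None
    true_nucleus_count: int | None = None
    true_td: dict = field(default_factory=dict)
    true_delay: dict = field(default_factory=dict)


def _mirna_names(n: int) -> list[str]:
    base = list(FIVE_MEMBER_SCORE)
    if n <= len(base):
        return base[:n]
    return base + [f"hsa-miR-sim-{i}" for i in range(n - len(base))]


def gen_cohort(
    config: SimulationConfig, cohort_index: int = 0, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate one cohort: miRNA expression matrix + clinical table.

    miRNA log2 values are multivariate Gaussian with equicorrelation
    ``inter_mirna_rho``; recurrence times are exponential with per-patient
    hazard ``baseline * exp(log_hr_score * score)``, administratively
    censored at ``censor_months``; the recurrence site is a single
    multinomial draw from ``site_mix``.
    """
    n = config.n_patients[cohort_index]
    if n < 10:
        raise ValueError("need at least 10 patients per cohort")
    k = config.n_mirnas
    rho = config.inter_mirna_rho
    cov = np.full((k, k), rho) + np.eye(k) * (1.0 - rho)
    if np.linalg.eigvalsh(cov).min() <= 0:
        raise ValueError("requested inter-miRNA correlation is not positive definite")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((k, n))
    expr = (chol @ z) + 8.0  # log2 RPM-like scale
    names = _mirna_names(k)
    samples = [f"cohort{cohort_index}_P{i:03d}" for i in range(n)]
    matrix = pd.DataFrame(expr, index=names, columns=samples)
    matrix.attrs["scale"] = "log2_rpm"

    score = compute_score(matrix, members=tuple(names)).values
    hazard = BASELINE_HAZARD_PER_MONTH * np.exp(config.log_hr_score * score.to_numpy())
    event_time = rng.exponential(1.0 / hazard)
    recurred = event_time <= config.censor_months
    site = rng.choice(
        ["central", "lateral", "distant"], size=n, p=list(config.site_mix)
    )
    followup = config.censor_months * (1.0 + 0.5 * rng.random(n))
    followup = np.where(recurred, np.maximum(followup, event_time), followup)
    clinical = pd.DataFrame(
        {
            "patient_id": samples,
            "followup_months": followup.astype(float),
            "recurrence_site": np.where(recurred, site, ""),
            "recurrence_months": np.where(recurred, event_time, np.nan),
            "figo_group": rng.choice(["IB-IIB", "IIIA-IVA"], size=n),
            "tumor_volume_cm3": np.exp(rng.normal(np.log(36.6), 0.6, size=n)),
            "lymph_node_status": rng.binomial(1, 0.35, size=n),
            "hypoxia_score": rng.normal(0.0, 1.0, size=n),
        }
    )
    clinical.loc[~recurred, "followup_months"] = followup[~recurred]
    truth = GroundTruth(true_hr=float(np.exp(config.log_hr_score)), scores=score)
    return matrix, clinical, truth


def gen_gene_expression(
    config: SimulationConfig,
    mirna_matrix: pd.DataFrame,
    seed: int | None = None,
    exact: bool = False,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Gene expression with planted anticorrelated targets of the miRNAs.

    Each planted target gene is a negative linear mix of one miRNA
    (round-robin across miRNAs) with Gaussian noise calibrated so the
    expected Spearman correlation equals ``target_rho`` (bivariate-normal
    relation rho_pearson = 2 sin(pi * rho_spearman / 6)).  The remaining
    genes are independent noise.  With ``exact=True`` planted genes are an
    exact negative transform of their miRNA (perfect rank inversion).
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n = mirna_matrix.shape[1]
    gene_ids = [f"GENE{i:05d}" for i in range(config.n_genes)]
    values = rng.normal(7.0, 1.0, size=(config.n_genes, n))
    target_of: dict[str, str] = {}
    rho_p = 2.0 * np.sin(np.pi * config.target_rho / 6.0)
    mirnas = list(mirna_matrix.index)
    for j in range(config.n_true_targets):
        mir = mirnas[j % len(mirnas)]
        z = mirna_matrix.loc[mir].to_numpy(float)
        zs = (z - z.mean()) / z.std()
        if exact:
            values[j] = 7.0 - zs
        else:
            noise = rng.standard_normal(n)
            values[j] = 7.0 + rho_p * zs + np.sqrt(1.0 - rho_p**2) * noise
        target_of[gene_ids[j]] = mir
    genes = pd.DataFrame(values, index=gene_ids, columns=mirna_matrix.columns)
    genes.attrs["scale"] = "log2_intensity"
    truth = GroundTruth(
        true_target_gene_ids=set(list(target_of)), target_of=target_of
    )
    return genes, truth


def gen_candidate_map(
    mirna_matrix: pd.DataFrame, genes: pd.DataFrame
) -> dict[str, set[str]]:
    """Candidate target map: every gene is a candidate of every miRNA."""
    all_genes = set(genes.index)
    return {m: set(all_genes) for m in mirna_matrix.index}


def gen_gene_sets(
    gene_ids: list[str],
    n_sets: int,
    planted_set_fraction: float,
    seed: int,
    true_targets: set[str] | None = None,
    set_size: int = 40,
) -> tuple[GeneSetCollection, str | None]:
    """Random gene sets plus one set enriched for the true targets.

    The planted set draws ``planted_set_fraction`` of its members from
    ``true_targets`` and the rest at random; returns (collection, name of
    the planted set or None).
    """
    if not gene_ids:
        raise ValueError("gene ids must be non-empty")
    if not 0.0 <= planted_set_fraction <= 1.0:
        raise ValueError("planted_set_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    sets: dict[str, set[str]] = {}
    planted_name = None
    if n_sets == 0:
        return GeneSetCollection(sets={}, category="pathway"), None
    if true_targets:
        tt = sorted(true_targets)
        n_from_true = min(int(round(planted_set_fraction * set_size)), len(tt))
        members = set(rng.choice(tt, size=n_from_true, replace=False))
        others = sorted(set(gene_ids) - set(members))
        fill = set_size - len(members)
        if fill > 0:
            members |= set(rng.choice(others, size=fill, replace=False))
        planted_name = "SET_PLANTED"
        sets[planted_name] = members
    while len(sets) < n_sets:
        name = f"SET_{len(sets):03d}"
        sets[name] = set(rng.choice(sorted(gene_ids), size=min(set_size, len(gene_ids)), replace=False))
    return GeneSetCollection(sets=sets, category="pathway"), planted_name


def gen_dwi(config: SimulationConfig, seed: int | None = None) -> tuple[DWISeries, GroundTruth]:
    """Mono-exponential DWI phantom with a contiguous necrotic (high-ADC) region.

    S(b) = S0 * exp(-b * ADC_true) + Gaussian noise of sd ``noise_sd``.
    The ROI is a centered disc; the first round(necrosis_fraction * |ROI|)
    ROI voxels in raster order carry the necrotic ADC (above the 0.0011
    mm^2/s classification threshold), the rest the viable ADC.
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    ny, nx = config.dwi_shape
    if ny <= 0 or nx <= 0:
        raise ValueError("dwi_shape must be positive")
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    roi = (yy - cy) ** 2 + (xx - cx) ** 2 <= (min(ny, nx) * 0.4) ** 2
    adc_true = np.full((ny, nx), config.adc_viable)
    roi_idx = np.flatnonzero(roi.ravel())
    n_necro = int(round(config.necrosis_fraction * roi_idx.size))
    necro_mask = np.zeros(ny * nx, bool)
    necro_mask[roi_idx[:n_necro]] = True
    necro_mask = necro_mask.reshape(ny, nx)
    adc_true[necro_mask] = config.adc_necrotic
    s0 = 1000.0
    b = np.asarray(config.b_values, float)
    signals = s0 * np.exp(-b[:, None, None] * adc_true[None])
    if config.noise_sd > 0:
        signals = signals + rng.normal(0.0, config.noise_sd, size=signals.shape)
    series = DWISeries(signals=signals, b_values=b, roi=roi)
    truth = GroundTruth(
        true_adc_map=adc_true,
        true_necrosis_mask=necro_mask,
        true_necrotic_fraction=n_necro / roi_idx.size,
    )
    return series, truth


def gen_histology(config: SimulationConfig, seed: int | None = None) -> dict:
    """H-DAB phantom: disc nuclei, necrosis band, hypoxia band, GFP parenchyma.

    Returns a dict with the Ki-67-style RGB image (DAB-stained nuclei on a
    hematoxylin background), the hypoxia (pimonidazole) RGB image, ROI /
    necrosis / parenchyma masks, and the ground truth.  Nuclei are placed
    on a jittered grid inside the viable parenchyma so discs never overlap;
    ``n_touching_pairs`` of them are rendered as touching disc pairs (each
    pair one connected component that watershed must split into two).
    """
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    ny, nx = config.image_shape
    roi = np.zeros((ny, nx), bool)
    roi[8 : ny - 8, 8 : nx - 8] = True
    # necrosis: top band of the ROI covering necrosis_fraction of it
    roi_rows = np.flatnonzero(roi.any(axis=1))
    necrosis = np.zeros_like(roi)
    target = int(round(config.necrosis_fraction * roi.sum()))
    acc = 0
    for r in roi_rows:
        if acc >= target:
            break
        necrosis[r] = roi[r]
        acc += int(roi[r].sum())
    viable = roi & ~necrosis
    parenchyma = viable.copy()
    # hypoxia: left band of the viable area covering hypoxia_fraction of it
    hypoxia = np.zeros_like(roi)
    cols = np.flatnonzero(viable.any(axis=0))
    target_h = int(round(config.hypoxia_fraction * viable.sum()))
    acc = 0
    for c in cols:
        if acc >= target_h:
            break
        hypoxia[:, c] = viable[:, c]
        acc += int(viable[:, c].sum())

    # place non-overlapping nuclei on a jittered grid inside the viable area
    r_px = config.nucleus_radius_px
    pitch = 4 * r_px + 2
    yy, xx = np.mgrid[0:ny, 0:nx]
    nuclei = np.zeros((ny, nx), bool)
    centers = []
    for gy in range(roi_rows[0] + pitch, ny - pitch, pitch):
        for gx in range(8 + pitch, nx - pitch, pitch):
            centers.append((gy, gx))
    centers = [c for c in centers if viable[c]]
    rng.shuffle(centers)
    n_single = config.n_nuclei - 2 * config.n_touching_pairs
    if n_single < 0:
        raise ValueError("n_touching_pairs too large for n_nuclei")
    used = 0
    pairs = 0
    it = iter(centers)
    for cy, cx in it:
        if used >= n_single:
            break
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
        if (disc & ~viable).any():
            continue
        nuclei |= disc
        used += 1
    for cy, cx in it:
        if pairs >= config.n_touching_pairs:
            break
        d1 = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
        d2 = (yy - cy) ** 2 + (xx - (cx + 2 * r_px)) ** 2 <= r_px**2
        if ((d1 | d2) & ~viable).any():
            continue
        nuclei |= d1 | d2
        pairs += 1
    n_placed = used + 2 * pairs

    # render through the forward stain model: DAB in nuclei / hypoxia band,
    # light hematoxylin everywhere in tissue
    def render(dab_mask: np.ndarray) -> np.ndarray:
        conc = np.zeros((ny, nx, 3))
        conc[..., 0] = np.where(roi, 0.25, 0.0)  # hematoxylin counterstain
        conc[..., 1] = np.where(dab_mask, 1.0, 0.0)  # DAB
        return stain_to_rgb(conc)

    ki67_rgb = render(nuclei)
    hypoxia_rgb = render(hypoxia)
    gfp_rgb = render(parenchyma)
    truth = GroundTruth(
        true_necrosis_mask=necrosis,
        true_necrotic_fraction=float(necrosis.sum() / roi.sum()),
        true_hypoxic_fraction=float(hypoxia.sum() / viable.sum()),
        true_gfp_fraction=float(parenchyma.sum() / viable.sum()),
        true_nucleus_count=n_placed,
    )
    return {
        "ki67_rgb": ki67_rgb,
        "hypoxia_rgb": hypoxia_rgb,
        "gfp_rgb": gfp_rgb,
        "roi": roi,
        "necrosis": necrosis,
        "parenchyma": parenchyma,
        "nucleus_mask": nuclei,
        "truth": truth,
    }


def gen_growth(config: SimulationConfig, seed: int | None = None) -> tuple[list[GrowthCurve], GroundTruth]:
    """Exponential growth curves for four groups with planted radiation delay.

    V(t) = V0 * 2^(t/Td) for unirradiated tumors; irradiated tumors stall
    at V0 for the line's delay before resuming the same exponential, so the
    planted tumor growth delay equals the delay parameter and the planted
    enhancement factor is delay(miR line)/delay(control line).  Optional
    multiplicative lognormal measurement noise (``growth_noise_sd``).
    """
    rng = np.random.default_rng(config.seed + 4 if seed is None else seed)
    days = np.arange(0.0, config.followup_days + 0.5, config.measurement_interval_days)
    curves: list[GrowthCurve] = []
    for line, td in config.td_days.items():
        for treated in (False, True):
            delay = config.delay_days[line] if treated else 0.0
            group = f"{line}_{'irradiated' if treated else 'unirradiated'}"
            for i in range(config.n_tumors_per_group):
                v = config.baseline_volume_mm3 * 2.0 ** (np.maximum(days - delay, 0.0) / td)
                if config.growth_noise_sd > 0:
                    v = v * np.exp(rng.normal(0.0, config.growth_noise_sd, size=v.size))
                    v[0] = config.baseline_volume_mm3
                curves.append(
                    GrowthCurve(
                        tumor_id=f"{group}_{i}",
                        group=group,
                        days=days.copy(),
                        volumes_mm3=v,
                        irradiation_day=0.0 if treated else None,
                    )
                )
    truth = GroundTruth(true_td=dict(config.td_days), true_delay=dict(config.delay_days))
    return curves, truth
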