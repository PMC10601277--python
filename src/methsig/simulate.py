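"""Synthetic two-arm AML cohort with planted response-linked methylation.

Emulates a randomized induction trial in which one arm (EXP) received an
azacytidine-containing regimen and the other (STD) standard chemotherapy,
and each patient is labelled complete response (CR) or refractory disease
(RD).  A single underlying methylation state per (region, sample) drives
three measurement layers:

* enrichment-sequencing bin counts (negative binomial on a 500-bp grid),
* array beta values for probes falling in candidate regions,
* mass-spectrometry CpG units with Gaussian noise and missing entries,

so cross-platform signals cohere by construction, and every downstream
stage of the pipeline is testable against the planted truth table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .screen import BinCountMatrix

__all__ = [
    "SimConfig",
    "AnnotationTrack",
    "make_cohort_meta",
    "make_bin_counts",
    "make_probe_betas",
    "make_unit_table",
    "make_annotation_track",
]

ARMS = ("STD", "EXP")
MUTATION_GENES = ("TP53", "ASXL1", "DNMT3A", "RUNX1", "IDH1", "IDH2", "TET2")
# Cohort prevalences typical of an intensively treated adult AML trial
# population lacking NPM1/FLT3-ITD/CBF genotypes.
MUTATION_PREVALENCE = {
    "TP53": 0.10,
    "ASXL1": 0.17,
    "DNMT3A": 0.17,
    "RUNX1": 0.21,
    "IDH1": 0.08,
    "IDH2": 0.15,
    "TET2": 0.10,
}
KARYOTYPES = ("CN", "complex", "t11q23", "del5q", "inv3", "other")
KARYOTYPE_PROBS = (0.42, 0.19, 0.06, 0.04, 0.01, 0.28)

# Relative chromosome weights for the scaled-down genome; chr3, chr11 and
# chrX are present so the selection-stage exclusion rules have targets.
DEFAULT_CHROM_WEIGHTS = {
    "chr1": 0.22,
    "chr2": 0.18,
    "chr3": 0.10,
    "chr7": 0.14,
    "chr11": 0.10,
    "chr17": 0.10,
    "chr19": 0.08,
    "chrX": 0.08,
}


def _default_layout(n_bins: int) -> list[tuple[str, int]]:
    names = list(DEFAULT_CHROM_WEIGHTS)
    sizes = [int(round(w * n_bins)) for w in DEFAULT_CHROM_WEIGHTS.values()]
    sizes[0] += n_bins - sum(sizes)
    return list(zip(names, sizes))


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic cohort.

    The defaults emulate the screening-trial conditions: ~5e6 mapped reads
    per library, a scaled-down genome of 20,000 informative 500-bp bins
    carrying a mean of ~7.5 reads each, 50 planted differentially
    methylated regions per arm at a 2.5-fold count difference between
    response groups, ~55% CR prevalence, and array/mass-spec layers with
    moderate technical noise and missingness.
    """

    n_samples_per_arm: int = 20
    n_bins: int = 20_000
    bin_size: int = 500
    chrom_layout: list[tuple[str, int]] | None = None
    n_planted_dmrs_exp: int = 50
    n_planted_dmrs_std: int = 50
    planted_log2fc: float = math.log2(2.5)
    nb_dispersion: float = 0.1
    library_size_mean: float = 5.0e6
    library_size_sigma: float = 0.25
    bin_abundance_median: float = 1.5e-6  # expected count fraction per bin
    bin_abundance_sigma: float = 1.0
    lowcount_outliers: int = 0  # per cohort, library < 1e6 to exercise QC
    beta_precision: float = 30.0
    beta_base_range: tuple[float, float] = (0.35, 0.65)
    theta_delta: float = 0.2  # methylation-level shift of planted regions
    probe_coverage_fraction: float = 0.8
    unit_noise_sd: float = 0.05
    missing_rate: float = 0.05
    forced_missing_frac: float = 0.1  # units pushed above the 20% QC cut
    forced_missing_rate: float = 0.3
    response_coefficients: tuple[float, ...] = (0.2,)
    force_overlap: int = 0  # planted bins shared by both arms
    seed: int = 0

    def layout(self) -> list[tuple[str, int]]:
        return self.chrom_layout or _default_layout(self.n_bins)

    def validate(self) -> None:
        if self.n_samples_per_arm < 4:
            raise ValueError("n_samples_per_arm must be >= 4 (cells too small)")
        if self.n_bins < self.n_planted_dmrs_exp + self.n_planted_dmrs_std:
            raise ValueError("n_bins must cover all planted DMRs")
        for p in (self.missing_rate, self.forced_missing_rate,
                  self.probe_coverage_fraction, self.forced_missing_frac):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 < self.unit_noise_sd < 0.5 and self.unit_noise_sd != 0.0:
            raise ValueError("unit_noise_sd must lie in [0, 0.5)")
        if self.beta_precision <= 0:
            raise ValueError("beta_precision must be positive")
        if self.nb_dispersion < 0 or self.library_size_mean <= 0:
            raise ValueError("dispersion and library size must be non-negative/positive")
        if sum(n for _, n in self.layout()) != self.n_bins:
            raise ValueError("chromosome layout does not sum to n_bins")
        names = {c for c, _ in self.layout()}
        if not {"chr3", "chr11", "chrX"} <= names:
            raise ValueError("layout must include chr3, chr11 and chrX")

    def rng(self, stage: int) -> np.random.Generator:
        # Independent stream per generator stage so outputs do not depend
        # on which stages the caller runs.
        return np.random.default_rng([self.seed, stage])


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def make_cohort_meta(cfg: SimConfig) -> pd.DataFrame:
    """Sample metadata: arm, response, mutations, karyotype, age, sex.

    Response is drawn from a logistic model on a latent per-sample
    methylation burden (``response_coefficients`` = (c0, c1, ...)); with
    the default single coefficient the CR fraction is sigmoid(c0) ~ 55%.
    At least two samples per (arm, response) cell are guaranteed.
    """
    cfg.validate()
    rng = cfg.rng(0)
    n = 2 * cfg.n_samples_per_arm
    sample_ids = [f"S{i:03d}" for i in range(n)]
    arm = np.array(ARMS * cfg.n_samples_per_arm)[:n]
    rng.shuffle(arm)

    latent = rng.normal(size=n)
    coefs = np.asarray(cfg.response_coefficients, dtype=float)
    c0 = coefs[0] if coefs.size else 0.0
    c1 = coefs[1] if coefs.size > 1 else 0.0
    p_cr = _sigmoid(c0 + c1 * latent)
    response = np.where(rng.random(n) < p_cr, "CR", "RD")
    # Guarantee testable cells: redraw deficient arms, then force-flip.
    for a in ARMS:
        idx = np.where(arm == a)[0]
        for _ in range(200):
            vals, cts = np.unique(response[idx], return_counts=True)
            if len(vals) == 2 and cts.min() >= 2:
                break
            response[idx] = np.where(rng.random(idx.size) < p_cr[idx], "CR", "RD")
        vals, cts = np.unique(response[idx], return_counts=True)
        if len(vals) < 2 or cts.min() < 2:
            majority = vals[np.argmax(cts)]
            minority = "RD" if majority == "CR" else "CR"
            flip = idx[response[idx] == majority][:2]
            response[flip] = minority

    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "arm": arm,
            "response": response,
            "karyotype": rng.choice(KARYOTYPES, size=n, p=KARYOTYPE_PROBS),
            "age": np.clip(np.round(rng.normal(60, 12, size=n), 1), 18, 82),
            "sex": rng.choice(["female", "male"], size=n, p=[0.45, 0.55]),
            "latent": latent,
        }
    )
    for gene in MUTATION_GENES:
        meta[gene] = (rng.random(n) < MUTATION_PREVALENCE[gene]).astype(int)
    return meta.set_index("sample_id")


def _bin_table(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for chrom, nb in cfg.layout():
        for i in range(nb):
            rows.append((chrom, i * cfg.bin_size, (i + 1) * cfg.bin_size))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    bins["bin_id"] = [
        f"{c}:{s}-{e}" for c, s, e in zip(bins.chrom, bins.start, bins.end)
    ]
    return bins


def make_bin_counts(
    cfg: SimConfig, meta: pd.DataFrame
) -> tuple[BinCountMatrix, pd.DataFrame]:
    """Enrichment-seq counts plus the planted-DMR truth table.

    count ~ NB(mean = lib_s * a_b * fold, dispersion phi) where a_b is a
    lognormal per-bin abundance and fold = 2**planted_log2fc for samples
    of the elevated response group in the designated arm.  Planted bins
    for the two arms are disjoint unless ``force_overlap`` > 0.
    """
    cfg.validate()
    rng = cfg.rng(1)
    bins = _bin_table(cfg)
    n_bins, n = len(bins), len(meta)

    abundance = rng.lognormal(
        mean=math.log(cfg.bin_abundance_median), sigma=cfg.bin_abundance_sigma,
        size=n_bins,
    )
    lib = rng.lognormal(math.log(cfg.library_size_mean), cfg.library_size_sigma, n)
    if cfg.lowcount_outliers > 0:
        for a in ARMS:
            idx = np.where(meta["arm"].to_numpy() == a)[0]
            pick = rng.choice(idx, size=min(cfg.lowcount_outliers, idx.size),
                              replace=False)
            lib[pick] = rng.uniform(3e5, 9e5, size=pick.size)

    n_exp, n_std = cfg.n_planted_dmrs_exp, cfg.n_planted_dmrs_std
    overlap = min(cfg.force_overlap, n_exp, n_std)
    n_distinct = n_exp + n_std - overlap
    planted = rng.choice(n_bins, size=n_distinct, replace=False)
    exp_bins = planted[:n_exp]
    std_bins = np.concatenate([planted[n_exp - overlap : n_exp],
                               planted[n_exp:]]) if n_std else planted[:0]

    truth_rows = []
    fold = np.ones((n_bins, n))
    null_effect = cfg.planted_log2fc == 0.0
    for arm_name, arm_bins in (("EXP", exp_bins), ("STD", std_bins)):
        in_arm = (meta["arm"] == arm_name).to_numpy()
        is_rd = (meta["response"] == "RD").to_numpy()
        for b in arm_bins:
            hyper_in_rd = bool(rng.random() < 0.5)
            if not null_effect:
                high = in_arm & (is_rd if hyper_in_rd else ~is_rd)
                fold[b, high] *= 2.0**cfg.planted_log2fc
            truth_rows.append(
                (
                    bins.bin_id.iloc[b],
                    bins.chrom.iloc[b],
                    bins.start.iloc[b],
                    bins.end.iloc[b],
                    arm_name,
                    "none" if null_effect else
                    ("hyper_in_RD" if hyper_in_rd else "hypo_in_RD"),
                    0.0 if null_effect else cfg.planted_log2fc,
                )
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["bin_id", "chrom", "start", "end", "arm", "direction", "log2fc"],
    )

    mean = abundance[:, None] * lib[None, :] * fold
    if cfg.nb_dispersion < 1e-12:
        counts = rng.poisson(mean)
    else:
        r = 1.0 / cfg.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mean))
    counts_df = pd.DataFrame(counts, index=bins.bin_id.to_numpy(),
                             columns=meta.index)
    lib_series = pd.Series(lib, index=meta.index, name="library_size")
    return BinCountMatrix(bins=bins, counts=counts_df,
                          library_sizes=lib_series), truth


def _region_theta(
    cfg: SimConfig, regions: pd.DataFrame, meta: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Underlying methylation level per (region, sample) in [0, 1].

    Planted regions shift by ``theta_delta`` in the elevated response
    group of their designated arm; null regions are group-independent.
    """
    lo, hi = cfg.beta_base_range
    base = rng.uniform(lo, hi, size=len(regions))
    theta = np.tile(base[:, None], (1, len(meta)))
    in_arm = {a: (meta["arm"] == a).to_numpy() for a in ARMS}
    is_rd = (meta["response"] == "RD").to_numpy()
    for i, row in enumerate(regions.itertuples()):
        if row.direction in ("hyper_in_RD", "hypo_in_RD"):
            high = in_arm[row.arm] & (is_rd if row.direction == "hyper_in_RD"
                                      else ~is_rd)
            theta[i, high] = base[i] + cfg.theta_delta
    theta = np.clip(theta, 0.02, 0.98)
    return pd.DataFrame(theta, index=regions.bin_id.to_numpy(), columns=meta.index)


def _candidate_regions(
    cfg: SimConfig, truth: pd.DataFrame, rng: np.random.Generator,
    n_null: int | None,
) -> pd.DataFrame:
    bins = _bin_table(cfg)
    planted_ids = set(truth.bin_id)
    cand = truth[["bin_id", "chrom", "start", "end", "arm", "direction"]].copy()
    if n_null is None:
        n_null = len(truth)
    null_pool = bins[~bins.bin_id.isin(planted_ids)]
    take = null_pool.iloc[
        rng.choice(len(null_pool), size=min(n_null, len(null_pool)), replace=False)
    ].copy()
    take["arm"] = "none"
    take["direction"] = "none"
    return pd.concat([cand, take], ignore_index=True)


def make_probe_betas(
    cfg: SimConfig,
    truth: pd.DataFrame,
    meta: pd.DataFrame,
    n_null_regions: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Array layer: probe manifest, beta matrix and the underlying theta.

    Candidate regions are the planted regions plus ``n_null_regions``
    group-independent null regions (default: as many as planted).  A
    region is uncovered with probability 1 - probe_coverage_fraction;
    covered regions carry 1-7 probes.  beta ~ Beta(theta*s, (1-theta)*s).
    """
    cfg.validate()
    rng = cfg.rng(2)
    regions = _candidate_regions(cfg, truth, rng, n_null_regions)
    theta = _region_theta(cfg, regions, meta, rng)

    rows, beta_rows = [], []
    for i, row in enumerate(regions.itertuples()):
        if rng.random() >= cfg.probe_coverage_fraction:
            continue
        n_probes = int(rng.integers(1, 8))
        positions = np.sort(
            rng.choice(np.arange(row.start, row.end), size=n_probes, replace=False)
        )
        th = theta.iloc[i].to_numpy()
        for k, pos in enumerate(positions):
            probe_id = f"cg_{row.bin_id}_{k}"
            rows.append((probe_id, row.chrom, int(pos), row.bin_id,
                         row.direction != "none"))
            s = cfg.beta_precision
            beta_rows.append(rng.beta(th * s, (1.0 - th) * s))
    panel = pd.DataFrame(
        rows, columns=["probe_id", "chrom", "pos", "bin_id", "is_planted"]
    ).set_index("probe_id")
    betas = pd.DataFrame(beta_rows, index=panel.index, columns=meta.index)
    return panel, betas, theta


def make_unit_table(
    cfg: SimConfig,
    panel: pd.DataFrame,
    theta: pd.DataFrame,
    meta: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Mass-spec layer: CpG-unit matrix with missingness, plus unit->probe map.

    Each assayed probe contributes 1-3 units; a unit value is the region's
    underlying theta plus truncated Gaussian noise.  Entries are missing
    completely at random at ``missing_rate``; a ``forced_missing_frac``
    subset of units is degraded to ``forced_missing_rate`` so the >20%
    missingness QC filter has work to do.
    """
    cfg.validate()
    rng = cfg.rng(3)
    n = len(meta)
    unit_rows, unit_ids, parents = [], [], []
    for probe_id, probe in panel.iterrows():
        th = theta.loc[probe["bin_id"]].to_numpy()
        for u in range(int(rng.integers(1, 4))):
            vals = np.clip(th + rng.normal(0.0, cfg.unit_noise_sd, size=n), 0.0, 1.0)
            unit_rows.append(vals)
            unit_ids.append(f"{probe_id}_u{u}")
            parents.append(probe_id)
    units = pd.DataFrame(unit_rows, index=unit_ids, columns=meta.index)

    rates = np.full(len(units), cfg.missing_rate)
    n_forced = int(round(cfg.forced_missing_frac * len(units)))
    if n_forced:
        forced = rng.choice(len(units), size=n_forced, replace=False)
        rates[forced] = cfg.forced_missing_rate
    mask = rng.random(units.shape) < rates[:, None]
    units = units.mask(mask)
    return units, pd.Series(parents, index=unit_ids, name="probe_id")


@dataclass
class AnnotationTrack:
    """TSS positions, gene/exon intervals and GC source per chromosome.

    ``gc_by_bin`` maps (chrom, start) to a GC fraction; alternatively
    ``sequences`` holds a full chromosome string from which GC is counted.
    Intervals are 0-based half-open and sorted.
    """

    tss: dict[str, np.ndarray]
    genes: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    exons: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    gc_by_bin: dict[tuple[str, int], float] = field(default_factory=dict)
    sequences: dict[str, str] = field(default_factory=dict)


def make_annotation_track(cfg: SimConfig) -> AnnotationTrack:
    """A random but deterministic annotation track over the synthetic genome.

    Genes (with 1-4 exons) tile roughly 40% of each chromosome; one TSS
    per gene at its start; per-bin GC fractions drawn around 0.45.
    """
    cfg.validate()
    rng = cfg.rng(4)
    tss: dict[str, np.ndarray] = {}
    genes: dict[str, list[tuple[int, int]]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    gc_by_bin: dict[tuple[str, int], float] = {}
    for chrom, nb in cfg.layout():
        length = nb * cfg.bin_size
        g_list, e_list, t_list = [], [], []
        pos = int(rng.integers(0, 5_000))
        while pos < length - 2_000:
            g_len = int(rng.integers(2_000, 20_000))
            g_end = min(pos + g_len, length)
            g_list.append((pos, g_end))
            t_list.append(pos)
            n_ex = int(rng.integers(1, 5))
            ex_starts = np.sort(rng.integers(pos, max(pos + 1, g_end - 200),
                                             size=n_ex))
            for es in ex_starts:
                e_list.append((int(es), int(min(es + int(rng.integers(100, 400)),
                                                g_end))))
            pos = g_end + int(rng.integers(2_000, 30_000))
        tss[chrom] = np.array(sorted(t_list))
        genes[chrom] = sorted(g_list)
        exons[chrom] = sorted(e_list)
        for i in range(nb):
            gc_by_bin[(chrom, i * cfg.bin_size)] = float(
                np.clip(rng.normal(0.45, 0.08), 0.2, 0.8)
            )
    return AnnotationTrack(tss=tss, genes=genes, exons=exons, gc_by_bin=gc_by_bin)
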