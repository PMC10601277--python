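"""Bin-level QC and negative-binomial differential methylation testing.

Enrichment sequencing (MCIp-seq) yields, for every 500-bp genomic bin, a
read count per sample that scales with the bin's methylation level.  This
module screens responders (CR) against non-responders (RD): it removes
uninformative bins, flags low-depth samples, normalizes libraries with a
trimmed-mean-of-M-values (TMM) procedure, estimates negative-binomial
dispersions by conditional maximum likelihood on quantile-adjusted
pseudo-counts, and computes a two-sided exact test per bin conditional on
the pseudo-count sum — the classic count-based differential pipeline for
two-group designs, re-implemented here so that every step is inspectable.

Conventions: bins are 0-based half-open intervals on a fixed grid;
``logFC`` is log2(mean CR / mean RD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

__all__ = [
    "BinCountMatrix",
    "FilterReport",
    "filter_uninformative_bins",
    "flag_lowcount_samples",
    "compute_rpkm",
    "tmm_norm_factors",
    "nb_differential_test",
    "adjust_bh",
]

LOWCOUNT_THRESHOLD = 1.0e6  # reads; samples below are screening outliers


@dataclass
class BinCountMatrix:
    """Bins x samples enrichment counts with per-sample library sizes.

    ``bins`` holds chrom/start/end/bin_id (0-based half-open, fixed grid);
    ``counts`` is indexed by bin_id with sample columns; ``library_sizes``
    defaults to column sums when not supplied externally.
    """

    bins: pd.DataFrame
    counts: pd.DataFrame
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if len(self.bins) != len(self.counts):
            raise ValueError("bins and counts row counts differ")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def bin_lengths(self) -> np.ndarray:
        return (self.bins["end"] - self.bins["start"]).to_numpy()

    def subset_samples(self, keep: list[str]) -> "BinCountMatrix":
        return BinCountMatrix(
            bins=self.bins.copy(),
            counts=self.counts[keep].copy(),
            library_sizes=self.library_sizes[keep].copy(),
        )

    def subset_bins(self, mask: np.ndarray) -> "BinCountMatrix":
        return BinCountMatrix(
            bins=self.bins.loc[mask].reset_index(drop=True),
            counts=self.counts.loc[mask],
            library_sizes=self.library_sizes.copy(),
        )


@dataclass
class FilterReport:
    total: int
    retained: int

    @property
    def removed(self) -> int:
        return self.total - self.retained


def filter_uninformative_bins(m: BinCountMatrix) -> tuple[BinCountMatrix, FilterReport]:
    """Drop bins with no reads across all, or all but one, sample.

    A bin is retained iff it has a nonzero count in at least two samples.
    Idempotent.
    """
    if len(m.counts) == 0:
        raise ValueError("empty count matrix")
    nonzero_samples = (m.counts.to_numpy() > 0).sum(axis=1)
    mask = nonzero_samples >= 2
    return m.subset_bins(mask), FilterReport(total=len(mask), retained=int(mask.sum()))


def flag_lowcount_samples(
    m: BinCountMatrix, threshold: float = LOWCOUNT_THRESHOLD
) -> pd.Series:
    """Flag samples whose mean total read count is strictly below ``threshold``."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return m.library_sizes < threshold


def compute_rpkm(m: BinCountMatrix) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads, bin x sample."""
    lib = m.library_sizes.to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("zero or negative library size")
    lengths_kb = m.bin_lengths[:, None] / 1000.0
    return m.counts / (lengths_kb * (lib[None, :] / 1e6))


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> float:
    # Bins with a zero in either sample carry no usable log-ratio.
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / lib_obs, ref / lib_ref
    log_ratio = np.log2(p_obs / p_ref)
    abs_expr = 0.5 * np.log2(p_obs * p_ref)
    # Asymptotic binomial variance of the log-ratio (delta method).
    variance = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)

    n = log_ratio.size
    lo_l = np.floor(n * logratio_trim) + 1
    lo_h = n + 1 - lo_l
    a_l = np.floor(n * sum_trim) + 1
    a_h = n + 1 - a_l
    rank_m = stats.rankdata(log_ratio)
    rank_a = stats.rankdata(abs_expr)
    keep2 = (rank_m >= lo_l) & (rank_m <= lo_h) & (rank_a >= a_l) & (rank_a <= a_h)
    if not keep2.any():
        return 1.0
    w = 1.0 / variance[keep2]
    f = np.sum(w * log_ratio[keep2]) / np.sum(w)
    return float(2.0**f)


def tmm_norm_factors(m: BinCountMatrix) -> pd.Series:
    """Per-sample TMM normalization factors (geometric mean 1).

    Reference sample: the one whose 75th count-fraction percentile is
    closest to the cohort mean.
    """
    counts = m.counts.to_numpy(dtype=float)
    lib = m.library_sizes.to_numpy(dtype=float)
    f75 = np.quantile(counts / lib[None, :], 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            1.0
            if j == ref_idx
            else _tmm_pair_factor(counts[:, j], counts[:, ref_idx], lib[j], lib[ref_idx])
            for j in range(counts.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=m.counts.columns, name="tmm_factor")


# ---------------------------------------------------------------------------
# Quantile adjustment to a common library size (pseudo-counts)
# ---------------------------------------------------------------------------


def _q2q_nbinom(
    x: np.ndarray, input_mean: np.ndarray, output_mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Map counts to the quantile of an NB with a different mean.

    Average of a normal and a gamma approximation of the NB cdf on the
    input scale, inverted on the output scale; identity when the means
    coincide.
    """
    eps = 0.25
    x_raw = np.asarray(x, dtype=float)
    x = x_raw + eps
    mu_in = np.asarray(input_mean, dtype=float) + eps
    mu_out = np.asarray(output_mean, dtype=float) + eps
    r_in = 1.0 + dispersion * mu_in
    r_out = 1.0 + dispersion * mu_out
    tiny, big = 1e-300, 1.0 - 1e-14  # keep ppf finite in the far tails
    # normal approximation
    p_n = np.clip(stats.norm.cdf(x, loc=mu_in, scale=np.sqrt(mu_in * r_in)),
                  tiny, big)
    q_n = stats.norm.ppf(p_n, loc=mu_out, scale=np.sqrt(mu_out * r_out))
    # gamma approximation
    p_g = np.clip(stats.gamma.cdf(x, a=mu_in / r_in, scale=r_in), tiny, big)
    q_g = stats.gamma.ppf(p_g, a=mu_out / r_out, scale=r_out)
    out = (q_n + q_g) / 2.0 - eps
    # equal means: the map is the identity; bypass tail-clipping error
    same = np.isclose(mu_in, mu_out, rtol=1e-12, atol=1e-12)
    out = np.where(same, x_raw, out)
    return np.clip(out, 0.0, None)


def _pseudo_counts(
    counts: np.ndarray,
    eff_lib: np.ndarray,
    groups: np.ndarray,
    dispersion: float,
) -> tuple[np.ndarray, float]:
    """Quantile-adjust counts to the geometric-mean library size, per group."""
    common_lib = float(np.exp(np.mean(np.log(eff_lib))))
    pseudo = np.empty_like(counts, dtype=float)
    for g in np.unique(groups):
        cols = np.where(groups == g)[0]
        lib_g = eff_lib[cols]
        props = counts[:, cols].sum(axis=1) / lib_g.sum()
        for j in cols:
            pseudo[:, j] = _q2q_nbinom(
                counts[:, j], props * eff_lib[j], props * common_lib, dispersion
            )
    return pseudo, common_lib


# ---------------------------------------------------------------------------
# Conditional likelihood dispersion estimation (qCML)
# ---------------------------------------------------------------------------


def _cond_loglik(y: np.ndarray, phi: float) -> np.ndarray:
    """Per-bin conditional NB log-likelihood for one group with equal means.

    y is bins x replicates (pseudo-counts, equalized libraries); terms not
    involving the dispersion are dropped.
    """
    r = 1.0 / phi
    n = y.shape[1]
    z = y.sum(axis=1)
    return (
        gammaln(y + r).sum(axis=1)
        + gammaln(n * r)
        - gammaln(z + n * r)
        - n * gammaln(r)
    )


def _common_dispersion(pseudo: np.ndarray, groups: np.ndarray) -> float:
    group_blocks = [pseudo[:, groups == g] for g in np.unique(groups)]

    def neg_ll(delta: float) -> float:
        phi = delta / (1.0 - delta)
        return -sum(float(_cond_loglik(b, phi).sum()) for b in group_blocks)

    res = minimize_scalar(neg_ll, bounds=(1e-6, 0.95), method="bounded")
    delta = float(res.x)
    return delta / (1.0 - delta)


def _tagwise_dispersion(
    pseudo: np.ndarray, groups: np.ndarray, common_phi: float, prior_df: float = 10.0
) -> np.ndarray:
    """Moderate per-bin dispersions toward the common value.

    Maximizes, on a log-spaced grid around the common dispersion, the sum
    of the bin's own conditional log-likelihood and ``prior_n`` times the
    cohort-average conditional log-likelihood.
    """
    uniq = np.unique(groups)
    n_samples = pseudo.shape[1]
    resid_df = max(n_samples - len(uniq), 1)
    prior_n = prior_df / resid_df
    phi_grid = np.maximum(common_phi, 1e-6) * 2.0 ** np.linspace(-8, 8, 33)
    ll = np.zeros((pseudo.shape[0], phi_grid.size))
    for k, phi in enumerate(phi_grid):
        for g in uniq:
            ll[:, k] += _cond_loglik(pseudo[:, groups == g], phi)
    score = ll + prior_n * ll.mean(axis=0)[None, :]
    return phi_grid[np.argmax(score, axis=1)]


# ---------------------------------------------------------------------------
# Exact conditional test
# ---------------------------------------------------------------------------


def _exact_nb_pvalue(y1: int, y2: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided exact test of equal group means given the total count.

    Group sums of i.i.d. NB variables with common per-sample mean are NB;
    conditioning on the total, the p-value sums the probabilities of every
    partition no more likely than the observed one ("minlike" two-sided
    rule).  At dispersion 0 this is the conditional-binomial (Poisson)
    exact test.
    """
    t = y1 + y2
    if t == 0:
        return 1.0
    a = np.arange(t + 1)
    if phi <= 0:
        probs = stats.binom.pmf(a, t, n1 / (n1 + n2))
    else:
        mu = t / (n1 + n2)
        r1, r2 = n1 / phi, n2 / phi
        p1 = r1 / (r1 + n1 * mu)
        p2 = r2 / (r2 + n2 * mu)
        probs = stats.nbinom.pmf(a, r1, p1) * stats.nbinom.pmf(t - a, r2, p2)
        s = probs.sum()
        if s <= 0 or not np.isfinite(s):
            return 1.0
        probs = probs / s
    p_obs = probs[y1]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-7)].sum()))


def nb_differential_test(
    m: BinCountMatrix,
    labels: pd.Series,
    dispersion: float | None = None,
    tagwise: bool = True,
    norm_method: str = "tmm",
    prior_df: float = 10.0,
) -> pd.DataFrame:
    """Per-bin two-sided exact NB test of CR vs RD.

    Parameters
    ----------
    m : BinCountMatrix
        Pre-filtered counts (no all-zero / single-sample bins).
    labels : Series
        'CR'/'RD' per sample, aligned to ``m`` columns.
    dispersion : float, optional
        Fix the NB dispersion (0 gives the Poisson-limit exact binomial
        test).  Default: estimate by qCML with tagwise moderation.
    norm_method : {'tmm', 'none'}
        Library normalization for effective library sizes.

    Returns
    -------
    DataFrame with chrom/start/end, logFC (log2 CR/RD), p_value, group
    mean RPKMs and the dispersion used, indexed by bin_id.
    """
    labels = pd.Series(labels).reindex(m.counts.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    groups = labels.to_numpy()
    uniq, counts_per = np.unique(groups, return_counts=True)
    if len(uniq) != 2 or (counts_per < 2).any():
        raise ValueError("need two groups with >=2 samples each")
    counts = m.counts.to_numpy(dtype=float)
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("all-zero bin reached the test; filter first")

    lib = m.library_sizes.to_numpy(dtype=float)
    if norm_method == "tmm":
        eff_lib = lib * tmm_norm_factors(m).to_numpy()
    elif norm_method == "none":
        eff_lib = lib.copy()
    else:
        raise ValueError(f"unknown norm_method {norm_method!r}")

    # Dispersion on quantile-adjusted pseudo-counts (two refinement passes).
    if dispersion is None:
        phi = 0.01
        for _ in range(2):
            pseudo, _ = _pseudo_counts(counts, eff_lib, groups, phi)
            phi = _common_dispersion(pseudo, groups)
        pseudo, _ = _pseudo_counts(counts, eff_lib, groups, phi)
        if tagwise:
            phi_by_bin = _tagwise_dispersion(pseudo, groups, phi, prior_df)
        else:
            phi_by_bin = np.full(len(pseudo), phi)
    else:
        phi = float(dispersion)
        pseudo, _ = _pseudo_counts(counts, eff_lib, groups, phi)
        phi_by_bin = np.full(len(pseudo), phi)

    cr_cols = groups == "CR"
    rd_cols = groups == "RD"
    n_cr, n_rd = int(cr_cols.sum()), int(rd_cols.sum())
    y_cr = np.rint(pseudo[:, cr_cols].sum(axis=1)).astype(int)
    y_rd = np.rint(pseudo[:, rd_cols].sum(axis=1)).astype(int)

    pvals = np.array(
        [
            _exact_nb_pvalue(y_cr[i], y_rd[i], n_cr, n_rd, phi_by_bin[i])
            for i in range(len(y_cr))
        ]
    )

    mean_cr = pseudo[:, cr_cols].mean(axis=1)
    mean_rd = pseudo[:, rd_cols].mean(axis=1)
    zero = (mean_cr == 0) | (mean_rd == 0)
    prior = np.where(zero, 0.125, 0.0)
    logfc = np.log2((mean_cr + prior) / (mean_rd + prior))

    rpkm = compute_rpkm(m)
    out = m.bins.copy()
    out["logFC"] = logfc
    out["p_value"] = pvals
    out["mean_rpkm_CR"] = rpkm.loc[:, labels.index[cr_cols]].mean(axis=1).to_numpy()
    out["mean_rpkm_RD"] = rpkm.loc[:, labels.index[rd_cols]].mean(axis=1).to_numpy()
    out["dispersion"] = phi_by_bin
    return out.set_index(m.counts.index)


def adjust_bh(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1, returned in input order.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
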