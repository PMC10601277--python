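"""Cross-platform confirmation of enrichment-derived DMRs on array probes.

Each candidate region is checked against its single-CpG array probes with
three criteria per probe: (i) Spearman correlation between probe beta
values and the region's normalized enrichment (RPKM) strictly above the
cohort median over all candidate probes, (ii) the CR-vs-RD beta
difference has the same sign as the region's enrichment logFC, and
(iii) a two-sided group-difference test at p < 0.2 (lenient by design for
small cohorts).  A region is confirmed in full when every probe passes,
partially when at least one does.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "map_probes_to_regions",
    "beta_to_m",
    "confirm_regions",
]

M_VALUE_EPS = 1e-3


def map_probes_to_regions(
    panel: pd.DataFrame, regions: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign probes to regions by half-open containment (start <= pos < end).

    ``panel`` needs probe_id (index or column), chrom, pos; ``regions``
    needs chrom, start, end and a bin_id column or index.  Returns the
    probe->region mapping and a per-region coverage table flagging
    uncovered regions.
    """
    panel = panel.reset_index() if panel.index.name == "probe_id" else panel.copy()
    regions = regions.reset_index() if regions.index.name == "bin_id" else regions.copy()
    rows = []
    for reg in regions.itertuples():
        hits = panel[
            (panel["chrom"] == reg.chrom)
            & (panel["pos"] >= reg.start)
            & (panel["pos"] < reg.end)
        ]
        for probe in hits.itertuples():
            rows.append((probe.probe_id, reg.bin_id))
    mapping = pd.DataFrame(rows, columns=["probe_id", "bin_id"])
    counts = mapping.groupby("bin_id").size()
    coverage = pd.DataFrame(
        {
            "n_probes": counts.reindex(regions["bin_id"]).fillna(0).astype(int).to_numpy(),
        },
        index=regions["bin_id"],
    )
    coverage["uncovered"] = coverage["n_probes"] == 0
    return mapping, coverage


def beta_to_m(beta, eps: float = M_VALUE_EPS):
    """Logit transform of array beta values: M = log2(b / (1 - b)).

    Betas are clipped to [eps, 1 - eps] first so the boundary maps to a
    finite M value.
    """
    arr = np.asarray(beta, dtype=float)
    if ((arr < 0) | (arr > 1)).any() or np.isnan(arr).any():
        raise ValueError("beta values must lie in [0, 1]")
    clipped = np.clip(arr, eps, 1.0 - eps)
    m = np.log2(clipped / (1.0 - clipped))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index, name=beta.name)
    if np.isscalar(beta):
        return float(m)
    return m


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")  # undefined for a constant vector
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def aggregate_region_status(probes: pd.DataFrame) -> pd.DataFrame:
    """Region status from per-probe passes: all / partial / failed."""

    def status(grp: pd.DataFrame) -> str:
        if grp["passes"].all():
            return "confirmed_all"
        if grp["passes"].any():
            return "confirmed_partial"
        return "failed"

    out = (
        probes.groupby("bin_id")
        .apply(status, include_groups=False)
        .rename("status")
        .to_frame()
    )
    out["n_probes"] = probes.groupby("bin_id").size()
    out["n_passing"] = probes.groupby("bin_id")["passes"].sum()
    return out


def confirm_regions(
    mapping: pd.DataFrame,
    region_rpkm: pd.DataFrame,
    betas: pd.DataFrame,
    labels: pd.Series,
    region_logfc: pd.Series,
    alpha: float = 0.2,
    median_rho: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the three confirmation criteria probe-wise and aggregate.

    Parameters
    ----------
    mapping : probe_id -> bin_id table from :func:`map_probes_to_regions`.
    region_rpkm : region x sample normalized enrichment.
    betas : probe x sample beta values.
    labels : 'CR'/'RD' per sample (shared sample set).
    region_logfc : enrichment log2 FC (CR vs RD) per region; the direction
        reference for congruency.
    alpha : significance gate for the two-sided Mann-Whitney group test.
    median_rho : optional external reference for the correlation gate
        (e.g. the median over a wider candidate-probe population); by
        default the median over the probes of this run.

    Returns (per-probe table, per-region status table) where status is
    'confirmed_all', 'confirmed_partial' or 'failed'.
    """
    samples = [s for s in region_rpkm.columns if s in betas.columns]
    if len(samples) < 3:
        raise ValueError("need >=3 paired samples")
    labels = pd.Series(labels).reindex(samples)
    cr = labels.index[labels == "CR"]
    rd = labels.index[labels == "RD"]

    rows = []
    for rec in mapping.itertuples():
        beta = betas.loc[rec.probe_id, samples].to_numpy(dtype=float)
        rpkm = region_rpkm.loc[rec.bin_id, samples].to_numpy(dtype=float)
        rho = _spearman(beta, rpkm)
        delta = betas.loc[rec.probe_id, cr].mean() - betas.loc[rec.probe_id, rd].mean()
        concordant = bool(np.sign(delta) == np.sign(region_logfc[rec.bin_id])
                          and np.sign(delta) != 0)
        b_cr = betas.loc[rec.probe_id, cr].to_numpy(dtype=float)
        b_rd = betas.loc[rec.probe_id, rd].to_numpy(dtype=float)
        if np.all(np.concatenate([b_cr, b_rd]) == b_cr[0]):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(b_cr, b_rd, alternative="two-sided").pvalue)
        rows.append((rec.probe_id, rec.bin_id, rho, delta, concordant, p))
    probes = pd.DataFrame(
        rows,
        columns=["probe_id", "bin_id", "rho", "beta_delta",
                 "direction_concordant", "p_value"],
    )
    if median_rho is None:
        median_rho = float(np.nanmedian(probes["rho"])) if len(probes) else float("nan")
    probes["rho_above_median"] = probes["rho"] > median_rho
    probes.loc[probes["rho"].isna(), "rho_above_median"] = False
    probes["passes"] = (
        probes["rho_above_median"]
        & probes["direction_concordant"]
        & (probes["p_value"] < alpha)
    )
    region_status = aggregate_region_status(probes)
    region_status.attrs["median_rho"] = median_rho
    return probes, region_status
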