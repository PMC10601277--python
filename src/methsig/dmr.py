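"""Top-candidate DMR selection and genomic annotation.

Distills per-arm differential results into a ranked candidate list using
the study's gates: FDR (q < 0.05), a 2.5-fold per-sample effect present in
at least half of the samples of the higher response group, exclusion of
chromosomes whose methylation can be driven by recurrent cytogenetics
(chr3, chr11) and of the sex chromosomes, and exclusion of regions found
in both treatment arms (candidate chemotherapy rather than azacytidine
effects).  Annotation adds TSS distance, GC fraction and a genomic class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import AnnotationTrack

__all__ = [
    "effect_size_consistency",
    "add_consistency",
    "build_top_list",
    "annotate_regions",
    "EXCLUDED_CHROMS",
]

EXCLUDED_CHROMS = ("chr3", "chr11", "chrX", "chrY")


def effect_size_consistency(
    values_cr: np.ndarray,
    values_rd: np.ndarray,
    fold: float = 2.5,
    min_fraction: float = 0.5,
    comparator: str = "median",
) -> tuple[float, str, bool]:
    """Per-sample fold-change consistency of a candidate region.

    The higher group is the one with the larger central normalized count;
    each of its samples must reach ``fold`` times the central value
    (median by default, mean optionally) of the lower group.  Returns
    (fraction passing, direction, passes).

    Direction is reported relative to RD: 'hyper_in_RD' when RD is the
    higher group.  A lower-group central value of zero makes any nonzero
    sample pass (ratio +inf); if both centrals are zero the candidate
    fails with direction 'undetermined'.
    """
    values_cr = np.asarray(values_cr, dtype=float)
    values_rd = np.asarray(values_rd, dtype=float)
    if values_cr.size < 2 or values_rd.size < 2:
        raise ValueError("need >=2 samples per group")
    center = np.median if comparator == "median" else np.mean
    if comparator not in ("median", "mean"):
        raise ValueError("comparator must be 'median' or 'mean'")
    c_cr, c_rd = float(center(values_cr)), float(center(values_rd))
    if c_cr == 0.0 and c_rd == 0.0:
        return 0.0, "undetermined", False
    if c_cr >= c_rd:
        high, low_center, direction = values_cr, c_rd, "hypo_in_RD"
    else:
        high, low_center, direction = values_rd, c_cr, "hyper_in_RD"
    if low_center == 0.0:
        passing = high > 0.0
    else:
        passing = high >= fold * low_center
    fraction = float(passing.mean())
    return fraction, direction, fraction >= min_fraction


def add_consistency(
    results: pd.DataFrame,
    rpkm: pd.DataFrame,
    labels: pd.Series,
    fold: float = 2.5,
    min_fraction: float = 0.5,
    comparator: str = "median",
) -> pd.DataFrame:
    """Attach consistency fraction/direction/pass columns to test results.

    ``rpkm`` is the normalized bin x sample matrix restricted to the same
    samples as ``labels``; rows are matched by the results index.
    """
    labels = pd.Series(labels).reindex(rpkm.columns)
    cr_cols = labels.index[labels == "CR"]
    rd_cols = labels.index[labels == "RD"]
    out = results.copy()
    fracs, dirs, passes = [], [], []
    for bin_id in out.index:
        row = rpkm.loc[bin_id]
        f, d, p = effect_size_consistency(
            row[cr_cols].to_numpy(), row[rd_cols].to_numpy(),
            fold=fold, min_fraction=min_fraction, comparator=comparator,
        )
        fracs.append(f)
        dirs.append(d)
        passes.append(p)
    out["consistent_fraction"] = fracs
    out["direction"] = dirs
    out["consistency_pass"] = passes
    return out


def _significant(df: pd.DataFrame, q_threshold: float) -> pd.DataFrame:
    need = {"q_value", "consistency_pass"}
    if not need <= set(df.columns):
        raise ValueError(f"results need columns {sorted(need)}")
    return df[(df["q_value"] < q_threshold) & df["consistency_pass"]]


def _overlaps(df: pd.DataFrame, other: pd.DataFrame) -> np.ndarray:
    """Interval-intersection mask of df rows against any row of other."""
    mask = np.zeros(len(df), dtype=bool)
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, grp in other.groupby("chrom"):
        by_chrom[chrom] = grp[["start", "end"]].to_numpy()
    for i, row in enumerate(df.itertuples()):
        ivals = by_chrom.get(row.chrom)
        if ivals is None:
            continue
        mask[i] = bool(((ivals[:, 0] < row.end) & (ivals[:, 1] > row.start)).any())
    return mask


def build_top_list(
    exp_results: pd.DataFrame,
    std_results: pd.DataFrame,
    k: int = 50,
    q_threshold: float = 0.05,
    excluded_chroms: tuple[str, ...] = EXCLUDED_CHROMS,
) -> dict[str, pd.DataFrame]:
    """Ranked per-arm top lists after all exclusion rules.

    Keeps records with q < ``q_threshold`` that pass the consistency gate,
    drops excluded chromosomes and any record overlapping a significant
    record of the other arm, ranks by q ascending (ties: larger \\|logFC\\|,
    then genomic order) and truncates to ``k``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sig = {"EXP": _significant(exp_results, q_threshold),
           "STD": _significant(std_results, q_threshold)}
    out: dict[str, pd.DataFrame] = {}
    for arm, other in (("EXP", "STD"), ("STD", "EXP")):
        df = sig[arm]
        df = df[~df["chrom"].isin(excluded_chroms)]
        drop = _overlaps(df, sig[other])
        df = df[~drop].copy()
        df = df.sort_values(
            by=["q_value", "logFC", "chrom", "start"],
            ascending=[True, True, True, True],
            key=lambda col: -col.abs() if col.name == "logFC" else col,
        )
        out[arm] = df.head(k)
    return out


@dataclass
class _BinClass:
    promoter_window: int = 2_000


def _gc_fraction(track: AnnotationTrack, chrom: str, start: int, end: int) -> float:
    if (chrom, start) in track.gc_by_bin:
        return track.gc_by_bin[(chrom, start)]
    seq = track.sequences.get(chrom)
    if seq is None:
        return float("nan")
    window = seq[start:end].upper()
    if not window:
        return float("nan")
    return (window.count("G") + window.count("C")) / len(window)


def annotate_regions(
    records: pd.DataFrame,
    track: AnnotationTrack,
    promoter_window: int = 2_000,
) -> pd.DataFrame:
    """Add signed TSS distance, GC fraction and genomic class.

    TSS distance is bin midpoint minus the nearest TSS (negative =
    upstream).  Class precedence: promoter (midpoint within
    ``promoter_window`` bp upstream of a TSS) > exon > intron (inside a
    gene) > intergenic.  Chromosomes absent from the track yield missing
    annotations rather than an error.
    """
    out = records.copy()
    tss_d, gc, klass = [], [], []
    for row in out.itertuples():
        mid = (row.start + row.end) // 2
        positions = track.tss.get(row.chrom)
        if positions is None or len(positions) == 0:
            tss_d.append(np.nan)
            gc.append(_gc_fraction(track, row.chrom, row.start, row.end))
            klass.append("missing")
            continue
        nearest = positions[np.argmin(np.abs(positions - mid))]
        dist = int(mid - nearest)
        tss_d.append(dist)
        gc.append(_gc_fraction(track, row.chrom, row.start, row.end))
        if -promoter_window <= dist < 0:
            klass.append("promoter")
            continue
        exons = track.exons.get(row.chrom, [])
        genes = track.genes.get(row.chrom, [])
        if any(es < row.end and ee > row.start for es, ee in exons):
            klass.append("exon")
        elif any(gs < row.end and ge > row.start for gs, ge in genes):
            klass.append("intron")
        else:
            klass.append("intergenic")
    out["tss_distance"] = tss_d
    out["gc_fraction"] = gc
    out["genomic_class"] = klass
    return out
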