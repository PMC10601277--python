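"""Plain-text I/O for the pipeline's standard artifacts.

Bins travel as BED3+ (0-based half-open, tab-separated, bin_id in column
4); matrices as TSV with the feature id in the first column and sample
ids as header; unit matrices use empty cells for missing values.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .screen import BinCountMatrix

__all__ = [
    "write_bed",
    "read_bed",
    "write_matrix",
    "read_matrix",
    "read_bin_counts",
    "write_bin_counts",
]


def write_bed(bins: pd.DataFrame, path) -> None:
    bins[["chrom", "start", "end", "bin_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path) -> pd.DataFrame:
    bins = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "bin_id"]
    )
    return bins


def write_matrix(df: pd.DataFrame, path, index_label: str = "feature") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, na_rep="")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_bin_counts(m: BinCountMatrix, outdir, prefix: str = "bins") -> None:
    outdir = Path(outdir)
    write_bed(m.bins, outdir / f"{prefix}.bed")
    write_matrix(m.counts, outdir / f"{prefix}_counts.tsv", index_label="bin_id")
    m.library_sizes.to_frame().to_csv(outdir / f"{prefix}_libsizes.tsv", sep="\t",
                                      index_label="sample_id")


def read_bin_counts(bed_path, counts_path, libsizes_path=None) -> BinCountMatrix:
    bins = read_bed(bed_path)
    counts = read_matrix(counts_path)
    lib = None
    if libsizes_path is not None:
        lib = read_matrix(libsizes_path).iloc[:, 0]
    return BinCountMatrix(bins=bins, counts=counts, library_sizes=lib)
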