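"""Readers and writers for the plain-text exchange formats.

Coverage is exchanged as fixed-bin bedGraph, annotations as BED6 (0-based,
half-open; the score column is ignored), gene classes as a two-column TSV
(gene_id, class_label), and all measurement tables as long-format TSV.
Numeric output uses 6 significant digits so regenerated files are
byte-stable.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chip import CoverageTrack, GeneAnnotation
from .expression import LuciferaseRecord
from .kinetics import TimeCourse

__all__ = [
    "read_timecourse_tsv",
    "write_timecourse_tsv",
    "read_bed6",
    "write_bed6",
    "read_bedgraph",
    "write_bedgraph",
    "read_class_table",
    "apply_class_table",
    "read_luciferase_tsv",
    "write_luciferase_tsv",
]

_FMT = "%.6g"


def read_timecourse_tsv(path, condition: str | None = None,
                        scale: str = "absolute") -> TimeCourse:
    """Load one condition from a (condition, time_min, replicate, value) TSV."""
    return TimeCourse.from_frame(pd.read_csv(path, sep="\t"), condition, scale)


def write_timecourse_tsv(tc: TimeCourse, path) -> None:
    tc.to_frame().to_csv(path, sep="\t", index=False, float_format=_FMT)


def read_bed6(path, classes: dict[str, str] | None = None) -> list[GeneAnnotation]:
    """BED6 -> gene annotations; optional gene_id -> class_label mapping."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    classes = classes or {}
    return [
        GeneAnnotation(
            gene_id=str(r.name_),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
            class_label=classes.get(str(r.name_)),
        )
        for r in df.rename(columns={"name": "name_"}).itertuples()
    ]


def write_bed6(genes: Sequence[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_class_table(path) -> dict[str, str]:
    """Two-column TSV (gene_id, class_label) -> mapping."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "class_label"} <= set(df.columns):
        raise ValueError("class table needs columns gene_id, class_label")
    return dict(zip(df["gene_id"].astype(str), df["class_label"].astype(str)))


def apply_class_table(
    genes: Iterable[GeneAnnotation], classes: dict[str, str]
) -> list[GeneAnnotation]:
    """Return annotations re-labelled from a gene_id -> class mapping."""
    from dataclasses import replace

    return [replace(g, class_label=classes.get(g.gene_id, g.class_label)) for g in genes]


def read_bedgraph(path, total_mapped_reads: float | None = None) -> CoverageTrack:
    """Fixed-bin bedGraph -> CoverageTrack; the bin size is inferred.

    All intervals must share one width (the trailing interval of a chromosome
    may be shorter).  Without ``total_mapped_reads`` the summed counts are
    used as library size.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "value"],
    )
    widths = (df["end"] - df["start"]).to_numpy()
    bin_size = int(np.bincount(widths.astype(int)).argmax())
    counts: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        n_bins = int(np.ceil(sub["end"].max() / bin_size))
        arr = np.zeros(n_bins)
        idx = (sub["start"] // bin_size).to_numpy(dtype=int)
        bad = (sub["start"].to_numpy() % bin_size) != 0
        if bad.any():
            row = sub[bad].iloc[0]
            raise ValueError(
                f"bedGraph interval not on the {bin_size} bp grid: "
                f"{row['chrom']}:{row['start']}-{row['end']}"
            )
        arr[idx] = sub["value"].to_numpy()
        counts[str(chrom)] = arr
    return CoverageTrack.from_arrays(counts, bin_size, total_mapped_reads)


def write_bedgraph(track: CoverageTrack, path, skip_zero: bool = True) -> None:
    bs = track.bin_size
    with open(path, "w") as fh:
        for chrom in track.counts:
            arr = track.counts[chrom]
            for i, v in enumerate(arr):
                if skip_zero and v == 0:
                    continue
                fh.write(f"{chrom}\t{i * bs}\t{(i + 1) * bs}\t{_FMT % v}\n")


def read_luciferase_tsv(path) -> list[LuciferaseRecord]:
    """TSV with columns strain, condition, chx, luminescence, od660."""
    df = pd.read_csv(path, sep="\t")
    chx = df["chx"].map(
        lambda v: str(v).strip().lower() in ("1", "true", "yes", "chx")
    )
    return [
        LuciferaseRecord(
            strain=str(r["strain"]),
            condition=str(r["condition"]),
            chx=bool(chx.iloc[i]),
            luminescence=float(r["luminescence"]),
            od660=float(r["od660"]),
        )
        for i, (_, r) in enumerate(df.iterrows())
    ]


def write_luciferase_tsv(records: Sequence[LuciferaseRecord], path) -> None:
    pd.DataFrame(
        {
            "strain": [r.strain for r in records],
            "condition": [r.condition for r in records],
            "chx": [int(r.chx) for r in records],
            "luminescence": [r.luminescence for r in records],
            "od660": [r.od660 for r in records],
        }
    ).to_csv(path, sep="\t", index=False, float_format=_FMT)
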