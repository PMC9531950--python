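"""ChIP coverage enrichment: RPKM ratios, metagene profiles, promoter windows.

The module consumes binned coverage tracks (bedGraph exchange format) and
BED-convention gene annotations (0-based, half-open), not alignments: read
mapping, duplicate removal and peak calling are upstream concerns.  Signal is
summarized as *normalized density* — RPKM of the ChIP track over RPKM of the
matched input — and contrasts against a mock/control IP (a non-chromatin
protein such as Pgk1) absorb the "hyper-ChIPable locus" artifact.

The metagene axis runs promoter -> terminator: an unscaled upstream flank
(default -500 bp to the TSS), the gene body rescaled to a fixed number of
bins, and an unscaled downstream flank.  Promoter enrichment per gene is the
log2 ratio of target over control read counts in the strand-aware
[TSS-500, TSS) window after scaling the control to the target's library
depth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "GeneAnnotation",
    "CoverageTrack",
    "MetageneProfile",
    "WindowEnrichment",
    "ClassComparison",
    "rpkm",
    "normalized_density",
    "metagene",
    "promoter_enrichment",
    "class_compare",
]


@dataclass(frozen=True)
class GeneAnnotation:
    """Strand-aware gene coordinates, BED convention (0-based, half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    class_label: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id}: start must be < end ({self.start}, {self.end})"
            )

    @property
    def tss(self) -> int:
        """Transcription start site in genomic coordinates."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        """Transcription end site in genomic coordinates."""
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def promoter_window(self, upstream_bp: int = 500) -> tuple[float, float]:
        """Strand-aware [TSS - upstream, TSS) window on the sense orientation."""
        if self.strand == "+":
            return (self.tss - upstream_bp, self.tss)
        return (self.tss, self.tss + upstream_bp)


@dataclass
class CoverageTrack:
    """Fixed-bin genome coverage with a library size.

    ``counts`` maps chromosome -> per-bin read counts; all chromosomes share
    ``bin_size``.  ``total_mapped_reads`` is the library depth used for RPKM.
    """

    counts: dict[str, np.ndarray]
    bin_size: int
    total_mapped_reads: float

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.total_mapped_reads <= 0:
            raise ValueError("total_mapped_reads must be positive")
        self.counts = {c: np.asarray(a, dtype=float) for c, a in self.counts.items()}
        for chrom, arr in self.counts.items():
            if np.any(arr < 0):
                raise ValueError(f"negative counts on {chrom}")

    @classmethod
    def from_arrays(cls, counts: Mapping[str, np.ndarray], bin_size: int,
                    total_mapped_reads: float | None = None) -> "CoverageTrack":
        total = total_mapped_reads
        if total is None:
            total = float(sum(np.sum(a) for a in counts.values()))
        return cls(dict(counts), bin_size, total)

    def chrom_length(self, chrom: str) -> int:
        return len(self.counts[chrom]) * self.bin_size

    def same_grid(self, other: "CoverageTrack") -> bool:
        if self.bin_size != other.bin_size:
            return False
        if set(self.counts) != set(other.counts):
            return False
        return all(
            self.counts[c].shape == other.counts[c].shape for c in self.counts
        )

    def window_count(self, chrom: str, start: float, end: float) -> tuple[float, bool]:
        """Reads overlapping [start, end), fractional at partial bins.

        Returns (count, clipped); ``clipped`` marks windows extending past the
        chromosome bounds, which are truncated.
        """
        if chrom not in self.counts:
            raise KeyError(f"unknown chromosome {chrom!r}")
        arr = self.counts[chrom]
        bs = self.bin_size
        length = len(arr) * bs
        clipped = start < 0 or end > length
        s, e = max(start, 0.0), min(end, float(length))
        if e <= s:
            return 0.0, clipped
        b0, b1 = int(s // bs), int(math.ceil(e / bs)) - 1
        if b0 == b1:
            return float(arr[b0] * (e - s) / bs), clipped
        total = arr[b0] * ((b0 + 1) * bs - s) / bs
        total += arr[b1] * (e - b1 * bs) / bs
        total += arr[b0 + 1 : b1].sum()
        return float(total), clipped


Interval = tuple[str, float, float]


def rpkm(track: CoverageTrack, interval: Interval) -> float:
    """Reads per kilobase per million mapped reads over an interval.

    RPKM = reads * 1e9 / (length_bp * total_mapped_reads).  Windows beyond the
    chromosome bounds are clipped with a warning and the clipped length is
    used, so the value stays a density.
    """
    chrom, start, end = interval
    if end <= start:
        raise ValueError(f"empty interval {interval}")
    count, clipped = track.window_count(chrom, start, end)
    eff_start, eff_end = max(start, 0.0), min(end, float(track.chrom_length(chrom)))
    if clipped:
        warnings.warn(
            f"interval {interval} clipped to ({chrom}, {eff_start}, {eff_end})",
            stacklevel=2,
        )
    length = eff_end - eff_start
    if length <= 0:
        return 0.0
    return count * 1e9 / (length * track.total_mapped_reads)


def normalized_density(
    chip: CoverageTrack,
    input_: CoverageTrack,
    interval: Interval,
    pseudocount: float = 0.5,
) -> float:
    """ChIP-over-input RPKM ratio, (RPKM_chip + pc) / (RPKM_input + pc).

    The pseudocount is applied on the RPKM scale, which keeps the ratio exactly
    invariant to library depth and finite on windows with no input signal.
    """
    if not chip.same_grid(input_):
        raise ValueError("ChIP and input tracks are on different bin grids")
    return (rpkm(chip, interval) + pseudocount) / (rpkm(input_, interval) + pseudocount)


@dataclass
class MetageneProfile:
    """Per-gene normalized densities on the scaled metagene axis."""

    gene_ids: list[str]
    positions: np.ndarray  # axis coordinate: upstream bp offsets, scaled body, downstream
    matrix: np.ndarray  # genes x positions
    n_upstream: int
    n_body: int
    n_downstream: int

    def summary(self, ci: float = 0.95) -> pd.DataFrame:
        """Per-position mean and symmetric t-interval across genes."""
        mean = self.matrix.mean(axis=0)
        n = self.matrix.shape[0]
        if n > 1:
            sem = self.matrix.std(axis=0, ddof=1) / math.sqrt(n)
            tcrit = scipy.stats.t.ppf(0.5 + ci / 2, n - 1)
        else:
            sem = np.zeros_like(mean)
            tcrit = 0.0
        return pd.DataFrame(
            {
                "position": self.positions,
                "mean": mean,
                "ci_low": mean - tcrit * sem,
                "ci_high": mean + tcrit * sem,
            }
        )


def _gene_bins(
    gene: GeneAnnotation,
    upstream_bp: int,
    downstream_bp: int,
    body_bins: int,
    flank_bin_bp: int,
) -> list[tuple[float, float]]:
    """Bin windows in genomic coordinates, ordered promoter -> terminator."""
    n_up = upstream_bp // flank_bin_bp
    n_down = downstream_bp // flank_bin_bp
    L = gene.length
    windows: list[tuple[float, float]] = []
    if gene.strand == "+":
        for i in range(n_up):
            s = gene.tss - upstream_bp + i * flank_bin_bp
            windows.append((s, s + flank_bin_bp))
        for i in range(body_bins):
            windows.append((gene.tss + i * L / body_bins, gene.tss + (i + 1) * L / body_bins))
        for i in range(n_down):
            s = gene.tes + i * flank_bin_bp
            windows.append((s, s + flank_bin_bp))
    else:
        for i in range(n_up):
            e = gene.tss + upstream_bp - i * flank_bin_bp
            windows.append((e - flank_bin_bp, e))
        for i in range(body_bins):
            windows.append((gene.tss - (i + 1) * L / body_bins, gene.tss - i * L / body_bins))
        for i in range(n_down):
            e = gene.tes - i * flank_bin_bp
            windows.append((e - flank_bin_bp, e))
    return windows


def _window_rpkm(track: CoverageTrack, chrom: str, win: tuple[float, float]) -> float:
    start, end = win
    count, _ = track.window_count(chrom, start, end)
    eff = min(end, float(track.chrom_length(chrom))) - max(start, 0.0)
    if eff <= 0:
        return 0.0
    return count * 1e9 / (eff * track.total_mapped_reads)


def metagene(
    tracks: Mapping[str, CoverageTrack],
    annotations: Sequence[GeneAnnotation],
    upstream_bp: int = 500,
    downstream_bp: int = 500,
    body_bins: int = 100,
    flank_bin_bp: int = 10,
    pseudocount: float = 0.5,
) -> MetageneProfile:
    """Strand-aware scaled metagene of target density over control density.

    ``tracks`` requires keys ``target`` and ``control``; optional
    ``target_input`` and ``control_input`` tracks convert each side to an
    RPKM-over-input normalized density before the target/control ratio is
    taken (without inputs the ratio is target RPKM over control RPKM).  Minus
    strand genes are flipped so the axis always runs promoter -> terminator.
    Genes shorter than ``body_bins`` bp are excluded with a warning.
    """
    if "target" not in tracks or "control" not in tracks:
        raise ValueError("tracks must contain 'target' and 'control'")
    if not annotations:
        raise ValueError("no gene annotations supplied")
    target, control = tracks["target"], tracks["control"]
    t_in = tracks.get("target_input")
    c_in = tracks.get("control_input")

    def density(win, chrom) -> float:
        num = _window_rpkm(target, chrom, win) + pseudocount
        den = _window_rpkm(control, chrom, win) + pseudocount
        if t_in is not None:
            num /= _window_rpkm(t_in, chrom, win) + pseudocount
        if c_in is not None:
            den /= _window_rpkm(c_in, chrom, win) + pseudocount
        return num / den

    kept: list[str] = []
    rows: list[np.ndarray] = []
    for gene in annotations:
        if gene.length < body_bins:
            warnings.warn(
                f"gene {gene.gene_id} shorter than one body bin; excluded",
                stacklevel=2,
            )
            continue
        wins = _gene_bins(gene, upstream_bp, downstream_bp, body_bins, flank_bin_bp)
        rows.append(np.array([density(w, gene.chrom) for w in wins]))
        kept.append(gene.gene_id)
    if not rows:
        raise ValueError("all genes were filtered out")

    n_up = upstream_bp // flank_bin_bp
    n_down = downstream_bp // flank_bin_bp
    # axis convention: upstream flank in [-1, 0) (bp / upstream_bp), scaled
    # body in [0, 1), downstream flank in [1, 2) (bp / downstream_bp past TES)
    positions = np.concatenate(
        [
            -1.0 + (np.arange(n_up) + 0.5) / n_up,
            (np.arange(body_bins) + 0.5) / body_bins,
            1.0 + (np.arange(n_down) + 0.5) / n_down,
        ]
    )
    return MetageneProfile(kept, positions, np.vstack(rows), n_up, body_bins, n_down)


@dataclass(frozen=True)
class WindowEnrichment:
    """Per-gene log2 target/control signal in the promoter window."""

    gene_id: str
    log2_ratio: float
    class_label: str | None = None
    clipped: bool = False


def promoter_enrichment(
    target: CoverageTrack,
    control: CoverageTrack,
    annotations: Sequence[GeneAnnotation],
    pseudocount: float = 0.5,
    upstream_bp: int = 500,
    mode: str = "counts",
) -> list[WindowEnrichment]:
    """log2(target / control) read counts in the [TSS-500, TSS) window.

    In ``counts`` mode (the default) raw window read counts are compared —
    the window length is constant so no length normalization is needed — with
    the control counts scaled to the target's library depth first.  ``rpkm``
    mode compares pseudocounted RPKM values instead.  Windows truncated at a
    chromosome boundary are flagged ``clipped``.
    """
    if not annotations:
        raise ValueError("no gene annotations supplied")
    if not target.same_grid(control):
        raise ValueError("target and control tracks are on different bin grids")
    if mode not in ("counts", "rpkm"):
        raise ValueError(f"unknown mode {mode!r}")
    depth_scale = target.total_mapped_reads / control.total_mapped_reads

    out: list[WindowEnrichment] = []
    for gene in annotations:
        start, end = gene.promoter_window(upstream_bp)
        tc, clip_t = target.window_count(gene.chrom, start, end)
        cc, clip_c = control.window_count(gene.chrom, start, end)
        if mode == "counts":
            ratio = (tc + pseudocount) / (cc * depth_scale + pseudocount)
        else:
            interval = (gene.chrom, start, end)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ratio = (rpkm(target, interval) + pseudocount) / (
                    rpkm(control, interval) + pseudocount
                )
        out.append(
            WindowEnrichment(
                gene_id=gene.gene_id,
                log2_ratio=math.log2(ratio),
                class_label=gene.class_label,
                clipped=clip_t or clip_c,
            )
        )
    return out


@dataclass(frozen=True)
class ClassComparison:
    """Welch two-sample t contrast of promoter enrichment between gene classes."""

    class_a: str
    class_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    difference: float
    t_statistic: float
    p_value: float
    ecdf_a: tuple[np.ndarray, np.ndarray] = field(repr=False, default=(None, None))
    ecdf_b: tuple[np.ndarray, np.ndarray] = field(repr=False, default=(None, None))


def _ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.sort(values)
    return x, np.arange(1, x.size + 1) / x.size


def class_compare(
    enrichments: Sequence[WindowEnrichment], class_a: str, class_b: str
) -> ClassComparison:
    """Welch t-test on per-gene log2 promoter ratios between two gene classes.

    Null hypothesis: mean promoter-window enrichment is equal in the two
    classes.  Also returns the empirical CDF coordinates of each class for
    cumulative-distribution plots.
    """
    a = np.array([e.log2_ratio for e in enrichments if e.class_label == class_a])
    b = np.array([e.log2_ratio for e in enrichments if e.class_label == class_b])
    for name, vals in ((class_a, a), (class_b, b)):
        if vals.size < 2:
            raise ValueError(f"class {name!r} has fewer than 2 genes")
    t_stat, p = scipy.stats.ttest_ind(a, b, equal_var=False)
    return ClassComparison(
        class_a=class_a,
        class_b=class_b,
        n_a=a.size,
        n_b=b.size,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        difference=float(a.mean() - b.mean()),
        t_statistic=float(t_stat),
        p_value=float(p),
        ecdf_a=_ecdf(a),
        ecdf_b=_ecdf(b),
    )
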