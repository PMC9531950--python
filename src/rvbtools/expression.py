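"""Reporter protein-synthesis rates, translatability, and ribosome occupancy.

Nanoluciferase (nLuc) plates measure protein synthesized within a short
window: each sample has a paired well treated with cycloheximide (CHX) a few
minutes earlier, whose luminescence captures pre-existing enzyme plus any
translation-independent background.  The synthesis rate is the OD-normalized
difference between the untreated and CHX wells.

*Translatability* is a translational-efficiency proxy on relative scales:
log2(protein fold vs control) minus log2(mRNA fold vs control).  Protein down
while mRNA is up therefore yields a negative translatability.

*Ribosome occupancy* is ribo-seq RPM over RNA-seq RPM in the region from
120 nt downstream of the AUG to the end of the ORF; the first 120 nt are
excluded because initiation-region footprints pile up there independently of
elongation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.stats
from statsmodels.stats.proportion import proportions_ztest

__all__ = [
    "LuciferaseRecord",
    "ProteinRate",
    "TranslatabilityResult",
    "RegionCounts",
    "FociComparison",
    "protein_rate",
    "translatability",
    "ribosome_occupancy",
    "positional_occupancy",
    "downstream_region_length",
    "foci_fraction",
    "compare_foci",
]

INITIATION_EXCLUSION_NT = 120  # AUG+120 (inclusive) to ORF end (exclusive)


@dataclass(frozen=True)
class LuciferaseRecord:
    """One plate well: luminescence plus culture density, CHX-paired."""

    strain: str
    condition: str
    chx: bool
    luminescence: float
    od660: float

    def __post_init__(self) -> None:
        if self.od660 <= 0:
            raise ValueError(f"od660 must be positive, got {self.od660}")
        if self.luminescence < 0:
            raise ValueError("luminescence must be >= 0")


@dataclass(frozen=True)
class ProteinRate:
    strain: str
    condition: str
    rate: float
    negative_rate: bool  # QC flag: CHX baseline exceeded the signal


def protein_rate(
    records: Sequence[LuciferaseRecord], strain: str, condition: str
) -> ProteinRate:
    """OD-normalized, CHX-subtracted protein synthesis rate.

    rate = lum_noCHX / OD_noCHX - lum_CHX / OD_CHX.  Multiple wells per arm
    are averaged after OD normalization.  A negative rate (baseline above
    signal) is reported with ``negative_rate=True`` rather than clamped:
    silent clamping would hide assay failure.
    """
    sel = [r for r in records if r.strain == strain and r.condition == condition]
    signal = [r.luminescence / r.od660 for r in sel if not r.chx]
    baseline = [r.luminescence / r.od660 for r in sel if r.chx]
    if not signal or not baseline:
        raise ValueError(
            f"missing CHX/non-CHX well pair for strain {strain!r}, "
            f"condition {condition!r}"
        )
    rate = float(np.mean(signal) - np.mean(baseline))
    return ProteinRate(strain, condition, rate, negative_rate=rate < 0)


@dataclass(frozen=True)
class TranslatabilityResult:
    protein_rel: float
    mrna_rel: float
    translatability_log2: float

    @property
    def fold(self) -> float:
        """Translational-efficiency fold, 2**translatability_log2."""
        return 2.0 ** self.translatability_log2


def translatability(protein_rel: float, mrna_rel: float) -> TranslatabilityResult:
    """Translational-efficiency change from relative protein and mRNA folds.

    translatability_log2 = log2(protein_rel) - log2(mrna_rel).  Both folds are
    relative to the same control condition and must be positive.
    """
    if protein_rel <= 0 or mrna_rel <= 0:
        raise ValueError("protein_rel and mrna_rel must be positive folds")
    return TranslatabilityResult(
        protein_rel=protein_rel,
        mrna_rel=mrna_rel,
        translatability_log2=math.log2(protein_rel) - math.log2(mrna_rel),
    )


def downstream_region_length(orf_length_nt: int) -> int:
    """Length of the occupancy region [AUG+120, ORF end) for an ORF."""
    region = orf_length_nt - INITIATION_EXCLUSION_NT
    if region <= 0:
        raise ValueError(
            f"ORF of {orf_length_nt} nt has no downstream region beyond "
            f"AUG+{INITIATION_EXCLUSION_NT}"
        )
    return region


@dataclass(frozen=True)
class RegionCounts:
    """Ribo-seq and RNA-seq reads in a gene's [AUG+120, ORF end) region."""

    gene_id: str
    ribo_reads: float
    rna_reads: float
    ribo_total: float
    rna_total: float
    region_length: int

    def __post_init__(self) -> None:
        if self.ribo_reads < 0 or self.rna_reads < 0:
            raise ValueError("read counts must be >= 0")
        if self.ribo_total <= 0 or self.rna_total <= 0:
            raise ValueError("library totals must be positive")
        if self.region_length <= 0:
            raise ValueError("region length must be positive")


def ribosome_occupancy(rc: RegionCounts) -> float:
    """Ribo-seq RPM over RNA-seq RPM in the downstream ORF region.

    occupancy = (ribo_reads / ribo_total) / (rna_reads / rna_total); the 1e6
    RPM factors cancel.  Zero mRNA reads make the ratio undefined and return
    NaN as a sentinel.
    """
    if rc.rna_reads == 0:
        return math.nan
    return (rc.ribo_reads / rc.ribo_total) / (rc.rna_reads / rc.rna_total)


def positional_occupancy(
    ribo_per_base: np.ndarray, rna_mean_per_base: float
) -> np.ndarray:
    """Per-base ribosome occupancy: footprint counts over mean mRNA density."""
    if rna_mean_per_base <= 0:
        raise ValueError("rna_mean_per_base must be positive")
    ribo = np.asarray(ribo_per_base, dtype=float)
    if np.any(ribo < 0):
        raise ValueError("ribosome counts must be >= 0")
    return ribo / rna_mean_per_base


def foci_fraction(n_foci: int, n_cells: int) -> float:
    """Fraction of scored cells containing an mRNA granule focus."""
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if not 0 <= n_foci <= n_cells:
        raise ValueError(f"n_foci must lie in [0, {n_cells}], got {n_foci}")
    return n_foci / n_cells


@dataclass(frozen=True)
class FociComparison:
    fraction_a: float
    fraction_b: float
    statistic: float
    p_value: float
    method: str


def compare_foci(
    a,
    b,
    method: str = "t",
    n_cells: int | None = None,
) -> FociComparison:
    """Two-group comparison of foci fractions.

    ``method='t'`` (default, as used on replicate imaging fields): ``a`` and
    ``b`` are sequences of replicate fractions compared by a two-sample
    t-test.  ``method='z'``: ``a`` and ``b`` are foci counts and ``n_cells``
    gives the cells scored per group (int or pair), compared by a
    two-proportion z-test.
    """
    if method == "t":
        a, b = np.asarray(a, float), np.asarray(b, float)
        if a.size < 2 or b.size < 2:
            raise ValueError("t-test mode requires >= 2 replicate fractions per group")
        stat, p = scipy.stats.ttest_ind(a, b, equal_var=False)
        return FociComparison(float(a.mean()), float(b.mean()), float(stat), float(p), "t")
    if method == "z":
        if n_cells is None:
            raise ValueError("z mode requires n_cells")
        n = (n_cells, n_cells) if np.isscalar(n_cells) else tuple(n_cells)
        fa, fb = foci_fraction(a, n[0]), foci_fraction(b, n[1])
        if a == b == 0 or (a == n[0] and b == n[1]):
            # degenerate pooled proportion: no evidence of a difference
            return FociComparison(fa, fb, 0.0, 1.0, "z")
        stat, p = proportions_ztest([a, b], list(n))
        return FociComparison(fa, fb, float(stat), float(p), "z")
    raise ValueError(f"unknown method {method!r}")
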