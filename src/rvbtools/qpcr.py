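"""ΔΔCt fold changes and the RIP-enrichment normalization cascade.

A qPCR cycle threshold (Ct) is inversely log2-linear in template abundance,
so with perfect doubling per cycle a fold change between samples is
``2**(-ΔΔCt)`` where ``ΔCt = Ct_target - Ct_reference`` normalizes each sample
to a reference transcript (ACT1 by convention) and ``ΔΔCt`` contrasts a test
sample against a calibrator.  RIP enrichments extend this to a three-stage
cascade: reference gene -> input fraction -> wild-type (untagged) IP control.

Replicates are averaged on the Ct scale before differencing; standard errors
are propagated on the log2 scale from replicate variances (one Ct cycle is
one log2 unit).  Amplification efficiency is fixed at 2; efficiency
correction is out of scope.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .kinetics import TimeCourse

__all__ = [
    "CtTable",
    "FoldChange",
    "EnrichmentResult",
    "delta_delta_ct",
    "rip_enrichment",
    "induction_series",
]

_COLUMNS = ["sample", "fraction", "strain", "target", "replicate", "ct"]


@dataclass
class CtTable:
    """Structured qPCR cycle-threshold records.

    Wraps a long-format DataFrame with columns sample, fraction (IP | input |
    total), strain, target, replicate, ct.  Ct values must lie in (0, 45).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col, default in (("fraction", "total"), ("strain", "")):
            if col not in df.columns:
                df[col] = default
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"CtTable missing columns: {missing}")
        df["ct"] = df["ct"].astype(float)
        if ((df["ct"] <= 0) | (df["ct"] >= 45)).any():
            bad = df.loc[(df["ct"] <= 0) | (df["ct"] >= 45)].iloc[0]
            raise ValueError(
                f"Ct out of range (0, 45): {bad['ct']} for sample "
                f"{bad['sample']!r}, target {bad['target']!r}"
            )
        self.data = df[_COLUMNS].reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path, exclude: Iterable[tuple] | None = None) -> "CtTable":
        """Read a TSV; ``exclude`` lists (sample, target, replicate) records
        flagged during QC (e.g. wells with high technical variation)."""
        df = pd.read_csv(path, sep="\t")
        table = cls(df)
        if exclude:
            return table.exclude(exclude)
        return table

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    def exclude(self, records: Iterable[tuple]) -> "CtTable":
        """Drop explicit (sample, target, replicate) records; no automatic
        outlier removal is performed."""
        df = self.data
        keys = set(records)
        mask = ~df.apply(
            lambda r: (r["sample"], r["target"], r["replicate"]) in keys, axis=1
        )
        return CtTable(df[mask])

    def _cts(self, **criteria) -> np.ndarray:
        df = self.data
        for col, val in criteria.items():
            df = df[df[col] == val]
        if df.empty:
            desc = ", ".join(f"{k}={v!r}" for k, v in criteria.items())
            raise KeyError(f"no Ct records for {desc}")
        return df["ct"].to_numpy()

    def mean_ct(self, **criteria) -> tuple[float, float, int]:
        """Replicate-mean Ct, its variance-of-the-mean, and n."""
        cts = self._cts(**criteria)
        n = cts.size
        var = float(cts.var(ddof=1) / n) if n > 1 else 0.0
        return float(cts.mean()), var, n


@dataclass(frozen=True)
class FoldChange:
    target: str
    test_sample: str
    calibrator_sample: str
    fold: float
    log2_fold: float
    se_log2: float
    ddct: float


@dataclass(frozen=True)
class EnrichmentResult:
    target: str
    strain: str
    enrichment: float
    log2_enrichment: float
    se_log2: float
    wt_normalized: bool = True


def _delta_ct(table: CtTable, target: str, reference_gene: str, **criteria):
    m_t, v_t, _ = table.mean_ct(target=target, **criteria)
    m_r, v_r, _ = table.mean_ct(target=reference_gene, **criteria)
    return m_t - m_r, v_t + v_r


def delta_delta_ct(
    table: CtTable,
    target: str,
    reference_gene: str,
    test_sample: str,
    calibrator_sample: str,
) -> FoldChange:
    """Standard ΔΔCt fold change of ``target`` in test vs calibrator sample.

    fold = 2**(-ΔΔCt) with ΔCt = Ct_target - Ct_reference per sample.  Missing
    (sample, gene) combinations raise a KeyError naming the combination.
    """
    d_test, v_test = _delta_ct(table, target, reference_gene, sample=test_sample)
    d_cal, v_cal = _delta_ct(table, target, reference_gene, sample=calibrator_sample)
    ddct = d_test - d_cal
    return FoldChange(
        target=target,
        test_sample=test_sample,
        calibrator_sample=calibrator_sample,
        fold=2.0 ** (-ddct),
        log2_fold=-ddct,
        se_log2=math.sqrt(v_test + v_cal),
        ddct=ddct,
    )


def rip_enrichment(
    table: CtTable,
    target: str,
    reference_gene: str,
    ip_strain: str,
    wt_strain: str | None = None,
    input_fraction: float = 1.0,
) -> EnrichmentResult:
    """Three-stage RIP enrichment of ``target`` in a tagged strain.

    Stage 1 normalizes each (strain, fraction) to the reference gene; stage 2
    contrasts IP against input within a strain; stage 3 divides the tagged
    strain's IP/input ratio by the untagged wild-type control's.  If the
    wild-type records are absent (``wt_strain=None`` or missing) the result
    falls back to the two-stage IP/input ratio with ``wt_normalized=False`` —
    never silently.

    ``input_fraction`` corrects stage 2 for input dilution (e.g. 0.01 for a 1%
    input); the correction is a constant log2 offset that cancels in stage 3.
    """
    def two_stage(strain: str):
        d_ip, v_ip = _delta_ct(table, target, reference_gene, strain=strain, fraction="IP")
        d_in, v_in = _delta_ct(table, target, reference_gene, strain=strain, fraction="input")
        # ratio of target recovery in IP over input, corrected for dilution
        log2_ratio = -(d_ip - d_in) + math.log2(input_fraction)
        return log2_ratio, v_ip + v_in

    log2_ip, var_ip = two_stage(ip_strain)

    if wt_strain is not None:
        try:
            log2_wt, var_wt = two_stage(wt_strain)
        except KeyError:
            log2_wt, var_wt = None, None
    else:
        log2_wt, var_wt = None, None

    if log2_wt is None:
        return EnrichmentResult(
            target=target,
            strain=ip_strain,
            enrichment=2.0 ** log2_ip,
            log2_enrichment=log2_ip,
            se_log2=math.sqrt(var_ip),
            wt_normalized=False,
        )
    log2_enr = log2_ip - log2_wt
    return EnrichmentResult(
        target=target,
        strain=ip_strain,
        enrichment=2.0 ** log2_enr,
        log2_enrichment=log2_enr,
        se_log2=math.sqrt(var_ip + var_wt),
        wt_normalized=True,
    )


_TIME_RE = re.compile(r"(\d+(?:\.\d+)?)\s*(?:min)?\s*$")


def parse_time_label(sample: str) -> float:
    """Extract a time in minutes from a sample label like 't15' or '30min'."""
    m = _TIME_RE.search(str(sample))
    if not m:
        raise ValueError(f"cannot parse a time (minutes) from sample label {sample!r}")
    return float(m.group(1))


def induction_series(
    table: CtTable,
    target: str,
    reference_gene: str,
    timepoint_samples: Mapping[str, float] | Iterable[str],
    baseline_sample: str,
    condition: str | None = None,
) -> TimeCourse:
    """Fold-induction time course over a pre-stress baseline.

    ``timepoint_samples`` maps sample labels to times in minutes (or is an
    iterable of labels with parseable time suffixes).  Per-replicate ΔCt at
    each time point is contrasted against the baseline's replicate-mean ΔCt,
    preserving replicate spread in the returned course
    (scale = ``fold_over_t0``, ready for :func:`rvbtools.kinetics.fit_induction`).
    Row order in the table is irrelevant.
    """
    if isinstance(timepoint_samples, Mapping):
        sample_times = dict(timepoint_samples)
    else:
        sample_times = {s: parse_time_label(s) for s in timepoint_samples}
    if baseline_sample not in sample_times:
        sample_times[baseline_sample] = 0.0

    d_base, _ = _delta_ct(table, target, reference_gene, sample=baseline_sample)

    def replicate_folds(sample: str) -> np.ndarray:
        df = table.data
        sub_t = df[(df["sample"] == sample) & (df["target"] == target)]
        sub_r = df[(df["sample"] == sample) & (df["target"] == reference_gene)]
        if sub_t.empty or sub_r.empty:
            raise KeyError(
                f"missing Ct records for sample {sample!r} "
                f"(target {target!r} or reference {reference_gene!r})"
            )
        # replicate-mean within each replicate index guards duplicate rows
        t = sub_t.groupby("replicate")["ct"].mean()
        r = sub_r.groupby("replicate")["ct"].mean()
        common = t.index.intersection(r.index)
        if common.empty:
            raise KeyError(f"no paired replicates for sample {sample!r}")
        dct = (t[common] - r[common]).to_numpy()
        return 2.0 ** (-(dct - d_base))

    order = sorted(sample_times, key=lambda s: sample_times[s])
    times = np.array([sample_times[s] for s in order])
    folds = [replicate_folds(s) for s in order]
    n_rep = min(len(f) for f in folds)
    values = np.vstack([f[:n_rep] for f in folds])
    return TimeCourse(
        condition or f"{target} induction", times, values, "fold_over_t0"
    )
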