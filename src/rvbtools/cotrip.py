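"""CoTrIP proteomics enrichment screen: fold changes, volcano, candidates.

CoTrIP (co-transcriptional immunoprecipitation) purifies a LacO-array plasmid
carrying a promoter of interest and identifies co-purifying proteins by mass
spectrometry.  Promoter specificity is assessed by contrasting spectral
counts between plasmid groups (e.g. a GLC3-promoter group against an
HSP-promoter group, 2 vs 3 replicates) with a per-protein Welch t-test on
raw counts and a pseudocounted log2 fold change.  Candidates are the
proteins at p < 0.05, ranked by fold change; no multiple-testing correction
is applied (the screen is a ranking device, not an inference — treat the
p-values accordingly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "SpectralTable",
    "enrichment_volcano",
    "candidates",
    "background_filter",
]

_COLUMNS = ["protein", "sample", "group", "count"]


@dataclass
class SpectralTable:
    """Long-format spectral counts: protein, sample, group, count (>= 0)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"SpectralTable missing columns: {missing}")
        df = self.data[_COLUMNS].copy()
        df["count"] = df["count"].astype(float)
        if (df["count"] < 0).any():
            raise ValueError("spectral counts must be >= 0")
        dup = df.groupby(["sample"])["group"].nunique()
        if (dup > 1).any():
            raise ValueError("each sample must belong to exactly one group")
        self.data = df.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path) -> "SpectralTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    def group_counts(self, protein: str, group: str) -> np.ndarray:
        df = self.data
        samples = df.loc[df["group"] == group, "sample"].unique()
        sub = df[(df["protein"] == protein) & (df["group"] == group)]
        counts = sub.set_index("sample")["count"]
        # proteins not detected in a sample carry an implicit zero count
        return np.array([float(counts.get(s, 0.0)) for s in samples])


def enrichment_volcano(
    table: SpectralTable,
    group_a: str,
    group_b: str,
    pseudocount: float = 0.5,
    log: bool = False,
) -> pd.DataFrame:
    """Per-protein fold change and Welch t between two promoter groups.

    Returns a DataFrame indexed by protein with columns ``log2_fc``
    (= log2((mean_a + pc) / (mean_b + pc))), ``p_value``, ``neg_log10_p``,
    ``mean_a``, ``mean_b`` and QC flags.  The t-test runs on raw counts by
    default (``log=True`` tests log2(count + pc) instead).  A contrast with
    zero variance in both groups has an undefined t: p is set to 1 when the
    means are equal, otherwise NaN with ``qc_flag``.
    """
    groups = set(table.data["group"])
    for g in (group_a, group_b):
        if g not in groups:
            raise ValueError(f"group {g!r} not present in table")
    n_a = table.data.loc[table.data["group"] == group_a, "sample"].nunique()
    n_b = table.data.loc[table.data["group"] == group_b, "sample"].nunique()
    if max(n_a, n_b) < 2:
        raise ValueError("at least one group needs >= 2 replicates")

    rows = []
    for protein in sorted(table.data["protein"].unique()):
        a = table.group_counts(protein, group_a)
        b = table.group_counts(protein, group_b)
        mean_a, mean_b = float(a.mean()), float(b.mean())
        log2_fc = math.log2((mean_a + pseudocount) / (mean_b + pseudocount))
        xa, xb = (np.log2(a + pseudocount), np.log2(b + pseudocount)) if log else (a, b)
        qc = False
        if xa.var(ddof=0) == 0 and xb.var(ddof=0) == 0:
            if xa.mean() == xb.mean():
                p = 1.0
            else:
                p, qc = math.nan, True
        else:
            _, p = scipy.stats.ttest_ind(xa, xb, equal_var=False)
            p = float(p)
        rows.append(
            {
                "protein": protein,
                "log2_fc": log2_fc,
                "p_value": p,
                "neg_log10_p": -math.log10(p) if p > 0 else math.inf,
                "mean_a": mean_a,
                "mean_b": mean_b,
                "zero_in_b": mean_b == 0,
                "qc_flag": qc,
            }
        )
    return pd.DataFrame(rows).set_index("protein")


def candidates(results: pd.DataFrame, p_threshold: float = 0.05) -> pd.DataFrame:
    """Proteins below the p threshold, ranked by fold change descending.

    Ties are broken by protein id ascending, so the list is a deterministic
    function of the input table.
    """
    hits = results[results["p_value"] < p_threshold].copy()
    hits = hits.sort_values(
        ["log2_fc", "protein"], ascending=[False, True], kind="mergesort"
    )
    return hits


def background_filter(
    results: pd.DataFrame,
    background: Mapping[str, float] | pd.Series,
    min_fc: float = 2.0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Retain candidates enriched over a background (contaminant) table.

    ``background`` maps protein -> mean background count (e.g. a user-supplied
    contaminant-repository summary).  A candidate is kept when
    (mean_a + pc) / (background + pc) >= min_fc; proteins absent from the
    background are retained with ``background_missing=True`` rather than
    dropped.
    """
    bg = pd.Series(dict(background), dtype=float) if not isinstance(background, pd.Series) else background
    out = results.copy()
    bg_counts = out.index.to_series().map(bg)
    out["background_missing"] = bg_counts.isna()
    fold = (out["mean_a"] + pseudocount) / (bg_counts.fillna(0.0) + pseudocount)
    out["background_fold"] = fold.where(~out["background_missing"], math.nan)
    keep = out["background_missing"] | (fold >= min_fc)
    return out[keep]
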