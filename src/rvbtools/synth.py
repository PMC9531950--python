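"""Seeded generators for every input the analysis pipeline consumes.

Each generator emulates the statistical structure the corresponding assay is
assumed to have:

* time courses — the closed-form kinetic trajectory times multiplicative
  lognormal noise (qPCR-style error);
* Ct tables — Ct = c0 - log2(abundance) + Gaussian cycle noise, with the
  reference gene held at constant abundance;
* genome coverage — Poisson per-bin background with elevated means in the
  [TSS-500, TSS) window of one gene class on the target track only;
* luciferase plates — CHX-resistant background plus rate, gain- and
  OD-scaled;
* counts — Poisson region counts and negative-binomial spectral counts.

One global seed expands into fixed per-generator substreams, so adding a
generator never perturbs the output of the others, and ``noise_cv = 0``
switches every generator to its exact noiseless expectation (the pipeline's
round-trip test mode).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .chip import CoverageTrack, GeneAnnotation
from .expression import LuciferaseRecord, RegionCounts
from .kinetics import InductionModel, TimeCourse, induction_solution
from .qpcr import CtTable
from .cotrip import SpectralTable

__all__ = [
    "GenomeSpec",
    "GeneratorConfig",
    "gen_timecourse",
    "gen_ct_table",
    "gen_genome_coverage",
    "gen_luciferase",
    "gen_region_counts",
    "gen_spectral_table",
]

# fixed substream keys: appending new generators must not renumber these
_STREAMS = {
    "timecourse": 1,
    "ct": 2,
    "genome": 3,
    "luciferase": 4,
    "counts": 5,
    "spectra": 6,
}


@dataclass(frozen=True)
class GenomeSpec:
    """Shape of the synthetic genome used for coverage tracks."""

    n_chroms: int = 2
    n_genes: int = 60
    gene_length: tuple[int, int] = (500, 3000)
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"class_I": 0.3, "class_II": 0.3, "other": 0.4}
    )
    chrom_length: int = 300_000

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ValueError(f"class proportions must sum to 1, got {total}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Global knobs shared by all generators; the seed fixes outputs exactly."""

    seed: int = 0
    noise_cv: float = 0.05
    n_replicates: int = 4
    time_grid: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 30.0, 45.0)
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    depth: int = 1_000_000
    bin_size: int = 10
    ct_baseline: float = 30.0  # Ct of unit abundance
    ct_sigma: float = 0.0  # Gaussian cycle noise; defaults off (noise_cv rules)

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def noiseless(self) -> bool:
        return self.noise_cv == 0

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([_STREAMS[stream], self.seed])

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "genome" in raw:
            g = raw["genome"]
            if "gene_length" in g:
                g["gene_length"] = tuple(g["gene_length"])
            raw["genome"] = GenomeSpec(**g)
        if "time_grid" in raw:
            raw["time_grid"] = tuple(raw["time_grid"])
        return cls(**raw)


def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log(1.0 + cv * cv))


def gen_timecourse(
    cfg: GeneratorConfig,
    model: InductionModel,
    mode: str = "induction",
    scale: str | None = None,
) -> TimeCourse:
    """Replicated kinetic time course with multiplicative lognormal noise.

    ``mode`` is ``induction`` or ``decay``.  For induction the default output
    scale is ``fold_over_t0`` (requires x0 > 0); pass ``scale='absolute'`` for
    raw trajectories.  Noise is median-one lognormal, exp(N(0, sigma)) with
    sigma set from ``noise_cv``, so log-scale fits are unbiased and
    ``noise_cv = 0`` reproduces the closed form exactly.
    """
    times = np.asarray(cfg.time_grid, dtype=float)
    if times.size == 0:
        raise ValueError("empty time grid")
    if mode == "induction":
        truth = induction_solution(model, times)
        if scale is None:
            scale = "fold_over_t0"
        if scale == "fold_over_t0":
            if model.x0 <= 0:
                raise ValueError("fold scale requires x0 > 0")
            truth = truth / model.x0
    elif mode == "decay":
        if model.x0 <= 0:
            raise ValueError("decay mode requires x0 > 0")
        truth = model.x0 * np.exp(-model.alpha * times)
        scale = scale or "absolute"
    else:
        raise ValueError(f"unknown mode {mode!r}")

    values = np.repeat(truth[:, None], cfg.n_replicates, axis=1)
    if not cfg.noiseless:
        rng = cfg.rng("timecourse")
        sigma = _lognormal_sigma(cfg.noise_cv)
        values = values * np.exp(rng.normal(0.0, sigma, size=values.shape))
    return TimeCourse(f"synthetic {mode}", times, values, scale)


def gen_ct_table(
    cfg: GeneratorConfig,
    abundances: pd.DataFrame,
    reference_gene: str = "ACT1",
    reference_abundance: float = 1.0,
) -> CtTable:
    """Ct records from true abundances: Ct = c0 - log2(abundance) + noise.

    ``abundances`` is long-format with columns sample, target, abundance and
    optional fraction / strain metadata.  A reference-gene record at constant
    abundance is appended for every (sample, fraction, strain) present, so
    every downstream normalization can find its internal control.  Cycle
    noise is N(0, ct_sigma), or max(ct_sigma, noise_cv in log2 units) when
    multiplicative noise is on.
    """
    df = abundances.copy()
    if (df["abundance"] <= 0).any():
        bad = df[df["abundance"] <= 0].iloc[0]
        raise ValueError(
            f"nonpositive abundance for sample {bad['sample']!r}, "
            f"target {bad['target']!r}"
        )
    for col, default in (("fraction", "total"), ("strain", "")):
        if col not in df.columns:
            df[col] = default

    meta = df[["sample", "fraction", "strain"]].drop_duplicates()
    ref = meta.assign(target=reference_gene, abundance=reference_abundance)
    df = pd.concat([df, ref], ignore_index=True)

    sigma = cfg.ct_sigma
    if not cfg.noiseless:
        sigma = max(sigma, _lognormal_sigma(cfg.noise_cv) / math.log(2.0))
    rng = cfg.rng("ct")

    rows = []
    for _, r in df.iterrows():
        true_ct = cfg.ct_baseline - math.log2(r["abundance"])
        for rep in range(1, cfg.n_replicates + 1):
            ct = true_ct + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
            rows.append(
                {
                    "sample": r["sample"],
                    "fraction": r["fraction"],
                    "strain": r["strain"],
                    "target": r["target"],
                    "replicate": rep,
                    "ct": ct,
                }
            )
    return CtTable(pd.DataFrame(rows))


def _place_genes(
    rng: np.random.Generator, spec: GenomeSpec, margin: int = 600, max_tries: int = 200
) -> list[GeneAnnotation]:
    """Random non-overlapping gene placement with promoter clearance."""
    labels = list(spec.class_proportions)
    probs = np.array([spec.class_proportions[k] for k in labels])
    genes: list[GeneAnnotation] = []
    per_chrom = np.array_split(np.arange(spec.n_genes), spec.n_chroms)
    for ci, idx in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        occupied: list[tuple[int, int]] = []
        for gi in idx:
            length = int(rng.integers(spec.gene_length[0], spec.gene_length[1] + 1))
            for attempt in range(max_tries):
                start = int(rng.integers(margin, spec.chrom_length - length - margin))
                span = (start - margin, start + length + margin)
                if all(span[1] <= s or span[0] >= e for s, e in occupied):
                    occupied.append(span)
                    break
            else:
                raise RuntimeError(
                    "could not place non-overlapping genes; genome too dense"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            label = labels[int(rng.choice(len(labels), p=probs))]
            genes.append(
                GeneAnnotation(f"gene{gi + 1:04d}", chrom, start, start + length, strand, label)
            )
    return genes


def gen_genome_coverage(
    cfg: GeneratorConfig,
    class_enrichment: Mapping[str, float],
    promoter_bp: int = 500,
) -> tuple[list[GeneAnnotation], dict[str, CoverageTrack]]:
    """Synthetic genome, target/control/input coverage with promoter signal.

    Background coverage is Poisson per bin with a mean set by ``cfg.depth``;
    on the *target* track only, bins in the strand-aware [TSS-500, TSS)
    window of each gene class are multiplied by ``class_enrichment[class]``.
    Control and input tracks are background-only.  Returns the annotations
    and ``{"target", "control", "input"}`` tracks whose
    ``total_mapped_reads`` are the realized sums.
    """
    for label, fold in class_enrichment.items():
        if fold <= 0:
            raise ValueError(f"enrichment fold for {label!r} must be > 0")
    rng = cfg.rng("genome")
    spec = cfg.genome
    genes = _place_genes(rng, spec)

    n_bins = spec.chrom_length // cfg.bin_size
    total_bins = n_bins * spec.n_chroms
    lam = cfg.depth / total_bins

    mean_target = {f"chr{i + 1}": np.full(n_bins, lam) for i in range(spec.n_chroms)}
    for gene in genes:
        fold = class_enrichment.get(gene.class_label, 1.0)
        if fold == 1.0:
            continue
        start, end = gene.promoter_window(promoter_bp)
        b0 = max(int(start) // cfg.bin_size, 0)
        b1 = min(int(math.ceil(end / cfg.bin_size)), n_bins)
        mean_target[gene.chrom][b0:b1] *= fold

    def draw(means: dict[str, np.ndarray]) -> CoverageTrack:
        if cfg.noiseless:
            counts = {c: m.copy() for c, m in means.items()}
        else:
            counts = {c: rng.poisson(m).astype(float) for c, m in means.items()}
        return CoverageTrack.from_arrays(counts, cfg.bin_size)

    background = {f"chr{i + 1}": np.full(n_bins, lam) for i in range(spec.n_chroms)}
    tracks = {
        "target": draw(mean_target),
        "control": draw(background),
        "input": draw(background),
    }
    return genes, tracks


def gen_luciferase(
    cfg: GeneratorConfig,
    true_rates: Mapping[tuple[str, str], float],
    background_rate: float = 100.0,
    od660: float = 0.4,
    gain: float = 1.0,
) -> list[LuciferaseRecord]:
    """CHX-paired plate wells for each (strain, condition) true rate.

    lum_noCHX = (rate + background) * OD * gain * noise and
    lum_CHX = background * OD * gain * noise, with one replicate pair per
    ``cfg.n_replicates``.  Noiseless mode recovers every rate exactly through
    :func:`rvbtools.expression.protein_rate` (up to the gain factor).
    """
    if background_rate < 0 or any(r < 0 for r in true_rates.values()):
        raise ValueError("rates must be >= 0")
    rng = cfg.rng("luciferase")
    sigma = _lognormal_sigma(cfg.noise_cv)
    records = []
    for (strain, condition), rate in true_rates.items():
        for _ in range(cfg.n_replicates):
            for chx, level in ((False, rate + background_rate), (True, background_rate)):
                lum = level * od660 * gain
                if not cfg.noiseless:
                    lum *= math.exp(rng.normal(0.0, sigma))
                records.append(
                    LuciferaseRecord(strain, condition, chx, lum, od660)
                )
    return records


def gen_region_counts(
    cfg: GeneratorConfig,
    true_occupancy: Mapping[str, float],
    rna_mean_reads: float = 500.0,
    region_length: int = 600,
    ribo_total: float = 1e6,
    rna_total: float = 1e6,
) -> list[RegionCounts]:
    """Per-gene ribo/RNA region counts with Poisson sampling around truths.

    Expected RNA reads are ``rna_mean_reads`` per gene; expected ribo reads
    are chosen so the RPM ratio equals ``true_occupancy[gene]``.  Noiseless
    mode returns the expectations, making occupancy recovery exact.
    """
    rng = cfg.rng("counts")
    out = []
    for gene, occ in true_occupancy.items():
        if occ < 0:
            raise ValueError(f"occupancy for {gene!r} must be >= 0")
        mu_rna = rna_mean_reads
        mu_ribo = occ * mu_rna * ribo_total / rna_total
        if cfg.noiseless:
            ribo, rna = mu_ribo, mu_rna
        else:
            ribo = float(rng.poisson(mu_ribo))
            rna = float(rng.poisson(mu_rna))
        out.append(
            RegionCounts(gene, ribo, rna, ribo_total, rna_total, region_length)
        )
    return out


def gen_spectral_table(
    cfg: GeneratorConfig,
    true_means: pd.DataFrame,
    replicates_per_group: Mapping[str, int] | None = None,
    dispersion: float = 0.1,
) -> SpectralTable:
    """Negative-binomial spectral counts around per-(protein, group) means.

    ``true_means`` is indexed by protein with one column per group.
    ``dispersion`` is the NB overdispersion (variance = mu + dispersion*mu^2);
    0 reduces to Poisson.  Noiseless mode emits the means themselves.
    """
    rng = cfg.rng("spectra")
    reps = replicates_per_group or {}
    rows = []
    for group in true_means.columns:
        n_rep = reps.get(group, cfg.n_replicates)
        for rep in range(1, n_rep + 1):
            sample = f"{group}_rep{rep}"
            for protein, mu in true_means[group].items():
                if mu < 0:
                    raise ValueError("true means must be >= 0")
                if cfg.noiseless:
                    count = float(mu)
                elif mu == 0:
                    count = 0.0
                elif dispersion > 0:
                    # NB via gamma-Poisson mixture
                    shape = 1.0 / dispersion
                    lam = rng.gamma(shape, mu / shape)
                    count = float(rng.poisson(lam))
                else:
                    count = float(rng.poisson(mu))
                rows.append(
                    {"protein": protein, "sample": sample, "group": group, "count": count}
                )
    return SpectralTable(pd.DataFrame(rows))
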