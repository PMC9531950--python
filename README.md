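# rvbtools

Quantitative analysis of transcription–translation coupling during glucose
starvation in budding yeast.

When yeast cells lose glucose, a set of alternative-glucose-metabolism genes
(class II, e.g. *GSY1*, *GLC3*) is transcriptionally induced yet
translationally repressed, with their mRNAs sequestered in cytoplasmic
granules, while heat-shock genes (class I, e.g. *HSP30*) are induced and well
translated. Dissecting that coupling requires a chain of quantitative
analyses — promoter-proteomics screens, ChIP enrichment by gene class,
RIP-qPCR normalization cascades, reporter translation assays, ribosome
occupancy, and kinetic modeling of mRNA induction — and this package
implements that chain as a tested, reusable Python library for researchers
analyzing their own starvation-response or reporter-tethering data.

## What it computes

* **kinetics** — the induction ODE dX/dt = β − αX with closed form
  X(t) = X0 + (β/α − X0)(1 − e^{−αt}); log2-scale fits of fold induction
  F(t) = 1 + (Fss − 1)(1 − e^{−αt}); half-life T½ = ln 2/α from decay chases
  (half_life = −1/slope of log2 abundance vs time); an interaction-model
  contrast of decay rates; and a classifier that decides whether a treatment
  shifted the transcription rate (constant log2 offset between induction
  curves) or the decay rate (time-dependent offset).
* **qpcr** — standard ΔΔCt fold changes (fold = 2^(−ΔΔCt), ACT1 reference)
  and the three-stage RIP enrichment: reference gene → input fraction →
  wild-type IP control.
* **chip** — RPKM, ChIP/input normalized density, strand-aware scaled
  metagene profiles (−500→TSS | TSS→TES | TES→+500), promoter-window log2
  enrichment vs a control IP, and Welch t contrasts between gene classes
  with empirical CDFs.
* **expression** — cycloheximide-subtracted, OD-normalized nanoluciferase
  synthesis rates; translatability = log2(protein fold) − log2(mRNA fold);
  ribosome occupancy = ribo-seq RPM / RNA-seq RPM in [AUG+120, ORF end);
  per-base occupancy profiles; granule-foci fraction comparisons.
* **cotrip** — the promoter-proteomics enrichment screen: per-protein fold
  change, Welch t volcano coordinates, deterministic candidate ranking, and
  an optional contaminant-background filter.
* **synth** — seeded generators for every input above (time courses, Ct
  tables, genome coverage, plates, counts) whose noiseless mode round-trips
  exactly through the analyses.

Installation (the package is pure Python; numpy/scipy/pandas/statsmodels/
pyyaml are the only runtime dependencies):

```
pip install --no-build-isolation -e .
python -m pytest -q          # full test suite
```

## Worked example

```python
import math, numpy as np, rvbtools as rt

# a stress-induced reporter: 25-min half-life, strong induction
alpha = math.log(2) / 25
base = rt.InductionModel(alpha=alpha, beta=alpha * 200, x0=1.0)

# noisy fold-induction course, 4 replicates at 0,5,10,15,30,45 min
cfg = rt.GeneratorConfig(seed=1, noise_cv=0.05, n_replicates=4)
ctrl = rt.gen_timecourse(cfg, base, "induction")

# treated condition: transcription rate x4, same stability
trt = rt.gen_timecourse(
    rt.GeneratorConfig(seed=2, noise_cv=0.05, n_replicates=4),
    rt.InductionModel(alpha, base.beta * 4, 1.0), "induction")
print(rt.classify_mechanism(ctrl, trt))

# half-life from a transcription-shutoff chase
chase = rt.simulate_decay(rt.InductionModel(alpha, 0, 1.0), np.arange(0, 50, 5))
print(rt.fit_decay(chase).half_life)

# translational efficiency when protein falls 40% but mRNA doubles
print(rt.translatability(0.6, 2.0).translatability_log2)
```

prints

```
MechanismCall(call='transcription_shift', mean_shift_log2=1.9761015337671075, shift_trend_slope=-0.0008427583654660306, trend_p=0.20371227383311508, n_points=5)
25.0
-1.736965594166206
```

The classifier sees a constant ≈2 log2 offset with no significant time trend,
the signature of a 4-fold transcription-rate increase at unchanged mRNA
stability; the chase recovers the 25-minute half-life; and a reporter whose
protein output drops 40% while its mRNA doubles has lost more than 3-fold in
translational efficiency (−1.74 log2) — translation repressed even though the
message is more abundant.

The `examples/` directory has one short narrative script per capability
(kinetics, qPCR/RIP, ChIP metagene, expression/occupancy, CoTrIP screen);
each builds a small synthetic input, runs the analysis, and explains the
numbers it prints.

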