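"""Reporter protein-synthesis rate, translatability, ribosome occupancy.

Reproduces the arithmetic of the reporter analyses: CHX-subtracted
OD-normalized luciferase rates, the translatability (TE) computation from
relative protein and mRNA levels, and region-count ribosome occupancy.
"""

import rvbtools as rt

# CHX-paired plate wells, noiseless: rate recovered exactly
cfg = rt.GeneratorConfig(seed=5, noise_cv=0.0, n_replicates=3)
recs = rt.gen_luciferase(cfg, {("RVB2-CP", "starved"): 1200.0,
                               ("no-CP", "starved"): 2000.0},
                         background_rate=300.0)
r_teth = rt.protein_rate(recs, "RVB2-CP", "starved")
r_ctrl = rt.protein_rate(recs, "no-CP", "starved")
print(f"protein synthesis: tethered {r_teth.rate:.0f} vs control {r_ctrl.rate:.0f} "
      f"(ratio {r_teth.rate / r_ctrl.rate:.2f} -- a 40% reduction)")

# translatability from relative protein and mRNA
res = rt.translatability(protein_rel=0.6, mrna_rel=2.0)
print(f"translatability = {res.translatability_log2:.2f} log2 "
      f"({2 ** -res.translatability_log2:.1f}-fold TE reduction): protein down, "
      "mRNA up means translation fell more than either alone suggests")

# ribosome occupancy before/after glucose readdition (construction truth 8x)
starved = rt.gen_region_counts(cfg, {"GLC3": 0.25})[0]
readd = rt.gen_region_counts(cfg, {"GLC3": 2.0})[0]
occ_s, occ_r = rt.ribosome_occupancy(starved), rt.ribosome_occupancy(readd)
print(f"ribosome occupancy: starved {occ_s:.2f}, +glucose {occ_r:.2f} "
      f"({occ_r / occ_s:.0f}-fold increase on readdition)")

# granule foci fractions
cmpf = rt.compare_foci([0.26, 0.28], [0.04, 0.04], method="t")
print(f"foci: {cmpf.fraction_a:.0%} vs {cmpf.fraction_b:.0%} of cells, "
      f"p = {cmpf.p_value:.3f} (replicate t-test)")
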