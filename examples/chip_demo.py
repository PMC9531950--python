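"""Promoter-window ChIP enrichment and a class-level contrast.

Generates a synthetic genome where one gene class carries 4-fold elevated
target coverage in the [TSS-500, TSS) window, then recovers the per-gene
log2 enrichments over a mock-IP control and tests class II against class I.
"""

import numpy as np

import rvbtools as rt

cfg = rt.GeneratorConfig(seed=12, noise_cv=0.05, depth=1_000_000)
genes, tracks = rt.gen_genome_coverage(cfg, {"class_II": 4.0})

enr = rt.promoter_enrichment(tracks["target"], tracks["control"], genes)
cls2 = [e.log2_ratio for e in enr if e.class_label == "class_II"]
cls1 = [e.log2_ratio for e in enr if e.class_label == "class_I"]
print(f"class II mean promoter log2(target/control) = {np.mean(cls2):.2f} "
      "(construction truth: 2.0)")
print(f"class I  mean promoter log2(target/control) = {np.mean(cls1):.2f} "
      "(no enrichment built in)")

cmp = rt.class_compare(enr, "class_II", "class_I")
print(f"Welch t-test class II vs class I: difference = {cmp.difference:.2f} log2, "
      f"p = {cmp.p_value:.2e}")

prof = rt.metagene({"target": tracks["target"], "control": tracks["control"]},
                   [g for g in genes if g.class_label == "class_II"])
upstream_peak = prof.summary()["mean"][: prof.n_upstream].max()
body_mean = prof.summary()["mean"][prof.n_upstream : prof.n_upstream + prof.n_body].mean()
print(f"metagene: upstream peak density {upstream_peak:.1f} vs body mean "
      f"{body_mean:.2f} -- the signal sits in the -500..TSS promoter segment")
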