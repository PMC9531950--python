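"""CoTrIP proteomics screen: volcano coordinates and the candidate list.

Simulates spectral counts for a promoter-comparison screen (2 replicates of
the query promoter vs 3 of the reference promoters), computes per-protein
fold changes and Welch p-values, and filters against a background table.
"""

import pandas as pd

import rvbtools as rt

# construction: RVB1/RVB2 enriched ~10x on the query promoter; two sticky
# background proteins equally abundant everywhere
means = pd.DataFrame(
    {"GLC3": [55.0, 48.0, 30.0, 25.0], "HSP": [5.0, 5.0, 30.0, 25.0]},
    index=["RVB1", "RVB2", "SSA1", "TDH3"],
)
cfg = rt.GeneratorConfig(seed=8, noise_cv=0.1)
table = rt.gen_spectral_table(cfg, means, {"GLC3": 2, "HSP": 3}, dispersion=0.005)

volcano = rt.enrichment_volcano(table, "GLC3", "HSP")
print(volcano[["log2_fc", "p_value", "neg_log10_p"]].round(3))

hits = rt.candidates(volcano, p_threshold=0.05)
print(f"\ncandidates at p < 0.05, ranked by fold change: {list(hits.index)}")

background = {"SSA1": 30.0, "TDH3": 25.0, "RVB1": 3.0, "RVB2": 3.0}
kept = rt.background_filter(hits, background, min_fc=4.0)
print(f"surviving the background (contaminant) filter: {list(kept.index)}")
print("proteins enriched on the query promoter AND above background are the")
print("co-transcriptionally loaded factor candidates")
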