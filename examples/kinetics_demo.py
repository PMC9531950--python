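"""Fit induction/decay kinetics and classify the regulatory mechanism.

Simulates a stress-induced transcript (25-min half-life, strong induction),
recovers its parameters from a noisy fold-induction course, measures the
half-life from a transcription-shutoff chase, and asks whether a treated
condition differs by transcription rate or decay rate.
"""

import math

import numpy as np

import rvbtools as rt

LN2 = math.log(2.0)
GRID = (0.0, 5.0, 10.0, 15.0, 30.0, 45.0)

# -- parameter recovery from a noisy induction course ------------------------
true = rt.InductionModel(alpha=0.1, beta=0.1 * 16, x0=1.0)  # fold_ss = 16
cfg = rt.GeneratorConfig(seed=1, noise_cv=0.05, n_replicates=4, time_grid=GRID)
course = rt.gen_timecourse(cfg, true, "induction")
fit = rt.fit_induction(course)
print(f"induction fit: alpha = {fit.alpha_hat:.4f}/min (true 0.1), "
      f"steady-state fold = {fit.fss_hat:.2f} (true 16)")

# -- half-life from a decay chase ---------------------------------------------
chase = rt.simulate_decay(rt.InductionModel(LN2 / 25, 0.0, 1.0), np.arange(0, 50, 5))
decay = rt.fit_decay(chase)
print(f"decay fit: half-life = {decay.half_life:.1f} min "
      "(log2-linear regression after transcription shutoff)")

# -- transcription-shift vs decay-shift diagnostic ----------------------------
base = rt.InductionModel(LN2 / 25, (LN2 / 25) * 200, 1.0)
ctrl = rt.gen_timecourse(cfg, base, "induction")
treated_model = rt.InductionModel(base.alpha, base.beta * 4, 1.0)  # beta x4
trt = rt.gen_timecourse(
    rt.GeneratorConfig(seed=2, noise_cv=0.05, n_replicates=4, time_grid=GRID),
    treated_model, "induction",
)
call = rt.classify_mechanism(ctrl, trt)
print(f"mechanism call: {call.call} "
      f"(mean log2 offset {call.mean_shift_log2:.2f}, trend p = {call.trend_p:.2f})")
print("a constant ~2 log2 offset with no time trend means the treatment raised")
print("the transcription rate ~4-fold without touching mRNA stability")
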