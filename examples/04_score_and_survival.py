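"""Median scoring and survival analysis on a table-level cohort.

Simulates survival with a known hazard ratio of 0.25 between latent
density groups, dichotomises TP25 densities at the median, forms the
combined GZMB/CD68 score, and runs Kaplan-Meier / log-rank / Cox.
"""

import numpy as np
import pandas as pd

from periscore import (SimulationConfig, cox_fit, dichotomize_at_median,
                       log_rank_test, median_follow_up)
from periscore.scoring import combine_gzmb_cd68
from periscore.synthetic import assign_latent_groups, simulate_survival

config = SimulationConfig(seed=4, n_patients=200,
                          hazard_ratio_high_vs_low=0.25, censor_rate=0.2)
groups = assign_latent_groups(config)
records = simulate_survival(config, groups)

# emulate measured TP25 densities: the high group carries ~3x density
rng = np.random.default_rng(config.seed)
gzmb = pd.Series(rng.lognormal(4.0 + (groups == "high") * np.log(3.0), 0.4))
cd68 = pd.Series(rng.lognormal(4.5 + (groups == "high") * np.log(3.0), 0.4))
g_gzmb = dichotomize_at_median(gzmb)
g_cd68 = dichotomize_at_median(cd68)
combined = np.array([combine_gzmb_cd68(a, b) for a, b in zip(g_gzmb, g_cd68)])
print(f"combined GZMB/CD68 high: {(combined == 'high').sum()}"
      f"/{len(combined)} patients")

lr = log_rank_test(records, combined)
for r, g in zip(records, combined):
    r.covariates["combined"] = 1 if g == "high" else 0
fit = cox_fit(records, ["combined"])
lo, hi = fit.conf_int[0]
print(f"median follow-up (reverse KM): {median_follow_up(records):.1f} months")
print(f"log-rank: chi2 = {lr.statistic:.1f}, p = {lr.p_value:.2e}")
print(f"Cox HR (high vs low) = {fit.hazard_ratios[0]:.3f} "
      f"[{lo:.3f}, {hi:.3f}], p = {fit.p_values[0]:.2e}")
# The HR should sit near the simulated 0.25: high combined score,
# longer survival - the pattern the scoring system is built to detect.
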