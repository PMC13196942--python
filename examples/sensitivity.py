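"""Sensitivity analysis: OFAT signature factors and a small PRCC design.

Sweeps cooking skill and meal variety one at a time (all else at defaults)
and then jointly varies supermarkets, friends and the replenishment cycle to
estimate partial rank correlations with the meal and inventory outputs.
"""

import numpy as np

from dinnersim import SimConfig
from dinnersim.experiments import ofat_trends, run_ofat, run_prcc_experiment

cfg = SimConfig(years=3)  # three simulated years keep this demo quick

df = run_ofat(cfg, factors={"cooking_skill": [0.0, 0.2, 0.4, 0.6, 0.8, 1.0],
                            "meal_variety": [0.1, 0.3, 0.5]}, replicates=3, base_seed=7)
skill = df[df.factor == "cooking_skill"].groupby("level")["pct_enjoying"].median()
print("share enjoying dinner vs population cooking skill (S-curve):")
for level, value in skill.items():
    print(f"  skill {level:.1f}: {value * 100:5.1f}%")

trends = ofat_trends(df[df.factor == "meal_variety"], outcome="pct_enjoying")
print(f"\nmeal variety vs enjoyment: Spearman rho = {trends['spearman_rho'].iloc[0]:+.2f} "
      f"(p = {trends['p_value'].iloc[0]:.2f}; no trend expected)")

levels = {"n_supermarkets": [1, 6, 11], "n_friends": [0, 7, 15], "replenishment_cycle": [1, 6, 12]}
samples, coefs = run_prcc_experiment(cfg, levels=levels, replicates=2, base_seed=11)
print(f"\nPRCC over a {3}x{3}x{3} factorial design ({len(samples)} runs):")
print(coefs.pivot(index="parameter", columns="output", values="prcc").round(2))

# Enjoyment follows a probit S-curve in cooking skill and is flat in meal
# variety.  The PRCC table shows each parameter's monotone influence on meat
# and non-meat meals/inventories after controlling for the other two.
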