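"""Cross-level statistics on simulated hybrid-dysgenesis assays.

Six maternal lines with distinct dysgenesis logits are crossed to three
tester sublines (dysgenic direction) and reciprocally; per-line dysgenic
proportions, Fisher exact tests against the reciprocal cross, and the
binomial-GLM likelihood-ratio test for a maternal-line effect follow.
"""

import numpy as np

from pirnahd import (CrossDesign, classify_extremes, line_effect_glm,
                     line_resistance, reciprocal_fisher,
                     simulate_cross_counts)

design = CrossDesign(
    lines={"Lps5": -2.0, "SGA27": -1.2, "Hin17": -0.6,
           "SGA20": 0.6, "SGA14": 1.2, "SGA26": 2.0},
    tester_sublines={"T1": 0.0, "T2": 0.3, "T3": -0.3},
    n_f1_per_cross=100, reciprocal_logit=-4.0, seed=6)
crosses = simulate_cross_counts(design)

summary = reciprocal_fisher(crosses)
summary["resistance"] = line_resistance(crosses)
print(summary.round(4).to_string())

glm = line_effect_glm(crosses)
print(f"\nline-effect LRT: stat={glm.lrt_stat:.1f}, df={glm.df}, "
      f"p={glm.p_value:.3g}")

extremes = classify_extremes(
    (1 - summary["resistance"]).to_dict(), k=2)
print(f"most resistant lines:  {extremes.resistant}")
print(f"most susceptible:      {extremes.susceptible}")

# A line is scored dysgenic-responsive when significantly more F1 females
# lack ovaries in the dysgenic direction than in the reciprocal cross
# (Fisher p < 0.05); the LRT asks whether maternal line explains variation
# in dysgenesis beyond tester-subline differences.
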