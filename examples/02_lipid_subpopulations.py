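"""Detect lipid-poor vs lipid-rich subpopulations in per-cell intensities.

Simulates the bimodal integrated-lipid histogram characteristic of a partly
resistant cell population, fits log-normal mixtures for k = 1..4 and selects
k by BIC, then compares two conditions differing in their lipid-rich
fraction (a cisplatin-treatment-like shift).
"""

import numpy as np
import pandas as pd

import srscell as sc

values, true_labels = sc.generate_population_intensities(
    weights=(0.6, 0.4), log_means=(1.0, 3.3), log_sd=0.3, n=600, seed=7
)
fit = sc.classify_subpopulations(values, seed=0)
print(f"selected k = {fit.k_selected} (BIC per k: "
      + ", ".join(f"{k}: {v:.1f}" for k, v in fit.criterion.items()) + ")")
print(f"weights: lipid-poor {fit.weights[0]:.3f}, lipid-rich {fit.weights[1]:.3f}"
      f"  (truth: 0.600 / 0.400)")

hist = sc.population_histogram(np.log(values), binning=25)
bars = (hist["count"] * 40 // hist["count"].max()).astype(int)
for left, n in zip(hist["bin_left"], bars):
    print(f"log I = {left:5.2f} | {'#' * n}")

before = pd.DataFrame({"integrated_lipid": values})
after_vals, _ = sc.generate_population_intensities(
    weights=(0.3, 0.7), log_means=(1.0, 3.3), log_sd=0.3, n=600, seed=8
)
after = pd.DataFrame({"integrated_lipid": after_vals})
cmp = sc.compare_populations(before, after, "integrated_lipid", seed=0)
print(f"\nlipid-rich fraction: {cmp.fraction_a:.3f} -> {cmp.fraction_b:.3f}, "
      f"shift {cmp.difference:+.3f} (95% CI {cmp.ci_low:+.3f}..{cmp.ci_high:+.3f}), "
      f"Welch t p = {cmp.p_value:.2e}")
print("A positive shift means the treated/resistant population gained "
      "lipid-rich cells.")
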