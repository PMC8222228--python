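"""Compare two SEP sets with the between/within Euclidean-distance t-test.

Two sets from the same profile family should not be separated; two sets
with mirrored L-shaped means (early peak vs late peak) should be.
"""

import numpy as np

from sepkit import analyze_2_seps, sample_sep_set

rng = np.random.default_rng(0)

same_a = sample_sep_set("ISSDSS", 10, "same-family A", rng=rng)
same_b = sample_sep_set("ISSDSS", 10, "same-family B", rng=rng)
null = analyze_2_seps(same_a, same_b, with_wilcoxon=True)
print("same family:    "
      f"mean(D_B)={null.mean_d_between:.3f} vs mean(D_W)={null.mean_d_within:.3f}, "
      f"t={null.t_statistic:.2f}, one-tailed p={null.p_value:.3f}")

early = sample_sep_set("DSSSSS", 10, "early peak", fold_change=8.0, rng=rng)
late = sample_sep_set("DSSSSI", 10, "late peak", fold_change=8.0, rng=rng)
res = analyze_2_seps(early, late, with_wilcoxon=True)
print("mirrored L:     "
      f"mean(D_B)={res.mean_d_between:.3f} vs mean(D_W)={res.mean_d_within:.3f}, "
      f"t={res.t_statistic:.2f}, one-tailed p={res.p_value:.2e} "
      f"(Wilcoxon corroboration p={res.wilcoxon_p:.2e})")

print("\nD_B holds all k*r cross-set distances, D_W the pooled within-set "
      "pairs; exchangeable sets give p near 0.5, divergent mean profiles "
      "give vanishing p.")
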