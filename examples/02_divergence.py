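"""Compare per-cytokine recovery trajectories between groups.

Computes the resampled intra/inter-group distance distributions for each
cytokine (11 subsets of 10 subjects per group, repeated 11 times) and the
two-sample tests of inter vs pooled-intra separation.
"""

from immunet import default_cohort_spec, emit_cohort, preprocess
from immunet.divergence import divergence_table, resampled_distance_distributions

panel, _ = emit_cohort(default_cohort_spec(seed=1, distinct_groups=True))
series = preprocess(panel)
hc = [s for s in series if s.group == "HC"]
gwi = [s for s in series if s.group == "GWI"]

dists = resampled_distance_distributions(hc, gwi, seed=1)
table = divergence_table(dists)
cols = ["cytokine", "pooled_intra_mean", "inter_mean", "ranksum_p"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.3g}"))
n_sig = int((table["ranksum_p"] < 0.05).sum())
print(f"\n{n_sig}/16 cytokines show inter-group trajectory divergence "
      "beyond within-group spread (rank-sum p < 0.05).")
# Distances are a [0,1] semi-metric on trajectories: 0 = identical curves.
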