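"""Treatment-cohort analysis on simulated longitudinal vessel networks.

Simulates control, sprouting-increased and sprouting-decreased groups,
runs the radial-filtration pipeline on every network, and applies the
group-comparison battery (Kruskal-Wallis + pairwise Wilcoxon rank-sum
against control, level 0.05, no multiplicity correction).
"""

import vesseltopo as vt
from vesseltopo import synthetic as syn

cohort = syn.make_cohort(n_per_group=5, days=(0, 4), effect=0.5, seed=11)
day4 = cohort[cohort.day == 4]
table = vt.descriptor_table(day4, n_steps=500)

print("median loops per segment on day 4:")
print(table.groupby("group").loops_per_segment.median().round(3))

report = vt.group_tests(table, "loops_per_segment")
print("\ngroup tests:")
print(report.to_frame().to_string(index=False))
print("\nThe +50% loop-density group separates from control at n=5 per")
print("group; the loop descriptor normalizes by segment count, so the")
print("signal is loop density, not network size.")

# descriptor correlation structure, clustered
corr = vt.correlation_heatmap(
    table[["tortuosity_topological", "loops_per_segment", "n_loops",
           "n_segments", "clr_mean", "soam_mean"]])
print("\ncomplete-linkage leaf order:", corr.leaf_order)
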