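"""Undirected functional-connectivity analysis of a synthetic cohort.

Simulates the reference cohort, runs the temporal preprocessing chain
(discard 10 volumes, detrend, signal-change ratio, 0.01-0.08 Hz
band-pass, demean), computes per-subject Pearson matrices, Fisher-z
transforms them, forms the group Z-matrix (cross-subject mean / SD) and
lists the ROI pairs surviving Bonferroni correction at P < .005.
"""

import numpy as np

from restconn import (
    build_var_model,
    cohort_correlations,
    correlation_edges,
    group_z_matrix,
    preprocess,
    sensory_pattern_graph,
    simulate_cohort,
)

spec = sensory_pattern_graph()
cohort = simulate_cohort(build_var_model(spec), 29, 200, seed=2)
filtered = preprocess(cohort)  # discard -> detrend -> ratio -> band-pass -> demean

gz = group_z_matrix(cohort_correlations(filtered))
edges = correlation_edges(gz, alpha_family=0.005)

print(f"{len(edges)} of {gz.n_pairs} ROI pairs survive Bonferroni P < .005")
print("strongest pairs (Z = cross-subject mean Fisher-z / SD):")
ranked = sorted(edges, key=lambda e: -abs(e.weight))[:5]
for e in ranked:
    sign = "+" if e.sign > 0 else "-"
    print(f"  {e.source:>18s} -- {e.target:<18s} Z={e.weight:+.2f} ({sign}) "
          f"tier {e.tier}")
# Positive Z means the two regions fluctuate together across subjects;
# negative Z marks anticorrelated regions (e.g. olfactory vs the other
# sensory cortices in this network). Tier 3 = corrected p < 1e-4.
idx = {lab: i for i, lab in enumerate(gz.roi_labels)}
z_hom = gz.Z[idx["visual_L"], idx["visual_R"]]
print(f"left/right visual homologue Z = {z_hom:.2f} "
      "(bilateral homologues are reliably positively coupled)")
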