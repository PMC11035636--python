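"""Lipidome diversity (H_j) and specialization (delta_j) per culture.

H_j is the Shannon entropy of a sample's lipid frequency distribution;
delta_j weights each lipid's cross-sample specificity S_i by its
frequency.  A symbiont that recruits a narrow subset of host lipids
shows low diversity and low specialization; a co-culture rich in
condition-exclusive species scores high on both.
"""

import halolipidome as hl
from halolipidome.simulate import INTERNAL_STANDARD_ID

design = hl.default_design(seed=1)
table, truth = hl.simulate_lipidome(design)
merged, _ = hl.merge_adducts(hl.correct_recovery(table, INTERNAL_STANDARD_ID))

profile = hl.relative_abundance(merged)
result = hl.compute_indices(profile)

groups = merged.sample_meta["group"]
summary = hl.bootstrap_errorbars(profile, merged.groups())
for group, row in summary.iterrows():
    print(f"{group:>10s}:  H = {row['H_mean']:.2f} ± {row['H_sd']:.2f} bits   "
          f"delta = {row['delta_mean']:.3f} ± {row['delta_sd']:.3f} bits")
print("planted specialization ranking:", " > ".join(truth["delta_ranking"]))
# delta separates the three cultures: group-private lipids carry
# specificity up to log2(t) and pull their samples' delta upward.
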